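"""Seeded generator of demo multi-omics datasets.

Emulates the structure both layouts assume: two tissue groups (normal vs
tumor), per-gene log-ratio mRNA expression shifted between groups, one
miRNA per gene constructed anti-correlated with its gene, a two-level
methylation status correlated with group, sparse -1/+1 copy-number calls,
and a per-gene group-mean-difference ("mean fold change" of already
log-scaled values) summary column.  Default magnitudes keep values
predominantly inside the default [-3, 3] diverging-scale bounds.

All randomness flows from one ``numpy.random.default_rng(seed)``; the
same seed always yields element-wise identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dataset import (
    MatrixKind,
    OmicsMatrix,
    PlotDataSet,
    SampleAnnotation,
    SummaryData,
    assemble_dataset,
    pair_most_negative_mirna,
    validate_dataset,
)

__all__ = ["SynthParams", "generate_raw", "generate_dataset", "write_dataset"]


@dataclass(frozen=True)
class SynthParams:
    n_genes: int = 10
    n_samples: int = 30
    group_fraction: float = 0.5  # fraction of samples in the first (normal) group
    effect_size: float = 2.0  # mean log-ratio shift between groups
    noise_sd: float = 0.5
    anticorr_strength: float = 0.9  # paired miRNA = -strength * mRNA + noise
    methyl_levels: int = 2
    cnv_rate: float = 0.1  # probability a call is a gain or loss
    seed: int = 0
    summary_mode: str = "text"

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_samples < 1:
            raise ValueError("n_genes and n_samples must be >= 1")
        if not 0 < self.group_fraction < 1:
            raise ValueError("group_fraction must be in (0, 1)")
        if not 0 <= self.anticorr_strength <= 1:
            raise ValueError("anticorr_strength must be in [0, 1]")
        if not 0 <= self.cnv_rate <= 1:
            raise ValueError("cnv_rate must be in [0, 1]")
        if self.methyl_levels < 2:
            raise ValueError("methyl_levels must be >= 2")


def _ids(prefix: str, n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def generate_raw(p: SynthParams):
    """Raw matrices plus ground truth, before assembly.

    Returns ``(mrna, mirna, methyl, cnv, annotation, truth)`` where
    ``truth`` holds the per-gene group effect ("effect": signed shift of
    tumor minus normal means) and the true gene -> miRNA pairing
    ("pairing").  The miRNA matrix is keyed by miRNA ids (one per gene);
    pairing must be recovered downstream by correlation.
    """
    rng = np.random.default_rng(p.seed)
    genes = _ids("Gene", p.n_genes)
    samples = _ids("Sample", p.n_samples)
    mirnas = [f"miR-{g[4:]}" for g in genes]
    n1 = max(1, min(p.n_samples - 1, round(p.group_fraction * p.n_samples)))
    groups = np.array([0] * n1 + [1] * (p.n_samples - n1))

    # alternate effect sign per gene so the heatmap shows both directions
    sign = np.where(np.arange(p.n_genes) % 2 == 0, 1.0, -1.0)
    effect = sign * p.effect_size
    baseline = rng.normal(0.0, 0.3, size=p.n_genes)
    mrna_vals = (
        baseline[:, None]
        + np.where(groups[None, :] == 1, effect[:, None] / 2, -effect[:, None] / 2)
        + rng.normal(0.0, p.noise_sd, size=(p.n_genes, p.n_samples))
    )
    mirna_vals = (
        -p.anticorr_strength * mrna_vals
        + rng.normal(0.0, p.noise_sd, size=(p.n_genes, p.n_samples))
    )

    # methylation: high status enriched in the tumor group
    p_high = np.where(groups == 1, 0.8, 0.2)
    methyl_vals = rng.binomial(p.methyl_levels - 1, p_high[None, :],
                               size=(p.n_genes, p.n_samples))

    hit = rng.random((p.n_genes, p.n_samples)) < p.cnv_rate
    gain = rng.random((p.n_genes, p.n_samples)) < 0.5
    cnv_vals = np.where(hit, np.where(gain, 1, -1), 0).astype(int)

    levels = (("Methyl L", "Methyl H") if p.methyl_levels == 2
              else tuple(f"Methyl {i}" for i in range(p.methyl_levels)))
    mrna = OmicsMatrix("RNASeq", MatrixKind.CONTINUOUS,
                       pd.DataFrame(mrna_vals, index=genes, columns=samples))
    mirna = OmicsMatrix("miRNASeq", MatrixKind.CONTINUOUS,
                        pd.DataFrame(mirna_vals, index=mirnas, columns=samples))
    methyl = OmicsMatrix("Methylation", MatrixKind.CATEGORY,
                         pd.DataFrame(methyl_vals, index=genes, columns=samples),
                         category_labels=levels)
    cnv = OmicsMatrix("CNV", MatrixKind.BINARY,
                      pd.DataFrame(cnv_vals, index=genes, columns=samples))

    sex = np.where(rng.random(p.n_samples) < 0.5, "Female", "Male")
    annotation = SampleAnnotation(pd.DataFrame(
        {
            "Tissue Type": np.where(groups == 0, "Normal", "Tumor"),
            "Sex": sex,
        },
        index=samples,
    ))
    truth = {
        "effect": dict(zip(genes, effect)),
        "pairing": dict(zip(genes, mirnas)),
        "groups": dict(zip(samples, groups.tolist())),
    }
    return mrna, mirna, methyl, cnv, annotation, truth


def generate_dataset(p: SynthParams) -> PlotDataSet:
    """A ready-to-plot dataset: raw generation, miRNA pairing, assembly.

    The summary column is the per-gene mean difference of the (already
    log-scaled) mRNA values, tumor minus normal, to 2 decimals in text
    mode.
    """
    mrna, mirna, methyl, cnv, annotation, truth = generate_raw(p)
    pairing, paired = pair_most_negative_mirna(mrna, mirna)
    groups = np.array([truth["groups"][s] for s in mrna.col_ids])
    v = mrna.values
    diff = v[:, groups == 1].mean(axis=1) - v[:, groups == 0].mean(axis=1)
    if p.summary_mode == "text":
        per_gene: dict[str, object] = {
            g: f"{d:.2f}" for g, d in zip(mrna.row_ids, diff)
        }
    else:
        per_gene = {g: float(d) for g, d in zip(mrna.row_ids, diff)}
    summary = SummaryData(per_gene=per_gene, mode=p.summary_mode,
                          label="Mean fold change")
    return assemble_dataset(
        gene_ids=mrna.row_ids,
        sample_ids=mrna.col_ids,
        annotation=annotation,
        raw_matrices=[mrna, paired, methyl, cnv],
        summaries=[summary],
        mirna_pairing=pairing,
    )


# ---------------------------------------------------------------------------
# dataset directory output (tab-delimited files + YAML manifest)


def _write_matrix(m: OmicsMatrix, path: Path) -> None:
    df = m.data
    if m.kind is MatrixKind.CONTINUOUS:
        out = df.map(lambda v: "NA" if pd.isna(v) else repr(float(v)))
    else:
        out = df.astype(int).astype(str)
    out.to_csv(path, sep="\t", na_rep="NA")


def write_dataset(ds: PlotDataSet, directory: str | Path) -> Path:
    """Write the dataset as tab-delimited files plus ``manifest.yaml``.

    Reading the manifest back with :func:`omicsviz.dataset.read_dataset`
    reproduces the dataset exactly (continuous values are written with
    full ``repr`` precision).
    """
    problems = validate_dataset(ds)
    if problems:
        raise ValueError("refusing to write invalid dataset: " + "; ".join(problems))
    base = Path(directory)
    if not base.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {base.parent}")
    base.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"annotation": "annotation.tsv", "matrices": []}
    ds.annotation.data.to_csv(base / "annotation.tsv", sep="\t")
    for m in ds.matrices:
        fname = m.name.lower().replace(" ", "_") + ".tsv"
        _write_matrix(m, base / fname)
        entry = {"name": m.name, "kind": m.kind.value, "file": fname}
        if m.category_labels:
            entry["category_labels"] = list(m.category_labels)
        manifest["matrices"].append(entry)
    if ds.summaries:
        manifest["summaries"] = []
        for i, s in enumerate(ds.summaries):
            fname = f"summary_{i + 1}.tsv"
            pd.Series({g: s.per_gene[g] for g in ds.gene_ids},
                      name=s.label or "value").rename_axis("gene").to_csv(
                base / fname, sep="\t")
            manifest["summaries"].append(
                {"file": fname, "mode": s.mode, "label": s.label}
            )
    if ds.mirna_pairing:
        pd.Series({g: ds.mirna_pairing[g] for g in ds.gene_ids},
                  name="mirna").rename_axis("gene").to_csv(
            base / "pairing.tsv", sep="\t")
        manifest["pairing"] = "pairing.tsv"
    (base / "manifest.yaml").write_text(
        yaml.safe_dump(manifest, sort_keys=False), encoding="utf-8")
    return base / "manifest.yaml"
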