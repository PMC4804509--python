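import numpy as np
import pandas as pd
import pytest

from omicsviz.colors import category_palette_for
from omicsviz.dataset import (
    MatrixKind,
    OmicsMatrix,
    PlotDataSet,
    SampleAnnotation,
    SummaryData,
)


def make_matrix(name, kind, values, genes=None, samples=None, labels=()):
    values = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return OmicsMatrix(
        name=name, kind=kind,
        data=pd.DataFrame(values, index=genes, columns=samples),
        category_labels=tuple(labels),
    )


def make_dataset(n_genes=3, n_samples=4, n_features=2, seed=0,
                 cnv=None, summary_mode="text"):
    """Hand-built dataset with an arbitrary clinical-feature count,
    used by property tests that vary F beyond what the generator emits."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{i}" for i in range(n_samples)]
    mrna = make_matrix("RNASeq", MatrixKind.CONTINUOUS,
                       rng.normal(0, 1.2, (n_genes, n_samples)), genes, samples)
    mirna = make_matrix("miRNASeq", MatrixKind.CONTINUOUS,
                        -mrna.values + rng.normal(0, 0.2, (n_genes, n_samples)),
                        genes, samples)
    methyl = make_matrix("Methylation", MatrixKind.CATEGORY,
                         rng.integers(0, 2, (n_genes, n_samples)), genes, samples,
                         labels=("Methyl L", "Methyl H"))
    if cnv is None:
        cnv = rng.choice([-1, 0, 1], size=(n_genes, n_samples), p=[0.1, 0.8, 0.1])
    cnvm = make_matrix("CNV", MatrixKind.BINARY, np.asarray(cnv), genes, samples)
    feats = {}
    feats["Tissue Type"] = ["Normal" if i < n_samples / 2 else "Tumor"
                            for i in range(n_samples)]
    for f in range(1, n_features):
        feats[f"Feature{f}"] = list(rng.choice(["A", "B"], size=n_samples))
    ann = SampleAnnotation(pd.DataFrame(dict(list(feats.items())[:max(n_features, 1)]),
                                        index=samples))
    if summary_mode == "text":
        per_gene = {g: f"{v:.2f}" for g, v in zip(genes, rng.normal(0, 1, n_genes))}
    else:
        per_gene = {g: float(v) for g, v in zip(genes, rng.normal(0, 1, n_genes))}
    summary = SummaryData(per_gene=per_gene, mode=summary_mode, label="Mean fold change")
    return PlotDataSet(
        sample_ids=samples, gene_ids=genes, annotation=ann,
        matrices=[mrna, mirna, methyl, cnvm], summaries=[summary],
        mirna_pairing={g: f"mir_{g}" for g in genes},
    )


@pytest.fixture
def small_dataset():
    return make_dataset(n_genes=3, n_samples=4, seed=7)


@pytest.fixture
def feature_palettes():
    return {"Tissue Type": category_palette_for(["Normal", "Tumor"])}
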