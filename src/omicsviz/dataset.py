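"""Integrated multi-omics data model and data preparation.

The central container is :class:`PlotDataSet`: a sample-aligned bundle of
modality matrices (mRNA and miRNA expression as continuous log-ratios,
methylation status as small-integer category codes, copy-number calls as
-1/0/+1), a sample annotation table of clinical features, and optional
per-gene summary values.  Both plot layouts consume this one structure.

Data preparation mirrors the usual workflow: pull gene/sample subsets out
of large matrices, pair each gene with its most negatively correlated
miRNA, sort samples by a clinical feature, and assemble everything into an
aligned bundle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import rankdata

__all__ = [
    "MatrixKind",
    "OmicsMatrix",
    "SampleAnnotation",
    "SummaryData",
    "PlotDataSet",
    "assemble_dataset",
    "extract_subset",
    "sort_dataset",
    "pair_most_negative_mirna",
    "validate_dataset",
    "read_dataset",
    "read_matrix",
]


class MatrixKind(str, Enum):
    CONTINUOUS = "continuous"
    CATEGORY = "category"
    BINARY = "binary"


def _check_unique(ids, what: str, where: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id {i!r} in {where}")
        seen.add(i)


@dataclass
class OmicsMatrix:
    """One modality's gene x sample values.

    ``data`` is a DataFrame with gene ids as index and sample ids as
    columns.  ``kind`` declares the value domain: real numbers (NaN
    permitted) for continuous, non-negative integer codes with a
    ``category_labels`` table for category, and {-1, 0, +1} for binary
    loss/neutral/gain calls.
    """

    name: str
    kind: MatrixKind
    data: pd.DataFrame
    category_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.kind = MatrixKind(self.kind)
        _check_unique(self.data.index, "row", self.name)
        _check_unique(self.data.columns, "column", self.name)
        for msg in self.check_values():
            raise ValueError(msg)

    def check_values(self) -> list[str]:
        """Domain violations as messages (empty when the grid is legal)."""
        v = self.data.to_numpy()
        msgs: list[str] = []
        if self.kind is MatrixKind.BINARY:
            ok = np.isin(v, (-1, 0, 1)) & ~pd.isna(v)
            if not ok.all():
                bad = v[~ok].ravel()[0]
                msgs.append(
                    f"matrix {self.name!r} (binary) contains value {bad!r}; "
                    "allowed: -1, 0, +1"
                )
        elif self.kind is MatrixKind.CATEGORY:
            if pd.isna(v).any():
                msgs.append(f"matrix {self.name!r} (category) contains missing values")
            else:
                iv = v.astype(float)
                if not np.array_equal(iv, np.round(iv)) or (iv < 0).any():
                    msgs.append(
                        f"matrix {self.name!r} (category) codes must be "
                        "non-negative integers"
                    )
                elif self.category_labels and iv.max(initial=0) >= len(self.category_labels):
                    msgs.append(
                        f"matrix {self.name!r} code {int(iv.max())} has no label "
                        f"(label table has {len(self.category_labels)} entries)"
                    )
        return msgs

    @property
    def row_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def max_code(self) -> int:
        if self.kind is not MatrixKind.CATEGORY:
            raise ValueError(f"matrix {self.name!r} is not categorical")
        if self.category_labels:
            return len(self.category_labels) - 1
        return int(self.data.to_numpy().max())


@dataclass
class SampleAnnotation:
    """Per-sample clinical features; ``data`` index = sample ids."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample", "annotation")
        _check_unique(self.data.columns, "feature", "annotation")

    @property
    def col_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def labels(self, feature: str) -> list[str]:
        if feature not in self.data.columns:
            raise KeyError(f"unknown annotation feature {feature!r}")
        return [str(v) for v in self.data[feature]]

    def categories(self, feature: str) -> list[str]:
        """Distinct labels in first-appearance order."""
        out: list[str] = []
        for v in self.labels(feature):
            if v not in out:
                out.append(v)
        return out


@dataclass
class SummaryData:
    """Per-gene derived values shown in the matrix summary column."""

    per_gene: dict[str, object]
    mode: str = "text"  # text | bar
    label: str = ""

    def __post_init__(self) -> None:
        if self.mode not in ("text", "bar"):
            raise ValueError(f"summary mode must be 'text' or 'bar', got {self.mode!r}")
        if self.mode == "bar":
            for g, v in self.per_gene.items():
                if not np.isfinite(float(v)):
                    raise ValueError(f"bar summary value for {g!r} is not finite")


@dataclass
class PlotDataSet:
    """Aligned bundle of everything one plot needs."""

    sample_ids: list[str]
    gene_ids: list[str]
    annotation: SampleAnnotation
    matrices: list[OmicsMatrix]
    summaries: list[SummaryData] = field(default_factory=list)
    mirna_pairing: dict[str, str] | None = None

    def matrix(self, name: str) -> OmicsMatrix:
        for m in self.matrices:
            if m.name == name:
                return m
        raise KeyError(
            f"no matrix named {name!r}; have {[m.name for m in self.matrices]}"
        )

    def matrices_of_kind(self, kind: MatrixKind) -> list[OmicsMatrix]:
        return [m for m in self.matrices if m.kind is kind]


# ---------------------------------------------------------------------------
# operations


def extract_subset(matrix: OmicsMatrix, gene_ids, sample_ids) -> OmicsMatrix:
    """Subset rows/columns in the requested order, values preserved."""
    gene_ids, sample_ids = list(gene_ids), list(sample_ids)
    _check_unique(gene_ids, "requested gene", matrix.name)
    _check_unique(sample_ids, "requested sample", matrix.name)
    for g in gene_ids:
        if g not in matrix.data.index:
            raise KeyError(f"gene {g!r} not in matrix {matrix.name!r}")
    for s in sample_ids:
        if s not in matrix.data.columns:
            raise KeyError(f"sample {s!r} not in matrix {matrix.name!r}")
    return replace(matrix, data=matrix.data.loc[gene_ids, sample_ids].copy())


def assemble_dataset(
    gene_ids,
    sample_ids,
    annotation: SampleAnnotation | pd.DataFrame,
    raw_matrices: list[OmicsMatrix],
    summaries: list[SummaryData] | None = None,
    mirna_pairing: dict[str, str] | None = None,
) -> PlotDataSet:
    """Build an aligned :class:`PlotDataSet` from raw matrices.

    Every matrix is re-ordered (rows to ``gene_ids``, columns to
    ``sample_ids``); missing ids raise an error naming the id and the
    offending matrix.  Values are never re-sorted, only permuted.
    """
    gene_ids, sample_ids = list(gene_ids), list(sample_ids)
    _check_unique(gene_ids, "gene", "request")
    _check_unique(sample_ids, "sample", "request")
    if isinstance(annotation, pd.DataFrame):
        annotation = SampleAnnotation(annotation)
    for s in sample_ids:
        if s not in annotation.data.index:
            raise KeyError(f"sample {s!r} not in annotation table")
    ann = SampleAnnotation(annotation.data.loc[sample_ids].copy())
    aligned = [extract_subset(m, gene_ids, sample_ids) for m in raw_matrices]
    ds = PlotDataSet(
        sample_ids=sample_ids,
        gene_ids=gene_ids,
        annotation=ann,
        matrices=aligned,
        summaries=list(summaries or []),
        mirna_pairing=dict(mirna_pairing) if mirna_pairing else None,
    )
    problems = validate_dataset(ds)
    if problems:
        raise ValueError("assembled dataset invalid: " + "; ".join(problems))
    return ds


def sort_dataset(
    ds: PlotDataSet,
    by_feature: str,
    within: str | None = None,
    category_order: list[str] | None = None,
) -> PlotDataSet:
    """Stably group samples by an annotation feature.

    Category order defaults to first appearance; an explicit
    ``category_order`` overrides it.  ``within`` names an optional
    secondary feature used to order samples inside each group.  One
    identical column permutation is applied to every matrix and to the
    annotation; gene order is untouched.
    """
    labels = ds.annotation.labels(by_feature)  # raises on unknown feature
    cats = category_order or ds.annotation.categories(by_feature)
    rank = {c: i for i, c in enumerate(cats)}
    for lab in labels:
        if lab not in rank:
            raise ValueError(
                f"label {lab!r} of feature {by_feature!r} missing from "
                f"explicit category order {cats}"
            )
    if within is not None:
        sub = ds.annotation.labels(within)
        sub_cats = ds.annotation.categories(within)
        sub_rank = {c: i for i, c in enumerate(sub_cats)}
        key = lambda i: (rank[labels[i]], sub_rank[sub[i]])
    else:
        key = lambda i: rank[labels[i]]
    order = sorted(range(len(ds.sample_ids)), key=key)  # Timsort: stable
    new_samples = [ds.sample_ids[i] for i in order]
    return PlotDataSet(
        sample_ids=new_samples,
        gene_ids=list(ds.gene_ids),
        annotation=SampleAnnotation(ds.annotation.data.iloc[order].copy()),
        matrices=[replace(m, data=m.data.iloc[:, order].copy()) for m in ds.matrices],
        summaries=list(ds.summaries),
        mirna_pairing=dict(ds.mirna_pairing) if ds.mirna_pairing else None,
    )


def _row_correlations(a: np.ndarray, b: np.ndarray, method: str) -> np.ndarray:
    """All-pairs correlation between rows of ``a`` and rows of ``b``."""
    if method == "spearman":
        a = np.apply_along_axis(rankdata, 1, a)
        b = np.apply_along_axis(rankdata, 1, b)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    an = np.sqrt((az**2).sum(axis=1))
    bn = np.sqrt((bz**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (az @ bz.T) / np.outer(an, bn)
    return r


def pair_most_negative_mirna(
    mrna: OmicsMatrix,
    mirna: OmicsMatrix,
    method: str = "pearson",
) -> tuple[dict[str, str], OmicsMatrix]:
    """For each gene pick the miRNA most negatively correlated with it.

    Returns the gene -> miRNA map and the selected miRNA rows re-indexed
    by the gene each one is paired with, so the result aligns with the
    mRNA matrix row-for-row.  Ties break toward the earlier miRNA row;
    zero-variance miRNA rows are skipped with a warning.
    """
    if mrna.kind is not MatrixKind.CONTINUOUS or mirna.kind is not MatrixKind.CONTINUOUS:
        raise ValueError("pairing requires two continuous matrices")
    if mrna.col_ids != mirna.col_ids:
        raise ValueError("mRNA and miRNA matrices must share the same sample order")
    if len(mrna.col_ids) < 3:
        raise ValueError("miRNA pairing needs at least 3 shared samples")
    gv = mrna.data.to_numpy(dtype=float)
    mv = mirna.data.to_numpy(dtype=float)
    for gid, row in zip(mrna.row_ids, gv):
        if np.ptp(row) == 0:
            raise ValueError(f"gene {gid!r} has zero variance; correlation undefined")
    keep = [i for i, row in enumerate(mv) if np.ptp(row) > 0]
    skipped = [mirna.row_ids[i] for i in range(len(mv)) if i not in set(keep)]
    if skipped:
        warnings.warn(
            f"skipping zero-variance miRNA rows: {skipped}", stacklevel=2
        )
    if not keep:
        raise ValueError("all miRNA rows have zero variance")
    r = _row_correlations(gv, mv[keep], method)
    pick = np.argmin(r, axis=1)  # argmin takes the first minimum: row-order tie-break
    pairing = {
        gene: mirna.row_ids[keep[j]] for gene, j in zip(mrna.row_ids, pick)
    }
    paired = pd.DataFrame(
        mv[[keep[j] for j in pick]], index=mrna.row_ids, columns=mrna.col_ids
    )
    out = OmicsMatrix(name=mirna.name, kind=MatrixKind.CONTINUOUS, data=paired)
    return pairing, out


def validate_dataset(ds: PlotDataSet) -> list[str]:
    """All invariant violations as messages; empty list means valid."""
    msgs: list[str] = []
    sample_set = set(ds.sample_ids)
    if len(sample_set) != len(ds.sample_ids):
        msgs.append("duplicate sample ids in dataset")
    if len(set(ds.gene_ids)) != len(ds.gene_ids):
        msgs.append("duplicate gene ids in dataset")
    if ds.annotation.col_ids != ds.sample_ids:
        missing = [s for s in ds.sample_ids if s not in set(ds.annotation.col_ids)]
        for s in missing:
            msgs.append(f"annotation lacks sample {s!r}")
        if not missing:
            msgs.append("annotation sample order differs from dataset sample order")
    for m in ds.matrices:
        if m.col_ids != ds.sample_ids:
            msgs.append(f"matrix {m.name!r} column ids differ from dataset sample ids")
        if m.row_ids != ds.gene_ids:
            msgs.append(f"matrix {m.name!r} row ids differ from dataset gene ids")
        msgs.extend(m.check_values())
        if m.kind is MatrixKind.CONTINUOUS:
            v = m.data.to_numpy(dtype=float)
            if np.isinf(v).any():
                msgs.append(f"matrix {m.name!r} contains infinite values")
    for s in ds.summaries:
        for g in ds.gene_ids:
            if g not in s.per_gene:
                msgs.append(f"summary {s.label!r} lacks gene {g!r}")
    return msgs


# ---------------------------------------------------------------------------
# tab-delimited I/O (manifest + matrix files)


def read_matrix(path: str | Path, name: str, kind: str,
                category_labels: tuple[str, ...] = ()) -> OmicsMatrix:
    """Read a tab-delimited matrix: first row sample ids, first column gene ids."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"],
                     keep_default_na=False, float_precision="round_trip")
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    k = MatrixKind(kind)
    if k in (MatrixKind.CATEGORY, MatrixKind.BINARY):
        df = df.astype(int)
    else:
        df = df.astype(float)
    return OmicsMatrix(name=name, kind=k, data=df,
                       category_labels=tuple(category_labels))


def read_dataset(manifest_path: str | Path) -> PlotDataSet:
    """Load a dataset directory through its manifest (YAML key-value file)."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    base = manifest_path.parent
    cfg = yaml.safe_load(manifest_path.read_text())
    ann_df = pd.read_csv(base / cfg["annotation"], sep="\t", index_col=0, dtype=str)
    ann_df.index = ann_df.index.map(str)
    annotation = SampleAnnotation(ann_df)
    matrices = []
    for entry in cfg["matrices"]:
        labels = tuple(entry.get("category_labels", ()))
        matrices.append(
            read_matrix(base / entry["file"], entry["name"], entry["kind"], labels)
        )
    summaries = []
    for entry in cfg.get("summaries", []):
        tab = pd.read_csv(base / entry["file"], sep="\t", index_col=0, dtype=str)
        col = tab.columns[0]
        if entry.get("mode", "text") == "text":
            per_gene: dict[str, object] = {str(g): str(v) for g, v in tab[col].items()}
        else:
            per_gene = {str(g): float(v) for g, v in tab[col].items()}
        summaries.append(SummaryData(per_gene=per_gene,
                                     mode=entry.get("mode", "text"),
                                     label=entry.get("label", col)))
    pairing = None
    if "pairing" in cfg:
        tab = pd.read_csv(base / cfg["pairing"], sep="\t", index_col=0, dtype=str)
        pairing = {str(g): str(v) for g, v in tab[tab.columns[0]].items()}
    gene_ids = matrices[0].row_ids
    sample_ids = matrices[0].col_ids
    ds = PlotDataSet(
        sample_ids=sample_ids,
        gene_ids=gene_ids,
        annotation=annotation,
        matrices=matrices,
        summaries=summaries,
        mirna_pairing=pairing,
    )
    problems = validate_dataset(ds)
    if problems:
        raise ValueError(
            f"dataset at {manifest_path} invalid: " + "; ".join(problems)
        )
    return ds
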