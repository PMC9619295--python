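"""Loading, validation and serialization of expression data.

An expression matrix is genes x samples (rows are genes), paired with a
sample-metadata table assigning each sample a condition (treatment or
control), a sampling week and a replicate number.  Weeks are grouped into
developmental stages (three consecutive weeks per stage by default), and
all downstream analysis is per stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

TREATMENT = "treatment"
CONTROL = "control"
CONDITIONS = (TREATMENT, CONTROL)

METADATA_COLUMNS = ("sample_id", "condition", "week", "replicate")

#: Volcano-plot categories, from most to least significant.
DEG_CATEGORIES = ("sigUp", "sigDown", "FC_UpOnly", "FC_DownOnly", "P_Only", "NoDiff")


@dataclass
class ExpressionMatrix:
    """Validated genes x samples expression matrix.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by gene id, columns by sample id, finite numeric
        values.  At least 2 genes and 2 samples.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dup}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        if df.shape[0] < 2 or df.shape[1] < 2:
            raise ValueError(
                f"need at least 2 genes and 2 samples, got {df.shape[0]} x {df.shape[1]}"
            )
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = _first_non_numeric(df)
            raise ValueError(f"non-numeric value at gene {bad[0]!r}, sample {bad[1]!r}")
        if not np.isfinite(values).all():
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"missing/non-finite value at gene {df.index[i]!r}, sample {df.columns[j]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        """Genes x samples array (M, n)."""
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.data.index]
        if missing:
            raise KeyError(f"unknown gene ids: {missing}")
        return ExpressionMatrix(self.data.loc[list(gene_ids)])

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return ExpressionMatrix(self.data[list(sample_ids)])


def _first_non_numeric(df: pd.DataFrame):
    for gene, row in df.iterrows():
        for sample, v in row.items():
            try:
                float(v)
            except (TypeError, ValueError):
                return gene, sample
    return df.index[0], df.columns[0]


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def load_expression(
    path,
    orientation: str = "genes_by_samples",
    impute_missing: bool = False,
    log2_transform: bool = False,
) -> ExpressionMatrix:
    """Load a delimited expression matrix (TSV by default, CSV by extension).

    Parameters
    ----------
    orientation : {"genes_by_samples", "samples_by_genes"}
        Layout of the file; "samples_by_genes" files are transposed on load.
    impute_missing : bool
        If True, missing entries are replaced by the per-gene mean; the
        default is to reject files with missing values.
    log2_transform : bool
        Apply ``log2(x + 1)`` after loading (off by default; values are
        otherwise used exactly as provided).
    """
    if orientation not in ("genes_by_samples", "samples_by_genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.empty:
        raise ValueError(f"empty expression file: {path}")
    if orientation == "samples_by_genes":
        df = df.T
    df = df.apply(pd.to_numeric, errors="raise")
    if impute_missing and df.isna().to_numpy().any():
        row_means = df.mean(axis=1)
        df = df.apply(lambda row: row.fillna(row_means[row.name]), axis=1)
    if log2_transform:
        df = np.log2(df + 1.0)
    expr = ExpressionMatrix(df)
    logger.info("loaded expression matrix: %d genes x %d samples", expr.n_genes, expr.n_samples)
    return expr


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.data.to_csv(path, sep=_sep_for(path))


def load_metadata(path) -> pd.DataFrame:
    """Load and validate the sample-metadata table.

    Required columns: sample_id, condition (treatment/control), week
    (positive integer), replicate (integer >= 1).
    """
    meta = pd.read_csv(path, sep=_sep_for(path))
    return validate_metadata(meta)


def validate_metadata(meta: pd.DataFrame, expr: ExpressionMatrix | None = None) -> pd.DataFrame:
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing required column(s): {missing}")
    meta = meta.copy()
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dup}")
    bad = sorted(set(meta["condition"]) - set(CONDITIONS))
    if bad:
        raise ValueError(f"unknown condition label(s) {bad}; expected {CONDITIONS}")
    meta["week"] = meta["week"].astype(int)
    meta["replicate"] = meta["replicate"].astype(int)
    if (meta["week"] < 1).any():
        raise ValueError("weeks must be positive integers")
    if (meta["replicate"] < 1).any():
        raise ValueError("replicate numbers must be >= 1")
    if expr is not None:
        unknown = sorted(set(meta["sample_id"]) - set(expr.sample_ids))
        if unknown:
            raise ValueError(f"metadata samples absent from expression matrix: {unknown}")
        absent = sorted(set(expr.sample_ids) - set(meta["sample_id"]))
        if absent:
            raise ValueError(f"expression samples absent from metadata: {absent}")
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep=_sep_for(path), index=False)


def binary_response(meta: pd.DataFrame, sample_ids) -> np.ndarray:
    """0/1 response vector aligned to ``sample_ids`` (1 = treatment)."""
    cond = meta.set_index("sample_id")["condition"]
    missing = [s for s in sample_ids if s not in cond.index]
    if missing:
        raise KeyError(f"samples missing from metadata: {missing}")
    return (cond.loc[list(sample_ids)] == TREATMENT).to_numpy().astype(int)


@dataclass(frozen=True)
class StagePartition:
    """Assignment of sampling weeks to contiguous developmental stages."""

    stages: tuple  # ordered tuple of (stage index, tuple of weeks)
    stage_of_week: dict = field(hash=False)

    @property
    def stage_indices(self) -> list[int]:
        return [s for s, _ in self.stages]

    def weeks_of(self, stage: int):
        for s, weeks in self.stages:
            if s == stage:
                return weeks
        raise KeyError(f"stage {stage} not in partition")


def partition_stages(
    meta: pd.DataFrame, weeks_per_stage: int = 3, first_week: int = 3
) -> StagePartition:
    """Partition the observed weeks into contiguous equal-width stages.

    Stage ``s`` covers weeks ``first_week + (s-1)*w .. first_week + s*w - 1``.
    With the defaults (w=3, first week 3) weeks 3-17 yield five stages.
    """
    if weeks_per_stage < 1:
        raise ValueError("weeks_per_stage must be >= 1")
    weeks = sorted(set(int(w) for w in meta["week"]))
    below = [w for w in weeks if w < first_week]
    if below:
        raise ValueError(f"week(s) {below} are below first_week={first_week}")
    n_stages = (max(weeks) - first_week) // weeks_per_stage + 1
    stages = []
    stage_of_week: dict[int, int] = {}
    for s in range(1, n_stages + 1):
        lo = first_week + (s - 1) * weeks_per_stage
        covered = tuple(w for w in range(lo, lo + weeks_per_stage) if w in weeks)
        if covered:
            stages.append((s, covered))
            for w in covered:
                stage_of_week[w] = s
    return StagePartition(stages=tuple(stages), stage_of_week=stage_of_week)


def stage_submatrix(
    expr: ExpressionMatrix, meta: pd.DataFrame, part: StagePartition, stage: int
):
    """Restrict expression and metadata to the samples of one stage.

    Column order of the full matrix is preserved.  A stage lacking either
    treatment or control samples is an error, since differential
    co-expression needs both conditions.
    """
    weeks = set(part.weeks_of(stage))
    keep = meta[meta["week"].isin(weeks)]
    sample_ids = [s for s in expr.sample_ids if s in set(keep["sample_id"])]
    counts = keep["condition"].value_counts()
    for cond in CONDITIONS:
        if counts.get(cond, 0) == 0:
            raise ValueError(f"stage {stage} has no {cond} samples")
    sub = expr.subset_samples(sample_ids)
    sub_meta = keep.set_index("sample_id").loc[sample_ids].reset_index()
    return sub, sub_meta


def log2_fold_change(
    expr: ExpressionMatrix, meta: pd.DataFrame, pseudocount: float = 1.0
) -> pd.Series:
    """Per-gene log2 fold change: ratio of mean treatment to mean control
    expression, with a pseudo-count guarding against zero means."""
    y = binary_response(meta, expr.sample_ids)
    vals = expr.values
    mean_t = vals[:, y == 1].mean(axis=1)
    mean_c = vals[:, y == 0].mean(axis=1)
    fc = (mean_t + pseudocount) / (mean_c + pseudocount)
    return pd.Series(np.log2(fc), index=expr.gene_ids, name="log2_fc")


def classify_deg(
    log2_fc: float, p_value: float, fc_cut: float = 1.0, p_cut: float = 0.05
) -> str:
    """Volcano-plot category of one gene.

    sigUp / sigDown require a strict fold-change exceedance (|log2FC| > cut)
    together with p < p_cut; the FC-only classes use |log2FC| >= cut with a
    non-significant p; P_Only is significant p with a sub-threshold fold
    change; everything else is NoDiff.
    """
    if not (np.isfinite(log2_fc) and np.isfinite(p_value)):
        raise ValueError("log2_fc and p_value must be finite")
    if not 0.0 <= p_value <= 1.0:
        raise ValueError(f"p_value must be in [0, 1], got {p_value}")
    if p_value < p_cut and log2_fc > fc_cut:
        return "sigUp"
    if p_value < p_cut and log2_fc < -fc_cut:
        return "sigDown"
    if p_value >= p_cut and log2_fc >= fc_cut:
        return "FC_UpOnly"
    if p_value >= p_cut and log2_fc <= -fc_cut:
        return "FC_DownOnly"
    if p_value < p_cut and abs(log2_fc) < fc_cut:
        return "P_Only"
    return "NoDiff"


def deg_table(
    expr: ExpressionMatrix,
    meta: pd.DataFrame,
    p_values: pd.Series | None = None,
    fc_cut: float = 1.0,
    p_cut: float = 0.05,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Differential-expression table: log2FC, p-value and volcano category.

    If ``p_values`` is not supplied, per-gene Welch t-tests between the two
    conditions are used.
    """
    lfc = log2_fold_change(expr, meta, pseudocount=pseudocount)
    if p_values is None:
        y = binary_response(meta, expr.sample_ids)
        vals = expr.values
        _, p = stats.ttest_ind(vals[:, y == 1], vals[:, y == 0], axis=1, equal_var=False)
        p = np.where(np.isfinite(p), p, 1.0)
        p_values = pd.Series(p, index=expr.gene_ids)
    else:
        p_values = p_values.reindex(expr.gene_ids)
        if p_values.isna().any():
            raise ValueError("p_values missing for some genes")
    cats = [
        classify_deg(l, pv, fc_cut=fc_cut, p_cut=p_cut)
        for l, pv in zip(lfc.to_numpy(), p_values.to_numpy())
    ]
    return pd.DataFrame(
        {"gene_id": expr.gene_ids, "log2_fc": lfc.to_numpy(),
         "p_value": p_values.to_numpy(), "category": cats}
    )
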