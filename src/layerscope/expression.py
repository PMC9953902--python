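"""Expression-matrix and clinical-table I/O and preprocessing.

Multi-cohort microarray studies are merged on the probes measured in every
cohort, collapsed to one row per gene (most variable probe wins), corrected
for additive batch offsets, and reduced to the genes whose expression varies
enough to carry subtype information.  All values are assumed to be on a log2
scale already; no renormalization is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_probe_map",
    "merge_cohorts",
    "collapse_probes",
    "remove_batch_effect",
    "filter_by_variability",
    "read_clinical_table",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 expression with per-sample batch labels.

    Attributes
    ----------
    data : pandas.DataFrame
        Rows indexed by gene (or probe) id, columns by sample id, float values.
    batch : pandas.Series
        Cohort/batch label per sample, indexed identically to ``data.columns``.
    """

    data: pd.DataFrame
    batch: pd.Series = field(default=None)

    def __post_init__(self):
        if self.batch is None:
            self.batch = pd.Series("batch0", index=self.data.columns)
        self.batch = self.batch.reindex(self.data.columns)
        self.validate()

    def validate(self) -> None:
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated gene/probe ids: {dup[:5]}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicated sample ids: {dup[:5]}")
        if self.data.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.batch.isna().any():
            raise ValueError("every sample needs a batch label")

    @property
    def gene_ids(self) -> list:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.copy(), self.batch.copy())

    def subset_genes(self, genes) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[list(genes)], self.batch.copy())

    def __eq__(self, other) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.data.equals(other.data) and self.batch.equals(other.batch)


@dataclass
class ClinicalTable:
    """Unified clinical annotations: DFS time/event plus optional covariates."""

    table: pd.DataFrame

    REQUIRED = ("sample_id", "dfs_months", "relapse_event")
    OPTIONAL = ("batch", "stage", "location", "cms")

    def __post_init__(self):
        t = self.table
        for col in self.REQUIRED:
            if col not in t.columns:
                raise ValueError(f"clinical table missing required column {col!r}")
        if t["sample_id"].duplicated().any():
            raise ValueError("duplicated sample_id in clinical table")
        if (t["dfs_months"] < 0).any():
            raise ValueError("dfs_months must be non-negative")
        if not set(t["relapse_event"].unique()) <= {0, 1}:
            raise ValueError("relapse_event must be coded 0/1")

    @property
    def sample_ids(self) -> list:
        return self.table["sample_id"].tolist()

    def aligned_to(self, sample_ids) -> pd.DataFrame:
        t = self.table.set_index("sample_id")
        missing = [s for s in sample_ids if s not in t.index]
        if missing:
            raise KeyError(f"samples without clinical data: {missing[:5]}")
        return t.loc[list(sample_ids)]


def read_expression_matrix(path, batch_label: str | None = None) -> ExpressionMatrix:
    """Read a TSV matrix (first column = gene/probe id, header = sample ids)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        raise ValueError(f"{path}: duplicated sample column names")
    df = pd.read_csv(path, sep="\t", index_col=0,
                     float_precision="round_trip")
    try:
        df = df.astype(float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-numeric expression values ({exc})") from exc
    batch = pd.Series(batch_label if batch_label is not None else "batch0",
                      index=df.columns)
    return ExpressionMatrix(df, batch)


def write_expression_matrix(m: ExpressionMatrix, path) -> None:
    """Write TSV at full float precision so write-then-read is an identity."""
    m.data.to_csv(path, sep="\t", float_format="%.17g")


def read_probe_map(path) -> dict:
    """Two-column TSV (probe_id, gene_symbol) -> dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["probe_id", "gene_symbol"],
                     dtype=str)
    if df["probe_id"].duplicated().any():
        raise ValueError("probe map has duplicated probe ids")
    return dict(zip(df["probe_id"], df["gene_symbol"]))


def merge_cohorts(cohorts: list[ExpressionMatrix],
                  batch_labels: list[str] | None = None) -> ExpressionMatrix:
    """Merge cohorts on the intersection of their row ids.

    Rows are the probes/genes measured in *all* cohorts; columns are the
    concatenation of each cohort's samples, labelled by source cohort.
    """
    if len(cohorts) < 2:
        raise ValueError("need at least two cohorts to merge")
    if batch_labels is None:
        batch_labels = [f"batch{i}" for i in range(len(cohorts))]
    common = cohorts[0].data.index
    for c in cohorts[1:]:
        common = common.intersection(c.data.index)
    if len(common) == 0:
        raise ValueError("no common gene/probe ids across cohorts")
    common = sorted(common)
    all_samples = [s for c in cohorts for s in c.sample_ids]
    if len(set(all_samples)) != len(all_samples):
        raise ValueError("sample id collision across cohorts")
    parts = [c.data.loc[common] for c in cohorts]
    data = pd.concat(parts, axis=1)
    batch = pd.concat(
        [pd.Series(lbl, index=c.data.columns) for c, lbl in zip(cohorts, batch_labels)]
    )
    return ExpressionMatrix(data, batch)


def collapse_probes(m: ExpressionMatrix, probe_map: dict) -> ExpressionMatrix:
    """Keep, per gene, the probe with maximal variance across all samples.

    Ties break to the lexicographically smallest probe id so the result is
    deterministic across runs and platforms.
    """
    missing = [p for p in m.gene_ids if p not in probe_map]
    if missing:
        raise KeyError(f"probes missing from probe map: {missing[:10]}")
    var = m.data.var(axis=1, ddof=1)
    choice = pd.DataFrame({
        "probe": m.data.index,
        "gene": [probe_map[p] for p in m.data.index],
        "var": var.to_numpy(),
    })
    # sort: highest variance first, then probe id ascending for ties
    choice = choice.sort_values(["gene", "var", "probe"],
                                ascending=[True, False, True], kind="mergesort")
    winners = choice.drop_duplicates("gene")
    data = m.data.loc[winners["probe"]]
    data.index = winners["gene"].to_numpy()
    return ExpressionMatrix(data, m.batch.copy())


def remove_batch_effect(m: ExpressionMatrix) -> ExpressionMatrix:
    """Remove additive per-gene batch offsets.

    Per gene, each batch's mean is subtracted and the gene's grand mean added
    back — the least-squares fit of batch indicator variables with no other
    covariates.  Afterwards every batch shares the gene's grand mean.
    """
    levels = m.batch.unique()
    sizes = m.batch.value_counts()
    for lvl in levels:
        if sizes[lvl] < 2:
            logger.warning("batch %r has a single sample; its offset is "
                           "estimated from that one sample", lvl)
    grand = m.data.mean(axis=1)
    corrected = m.data.copy()
    for lvl in levels:
        cols = m.batch.index[m.batch == lvl]
        bmean = m.data[cols].mean(axis=1)
        corrected[cols] = m.data[cols].sub(bmean, axis=0).add(grand, axis=0)
    return ExpressionMatrix(corrected, m.batch.copy())


def filter_by_variability(m: ExpressionMatrix, sd_threshold: float = 2.0) -> ExpressionMatrix:
    """Keep genes whose sample standard deviation is strictly above threshold."""
    if sd_threshold < 0:
        raise ValueError("sd_threshold must be >= 0")
    sd = m.data.std(axis=1, ddof=1)
    keep = sd > sd_threshold
    if not keep.any():
        raise ValueError(
            f"no gene has SD > {sd_threshold}; lower the threshold "
            f"(max observed SD = {sd.max():.3g})")
    logger.info("variability filter: %d of %d genes kept (SD > %g)",
                int(keep.sum()), m.n_genes, sd_threshold)
    return ExpressionMatrix(m.data.loc[keep], m.batch.copy())


_STAGE_CODES = {"1": 1, "2": 2, "3": 3, "4": 4, 1: 1, 2: 2, 3: 3, 4: 4,
                1.0: 1, 2.0: 2, 3.0: 3, 4.0: 4}
_LOCATION_CODES = {"proximal": "proximal", "distal": "distal"}


def read_clinical_table(path, column_map: dict | None = None,
                        event_map: dict | None = None) -> ClinicalTable:
    """Read and validate a clinical CSV/TSV.

    Parameters
    ----------
    column_map : optional mapping from nonstandard header names to the
        canonical ones (sample_id, dfs_months, relapse_event, batch, stage,
        location, cms).
    event_map : optional mapping of raw event codes (e.g. "yes"/"no") to 0/1.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    raw = pd.read_csv(path, sep=sep)
    if column_map:
        raw = raw.rename(columns=column_map)
    for col in ClinicalTable.REQUIRED:
        if col not in raw.columns:
            raise ValueError(f"clinical file missing column {col!r}")
    t = pd.DataFrame({"sample_id": raw["sample_id"].astype(str)})
    t["dfs_months"] = pd.to_numeric(raw["dfs_months"])
    ev = raw["relapse_event"]
    if event_map:
        ev = ev.map(event_map)
        if ev.isna().any():
            raise ValueError("event values not covered by the declared mapping")
    t["relapse_event"] = pd.to_numeric(ev).astype(int)
    if "batch" in raw.columns:
        t["batch"] = raw["batch"].astype(str)
    n_na = 0
    if "stage" in raw.columns:
        stage = raw["stage"].map(_STAGE_CODES)
        n_na += int(stage.isna().sum() - raw["stage"].isna().sum())
        t["stage"] = stage
    if "location" in raw.columns:
        loc = raw["location"].astype(str).str.lower().map(_LOCATION_CODES)
        n_na += int(loc.isna().sum() - raw["location"].isna().sum())
        t["location"] = loc
    if "cms" in raw.columns:
        cms = raw["cms"].where(raw["cms"].isin(["CMS1", "CMS2", "CMS3", "CMS4"]))
        t["cms"] = cms
    if n_na:
        logger.info("coded %d unparseable stage/location values as NA", n_na)
    return ClinicalTable(t)
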