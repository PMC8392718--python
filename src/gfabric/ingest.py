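"""Spot-level filtering, per-array median normalization and tensor assembly.

The raw unit of data is a *spot table*: one row per microarray spot per
hybridized sample, identified by ``(gene_id, spot_id, region, phenotype,
replica)`` and carrying foreground/background fluorescence plus a corrupted
flag.  Quality control removes corrupted spots and spots whose foreground is
less than twice the background; surviving background-subtracted signals are
scaled so each array (one ``(region, phenotype, replica)`` hybridization) has
median 1, which makes every downstream expression level a multiple of the
median gene expression of its array.

The normalized rows are then assembled into one :class:`ExpressionTensor`
per ``(region, phenotype)`` dataset: a ``(gene, spot) x replica`` matrix of
positive values.  A spot enters the tensor only if it survived QC in every
replica of its dataset, and a gene only if it kept at least one such spot in
*every* dataset (the common gene universe), so all datasets share a single
gene count N.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GeneLookupError, NormalizationError, SpotTableError

SPOT_COLUMNS = [
    "gene_id",
    "spot_id",
    "region",
    "phenotype",
    "replica",
    "foreground",
    "background",
    "flag_corrupted",
]

#: columns identifying one hybridized array
ARRAY_KEY = ["region", "phenotype", "replica"]


def read_spot_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated spot table, validating the header."""
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "spot_id": str, "replica": str})
    missing = [c for c in SPOT_COLUMNS if c not in table.columns]
    if missing:
        raise SpotTableError(f"{path}: missing columns {missing}")
    return table


def write_spot_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


@dataclass
class FilterReport:
    """Bookkeeping of every row removed on the way to the tensors."""

    n_input: int = 0
    n_corrupted: int = 0
    n_low_signal: int = 0
    n_retained: int = 0
    n_nonpositive: int = 0
    array_medians: dict = field(default_factory=dict)
    genes_dropped: list = field(default_factory=list)
    n_genes_retained: int = 0

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_corrupted": self.n_corrupted,
            "n_low_signal": self.n_low_signal,
            "n_retained": self.n_retained,
            "n_nonpositive": self.n_nonpositive,
            "array_medians": {"|".join(k): v for k, v in self.array_medians.items()},
            "genes_dropped": list(self.genes_dropped),
            "n_genes_retained": self.n_genes_retained,
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _validate(table: pd.DataFrame) -> None:
    missing = [c for c in SPOT_COLUMNS if c not in table.columns]
    if missing:
        raise SpotTableError(f"spot table missing columns {missing}")
    for col in ("foreground", "background"):
        bad = table.index[~np.isfinite(table[col].to_numpy(float)) | (table[col].to_numpy(float) < 0)]
        if len(bad):
            raise SpotTableError(f"row {bad[0]}: non-finite or negative {col}")
    dup = table.duplicated(subset=["gene_id", "spot_id", *ARRAY_KEY])
    if dup.any():
        raise SpotTableError(f"row {table.index[dup][0]}: duplicate (gene, spot, array) key")


def filter_spots(table: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Remove corrupted spots and spots with foreground < 2 x background.

    The boundary is strict: a spot with foreground exactly twice the
    background is retained.  A corrupted spot is counted under the corrupted
    rule even if its signal is also low.
    """
    _validate(table)
    report = FilterReport(n_input=len(table))
    corrupted = table["flag_corrupted"].astype(int) != 0
    low = table["foreground"] < 2.0 * table["background"]
    report.n_corrupted = int(corrupted.sum())
    report.n_low_signal = int((low & ~corrupted).sum())
    kept = table.loc[~corrupted & ~low].reset_index(drop=True)
    report.n_retained = len(kept)
    return kept, report


def normalize_to_median(
    table: pd.DataFrame, report: FilterReport | None = None
) -> tuple[pd.DataFrame, FilterReport]:
    """Background-subtract and scale each array to median signal 1.

    Rows whose background-subtracted signal is not strictly positive are
    dropped (and counted); the per-array median is taken over the remaining
    valid signals, before any gene selection, so later subsetting does not
    change the scale.
    """
    if report is None:
        report = FilterReport(n_input=len(table))
    out = table.copy()
    out["signal"] = out["foreground"].astype(float) - out["background"].astype(float)
    nonpos = out["signal"] <= 0
    report.n_nonpositive = int(nonpos.sum())
    out = out.loc[~nonpos]
    for key, group in out.groupby(ARRAY_KEY, sort=True):
        med = float(group["signal"].median())
        report.array_medians[tuple(map(str, key))] = med
    if not report.array_medians and len(table):
        key = tuple(map(str, table.iloc[0][ARRAY_KEY]))
        raise NormalizationError(f"array {key}: no positive signals to normalize")
    empty = {tuple(map(str, k)) for k, _ in table.groupby(ARRAY_KEY, sort=True)} - set(
        report.array_medians
    )
    if empty:
        raise NormalizationError(f"array {sorted(empty)[0]}: no positive signals to normalize")
    med = out.groupby(ARRAY_KEY, sort=False)["signal"].transform("median")
    out = out.assign(signal=out["signal"] / med)
    cols = ["gene_id", "spot_id", *ARRAY_KEY, "signal"]
    return out[cols].reset_index(drop=True), report


class ExpressionTensor:
    """Normalized ``(gene, spot) x replica`` expression values of one dataset.

    Parameters
    ----------
    region, phenotype
        Labels of the dataset.
    values
        DataFrame with a two-level ``(gene_id, spot_id)`` index, one column
        per biological replica, all entries finite and positive.
    """

    def __init__(self, region: str, phenotype: str, values: pd.DataFrame):
        self.region = str(region)
        self.phenotype = str(phenotype)
        values = values.sort_index()
        if values.isna().any().any():
            raise SpotTableError("tensor values must be complete across replicas")
        values.index.names = ["gene_id", "spot_id"]
        values.columns.name = None
        self.values = values

    # -- basic bookkeeping -------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.values.index.get_level_values(0).unique()

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def replicas(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def n_replicas(self) -> int:
        return self.values.shape[1]

    @property
    def spot_counts(self) -> pd.Series:
        """R_i: number of spots with complete replica coverage, per gene."""
        return self.values.groupby(level=0, sort=True).size()

    # -- derived summaries -------------------------------------------------
    def spot_means(self) -> pd.Series:
        """mu_ik: per-(gene, spot) mean over replicas."""
        return self.values.mean(axis=1)

    def spot_sds(self) -> pd.Series:
        """s_ik: per-(gene, spot) sample standard deviation over replicas."""
        return self.values.std(axis=1, ddof=1)

    def replicate_profiles(self) -> pd.DataFrame:
        """v_i(xi) = (1/R_i) sum_k a_ik(xi): per-gene, per-replica profile.

        This is the gene-level quantity all correlation and Welch-test
        statistics operate on; the biological replica is the inference unit.
        """
        return self.values.groupby(level=0, sort=True).mean()

    def gene_values(self, gene: str) -> pd.DataFrame:
        if gene not in self.genes:
            raise GeneLookupError(f"gene {gene!r} not in tensor ({self.region}, {self.phenotype})")
        return self.values.loc[gene]

    def subset(self, genes) -> "ExpressionTensor":
        """Restrict to an analysis panel of genes (normalization is per-array
        and precedes any gene selection, so values are unchanged)."""
        genes = list(genes)
        missing = [g for g in genes if g not in self.genes]
        if missing:
            raise GeneLookupError(f"genes not in tensor: {missing[:5]}")
        keep = self.values.index.get_level_values(0).isin(genes)
        return ExpressionTensor(self.region, self.phenotype, self.values.loc[keep])

    # -- serialization -----------------------------------------------------
    def write(self, path: str | Path) -> None:
        wide = self.values.copy()
        wide.columns = [f"rep_{c}" for c in wide.columns]
        wide.reset_index().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path, region: str, phenotype: str) -> "ExpressionTensor":
        wide = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "spot_id": str})
        wide = wide.set_index(["gene_id", "spot_id"])
        wide.columns = [c.removeprefix("rep_") for c in wide.columns]
        return cls(region, phenotype, wide)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ExpressionTensor({self.region}, {self.phenotype}: "
            f"{self.n_genes} genes, {len(self.values)} spots, {self.n_replicas} replicas)"
        )


def assemble_tensors(
    table: pd.DataFrame, report: FilterReport | None = None
) -> dict[tuple[str, str], ExpressionTensor]:
    """Pivot a normalized spot table into one tensor per (region, phenotype).

    A spot is kept only where it has a value in every replica of its dataset
    (inconsistent spot sets are intersected down); a gene survives a dataset
    if at least one spot remains.  Genes are then restricted to the common
    universe present in every dataset, so all tensors report the same N.
    """
    if report is None:
        report = FilterReport(n_input=len(table))
    per_dataset: dict[tuple[str, str], pd.DataFrame] = {}
    for (region, phenotype), group in table.groupby(["region", "phenotype"], sort=True):
        wide = group.pivot_table(
            index=["gene_id", "spot_id"], columns="replica", values="signal", aggfunc="first"
        )
        wide = wide.dropna(axis=0, how="any")
        per_dataset[(str(region), str(phenotype))] = wide
    if not per_dataset:
        return {}
    universes = [set(w.index.get_level_values(0)) for w in per_dataset.values()]
    common = set.intersection(*universes)
    dropped = sorted(set(table["gene_id"]) - common)
    report.genes_dropped = dropped
    report.n_genes_retained = len(common)
    tensors = {}
    for (region, phenotype), wide in per_dataset.items():
        keep = wide.index.get_level_values(0).isin(common)
        tensors[(region, phenotype)] = ExpressionTensor(region, phenotype, wide.loc[keep])
    return tensors


def ingest_spot_table(
    table: pd.DataFrame,
) -> tuple[dict[tuple[str, str], ExpressionTensor], FilterReport]:
    """Filter, normalize and assemble in one call."""
    kept, report = filter_spots(table)
    normalized, report = normalize_to_median(kept, report)
    tensors = assemble_tensors(normalized, report)
    return tensors, report
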