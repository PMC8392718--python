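"""Differential-expression calling and weighted gene/pathway regulation.

A comparison "test vs reference" (two phenotypes of the same region) calls a
gene significantly regulated by a composite criterion: the absolute
expression ratio must exceed a per-gene cutoff built from the two compared
variabilities, AND a two-tailed heteroscedastic (Welch) t-test on the
per-replica profiles must give p < alpha:

    x   = AVE_test / AVE_ref            (sign flipped to -AVE_ref/AVE_test
                                         when the gene is down in test)
    CUT = 1 + sqrt(2 (REV_test^2 + REV_ref^2)) / 100
    significant  <=>  |x| > CUT  and  p < alpha          (both strict)

Beyond the traditional +1/-1 tally of significant genes, every gene gets a
Weighted Individual Regulation score

    WIR = AVE_ref * sign(x) * (|x| - 1) * (1 - p),

i.e. the net fold-change weighted by the reference expression level and the
statistical confidence of the regulation, and a pathway Gamma aggregates to
the Weighted Pathway Regulation WPR = mean |WIR| over its quantified genes
(root-mean-square available as a variant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .fabric_metrics import average_expression, relative_expression_variability
from .ingest import ExpressionTensor

WPR_VARIANTS = ("mean_abs", "rms")


def expression_ratio(ave_test: float, ave_ref: float) -> float:
    """Signed expression ratio; |x| >= 1, negative for down-regulation."""
    if not (ave_test > 0 and ave_ref > 0):
        raise ConfigError(f"AVEs must be positive, got ({ave_test}, {ave_ref})")
    if ave_test >= ave_ref:
        return ave_test / ave_ref
    return -ave_ref / ave_test


def regulation_cut(rev_test: float, rev_ref: float) -> float:
    """Fold-change cutoff from the combined variabilities (REVs in percent)."""
    if rev_test < 0 or rev_ref < 0:
        raise ConfigError(f"REVs must be >= 0, got ({rev_test}, {rev_ref})")
    return 1.0 + np.sqrt(2.0 * (rev_test**2 + rev_ref**2)) / 100.0


def welch_p(values_test, values_ref) -> float:
    """Two-tailed Welch p on per-replica profiles.

    Degenerate conventions: both groups zero-variance gives p = 1 for equal
    means and p = 0 otherwise (a difference with no within-group spread is
    taken at face value).
    """
    a = np.asarray(values_test, dtype=float)
    b = np.asarray(values_ref, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ConfigError("welch_p needs >= 2 values per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def call_regulation(x: float, cut: float, p: float, alpha: float = 0.05) -> tuple[bool, int]:
    """Composite significance call; returns (significant, uniform +1/-1/0)."""
    significant = bool(abs(x) > cut and p < alpha)
    return significant, (int(np.sign(x)) if significant else 0)


def weighted_individual_regulation(ave_ref: float, x: float, p: float) -> float:
    """WIR = AVE_ref * sign(x) * (|x| - 1) * (1 - p); computed for all genes."""
    return float(ave_ref * np.sign(x) * (abs(x) - 1.0) * (1.0 - p))


@dataclass
class Comparison:
    """An ordered phenotype contrast within one region (test vs reference)."""

    region: str
    test: str
    ref: str

    @property
    def label(self) -> str:
        return f"{self.region}:{self.test}_vs_{self.ref}"


def compute_regulation(
    tensor_test: ExpressionTensor,
    tensor_ref: ExpressionTensor,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full regulation table for one comparison (vectorized over genes).

    Both tensors must come from the same region and share the gene universe.
    Returns a DataFrame indexed by gene with columns
    ``x, CUT, p, significant, uniform, WIR``.
    """
    if tensor_test.region != tensor_ref.region:
        raise ConfigError(
            f"comparison crosses regions ({tensor_test.region} vs {tensor_ref.region})"
        )
    genes = tensor_test.genes
    if not genes.equals(tensor_ref.genes):
        raise ConfigError("tensors do not share a gene universe")

    ave_t = average_expression(tensor_test).to_numpy()
    ave_r = average_expression(tensor_ref).to_numpy()
    rev_t = relative_expression_variability(tensor_test, alpha=alpha).to_numpy()
    rev_r = relative_expression_variability(tensor_ref, alpha=alpha).to_numpy()

    up = ave_t >= ave_r
    x = np.where(up, ave_t / ave_r, -ave_r / ave_t)
    cut = 1.0 + np.sqrt(2.0 * (rev_t**2 + rev_r**2)) / 100.0

    vt = tensor_test.replicate_profiles().to_numpy()
    vr = tensor_ref.replicate_profiles().to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = stats.ttest_ind(vt, vr, axis=1, equal_var=False).pvalue
    degenerate = np.isnan(p)  # both groups zero-variance
    p = np.where(degenerate, np.where(vt.mean(1) == vr.mean(1), 1.0, 0.0), p)

    significant = (np.abs(x) > cut) & (p < alpha)
    uniform = np.where(significant, np.sign(x).astype(int), 0)
    wir = ave_r * np.sign(x) * (np.abs(x) - 1.0) * (1.0 - p)

    out = pd.DataFrame(
        {
            "x": x,
            "CUT": cut,
            "p": p,
            "significant": significant,
            "uniform": uniform.astype(int),
            "WIR": wir,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return out


# ---------------------------------------------------------------------------
# pathways
# ---------------------------------------------------------------------------

@dataclass
class PathwaySet:
    """A named gene set; ``card`` counts only quantified (in-tensor) genes."""

    name: str
    genes: list[str]

    def quantified(self, universe) -> list[str]:
        present = set(universe)
        return [g for g in self.genes if g in present]


def read_gmt(path) -> list[PathwaySet]:
    """Read a GMT gene-set file (name <TAB> description <TAB> genes...)."""
    sets = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ConfigError(f"{path}:{line_no}: GMT line needs name, description, genes")
            name, _desc, *genes = parts
            genes = [g for g in genes if g]
            seen: list[str] = []
            for g in genes:  # preserve order, drop duplicates
                if g not in seen:
                    seen.append(g)
            sets.append(PathwaySet(name=name, genes=seen))
    return sets


@dataclass
class PathwayRegulation:
    name: str
    card: int
    percent_up: float
    percent_down: float
    wpr: float


def percent_up_down(pathway: PathwaySet, records: pd.DataFrame) -> tuple[float, float]:
    """Percentages of significantly up-/down-called genes over Card(Gamma)."""
    genes = pathway.quantified(records.index)
    if not genes:
        raise ConfigError(f"pathway {pathway.name!r}: no quantified genes")
    sub = records.loc[genes]
    card = len(genes)
    up = 100.0 * int((sub["uniform"] > 0).sum()) / card
    down = 100.0 * int((sub["uniform"] < 0).sum()) / card
    return up, down


def weighted_pathway_regulation(
    pathway: PathwaySet, records: pd.DataFrame, variant: str = "mean_abs"
) -> float:
    """WPR over the pathway's quantified genes (mean |WIR| or RMS)."""
    if variant not in WPR_VARIANTS:
        raise ConfigError(f"wpr variant must be one of {WPR_VARIANTS}, got {variant!r}")
    genes = pathway.quantified(records.index)
    if not genes:
        raise ConfigError(f"pathway {pathway.name!r}: no quantified genes")
    wir = records.loc[genes, "WIR"].to_numpy(float)
    if variant == "mean_abs":
        return float(np.mean(np.abs(wir)))
    return float(np.sqrt(np.mean(wir**2)))


def pathway_regulation_table(
    pathways: list[PathwaySet], records: pd.DataFrame, variant: str = "mean_abs"
) -> pd.DataFrame:
    """Per-pathway Card, %up, %down and WPR; empty pathways are skipped with
    a warning column rather than raising."""
    rows = []
    for pw in pathways:
        genes = pw.quantified(records.index)
        if not genes:
            rows.append((pw.name, 0, np.nan, np.nan, np.nan))
            continue
        up, down = percent_up_down(pw, records)
        wpr = weighted_pathway_regulation(pw, records, variant=variant)
        rows.append((pw.name, len(genes), up, down, wpr))
    return pd.DataFrame(
        rows, columns=["pathway", "card", "percent_up", "percent_down", "WPR"]
    ).set_index("pathway")
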