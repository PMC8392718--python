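"""Per-gene transcriptome characteristics: AVE, REV, COR and the GCH hierarchy.

Each ``(region, phenotype)`` dataset assigns every gene three independent
characteristics:

AVE
    Average expression level: the mean over a gene's redundant spots of the
    per-spot replicate means, in multiples of the array median (the tensors
    are median-normalized).

REV
    Relative expression variability: a pooled coefficient of variation
    across biological replicas, corrected by the mid-point of the
    chi-square confidence interval of the standard deviation and expressed
    in percent,

        REV = 1/2 [ sqrt(r / chi2_{r; 1-a/2}) + sqrt(r / chi2_{r; a/2}) ]
              * sqrt( (1/R_i) sum_k (s_ik / mu_ik)^2 ) * 100,

    with r = n_rep * R_i - 1 pooled degrees of freedom.  The correction
    factor is > 1 and shrinks to 1 as the degrees of freedom grow; it
    removes the small-sample downward bias of the 4-replicate CV.  Low REV
    marks genes under strict homeostatic control.

COR
    Pearson correlation of two genes' per-replica profiles v_i(xi) across
    the biological replicas, with a two-tailed p-value from the t-transform
    t = r sqrt((n-2)/(1-r^2)).  At n = 4 and alpha = 0.05 the significance
    threshold is |COR| > 0.950.

GCH
    Gene Commanding Height, combining expression control and coordination:

        GCH_i = (REV_med / REV_i) * exp( (n_rep/N) sum_{j != i} COR_ij^2 - 1 )

    where REV_med is the dataset median REV and N the dataset gene count.
    The top-GCH gene of a dataset is its Gene Master Regulator (GMR).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, GeneLookupError
from .ingest import ExpressionTensor

GCH_VARIANTS = ("offset", "scaled")


def rev_correction(dof: int, alpha: float = 0.05) -> float:
    """Chi-square interval mid-point correction for a CV with ``dof`` degrees
    of freedom: 1/2 [ sqrt(dof/chi2_{dof;1-a/2}) + sqrt(dof/chi2_{dof;a/2}) ]."""
    if dof < 1:
        raise ConfigError(f"degrees of freedom must be >= 1, got {dof}")
    hi = stats.chi2.ppf(1.0 - alpha / 2.0, dof)
    lo = stats.chi2.ppf(alpha / 2.0, dof)
    return 0.5 * (np.sqrt(dof / hi) + np.sqrt(dof / lo))


def average_expression(tensor: ExpressionTensor, gene: str | None = None):
    """AVE per gene (Series), or for one gene if ``gene`` is given."""
    ave = tensor.spot_means().groupby(level=0, sort=True).mean().rename("AVE")
    if gene is None:
        return ave
    if gene not in ave.index:
        raise GeneLookupError(f"gene {gene!r} not in tensor")
    return float(ave.loc[gene])


def relative_expression_variability(
    tensor: ExpressionTensor, gene: str | None = None, alpha: float = 0.05
):
    """REV per gene in percent (Series), or for one gene."""
    mu = tensor.spot_means()
    if (mu == 0).any():
        raise ZeroDivisionError("zero replicate-mean expression: CV undefined")
    cv2 = (tensor.spot_sds() / mu) ** 2
    pooled = np.sqrt(cv2.groupby(level=0, sort=True).mean())
    r_i = tensor.n_replicas * tensor.spot_counts - 1
    corr = pd.Series(
        {dof: rev_correction(int(dof), alpha) for dof in r_i.unique()}, dtype=float
    )
    rev = (pooled * r_i.map(corr) * 100.0).rename("REV")
    if gene is None:
        return rev
    if gene not in rev.index:
        raise GeneLookupError(f"gene {gene!r} not in tensor")
    return float(rev.loc[gene])


# ---------------------------------------------------------------------------
# correlation machinery
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    gene_i: str
    gene_j: str
    cor: float
    n_points: int
    p_value: float
    sign_class: str  # synergistic | antagonistic | independent


def correlation_p(r: np.ndarray | float, n: int) -> np.ndarray | float:
    """Two-tailed p for a Pearson r at sample size ``n`` via the t-transform."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
        p = np.where(np.abs(r) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df))
    return p if p.ndim else float(p)


def critical_correlation(n: int, alpha: float = 0.05) -> float:
    """Smallest |r| significant at ``alpha`` (two-tailed) for sample size n."""
    tstar = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
    return float(tstar / np.sqrt(tstar**2 + (n - 2)))


def classify_sign(cor: float, p: float, alpha: float = 0.05) -> str:
    if not np.isfinite(cor) or not np.isfinite(p) or p >= alpha:
        return "independent"
    return "synergistic" if cor > 0 else "antagonistic"


def _standardized_profiles(tensor: ExpressionTensor, genes=None) -> pd.DataFrame:
    """Row-standardized (zero-mean, unit-norm) replicate profiles.

    Genes with zero profile variance come out as all-NaN rows; their
    correlations are undefined and excluded from downstream sums.
    """
    prof = tensor.replicate_profiles()
    if genes is not None:
        missing = [g for g in genes if g not in prof.index]
        if missing:
            raise GeneLookupError(f"genes not in tensor: {missing}")
        prof = prof.loc[list(genes)]
    v = prof.to_numpy(float)
    v = v - v.mean(axis=1, keepdims=True)
    norm = np.sqrt((v**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = v / norm[:, None]
    z[norm == 0] = np.nan
    return pd.DataFrame(z, index=prof.index, columns=prof.columns)


def expression_correlation(
    tensor: ExpressionTensor, gene_i: str, gene_j: str, alpha: float = 0.05
) -> CorrelationResult:
    """COR between two genes of one dataset, with significance class."""
    z = _standardized_profiles(tensor, [gene_i, gene_j]).to_numpy()
    n = tensor.n_replicas
    if np.isnan(z).any():
        return CorrelationResult(gene_i, gene_j, np.nan, n, np.nan, "independent")
    r = float(np.clip(z[0] @ z[1], -1.0, 1.0))
    p = correlation_p(r, n)
    return CorrelationResult(gene_i, gene_j, r, n, p, classify_sign(r, p, alpha))


def correlation_matrix(
    tensor: ExpressionTensor,
    accumulator: Callable[[np.ndarray, np.ndarray, np.ndarray], None],
    genes: Iterable[str] | None = None,
    chunk_size: int = 512,
) -> int:
    """Stream all distinct gene pairs through ``accumulator``.

    The accumulator receives ``(i_idx, j_idx, cor)`` blocks of flat arrays
    (indices into the sorted gene list, i < j), so the C(N, 2) pairs never
    reside in memory at once.  Pairs involving a zero-variance gene carry
    ``cor = nan``.  Returns the number of pairs emitted.
    """
    z = _standardized_profiles(tensor, genes).to_numpy()
    n = z.shape[0]
    emitted = 0
    for start in range(0, n, chunk_size):
        stop = min(start + chunk_size, n)
        block = np.clip(z[start:stop] @ z.T, -1.0, 1.0)  # rows start..stop vs all
        for local, i in enumerate(range(start, stop)):
            j = np.arange(i + 1, n)
            if len(j) == 0:
                continue
            accumulator(np.full(len(j), i), j, block[local, i + 1 :])
            emitted += len(j)
    return emitted


def sum_squared_correlations(tensor: ExpressionTensor) -> pd.Series:
    """sum_{j != i} COR_ij^2 for every gene, in O(N n^2).

    With unit-norm standardized profiles z_i, sum_j (z_i . z_j)^2 equals
    z_i^T (Z^T Z) z_i, so only the n x n Gram matrix of replica loadings is
    needed.  Zero-variance genes contribute nothing and receive NaN.
    """
    zf = _standardized_profiles(tensor)
    z = zf.to_numpy()
    valid = ~np.isnan(z[:, 0])
    zv = np.nan_to_num(z)
    gram = zv.T @ zv
    total = np.einsum("ij,jk,ik->i", zv, gram, zv)
    out = np.where(valid, total - 1.0, np.nan)  # drop the self term
    return pd.Series(np.clip(out, 0.0, None), index=zf.index, name="sum_cor2")


# ---------------------------------------------------------------------------
# GCH hierarchy
# ---------------------------------------------------------------------------

def gene_commanding_height(
    tensor: ExpressionTensor,
    gene: str | None = None,
    alpha: float = 0.05,
    variant: str = "offset",
    rev: pd.Series | None = None,
    sum_cor2: pd.Series | None = None,
):
    """GCH per gene (Series), or for one gene.

    ``variant="offset"`` (default) uses exp((n_rep/N) * sum COR^2 - 1);
    ``variant="scaled"`` uses exp(n_rep * (mean COR^2 - 1)).  A gene with
    REV = 0 would be infinitely controlled; it is assigned the smallest
    positive REV of the dataset (with a warning) to keep GCH finite.
    """
    if variant not in GCH_VARIANTS:
        raise ConfigError(f"gch variant must be one of {GCH_VARIANTS}, got {variant!r}")
    if rev is None:
        rev = relative_expression_variability(tensor, alpha=alpha)
    if sum_cor2 is None:
        sum_cor2 = sum_squared_correlations(tensor)
    rev = rev.copy()
    if (rev == 0).any():
        import warnings

        smallest = rev[rev > 0].min()
        warnings.warn("REV = 0 gene(s): substituting smallest positive REV for GCH")
        rev[rev == 0] = smallest
    rev_med = float(rev.median())
    n = tensor.n_genes
    n_rep = tensor.n_replicas
    s = sum_cor2.fillna(0.0)
    if variant == "offset":
        expo = (n_rep / n) * s - 1.0
    else:
        expo = n_rep * (s / n - 1.0)
    gch = ((rev_med / rev) * np.exp(expo)).rename("GCH")
    if gene is None:
        return gch
    if gene not in gch.index:
        raise GeneLookupError(f"gene {gene!r} not in tensor")
    return float(gch.loc[gene])


def gene_summary(
    tensor: ExpressionTensor, alpha: float = 0.05, variant: str = "offset"
) -> pd.DataFrame:
    """Per-gene AVE, REV, GCH table for one dataset (gene-id sorted)."""
    ave = average_expression(tensor)
    rev = relative_expression_variability(tensor, alpha=alpha)
    gch = gene_commanding_height(tensor, alpha=alpha, variant=variant, rev=rev)
    out = pd.concat([ave, rev, gch], axis=1)
    out.index.name = "gene_id"
    return out


def rank_hierarchy(summary: pd.DataFrame) -> pd.DataFrame:
    """Order genes by descending GCH (ties broken by gene id); rank 1 = GMR."""
    out = summary.sort_index(kind="stable").sort_values("GCH", ascending=False, kind="stable")
    out = out.assign(rank=np.arange(1, len(out) + 1))
    return out


def gene_master_regulator(summary: pd.DataFrame) -> str:
    """The top-GCH gene of a dataset."""
    return str(rank_hierarchy(summary).index[0])
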