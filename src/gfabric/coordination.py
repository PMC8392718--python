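"""Coordination networks and cross-region expression synchrony.

Within one dataset, two genes are *synergistically* expressed when their
profile correlation is significantly positive (p < alpha, two-tailed) and
*antagonistically* when significantly negative; otherwise they are
independent.  An edge list over a gene selection forms the coordination
network, which can be checked against declared expectations (e.g. pathway
stimulators expected synergistic with their targets, inhibitors
antagonistic).

Across two regions, the same gene's per-animal profiles (replicas pair the
same animal in both regions) are correlated to classify *in-phase*
(significantly positive) vs *anti-phase* (significantly negative)
expression, summarized as percentages over a gene set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, PairingError
from .fabric_metrics import _standardized_profiles, classify_sign, correlation_p
from .ingest import ExpressionTensor


def coordination_network(
    tensor: ExpressionTensor, gene_set, alpha: float = 0.05
) -> tuple[pd.DataFrame, list[str]]:
    """Classify every distinct pair within ``gene_set``.

    Returns (edges, skipped): an edge table with columns
    ``gene_i, gene_j, COR, p, sign_class`` for all in-tensor pairs, and the
    list of requested genes absent from the tensor.
    """
    present = [g for g in gene_set if g in tensor.genes]
    skipped = [g for g in gene_set if g not in tensor.genes]
    n = tensor.n_replicas
    z = _standardized_profiles(tensor, present).to_numpy()
    rows = []
    for a in range(len(present)):
        for b in range(a + 1, len(present)):
            if np.isnan(z[a, 0]) or np.isnan(z[b, 0]):
                rows.append((present[a], present[b], np.nan, np.nan, "independent"))
                continue
            r = float(np.clip(z[a] @ z[b], -1.0, 1.0))
            p = correlation_p(r, n)
            rows.append((present[a], present[b], r, p, classify_sign(r, p, alpha)))
    edges = pd.DataFrame(rows, columns=["gene_i", "gene_j", "COR", "p", "sign_class"])
    return edges, skipped


@dataclass
class ExpectedRelation:
    """One declared relation: a member of a source group (e.g. a stimulator
    set) expected synergistic ('+') or antagonistic ('-') with a target."""

    group: str
    member_gene: str
    target_gene: str
    expected_sign: str

    def __post_init__(self):
        if self.expected_sign not in ("+", "-"):
            raise ConfigError(
                f"expected_sign must be '+' or '-', got {self.expected_sign!r}"
            )


def read_expected_relations(path) -> list[ExpectedRelation]:
    """Read an expectations TSV: group, member_gene, target_gene, expected_sign."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    needed = ["group", "member_gene", "target_gene", "expected_sign"]
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise ConfigError(f"{path}: expectations file missing columns {missing}")
    return [ExpectedRelation(*row) for row in table[needed].itertuples(index=False)]


def compare_expected_relations(
    edges: pd.DataFrame, expectations: list[ExpectedRelation]
) -> pd.DataFrame:
    """Match observed edge classes against expected signs.

    Relations whose genes carry no edge (absent from the network) get
    observed class ``not_detected`` and do not match.  The returned table
    has one row per expectation with a boolean ``match``.
    """
    lookup = {}
    for row in edges.itertuples(index=False):
        lookup[(row.gene_i, row.gene_j)] = (row.COR, row.p, row.sign_class)
        lookup[(row.gene_j, row.gene_i)] = (row.COR, row.p, row.sign_class)
    rows = []
    for rel in expectations:
        key = (rel.member_gene, rel.target_gene)
        if key not in lookup:
            rows.append(
                (rel.group, rel.member_gene, rel.target_gene, rel.expected_sign,
                 np.nan, np.nan, "not_detected", False)
            )
            continue
        cor, p, cls = lookup[key]
        wanted = "synergistic" if rel.expected_sign == "+" else "antagonistic"
        rows.append(
            (rel.group, rel.member_gene, rel.target_gene, rel.expected_sign,
             cor, p, cls, cls == wanted)
        )
    return pd.DataFrame(
        rows,
        columns=["group", "member_gene", "target_gene", "expected_sign",
                 "COR", "p", "observed_class", "match"],
    )


def concordance_summary(comparison: pd.DataFrame) -> dict:
    """Counts of matches/mismatches/not-detected over a concordance table."""
    return {
        "n_relations": int(len(comparison)),
        "n_match": int(comparison["match"].sum()),
        "n_not_detected": int((comparison["observed_class"] == "not_detected").sum()),
        "n_mismatch": int(
            ((~comparison["match"]) & (comparison["observed_class"] != "not_detected")).sum()
        ),
    }


PHASE_CLASSES = ("in_phase", "anti_phase", "unsynchronized")


def cross_region_phase(
    tensor_a: ExpressionTensor,
    tensor_b: ExpressionTensor,
    gene_set=None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Per-gene between-region correlation and phase class.

    Both tensors must hold the same phenotype in different regions with
    identical replica (animal) labels.  Returns the per-gene table
    (``COR, p, phase_class``) and a summary dict with in-phase/anti-phase
    percentages over the analyzed genes.
    """
    if tensor_a.phenotype != tensor_b.phenotype:
        raise ConfigError(
            f"phase analysis needs one phenotype, got "
            f"{tensor_a.phenotype!r} vs {tensor_b.phenotype!r}"
        )
    if tensor_a.region == tensor_b.region:
        raise ConfigError("phase analysis needs two different regions")
    if tensor_a.replicas != tensor_b.replicas:
        odd = set(tensor_a.replicas) ^ set(tensor_b.replicas)
        raise PairingError(f"unpaired replicas across regions: {sorted(odd)}")
    if gene_set is None:
        gene_set = [g for g in tensor_a.genes if g in set(tensor_b.genes)]
    za = _standardized_profiles(tensor_a, [g for g in gene_set if g in tensor_a.genes])
    zb = _standardized_profiles(tensor_b, [g for g in gene_set if g in tensor_b.genes])
    common = [g for g in gene_set if g in za.index and g in zb.index]
    n = tensor_a.n_replicas
    a = za.loc[common].to_numpy()
    b = zb.loc[common].to_numpy()
    r = np.clip((a * b).sum(axis=1), -1.0, 1.0)
    p = correlation_p(r, n)
    cls = np.full(len(common), "unsynchronized", dtype=object)
    sig = np.isfinite(r) & np.isfinite(p) & (p < alpha)
    cls[sig & (r > 0)] = "in_phase"
    cls[sig & (r < 0)] = "anti_phase"
    table = pd.DataFrame(
        {"COR": r, "p": p, "phase_class": cls},
        index=pd.Index(common, name="gene_id"),
    )
    m = len(common)
    summary = {
        "phenotype": tensor_a.phenotype,
        "regions": [tensor_a.region, tensor_b.region],
        "n_genes": m,
        "percent_in_phase": 100.0 * int((cls == "in_phase").sum()) / m if m else np.nan,
        "percent_anti_phase": 100.0 * int((cls == "anti_phase").sum()) / m if m else np.nan,
    }
    return table, summary
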