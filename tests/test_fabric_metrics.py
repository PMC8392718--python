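"""AVE, REV, COR and GCH: worked values, invariants and streaming equality."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gfabric import (
    SynthConfig,
    average_expression,
    correlation_matrix,
    critical_correlation,
    expression_correlation,
    gene_commanding_height,
    gene_master_regulator,
    gene_summary,
    generate_experiment,
    ingest_spot_table,
    rank_hierarchy,
    relative_expression_variability,
    rev_correction,
    sum_squared_correlations,
)
from gfabric.errors import GeneLookupError

from conftest import make_tensor


class TestAverageExpression:
    def test_mean_over_spot_means(self):
        t = make_tensor({"gA": {"s1": [2, 2, 2, 2], "s2": [4, 4, 4, 4]}})
        assert average_expression(t, "gA") == 3.0

    def test_single_spot_is_replica_mean(self, simple_tensor):
        assert average_expression(simple_tensor, "gA") == 10.0

    def test_constant_values(self):
        t = make_tensor({"gA": {"s1": [5, 5, 5, 5]}})
        assert average_expression(t, "gA") == 5.0

    def test_unknown_gene_raises(self, simple_tensor):
        with pytest.raises(GeneLookupError):
            average_expression(simple_tensor, "nope")


class TestRelativeExpressionVariability:
    def test_worked_value(self, simple_tensor):
        """Replicas (8, 10, 10, 12) with one spot: CV = 0.16330, 3 degrees of
        freedom, chi-square correction 2.1475, hence REV = 35.07%."""
        assert relative_expression_variability(simple_tensor, "gA") == pytest.approx(
            35.07, abs=0.005
        )

    def test_zero_replicate_variance_gives_zero(self):
        t = make_tensor({"gA": {"s1": [3, 3, 3, 3], "s2": [9, 9, 9, 9]}})
        assert relative_expression_variability(t, "gA") == 0.0

    def test_correction_exceeds_one_and_shrinks_with_dof(self):
        assert rev_correction(3) == pytest.approx(2.1475, abs=2e-4)
        values = [rev_correction(4 * r - 1) for r in (1, 5, 50, 5000)]
        assert all(a > b for a, b in zip(values, values[1:]))
        assert values[-1] == pytest.approx(1.0, abs=0.01)

    @given(scale=st.floats(0.1, 1000.0))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, scale):
        base = make_tensor({"gA": {"s1": [8, 10, 10, 12]}})
        scaled = make_tensor({"gA": {"s1": [scale * v for v in (8, 10, 10, 12)]}})
        assert relative_expression_variability(
            scaled, "gA"
        ) == pytest.approx(relative_expression_variability(base, "gA"), rel=1e-9)
        assert average_expression(scaled, "gA") == pytest.approx(10.0 * scale, rel=1e-9)


class TestExpressionCorrelation:
    def test_identical_profiles_are_fully_synergistic(self):
        t = make_tensor({"gA": {"s1": [1, 2, 3, 4]}, "gB": {"s1": [1, 2, 3, 4]}})
        res = expression_correlation(t, "gA", "gB")
        assert res.cor == pytest.approx(1.0)
        assert res.sign_class == "synergistic"

    def test_reversed_profiles_are_antagonistic(self):
        t = make_tensor({"gA": {"s1": [1, 2, 3, 4]}, "gB": {"s1": [4, 3, 2, 1]}})
        res = expression_correlation(t, "gA", "gB")
        assert res.cor == pytest.approx(-1.0)
        assert res.p_value == 0.0
        assert res.sign_class == "antagonistic"

    def test_symmetry(self):
        t = make_tensor({"gA": {"s1": [1, 5, 2, 4]}, "gB": {"s1": [2, 1, 7, 3]}})
        ab = expression_correlation(t, "gA", "gB")
        ba = expression_correlation(t, "gB", "gA")
        assert ab.cor == pytest.approx(ba.cor)
        assert abs(ab.cor) <= 1.0

    def test_critical_threshold_at_four_replicas(self):
        assert critical_correlation(4, 0.05) == pytest.approx(0.950, abs=1e-3)

    def test_zero_variance_profile_is_flagged(self):
        t = make_tensor({"gA": {"s1": [2, 2, 2, 2]}, "gB": {"s1": [1, 2, 3, 4]}})
        res = expression_correlation(t, "gA", "gB")
        assert np.isnan(res.cor) and res.sign_class == "independent"


class TestCorrelationMatrix:
    def test_pair_count(self):
        t = make_tensor(
            {g: {"s1": list(np.random.default_rng(i).uniform(1, 2, 4))}
             for i, g in enumerate("abc")}
        )
        pairs = []
        n = correlation_matrix(t, lambda i, j, c: pairs.append((i, j, c)))
        assert n == 3

    def test_streaming_equals_brute_force(self, small_experiment):
        """On a 50-gene instance the streamed correlations and the per-gene
        squared-correlation sums match dense recomputation to 1e-12."""
        *_, tensors, _ = small_experiment
        t = tensors[("cortex", "MRL_lpr")].subset([f"g{i:05d}" for i in range(50)])
        prof = t.replicate_profiles()
        dense = np.corrcoef(prof.to_numpy())
        got = np.zeros_like(dense)

        def acc(i, j, c):
            got[i, j] = c

        n = correlation_matrix(t, acc, chunk_size=7)
        assert n == 50 * 49 // 2
        iu = np.triu_indices(50, k=1)
        assert np.allclose(got[iu], dense[iu], atol=1e-12)
        s2 = sum_squared_correlations(t)
        brute = (dense**2).sum(axis=1) - 1.0
        assert np.allclose(s2.to_numpy(), brute, atol=1e-12)


class TestGeneCommandingHeight:
    def test_uncorrelated_genes_at_median_rev_score_one_over_e(self):
        # three genes with mutually orthogonal centered profiles and equal
        # per-spot CV: every COR vanishes and every REV equals the median
        t = make_tensor(
            {
                "gA": {"s1": [11, 9, 11, 9]},
                "gB": {"s1": [11, 11, 9, 9]},
                "gC": {"s1": [11, 9, 9, 11]},
            }
        )
        gch = gene_commanding_height(t)
        assert np.allclose(gch, np.exp(-1.0))

    def test_monotone_decreasing_in_rev(self, small_experiment):
        *_, tensors, _ = small_experiment
        t = tensors[("cortex", "MRL_lpr")]
        rev = relative_expression_variability(t)
        s2 = sum_squared_correlations(t)
        base = gene_commanding_height(t, rev=rev, sum_cor2=s2)
        inflated = rev.copy()
        inflated.iloc[0] *= 2.0
        bumped = gene_commanding_height(t, rev=inflated, sum_cor2=s2)
        assert bumped.iloc[0] < base.iloc[0]

    def test_variant_switch_changes_only_the_exponent(self, simple_tensor):
        t = make_tensor(
            {"gA": {"s1": [8, 10, 10, 12]}, "gB": {"s1": [14, 10, 12, 9]}}
        )
        offset = gene_commanding_height(t, variant="offset")
        scaled = gene_commanding_height(t, variant="scaled")
        # both share the REV ratio; they differ by exp((n-n/N)(1 - <COR^2>))-type factors
        ratio = offset / scaled
        assert (ratio > 0).all()
        assert not np.allclose(offset, scaled)


class TestRankHierarchy:
    def test_descending_order_and_gmr(self):
        summary = pd.DataFrame(
            {"GCH": [5.0, 2.0, 9.0]}, index=pd.Index(["a", "b", "c"], name="gene_id")
        )
        ranked = rank_hierarchy(summary)
        assert list(ranked.index) == ["c", "a", "b"]
        assert list(ranked["rank"]) == [1, 2, 3]
        assert gene_master_regulator(summary) == "c"

    def test_ties_fall_back_to_gene_id_order(self):
        summary = pd.DataFrame(
            {"GCH": [1.0, 1.0, 1.0]}, index=pd.Index(["z", "a", "m"], name="gene_id")
        )
        assert list(rank_hierarchy(summary).index) == ["a", "m", "z"]


def test_rev_separates_tight_from_loose_control():
    """Genes simulated at 10% vs 40% CV separate in REV with AUC > 0.95."""
    tight = [f"g{i:05d}" for i in range(250)]
    cfg = SynthConfig(
        n_genes=500,
        regions=("hippocampus",),
        phenotypes=("MRL_lpr",),
        cv_range=(0.4, 0.4),
        cv_overrides={g: 0.1 for g in tight},
        frac_corrupted_spots=0.0,
        frac_low_signal_spots=0.0,
        seed=21,
    )
    table, _ = generate_experiment(cfg)
    tensors, _ = ingest_spot_table(table)
    rev = relative_expression_variability(tensors[("hippocampus", "MRL_lpr")])
    loose = rev.drop(tight)
    # AUC = P(REV_loose > REV_tight) over all pairs
    auc = (loose.to_numpy()[:, None] > rev[tight].to_numpy()[None, :]).mean()
    assert auc > 0.95


def test_gene_summary_layout(small_experiment):
    *_, tensors, _ = small_experiment
    summary = gene_summary(tensors[("cortex", "MRL_plus")])
    assert list(summary.columns) == ["AVE", "REV", "GCH"]
    assert (summary["AVE"] > 0).all() and (summary["REV"] >= 0).all()
    assert (summary["GCH"] > 0).all()
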