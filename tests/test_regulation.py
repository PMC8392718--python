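"""Composite regulation calls, WIR/WPR and the GMT reader."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gfabric import (
    PathwaySet,
    SynthConfig,
    call_regulation,
    compute_regulation,
    expression_ratio,
    generate_experiment,
    ingest_spot_table,
    pathway_regulation_table,
    percent_up_down,
    read_gmt,
    regulation_cut,
    weighted_individual_regulation,
    weighted_pathway_regulation,
    welch_p,
)
from gfabric.errors import ConfigError

from conftest import make_tensor

positive = st.floats(0.01, 1e6, allow_nan=False, allow_infinity=False)


class TestExpressionRatio:
    def test_symmetry_of_up_and_down(self):
        assert expression_ratio(20, 5) == 4.0
        assert expression_ratio(5, 20) == -4.0

    def test_equal_means_unity(self):
        assert expression_ratio(7.3, 7.3) == 1.0

    @given(a=positive, b=positive)
    @settings(max_examples=100, deadline=None)
    def test_antisymmetric_with_magnitude_at_least_one(self, a, b):
        x = expression_ratio(a, b)
        assert abs(x) >= 1.0
        if a != b:
            assert expression_ratio(b, a) == pytest.approx(-x, rel=1e-12)

    def test_nonpositive_raises(self):
        with pytest.raises(ConfigError):
            expression_ratio(0.0, 1.0)


class TestRegulationCut:
    @pytest.mark.parametrize(
        "rev_t, rev_r, expected",
        [(0, 0, 1.0), (10, 10, 1.2), (30, 40, 1.7071068)],
    )
    def test_worked_values(self, rev_t, rev_r, expected):
        assert regulation_cut(rev_t, rev_r) == pytest.approx(expected, abs=1e-6)

    def test_negative_rev_raises(self):
        with pytest.raises(ConfigError):
            regulation_cut(-1, 5)


class TestWelchP:
    def test_identical_groups(self):
        assert welch_p([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_worked_value(self):
        assert welch_p([1, 2, 3, 4], [2, 3, 4, 5]) == pytest.approx(0.315, abs=1e-3)

    def test_degenerate_conventions(self):
        assert welch_p([0, 0, 0, 0], [5, 5, 5, 5]) == 0.0
        assert welch_p([5, 5, 5, 5], [5, 5, 5, 5]) == 1.0

    def test_too_few_values_raises(self):
        with pytest.raises(ConfigError):
            welch_p([1], [1, 2])


class TestCallRegulation:
    @pytest.mark.parametrize(
        "x, cut, p, sig, uniform",
        [
            (3.0, 1.2, 0.01, True, 1),
            (-3.0, 1.2, 0.01, True, -1),
            (3.0, 3.0, 0.01, False, 0),   # strict |x| > CUT
            (3.0, 1.2, 0.07, False, 0),
            (3.0, 1.2, 0.05, False, 0),   # strict p < alpha
        ],
    )
    def test_composite_criterion(self, x, cut, p, sig, uniform):
        assert call_regulation(x, cut, p) == (sig, uniform)


class TestWeightedIndividualRegulation:
    def test_worked_values(self):
        assert weighted_individual_regulation(10, 2.0, 0.0) == 10.0
        assert weighted_individual_regulation(6, -3.0, 0.5) == -6.0

    @given(
        ave_ref=positive,
        mag=st.floats(1.0, 1e4),
        sign=st.sampled_from([-1.0, 1.0]),
        p=st.floats(0.0, 1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_confidence_factor_identity(self, ave_ref, mag, sign, p):
        """WIR/(AVE_ref * (|x|-1)) recovers 1-p exactly, so the implied
        confidence always lies in [0, 1] — and in (0, 1) when 0 < p < 1."""
        x = sign * mag
        wir = weighted_individual_regulation(ave_ref, x, p)
        if mag > 1.0 and p < 1.0:
            assert np.sign(wir) == np.sign(x)
        if mag > 1.0:
            implied = wir / (ave_ref * np.sign(x) * (mag - 1.0))
            assert implied == pytest.approx(1.0 - p, rel=1e-9, abs=1e-12)
        else:
            assert wir == 0.0


class TestPathways:
    def records(self):
        return pd.DataFrame(
            {
                "WIR": [3.0, -4.0, 0.0, 1.0, -2.0, 0.5, 0.0, 0.0, 0.0, 0.0],
                "uniform": [1, -1, 0, 1, 0, 0, 0, 0, 0, 0],
            },
            index=pd.Index([f"g{i}" for i in range(10)], name="gene_id"),
        )

    def test_wpr_mean_abs_and_rms(self):
        rec = self.records()
        pw = PathwaySet("p", ["g0", "g1"])
        assert weighted_pathway_regulation(pw, rec) == pytest.approx(3.5)
        assert weighted_pathway_regulation(pw, rec, variant="rms") == pytest.approx(
            np.sqrt((9 + 16) / 2)
        )

    def test_wpr_zero_for_silent_pathway(self):
        rec = self.records()
        assert weighted_pathway_regulation(PathwaySet("p", ["g6", "g7"]), rec) == 0.0

    def test_percent_up_down(self):
        rec = self.records()
        pw = PathwaySet("p", [f"g{i}" for i in range(10)])
        up, down = percent_up_down(pw, rec)
        assert (up, down) == (20.0, 10.0)
        assert up + down <= 100.0

    def test_card_counts_only_quantified_genes(self):
        rec = self.records()
        pw = PathwaySet("p", ["g0", "g1", "missing"])
        table = pathway_regulation_table([pw], rec)
        assert table.loc["p", "card"] == 2

    def test_empty_pathway_raises_or_is_flagged(self):
        rec = self.records()
        with pytest.raises(ConfigError):
            percent_up_down(PathwaySet("p", ["missing"]), rec)
        table = pathway_regulation_table([PathwaySet("p", ["missing"])], rec)
        assert np.isnan(table.loc["p", "WPR"])


class TestReadGmt:
    def test_parses_names_and_genes(self, tmp_path):
        gmt = tmp_path / "sets.gmt"
        gmt.write_text(
            "AKT\tPI3K-AKT signaling\tAkt1\tAkt2\tAkt3\tAkt2\n"
            "CHS\tchemokine signaling\tCcl2\tCxcl11\n"
        )
        sets = read_gmt(gmt)
        assert [s.name for s in sets] == ["AKT", "CHS"]
        assert sets[0].genes == ["Akt1", "Akt2", "Akt3"]  # duplicate dropped

    def test_short_line_raises(self, tmp_path):
        gmt = tmp_path / "bad.gmt"
        gmt.write_text("AKT\tonly-description\n")
        with pytest.raises(ConfigError):
            read_gmt(gmt)


class TestComputeRegulation:
    def test_matches_scalar_operations(self):
        t_test = make_tensor(
            {"gA": {"s1": [20, 22, 18, 20]}, "gB": {"s1": [5, 6, 4, 5]}},
            phenotype="P1",
        )
        t_ref = make_tensor(
            {"gA": {"s1": [5, 6, 4, 5]}, "gB": {"s1": [5, 5, 6, 4]}},
            phenotype="P2",
        )
        rec = compute_regulation(t_test, t_ref)
        from gfabric import average_expression, relative_expression_variability

        for g in ("gA", "gB"):
            x = expression_ratio(
                average_expression(t_test, g), average_expression(t_ref, g)
            )
            cut = regulation_cut(
                relative_expression_variability(t_test, g),
                relative_expression_variability(t_ref, g),
            )
            p = welch_p(
                t_test.replicate_profiles().loc[g], t_ref.replicate_profiles().loc[g]
            )
            assert rec.loc[g, "x"] == pytest.approx(x, rel=1e-12)
            assert rec.loc[g, "CUT"] == pytest.approx(cut, rel=1e-12)
            assert rec.loc[g, "p"] == pytest.approx(p, rel=1e-12)
            assert rec.loc[g, "WIR"] == pytest.approx(
                weighted_individual_regulation(average_expression(t_ref, g), x, p),
                rel=1e-12,
            )

    def test_swapping_phenotypes_flips_the_sign_of_x(self):
        t1 = make_tensor({"gA": {"s1": [20, 22, 18, 20]}}, phenotype="P1")
        t2 = make_tensor({"gA": {"s1": [5, 6, 4, 5]}}, phenotype="P2")
        fwd = compute_regulation(t1, t2)
        rev = compute_regulation(t2, t1)
        assert fwd.loc["gA", "x"] == pytest.approx(-rev.loc["gA", "x"])
        assert np.sign(fwd.loc["gA", "WIR"]) == -np.sign(rev.loc["gA", "WIR"])

    def test_cross_region_comparison_is_rejected(self):
        t1 = make_tensor({"gA": {"s1": [1, 2, 3, 4]}}, region="cortex")
        t2 = make_tensor({"gA": {"s1": [1, 2, 3, 4]}}, region="hippocampus")
        with pytest.raises(ConfigError):
            compute_regulation(t1, t2)


def test_detection_rate_is_monotone_in_fold_change():
    """Power of the composite call does not decrease with the true fold."""
    rates = []
    for fold in (1.5, 3.0, 8.0):
        hits = 0
        for seed in range(15):
            cfg = SynthConfig(
                n_genes=30,
                regions=("hippocampus",),
                phenotypes=("MRL_lpr", "MRL_plus"),
                cv_range=(0.2, 0.2),
                regulated_genes={"g00000": ("MRL_lpr", "MRL_plus", fold)},
                frac_corrupted_spots=0.0,
                frac_low_signal_spots=0.0,
                seed=seed,
            )
            table, _ = generate_experiment(cfg)
            tensors, _ = ingest_spot_table(table)
            rec = compute_regulation(
                tensors[("hippocampus", "MRL_lpr")], tensors[("hippocampus", "MRL_plus")]
            )
            hits += bool(rec.loc["g00000", "significant"])
        rates.append(hits)
    assert rates[0] <= rates[1] <= rates[2]
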