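"""Total effect, control strategies, counterfactual propagation, CDE and PA."""

import numpy as np
import pytest
from scipy import stats

from conftest import ELBW_EPTD, LBW_PTD, RACE_TOTALS, S_R_MEDIANS
from natmed.categorize import BWCategory, LGCategory, Race, StrataCounts
from natmed.mediation import (
    ControlStrategy,
    conditional_rate_ratio,
    controlled_stratum_counts,
    counterfactual_population_counts,
    incidence_relative_risk,
    new_po,
    percent_attributable,
    propagate_control,
    relative_risk,
    run_control,
    run_model1,
    run_model2,
    total_effect,
)
from natmed.posterior import BETA_1_10, posterior_draws, summarize
from natmed.synthetic_data import default_spec, generate_counts


def _flat_counts(n=1000, r=10, k=5, race_factor=1):
    """Uniform counts; Black cells optionally scaled."""
    births = np.full((2, k, k), n, dtype=np.int64)
    deaths = np.full((2, k, k), r, dtype=np.int64)
    deaths[1] *= race_factor
    scheme = "binary" if k == 2 else "five_by_five"
    return StrataCounts(births, deaths, scheme=scheme)


class TestMarginalEffects:
    def test_total_effect_on_published_totals(self, published_counts):
        te = total_effect(published_counts, n_draws=20_000, seed=1)
        assert np.median(te.values) == pytest.approx(0.0044, abs=2e-4)

    def test_relative_risk_on_published_totals(self, published_counts):
        rr = relative_risk(published_counts, n_draws=20_000, seed=1)
        assert np.median(rr.values) == pytest.approx(2.00, abs=0.02)

    def test_symmetry_under_identical_counts(self):
        counts = _flat_counts()
        te = total_effect(counts, n_draws=20_000, seed=3)
        rr = relative_risk(counts, n_draws=20_000, seed=3)
        lo, hi = np.percentile(te.values, [2.5, 97.5])
        assert lo < 0 < hi
        assert np.median(rr.values) == pytest.approx(1.0, abs=0.05)

    def test_doubling_black_deaths_doubles_rr(self):
        base = _flat_counts(n=100_000, r=400)
        doubled = StrataCounts(base.births, base.deaths * np.array([1, 2])[:, None, None])
        rr0 = np.median(relative_risk(base, n_draws=20_000, seed=4).values)
        rr1 = np.median(relative_risk(doubled, n_draws=20_000, seed=4).values)
        assert rr1 / rr0 == pytest.approx(2.0, rel=0.02)

    def test_zero_birth_race_rejected(self):
        births = np.zeros((2, 5, 5), dtype=np.int64)
        births[1] = 10
        counts = StrataCounts(births, np.zeros_like(births))
        with pytest.raises(ValueError, match="zero births"):
            total_effect(counts, n_draws=10, seed=0)


class TestControlStrategy:
    def test_targeted_cells_binary(self):
        bw = ControlStrategy("binary", "abnormal_bw", "match_other_mediator")
        assert sorted(bw.targeted_cells()) == [(0, 0), (0, 1)]
        assert bw.reference_for((0, 0)) == (1, 0)
        assert bw.reference_for((0, 1)) == (1, 1)
        both = ControlStrategy("binary", "all_abnormal")
        assert sorted(both.targeted_cells()) == [(0, 0), (0, 1), (1, 0)]
        assert both.reference_for((0, 0)) == (1, 1)

    def test_five_level_single_cell(self):
        s = ControlStrategy("five_by_five", (0, 0))
        assert s.targeted_cells() == [(0, 0)]
        assert s.reference_for((0, 0)) == (BWCategory.NBW - 1, LGCategory.TD - 1)

    def test_rejects_reference_target_and_bad_rules(self):
        with pytest.raises(ValueError, match="reference stratum"):
            ControlStrategy("five_by_five", (3, 3))
        with pytest.raises(ValueError, match="joint_normal"):
            ControlStrategy("binary", "all_abnormal", "match_other_mediator")


class TestCounterfactualPropagation:
    def test_published_worked_example_plugin(self):
        """Plug-in propagation reproduces the printed counterfactual counts."""
        race_deaths = (RACE_TOTALS["non_black"][1], RACE_TOTALS["black"][1])
        race_births = (RACE_TOTALS["non_black"][0], RACE_TOTALS["black"][0])

        targeted = (ELBW_EPTD["non_black"][1], ELBW_EPTD["black"][1])
        s_r = (S_R_MEDIANS["ELBW_EPTD"]["non_black"], S_R_MEDIANS["ELBW_EPTD"]["black"])
        p_r, npo, cde_val = propagate_control(race_deaths, race_births, targeted, s_r)
        assert p_r == (65_010, 11_225)
        assert npo[1] == pytest.approx(0.004535, abs=5e-7)
        assert npo[0] == pytest.approx(0.0028298, abs=5e-7)
        assert cde_val == pytest.approx(0.0017052, abs=5e-7)

        targeted = (LBW_PTD["non_black"][1], LBW_PTD["black"][1])
        s_r = (S_R_MEDIANS["LBW_PTD"]["non_black"], S_R_MEDIANS["LBW_PTD"]["black"])
        p_r, npo, cde_val = propagate_control(race_deaths, race_births, targeted, s_r)
        assert p_r == (93_638, 20_587)
        assert cde_val == pytest.approx(0.0042414, abs=5e-7)

    def test_no_change_control_is_identity(self):
        """s_r equal to the observed deaths leaves the population unchanged."""
        p_r, npo, cde_val = propagate_control(
            (100, 200), (10_000, 10_000), (30, 60), (30, 60))
        assert p_r == (100, 200)
        assert cde_val == pytest.approx(0.01)

    def test_controlled_counts_scale_with_reference_po(self):
        counts = _flat_counts(n=500, r=50)
        strat = ControlStrategy("five_by_five", (0, 0))
        ref = (3, 3)
        ref_draws = {ref: {race: np.full(100, 0.02) for race in Race}}
        s_r = controlled_stratum_counts(counts, strat, ref_draws)
        for race in Race:
            np.testing.assert_allclose(s_r[(0, 0)][race], 500 * 0.02)
        p_r = counterfactual_population_counts(counts, s_r)
        # race total 25*50 deaths, cell loses 50 - 10 = 40
        np.testing.assert_allclose(p_r[Race.BLACK], 1250 - 40)
        npo = new_po(p_r, counts)
        np.testing.assert_allclose(npo[Race.BLACK], 1210 / 12_500)

    def test_empty_targeted_cell_is_noop(self):
        counts = _flat_counts(n=500, r=5)
        births = counts.births.copy()
        births[:, 0, 0] = 0
        counts = StrataCounts(births, np.where(births > 0, counts.deaths, 0))
        strat = ControlStrategy("five_by_five", (0, 0))
        ref_draws = {(3, 3): {race: np.full(10, 0.5) for race in Race}}
        s_r = controlled_stratum_counts(counts, strat, ref_draws)
        for race in Race:
            assert (s_r[(0, 0)][race] == 0).all()

    def test_pa_drawwise_identity(self):
        rng = np.random.default_rng(11)
        te = rng.normal(0.004, 0.0002, 5000)
        cde_draws = rng.normal(0.002, 0.0002, 5000)
        pa = percent_attributable(te, cde_draws)
        np.testing.assert_allclose(pa, 100 * (te - cde_draws) / te, rtol=1e-12)

    def test_pa_zero_when_cde_equals_te(self):
        te = np.array([0.004, 0.005])
        assert percent_attributable(te, te.copy()) == pytest.approx([0.0, 0.0])

    def test_pa_excludes_zero_te_draws(self):
        pa = percent_attributable(np.array([0.0, 0.004]), np.array([0.001, 0.002]))
        assert pa.shape == (1,)

    def test_pr_below_race_total_under_improvement(self, published_counts):
        """When the reference rate beats every targeted rate, deaths only drop."""
        res = run_control(published_counts,
                          ControlStrategy("five_by_five", (0, 0)),
                          n_draws=5000, seed=2)
        for race in Race:
            assert res.p_r[race].hi97_5 <= published_counts.race_deaths[race.axis]
            assert res.p_r[race].lo2_5 >= 0


class TestDescriptiveContrasts:
    def test_incidence_rr_published(self, published_counts):
        irr = incidence_relative_risk(published_counts, (0, 0),
                                      n_draws=50_000, seed=6)
        plug_in = (26_163 / 2_475_161) / (88_158 / 22_973_056)
        assert plug_in == pytest.approx(2.7545, abs=1e-4)
        assert np.median(irr.values) == pytest.approx(plug_in, abs=0.01)

    def test_incidence_rr_equal_proportions(self):
        counts = _flat_counts(n=4000, r=10)
        irr = incidence_relative_risk(counts, (1, 1), n_draws=20_000, seed=7)
        assert np.median(irr.values) == pytest.approx(1.0, abs=0.02)

    def test_incidence_rr_unobserved_cell_flagged(self):
        births = np.full((2, 5, 5), 100, dtype=np.int64)
        births[0, 0, 0] = 0
        counts = StrataCounts(births, np.zeros_like(births))
        irr = incidence_relative_risk(counts, (0, 0), n_draws=100, seed=0)
        assert "[unstable]" in irr.label

    def test_conditional_rate_ratio_published(self):
        po_b = posterior_draws(*reversed(ELBW_EPTD["black"]), BETA_1_10, 50_000, 8)
        po_n = posterior_draws(*reversed(ELBW_EPTD["non_black"]), BETA_1_10, 50_000, 9)
        ratio = conditional_rate_ratio(po_b, po_n)
        plug_in = (10_729 / 26_163) / (36_779 / 88_158)
        assert plug_in == pytest.approx(0.9830, abs=1e-4)
        assert np.median(ratio.values) == pytest.approx(plug_in, abs=0.01)


class TestFullRuns:
    def test_model1_joint_equals_model2_all_cells(self):
        """Binary both-mediator control is the 5x5 all-cells joint control.

        With identical seeds the marginal and reference draws coincide, and
        the counterfactual sums are the same partition, so the CDE and PA
        posteriors agree draw for draw.
        """
        cohort = generate_counts(default_spec(200_000, seed=9))
        res5 = run_control(cohort.counts,
                           ControlStrategy("five_by_five", "all_abnormal"),
                           n_draws=2000, seed=42)
        res2 = run_control(cohort.counts.to_binary(),
                           ControlStrategy("binary", "all_abnormal"),
                           n_draws=2000, seed=42)
        np.testing.assert_allclose(res2.cde_draws.values, res5.cde_draws.values,
                                   atol=1e-12)
        np.testing.assert_allclose(res2.pa_draws.values, res5.pa_draws.values,
                                   atol=1e-9)

    def test_mediated_effect_identity(self):
        cohort = generate_counts(default_spec(100_000, seed=10))
        for res in run_model1(cohort.counts.to_binary(), n_draws=2000, seed=1):
            expected = summarize(res.te_draws.derived(
                res.te_draws.values - res.cde_draws.values, "mediated"))
            assert res.mediated == expected

    def test_no_disparity_population(self):
        """Equal-rate populations show RR ~ 1 and null effects everywhere."""
        spec = default_spec(400_000, seed=13)
        sym = type(spec)(
            births_per_race=(200_000, 200_000),
            incidence=np.stack([spec.incidence[0], spec.incidence[0]]),
            mortality=np.stack([spec.mortality[0], spec.mortality[0]]),
            seed=13,
        )
        counts = generate_counts(sym).counts
        te = total_effect(counts, n_draws=5000, seed=2)
        lo, hi = np.percentile(te.values, [2.5, 97.5])
        assert lo < 0 < hi
        assert np.median(relative_risk(counts, n_draws=5000, seed=2).values) \
            == pytest.approx(1.0, abs=0.1)
        frame, _ = run_model2(counts, n_draws=2000, seed=2)
        ok = frame[frame.status == "ok"]
        big = ok[(ok.births_black > 2000) & (ok.births_non_black > 2000)]
        assert (big.incidence_rr - 1.0).abs().max() < 0.1
        # rate ratios only stabilise with enough deaths behind each rate
        deep = big[(big.deaths_black > 50) & (big.deaths_non_black > 50)]
        assert (deep.cond_ratio - 1.0).abs().max() < 0.35
        # the CDE posterior is conditional on the realized population counts,
        # so it sits within sampling error of zero rather than straddling it
        res = run_model1(counts.to_binary(), n_draws=2000, seed=2)[2]
        assert abs(res.cde.median) < 1e-3

    def test_model2_flags_structural_zeros(self):
        cohort = generate_counts(default_spec(100_000, seed=14))
        frame, results = run_model2(cohort.counts, n_draws=500, seed=3)
        mac_eptd = frame[(frame.bw == "MAC") & (frame.lg == "EPTD")]
        assert (mac_eptd.status == "not_observed").all()
        ref = frame[(frame.bw == "NBW") & (frame.lg == "TD")]
        assert (ref.status == "reference").all()
        assert "pa" not in ref.dropna(axis=1).columns or ref["pa"].isna().all()
        assert (3, 3) not in results

    def test_model2_pa_identity_per_cell(self):
        cohort = generate_counts(default_spec(100_000, seed=15))
        _, results = run_model2(cohort.counts, n_draws=1000, seed=4)
        for res in results.values():
            np.testing.assert_allclose(
                res.pa_draws.values,
                100 * (res.te_draws.values - res.cde_draws.values) / res.te_draws.values,
                rtol=1e-10)


def test_tiny_counts_against_brute_force_oracle():
    """PA median on tiny strata matches an independent high-draw resampler.

    The oracle redoes the whole propagation with scipy's beta sampler at
    10^6 draws; agreement is required within three combined MC standard
    errors of the two medians.
    """
    rng = np.random.default_rng(21)
    births = rng.integers(5, 21, size=(2, 5, 5))
    deaths = rng.binomial(births, np.where(np.arange(5)[None, :, None] < 3, 0.4, 0.1))
    deaths[1] = np.minimum(deaths[1] + 1, births[1])  # clear disparity
    counts = StrataCounts(births, deaths)
    cell, ref = (0, 0), (3, 3)

    res = run_control(counts, ControlStrategy("five_by_five", cell),
                      n_draws=100_000, seed=5)

    n_oracle = 1_000_000
    rs = np.random.RandomState(12345)

    def post(r, n, size):
        return rs.beta(1 + r, 10 + n - r, size=size)

    te_o = (post(counts.race_deaths[1], counts.race_births[1], n_oracle)
            - post(counts.race_deaths[0], counts.race_births[0], n_oracle))
    cde_terms = []
    for axis in (0, 1):
        ref_po = post(deaths[axis][ref], births[axis][ref], n_oracle)
        s_r = births[axis][cell] * ref_po
        p_r = counts.race_deaths[axis] - (deaths[axis][cell] - s_r)
        cde_terms.append(p_r / counts.race_births[axis])
    pa_o = 100 * (te_o - (cde_terms[1] - cde_terms[0])) / te_o

    def med_se(x):
        return 1.2533 * np.std(x) / np.sqrt(x.size)

    tol = 3 * (med_se(pa_o) + med_se(res.pa_draws.values))
    assert np.median(res.pa_draws.values) == pytest.approx(np.median(pa_o), abs=tol)
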