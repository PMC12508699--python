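import numpy as np
import pytest

from sptkin.binding import BindingLabel, Population, Specificity
from sptkin.kinetics import (
    FitError,
    compare_groups,
    count_specific_events,
    fit_dwell_histogram,
    koff_from_tauB,
    relative_kon,
    tau_B_mle,
)
from sptkin.simulate import BOUND_SPECIFIC, SimConfig, simulate_ground_truth


def _label(spec):
    if spec is Specificity.NA:
        return BindingLabel(Population.FREE, spec, None)
    return BindingLabel(Population.BOUND, spec, 2.0)


class TestCountAndRatio:
    def test_count_specific(self):
        labels = [_label(Specificity.SPECIFIC), _label(Specificity.SPECIFIC), _label(Specificity.NONSPECIFIC), _label(Specificity.NA)]
        assert count_specific_events(labels) == 2

    def test_count_empty(self):
        assert count_specific_events([]) == 0

    @pytest.mark.parametrize("a,b,expected", [(40, 10, 4.0), (13, 10, 1.3), (7, 7, 1.0)])
    def test_fold_change(self, a, b, expected):
        assert relative_kon(a, b) == pytest.approx(expected)

    def test_zero_reference_is_undefined(self):
        assert relative_kon(5, 0) is None

    def test_scale_invariance(self):
        for k in (2, 3, 10):
            assert relative_kon(40 * k, 10 * k) == pytest.approx(4.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            relative_kon(-1, 10)


class TestDwellFit:
    def test_noiseless_exponential_histogram(self):
        # counts evaluated exactly from y0=0, A=100, tau=1 at the bin centres
        centers = np.arange(0.05, 5.0, 0.1)
        counts = np.rint(100 * np.exp(-centers / 1.0)).astype(int)
        dwells = np.repeat(centers, counts)
        fit = fit_dwell_histogram(dwells, bin_width=0.1)
        assert fit.tau_B == pytest.approx(1.0, abs=0.02)
        assert fit.A == pytest.approx(100.0, rel=0.05)
        assert abs(fit.y0) < 1.0

    def test_seeded_draws_recover_tau(self):
        rng = np.random.default_rng(51)
        dwells = rng.exponential(0.5, size=1000)
        dwells = dwells[dwells > 0]
        fit = fit_dwell_histogram(dwells, bin_width=0.1)
        assert abs(fit.tau_B - 0.5) < 0.05
        mle = tau_B_mle(dwells)
        joint = np.hypot(fit.tau_B_se, mle.se)
        assert abs(fit.tau_B - mle.tau) < 2 * joint

    def test_identical_dwells_degenerate(self):
        with pytest.raises(FitError, match="non-empty"):
            fit_dwell_histogram(np.full(100, 1.5), bin_width=0.1)

    def test_too_few_events_rejected(self):
        with pytest.raises(FitError, match="at least"):
            fit_dwell_histogram(np.ones(10), bin_width=0.1)

    def test_koff_property_of_fit(self):
        rng = np.random.default_rng(52)
        fit = fit_dwell_histogram(rng.exponential(2.0, size=2000), bin_width=0.1)
        assert fit.k_off * fit.tau_B == pytest.approx(1.0)


class TestTauMLE:
    def test_closed_form_with_truncation(self):
        est = tau_B_mle([1.5, 2.5], min_dwell=1.0)
        assert est.tau == pytest.approx(1.0)

    def test_degenerate_sample_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            est = tau_B_mle([1.0, 1.0, 1.0], min_dwell=1.0)
        assert est.tau == 0.0

    def test_large_truncated_sample_within_3se(self):
        rng = np.random.default_rng(53)
        draws = rng.exponential(2.0, size=20_000)
        kept = draws[draws >= 1.0]
        est = tau_B_mle(kept, min_dwell=1.0)
        assert abs(est.tau - 2.0) < 3 * 2.0 / np.sqrt(len(kept))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tau_B_mle([])

    def test_below_truncation_rejected(self):
        with pytest.raises(ValueError, match="min_dwell"):
            tau_B_mle([0.5, 1.5], min_dwell=1.0)


class TestKoff:
    @pytest.mark.parametrize("tau,expected", [(1.0, 1.0), (0.5, 2.0)])
    def test_reciprocal(self, tau, expected):
        assert koff_from_tauB(tau) == pytest.approx(expected)

    def test_identity_with_mle(self):
        rng = np.random.default_rng(54)
        est = tau_B_mle(rng.exponential(1.7, size=500))
        assert koff_from_tauB(est.tau) * est.tau == pytest.approx(1.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            koff_from_tauB(0.0)


class TestCensoring:
    def test_apparent_rate_adds_termination_hazard(self):
        # bound intervals terminated by bleaching as well as unbinding:
        # competing exponentials give apparent rate 1/tau + lambda_bleach
        sim = SimConfig(
            n_particles=600,
            n_frames=2000,
            cell_radius=1000.0,
            lambda_on=2.0,
            tau_B_true=1.0,
            lambda_nonspecific=0.0,
            bleach_rate=0.5,
            seed=55,
        )
        _, truth = simulate_ground_truth(sim)
        # all specific intervals except those cut by the end of the movie
        dwells = np.array(
            [e.dwell(sim.frame_interval) for e in truth.events if e.kind == BOUND_SPECIFIC and e.end < sim.n_frames - 1]
        )
        assert len(dwells) >= 1000
        apparent_rate = 1.0 / tau_B_mle(dwells).tau
        expected = 1.0 / sim.tau_B_true + sim.bleach_rate
        assert abs(apparent_rate - expected) / expected < 0.10


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        g = {"a": [10.0, 11.0, 12.0], "b": [10.0, 11.0, 12.0], "c": [10.0, 11.0, 12.0]}
        table = compare_groups(g, reference="a")
        anova = table[table["comparison"] == "ANOVA"].iloc[0]
        assert anova["p_value"] > 0.9
        assert (table["stars"] == "ns").all()

    def test_separated_groups_significant(self):
        # oracle: Welch/pooled t on means 10 vs 20, sd 1, n=3 -> p << 0.05
        g = {"ref": [9.0, 10.0, 11.0], "high": [19.0, 20.0, 21.0]}
        table = compare_groups(g, reference="ref")
        row = table[table["comparison"] == "high vs ref"].iloc[0]
        assert row["p_value"] < 0.05
        assert row["stars"] in {"*", "**", "***"}

    def test_three_groups_emit_two_dunnett_rows(self):
        g = {"ref": [1.0, 2.0], "a": [2.0, 3.0], "b": [4.0, 5.0]}
        table = compare_groups(g, reference="ref")
        assert len(table) == 3  # ANOVA + 2 comparisons
        assert set(table["comparison"][1:]) == {"a vs ref", "b vs ref"}

    def test_small_group_skipped_with_warning(self):
        g = {"ref": [1.0, 2.0, 3.0], "a": [2.0, 3.0, 4.0], "tiny": [5.0]}
        with pytest.warns(UserWarning, match="tiny"):
            table = compare_groups(g, reference="ref")
        assert "tiny vs ref" not in set(table["comparison"])

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            compare_groups({"a": [1.0, 2.0], "b": [2.0, 3.0]}, reference="zz")


class TestParameterRecoverySweep:
    @pytest.mark.parametrize("tau_true", [0.5, 1.0, 2.0])
    def test_fit_and_mle_agree_on_truncated_dwells(self, tau_true):
        # pipeline protocol: dwells below the 1 s specificity threshold are
        # excluded, so the histogram fit sees a left-truncated exponential
        rng = np.random.default_rng(int(tau_true * 100))
        need = int(np.ceil(5500 / np.exp(-1.0 / tau_true)))
        dwells = rng.exponential(tau_true, size=need)
        dwells = dwells[dwells >= 1.0]
        assert len(dwells) >= 1000
        fit = fit_dwell_histogram(dwells, bin_width=0.1)
        mle = tau_B_mle(dwells, min_dwell=1.0)
        assert abs(fit.tau_B - tau_true) / tau_true < 0.10
        assert abs(fit.tau_B - mle.tau) < 2 * np.hypot(fit.tau_B_se, mle.se)
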