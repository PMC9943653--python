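"""Dwell extraction, censored/truncated exponential MLE, model selection."""

import numpy as np
import pytest

import siteexposure as se
from siteexposure.dwell import (
    DwellSet,
    extract_dwells,
    fit_exponential_mle,
    pool_dwells,
    rates_at_concentration,
    select_dwell_model,
)
from siteexposure.idealize import HIGH, LOW, IdealizedTrace


def _ideal_from_labels(labels, frame_time=0.1, trace_id="t", conc=0.0):
    labels = np.asarray(labels, dtype=int)
    return IdealizedTrace(
        trace_id=trace_id,
        conc=conc,
        times=np.arange(len(labels)) * frame_time,
        labels=labels,
        mean_high=0.75,
        mean_low=0.15,
        sd_high=0.05,
        sd_low=0.05,
        frame_time=frame_time,
    )


def _dwellset(durations, censored=None, t_min=0.0, state="low"):
    durations = np.asarray(durations, dtype=float)
    if censored is None:
        censored = np.zeros(len(durations), dtype=bool)
    return DwellSet(state=state, durations=durations,
                    censored=np.asarray(censored, bool), t_min=t_min)


class TestExtractDwells:
    def test_run_length_arithmetic(self):
        """H H H L L H H at 0.1 s: high {0.3c, 0.2c}, low {0.2}."""
        out = extract_dwells(_ideal_from_labels([1, 1, 1, 0, 0, 1, 1]))
        high, low = out["high"], out["low"]
        assert np.allclose(sorted(high.durations), [0.2, 0.3])
        assert np.all(high.censored)
        assert np.allclose(low.durations, [0.2])
        assert not low.censored[0]
        assert high.t_min == pytest.approx(0.2)

    def test_all_one_state_gives_flagged_empty_set(self):
        out = extract_dwells(_ideal_from_labels([1] * 30))
        assert out["high"].empty and out["low"].empty

    def test_truncation_index_respected(self):
        ideal = _ideal_from_labels([1, 1, 0, 0, 1, 1, 0, 0])
        shortened = IdealizedTrace(**{**ideal.__dict__, "truncation_index": 4})
        out = extract_dwells(shortened)
        assert len(out["low"].durations) == 1

    def test_simulated_low_dwells_recover_k32(self):
        """Uncensored low dwells from true-path labels average ~1/k32."""
        from siteexposure.presets import DEFAULT_K21, KINETIC_PARAMS
        from siteexposure.simulate import _frame_average

        em = se.EmissionModel()
        rates = KINETIC_PARAMS["P26"].to_rateset(DEFAULT_K21)
        rng = np.random.default_rng(2)
        sets = []
        for i in range(200):
            path = se.simulate_state_path(rates, 2.0, 120.0, seed=rng)
            eff = _frame_average(path, em, 1200)
            labels = (eff > 0.45).astype(int)
            if labels.min() == labels.max():
                continue
            sets.append(extract_dwells(_ideal_from_labels(labels))["low"])
        pooled = pool_dwells(sets)
        fit = fit_exponential_mle(pooled, 1)
        k_lh = se.k_low_to_high(0.66, 0.11, 2.5, 2.0)
        assert fit.rates[0] == pytest.approx(k_lh, rel=0.10)


class TestExponentialMle:
    def test_closed_form_equals_inverse_mean_without_truncation(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(2.0, size=500)
        fit = fit_exponential_mle(_dwellset(t), 1, t_min=0.0)
        assert fit.rates[0] == pytest.approx(1.0 / t.mean(), rel=1e-12)

    def test_truncated_fit_recovers_rate(self):
        """Truncation at t_min = 0.2 s leaves the MLE unbiased (3 SE)."""
        rng = np.random.default_rng(1)
        rate = 0.66
        t = rng.exponential(1.0 / rate, size=10_000)
        t = t[t >= 0.2]
        fit = fit_exponential_mle(_dwellset(t, t_min=0.2), 1, t_min=0.2)
        se_rate = rate / np.sqrt(len(t))
        assert abs(fit.rates[0] - rate) < 3 * se_rate

    def test_survival_likelihood_uses_censored_dwells(self):
        """Right-censored dwells push the rate down vs ignoring them."""
        rng = np.random.default_rng(2)
        t = rng.exponential(1.0, size=200)
        cens = np.zeros(200, bool)
        cens[:50] = True
        surv = fit_exponential_mle(_dwellset(t, cens), 1, censoring="survival")
        drop = fit_exponential_mle(_dwellset(t, cens), 1, censoring="drop")
        assert surv.rates[0] < drop.rates[0]

    def test_two_component_mixture_recovered(self):
        """70/30 mixture of rates (2.0, 0.3) recovered within 15% at n=2000."""
        rng = np.random.default_rng(3)
        n = 2000
        comp = rng.random(n) < 0.7
        t = np.where(comp, rng.exponential(1 / 2.0, n), rng.exponential(1 / 0.3, n))
        fit = fit_exponential_mle(_dwellset(t), 2, t_min=0.0)
        assert fit.rates[0] == pytest.approx(2.0, rel=0.15)
        assert fit.rates[1] == pytest.approx(0.3, rel=0.15)
        assert fit.amplitudes[0] == pytest.approx(0.7, abs=0.08)

    def test_insufficient_dwells_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential_mle(_dwellset([1.0] * 5), 1, t_min=0.0)
        with pytest.raises(ValueError):
            fit_exponential_mle(_dwellset([1.0] * 30), 2, t_min=0.0)

    def test_primary_rate_is_majority_amplitude_component(self):
        fit = se.ExpFit(2, (5.0, 0.5), (0.3, 0.7), -10.0, 100, 0.0)
        assert fit.primary_rate == 0.5
        tie = se.ExpFit(2, (5.0, 0.5), (0.5, 0.5), -10.0, 100, 0.0)
        assert tie.primary_rate == 5.0  # tie goes to the faster rate


class TestModelSelection:
    def _fits(self, t, t_min=0.0):
        ds = _dwellset(t, t_min=t_min)
        return (fit_exponential_mle(ds, 1, t_min=t_min),
                fit_exponential_mle(ds, 2, t_min=t_min))

    def test_single_exponential_data_selects_one_component(self):
        """Type-I control: 1 component chosen in >= 90% of pure-exp repeats."""
        rng = np.random.default_rng(4)
        chose_one = 0
        reps = 100
        for _ in range(reps):
            t = rng.exponential(1.0, size=1000)
            fit1, fit2 = self._fits(t)
            chosen, _ = select_dwell_model(fit1, fit2, alpha=0.05)
            chose_one += chosen.n_components == 1
        assert chose_one >= 0.90 * reps

    def test_well_separated_mixture_selects_two_components(self):
        """Power: 2 components chosen in >= 95% of mixture repeats."""
        rng = np.random.default_rng(5)
        chose_two = 0
        reps = 100
        for _ in range(reps):
            comp = rng.random(1000) < 0.6
            t = np.where(comp, rng.exponential(1 / 5.0, 1000),
                         rng.exponential(1 / 0.2, 1000))
            fit1, fit2 = self._fits(t)
            chosen, _ = select_dwell_model(fit1, fit2, alpha=0.05)
            chose_two += chosen.n_components == 2
        assert chose_two >= 0.95 * reps

    def test_tie_goes_to_single_component(self):
        f1 = se.ExpFit(1, (1.0,), (1.0,), -50.0, 100, 0.0)
        f2 = se.ExpFit(2, (2.0, 1.0), (0.5, 0.5), -50.0, 100, 0.0)
        chosen, rec = select_dwell_model(f1, f2)
        assert chosen.n_components == 1
        assert rec["p_value"] == 1.0

    def test_mismatched_inputs_rejected(self):
        f1 = se.ExpFit(1, (1.0,), (1.0,), -50.0, 100, 0.0)
        f2 = se.ExpFit(2, (2.0, 1.0), (0.5, 0.5), -49.0, 120, 0.0)
        with pytest.raises(ValueError):
            select_dwell_model(f1, f2)


class TestRatesAtConcentration:
    def _cohort_dwells(self, rate_hl=0.5, rate_lh=0.8, n_traces=60, seed=0):
        """Alternating-renewal labels generated directly from two rates."""
        rng = np.random.default_rng(seed)
        out = []
        ft = 0.1
        for i in range(n_traces):
            labels = []
            state = 1
            t = 0.0
            while t < 120.0:
                lam = rate_hl if state else rate_lh
                d = rng.exponential(1.0 / lam)
                labels.extend([state] * max(int(round(d / ft)), 1))
                t += d
                state = 1 - state
            ideal = _ideal_from_labels(labels[:1200], conc=5.0, trace_id=f"t{i}")
            out.append(extract_dwells(ideal))
        return out

    def test_rates_match_generator(self):
        ds = self._cohort_dwells()
        pt = rates_at_concentration(ds, 5.0, n_boot=80, seed=1)
        assert pt.k_hl == pytest.approx(0.5, rel=3 * pt.k_hl_se / 0.5 + 0.02)
        assert pt.k_lh == pytest.approx(0.8, rel=3 * pt.k_lh_se / 0.8 + 0.02)

    def test_bootstrap_reproducible_under_seed(self):
        ds = self._cohort_dwells()
        a = rates_at_concentration(ds, 5.0, n_boot=50, seed=9)
        b = rates_at_concentration(ds, 5.0, n_boot=50, seed=9)
        assert a.k_hl_se == b.k_hl_se
        assert a.k_lh_se == b.k_lh_se

    def test_contaminant_component_does_not_shift_primary_rate(self):
        """A <= 10%-amplitude slow contaminant leaves the primary rate intact."""
        rng = np.random.default_rng(6)
        n = 3000
        comp = rng.random(n) < 0.9
        t = np.where(comp, rng.exponential(1 / 1.5, n), rng.exponential(1 / 0.15, n))
        t = t[t >= 0.2]
        ds = _dwellset(t, t_min=0.2)
        fit2 = fit_exponential_mle(ds, 2)
        assert fit2.primary_rate == pytest.approx(1.5, rel=0.10)


def test_censoring_policy_changes_estimate_in_expected_direction():
    """Dropping censored dwells removes the downward bias that treating them
    as complete would cause: the drop estimate exceeds the survival one."""
    rng = np.random.default_rng(7)
    # observation-window censoring: dwells sampled within a 10 s window
    sets = []
    for i in range(300):
        t_total = 0.0
        durations, cens = [], []
        while True:
            d = rng.exponential(1.0 / 0.4)
            if t_total + d > 10.0:
                durations.append(10.0 - t_total)
                cens.append(True)
                break
            durations.append(d)
            cens.append(False)
            t_total += d
        sets.append(_dwellset(durations, cens))
    pooled = pool_dwells(sets)
    surv = fit_exponential_mle(pooled, 1, censoring="survival")
    drop = fit_exponential_mle(pooled, 1, censoring="drop")
    # survival likelihood is unbiased; dropping censored dwells loses the
    # long right tail and overestimates the rate
    assert drop.rates[0] > surv.rates[0]
    assert surv.rates[0] == pytest.approx(0.4, rel=0.05)
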