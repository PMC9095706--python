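"""Tests for trace normalisation, calibration, scrambling fits and batch QC."""

import numpy as np
import pytest

from scramblekit import (
    AssayDesign,
    FluorescenceTrace,
    ScramblingParams,
    calibrate_protein_free,
    fit_scrambling,
    normalize_trace,
    qc_batch,
    simulate_trace,
)
from scramblekit.fitting import InsufficientBaselineError


def _pf_params(li_pf=0.5, gamma=0.02, leak=0.0):
    return ScramblingParams(alpha=0.0, beta=0.0, gamma=gamma, f0=1.0, li_pf=li_pf, leak=leak)


class TestNormalize:
    def test_constant_baseline_scales_to_one(self):
        tr = FluorescenceTrace(
            time=np.arange(40.0),
            fluorescence=np.where(np.arange(40.0) < 20, 5.0, 2.5),
            dithionite_time=20.0,
        )
        out = normalize_trace(tr)
        assert out.normalized
        assert np.allclose(out.fluorescence[out.pre_mask], 1.0)
        assert np.allclose(out.fluorescence[out.post_mask], 0.5)

    def test_generator_round_trip_baseline_is_unity(self, canonical_params):
        tr = simulate_trace(canonical_params, AssayDesign(noise_sd=0.01), seed=3)
        out = normalize_trace(tr)
        assert np.mean(out.fluorescence[out.pre_mask]) == pytest.approx(1.0, abs=1e-12)
        # first post-addition sample is ~1 up to noise
        assert out.post_fluorescence[0] == pytest.approx(1.0, abs=0.05)

    def test_insufficient_baseline_raises(self):
        tr = FluorescenceTrace(
            time=np.arange(30.0), fluorescence=np.ones(30), dithionite_time=3.0
        )
        with pytest.raises(InsufficientBaselineError):
            normalize_trace(tr)

    def test_zero_baseline_raises(self):
        tr = FluorescenceTrace(
            time=np.arange(30.0), fluorescence=np.zeros(30), dithionite_time=15.0
        )
        with pytest.raises(InsufficientBaselineError):
            normalize_trace(tr)


class TestCalibrateProteinFree:
    def test_noiseless_recovery(self, noiseless_design):
        tr = simulate_trace(_pf_params(), noiseless_design, seed=0)
        cal = calibrate_protein_free([tr])
        assert cal.li_pf == pytest.approx(0.5, rel=1e-3)
        assert cal.gamma == pytest.approx(0.02, rel=1e-3)
        assert cal.leak == pytest.approx(0.0, abs=1e-8)

    def test_leak_recovered_within_confidence_interval(self):
        leak = 5.4e-5
        traces = [
            simulate_trace(_pf_params(leak=leak), AssayDesign(noise_sd=0.01), seed=s)
            for s in range(20)
        ]
        cal = calibrate_protein_free(traces)
        lo, hi = cal.leak_confidence_interval()
        assert lo <= leak <= hi

    def test_fully_protected_label_flags_gamma_unidentifiable(self, noiseless_design):
        tr = simulate_trace(_pf_params(li_pf=1.0), noiseless_design, seed=0)
        with pytest.warns(UserWarning, match="unidentifiable"):
            cal = calibrate_protein_free([tr])
        assert not cal.gamma_identifiable


class TestFitScrambling:
    def test_noiseless_recovery_under_one_percent(self, canonical_params, noiseless_design):
        tr = normalize_trace(simulate_trace(canonical_params, noiseless_design, seed=0))
        fit = fit_scrambling(tr, li_pf=0.5, gamma=0.02)
        e = fit.estimates
        assert e.alpha == pytest.approx(0.05, rel=0.01)
        assert e.beta == pytest.approx(0.03, rel=0.01)
        assert e.f0 == pytest.approx(0.3, rel=0.01)
        assert fit.converged and fit.n_starts_converged > 0

    def test_symmetric_truth_gives_symmetric_fit(self, noiseless_design):
        p = ScramblingParams(alpha=0.04, beta=0.04, gamma=0.02, f0=0.3, li_pf=0.5)
        tr = normalize_trace(simulate_trace(p, noiseless_design, seed=0))
        e = fit_scrambling(tr, li_pf=0.5, gamma=0.02).estimates
        assert e.alpha == pytest.approx(e.beta, rel=1e-3)

    def test_recovery_in_identifiable_regime(self):
        """Monte-Carlo recovery: with 1% noise and scrambling rates in the
        regime where the fast eigenmode rises above the noise floor
        (alpha+beta comparable to gamma), median relative errors of alpha
        and beta stay below 5%."""
        rng = np.random.default_rng(2024)
        err_a, err_b = [], []
        for _ in range(12):
            a = 10 ** rng.uniform(np.log10(3e-3), np.log10(0.03))
            b = 10 ** rng.uniform(np.log10(3e-3), np.log10(0.03))
            f0 = rng.uniform(0.1, 0.6)
            p = ScramblingParams(alpha=a, beta=b, gamma=0.02, f0=f0, li_pf=0.5)
            tr = simulate_trace(p, AssayDesign(noise_sd=0.01), seed=int(rng.integers(2**31)))
            e = fit_scrambling(normalize_trace(tr), li_pf=0.5, gamma=0.02).estimates
            err_a.append(abs(e.alpha - a) / a)
            err_b.append(abs(e.beta - b) / b)
        assert np.median(err_a) < 0.05
        assert np.median(err_b) < 0.05

    def test_bias_shrinks_with_noise(self, canonical_params):
        """The estimator is consistent: average error decreases as the
        noise level drops."""
        def mean_err(noise, n=6):
            errs = []
            for s in range(n):
                tr = simulate_trace(canonical_params, AssayDesign(noise_sd=noise), seed=s)
                e = fit_scrambling(normalize_trace(tr), 0.5, 0.02).estimates
                errs.append(abs(e.alpha - 0.05) / 0.05)
            return np.mean(errs)

        assert mean_err(0.002) < mean_err(0.02)

    def test_residuals_have_no_trend_for_correct_model(self, canonical_params, noiseless_design):
        """Noiseless truth fit leaves residuals at solver tolerance: no
        systematic lack of fit."""
        from scramblekit.kinetics import closed_form_fluorescence

        tr = normalize_trace(simulate_trace(canonical_params, noiseless_design, seed=0))
        fit = fit_scrambling(tr, 0.5, 0.02)
        resid = closed_form_fluorescence(fit.estimates, tr.post_time) - tr.post_fluorescence
        assert np.max(np.abs(resid)) < 1e-8


class TestBatchQC:
    REF_MEAN = {"alpha": 0.10, "beta": 0.08}
    REF_SD = {"alpha": 0.02, "beta": 0.02}

    def test_control_at_mean_is_kept(self):
        qc = qc_batch({"b1": {"alpha": 0.10, "beta": 0.08}}, self.REF_MEAN, self.REF_SD)
        assert qc.decision["b1"] == "keep"

    def test_control_beyond_three_sd_discards_whole_batch(self):
        qc = qc_batch(
            {"b1": {"alpha": 0.10 + 3.5 * 0.02, "beta": 0.08}},
            self.REF_MEAN,
            self.REF_SD,
        )
        assert qc.decision["b1"] == "discard"
        assert qc.discarded_batches == ["b1"]

    def test_exactly_three_sd_is_kept(self):
        """Boundary convention: the rule is strict inequality."""
        qc = qc_batch(
            {"b1": {"alpha": 0.10 + 3.0 * 0.02, "beta": 0.08}},
            self.REF_MEAN,
            self.REF_SD,
        )
        assert qc.decision["b1"] == "keep"

    def test_order_invariance(self):
        batches = {
            "b1": {"alpha": 0.10},
            "b2": {"alpha": 0.18},
            "b3": {"alpha": 0.11},
        }
        ref_m, ref_s = {"alpha": 0.10}, {"alpha": 0.02}
        fwd = qc_batch(batches, ref_m, ref_s).decision
        rev = qc_batch(dict(reversed(batches.items())), ref_m, ref_s).decision
        assert fwd == rev

    def test_missing_reference_raises(self):
        with pytest.raises(KeyError):
            qc_batch({"b1": {"f0": 0.3}}, self.REF_MEAN, self.REF_SD)

    def test_too_few_historical_controls_raise(self):
        with pytest.raises(ValueError):
            qc_batch({"b1": {"alpha": 0.1}}, self.REF_MEAN, self.REF_SD, n_reference=1)
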