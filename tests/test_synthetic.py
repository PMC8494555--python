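"""Generators: determinism, invariants, closed-form oracle self-consistency."""

import dataclasses

import numpy as np
import pytest

from ceuskit import (
    CohortSpec,
    Conventions,
    DefectWaveSpec,
    GrassWaveSpec,
    PerfusionParams,
    add_tic_noise,
    analytic_tic_parameters,
    generate_cohort,
    generate_defect_wave,
    generate_grass_wave,
    perfusion_curve,
    quantify,
)
from ceuskit.codec import rle_encode
from ceuskit.errors import InvalidSpecError
from ceuskit.serialize import signal_to_stream
from ceuskit.synthetic import default_bile_duct_cohort


class TestWaveGenerators:
    def test_invalid_specs_rejected(self):
        with pytest.raises(InvalidSpecError):
            generate_grass_wave(GrassWaveSpec(length=0), seed=0)
        with pytest.raises(InvalidSpecError):
            generate_defect_wave(
                DefectWaveSpec(echo_amp_range=(5.0, 5.0)), seed=0
            )

    @pytest.mark.parametrize("generator,spec", [
        (generate_grass_wave, GrassWaveSpec()),
        (generate_defect_wave, DefectWaveSpec()),
    ])
    def test_seed_determinism(self, generator, spec):
        a = generator(spec, seed=99)
        b = generator(spec, seed=99)
        c = generator(spec, seed=100)
        assert np.array_equal(a.samples, b.samples)
        assert not np.array_equal(a.samples, c.samples)

    def test_silent_defect_wave_is_zero(self):
        sig = generate_defect_wave(DefectWaveSpec(n_echoes=0, noise_sd=0.0), seed=0)
        assert np.all(sig.samples == 0)

    def test_grass_wave_is_rle_compressible(self):
        spec = GrassWaveSpec(run_length_mean=20, spike_rate=1)
        sig = generate_grass_wave(spec, seed=3)
        raw = signal_to_stream(sig)
        assert 100.0 * len(rle_encode(raw).payload) / len(raw) < 100.0

    def test_grass_runs_have_roughly_the_requested_mean_length(self):
        sig = generate_grass_wave(GrassWaveSpec(length=20000, spike_rate=0), seed=5)
        changes = np.nonzero(np.diff(sig.samples))[0]
        mean_run = len(sig.samples) / (len(changes) + 1)
        # runs merge when neighbouring values coincide, so the observed mean
        # can only exceed the nominal one
        assert 0.8 * GrassWaveSpec().run_length_mean < mean_run < 3 * GrassWaveSpec().run_length_mean


class TestPerfusionCurve:
    def test_zero_amplitude_constant_at_baseline(self):
        p = PerfusionParams(A=0.0, baseline=7.0)
        curve = perfusion_curve(p)
        assert np.allclose(curve.intensities, 7.0)

    def test_flat_before_arrival_and_nonnegative(self, fast_bolus):
        curve = perfusion_curve(fast_bolus)
        pre = curve.times <= fast_bolus.t0
        assert np.allclose(curve.intensities[pre], fast_bolus.baseline)
        assert np.all(curve.intensities >= 0)

    def test_analytic_peak_position_and_height(self):
        p = PerfusionParams(t0=10.0, alpha=2.0, beta=5.0, A=1.0, baseline=0.0)
        curve = perfusion_curve(p)
        k = int(np.argmax(curve.intensities))
        assert curve.times[k] == pytest.approx(20.0, abs=p.dt)
        expected_peak = (2.0 * 5.0) ** 2.0 * np.exp(-2.0)
        assert curve.intensities[k] == pytest.approx(expected_peak, rel=1e-3)


class TestNoise:
    def test_zero_noise_identity(self, fast_curve):
        assert np.array_equal(
            add_tic_noise(fast_curve, 0.0, seed=1).intensities, fast_curve.intensities
        )

    def test_seed_determinism(self, fast_curve):
        a = add_tic_noise(fast_curve, 3.0, seed=5)
        b = add_tic_noise(fast_curve, 3.0, seed=5)
        assert np.array_equal(a.intensities, b.intensities)

    def test_negative_sd_rejected(self, fast_curve):
        with pytest.raises(InvalidSpecError):
            add_tic_noise(fast_curve, -1.0, seed=0)

    def test_noise_is_unbiased_at_fixed_time(self, fast_curve):
        k = len(fast_curve.times) // 2
        sd = 4.0
        values = [
            add_tic_noise(fast_curve, sd, seed=s).intensities[k] for s in range(1000)
        ]
        se = sd / np.sqrt(len(values))
        assert abs(np.mean(values) - fast_curve.intensities[k]) < 3 * se


class TestAnalyticOracle:
    def test_zero_amplitude_degenerates(self):
        p = analytic_tic_parameters(PerfusionParams(A=0.0))
        assert p.AUC == 0.0
        assert p.Grad is None and p.K_UP is None

    def test_closed_form_ttp(self):
        p = analytic_tic_parameters(PerfusionParams(t0=10, alpha=2, beta=5, A=1))
        assert p.TTP == pytest.approx(20.0)

    def test_quadrature_convergence(self, fast_bolus):
        conv_lo = Conventions(oracle_refinement=100)
        conv_hi = Conventions(oracle_refinement=300)
        a = analytic_tic_parameters(fast_bolus, conv_lo)
        b = analytic_tic_parameters(fast_bolus, conv_hi)
        for name in ("AUC", "mTT", "Grad"):
            va, vb = getattr(a, name), getattr(b, name)
            assert abs(va - vb) / abs(vb) < 1e-3

    def test_oracle_matches_brute_force_fine_grid(self, fast_bolus, slow_bolus):
        """Every indicator agrees with direct evaluation on a 10x finer grid."""
        for params in (fast_bolus, slow_bolus):
            oracle = analytic_tic_parameters(params)
            fine = dataclasses.replace(params, dt=params.dt / 10)
            est = quantify(perfusion_curve(fine))
            for name, ov in oracle.as_dict().items():
                ev = getattr(est, name)
                assert ov is not None and ev is not None
                tol = 0.001 if name in ("AUC", "TTP", "baseline") else 0.01
                assert ev == pytest.approx(ov, rel=tol), name


class TestCohort:
    def small_spec(self, **kw):
        base = default_bile_duct_cohort(seed=42)
        kw.setdefault("n_per_group", {"benign": 4, "malignant": 4})
        return dataclasses.replace(base, **kw)

    def test_zero_cv_shares_parameters_within_group(self):
        spec = self.small_spec(between_subject_cv=0.0)
        records = generate_cohort(spec)
        benign = [r.true_params for r in records if r.group_label == "benign"]
        assert all(p == benign[0] for p in benign)

    def test_seed_determinism(self):
        spec = self.small_spec()
        a = generate_cohort(spec)
        b = generate_cohort(spec)
        assert all(
            np.array_equal(x.curve.intensities, y.curve.intensities)
            for x, y in zip(a, b)
        )

    def test_default_effect_directions_in_true_parameters(self):
        records = generate_cohort(self.small_spec(n_per_group=30))
        ttp = {
            g: np.mean([r.true_params.ttp for r in records if r.group_label == g])
            for g in ("benign", "malignant")
        }
        assert ttp["malignant"] < ttp["benign"]

    def test_misconfigured_directions_warn_but_run(self, caplog):
        base = default_bile_duct_cohort(seed=0)
        swapped = dataclasses.replace(
            base,
            n_per_group=2,
            group_param_means={
                "benign": base.group_param_means["malignant"],
                "malignant": base.group_param_means["benign"],
            },
        )
        with caplog.at_level("WARNING", logger="ceuskit.synthetic"):
            records = generate_cohort(swapped)
        assert len(records) == 4
        assert any("TTP" in rec.message for rec in caplog.records)

    def test_noiseless_zero_cv_cohort_matches_oracle(self):
        spec = self.small_spec(between_subject_cv=0.0, noise_sd=0.0)
        records = generate_cohort(spec)
        for rec in records[:2]:
            oracle = analytic_tic_parameters(rec.true_params)
            est = quantify(rec.curve)
            assert est.TTP == pytest.approx(oracle.TTP, rel=0.02)
            assert est.AUC == pytest.approx(oracle.AUC, rel=0.02)

    def test_undersized_group_rejected(self):
        with pytest.raises(InvalidSpecError):
            generate_cohort(self.small_spec(n_per_group=1))
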