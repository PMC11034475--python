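"""Baseline correction, contact detection, indentation axis, rupture."""

import numpy as np
import pytest

from poremech.errors import DataError
from poremech.io import ForceCurve
from poremech.preprocess import (ContactAnnotation, PreprocessConfig,
                                 correct_baseline, find_breakthrough,
                                 find_contact_point, to_indentation)
from poremech.synthetic import generate_curve, make_preset

PN = 1e-12
NM = 1e-9


def _flat_curve(n=200, noise=0.0, seed=0):
    z = np.linspace(0, 150e-9, n)
    f = np.random.default_rng(seed).normal(0.0, noise, n)
    return ForceCurve(curve_id="t", z=z, force=f, spring_constant=0.03)


class TestBaseline:
    def test_recovers_generating_line(self):
        # tilted synthetic curves: fitted slope/offset near the truth
        preset = make_preset("PMC")
        for i in range(20):
            curve, _, truth = generate_curve(preset, [3, i])
            _, ann = correct_baseline(curve)
            # 3 standard errors of an OLS line over the baseline window
            k = int(0.4 * len(curve))
            span = curve.z[k - 1] - curve.z[0]
            noise = preset.noise_rms_pN * PN
            se_slope = noise * np.sqrt(12.0 / k) / span
            se_offset = 2.0 * noise / np.sqrt(k)
            assert ann.baseline_slope == pytest.approx(
                truth.baseline_slope, abs=3 * se_slope)
            assert ann.baseline_offset == pytest.approx(
                truth.baseline_offset, abs=3 * se_offset)

    def test_zero_noise_zero_tilt_is_identity(self):
        curve = _flat_curve()
        corrected, ann = correct_baseline(curve)
        np.testing.assert_allclose(corrected.force, curve.force, atol=1e-18)
        assert ann.baseline_slope == pytest.approx(0.0, abs=1e-12)

    def test_idempotence(self):
        preset = make_preset("PMC")
        curve, _, _ = generate_curve(preset, [3, 0])
        once, _ = correct_baseline(curve)
        twice, ann2 = correct_baseline(once)
        # second pass finds nothing left to remove
        assert abs(ann2.baseline_slope) < 0.005 * PN / NM
        assert abs(ann2.baseline_offset) < 1.5 * PN
        np.testing.assert_allclose(twice.force, once.force, atol=2 * PN)

    def test_corrected_noncontact_mean_near_zero(self):
        curve = _flat_curve(noise=10e-12, seed=4)
        corrected, ann = correct_baseline(curve)
        k = int(0.4 * len(curve))
        assert abs(corrected.force[:k].mean()) < ann.baseline_noise / np.sqrt(k)

    def test_too_short_baseline_region_raises(self):
        curve = _flat_curve(n=60)
        with pytest.raises(DataError, match="baseline"):
            correct_baseline(curve, PreprocessConfig(baseline_fraction=0.05))


class TestContact:
    def test_pure_noise_curve_has_no_contact(self):
        curve = _flat_curve(noise=10e-12, seed=7)
        corrected, ann = correct_baseline(curve)
        ann = find_contact_point(corrected, ann)
        assert ann.contact_index is None

    def test_step_function_contact_at_step(self):
        n, k = 200, 120
        z = np.linspace(0, 150e-9, n)
        f = np.where(np.arange(n) >= k, 500e-12, 0.0)
        curve = ForceCurve(curve_id="s", z=z, force=f, spring_constant=0.03)
        _, ann = correct_baseline(curve)
        ann = ContactAnnotation(baseline_noise=10e-12)
        ann = find_contact_point(curve, ann)
        assert ann.contact_index == k

    def test_snap_in_depth_and_contact_after_dip(self):
        # hand-built: flat, a -80 pN dip, then a clean linear rise
        z = np.linspace(0, 99, 100) * NM
        f = np.zeros(100)
        f[60:70] = -80e-12 * np.sin(np.pi * np.arange(10) / 10) ** 2
        f[70:] = np.arange(30) * 10e-12
        curve = ForceCurve(curve_id="snap", z=z, force=f,
                           spring_constant=0.03)
        ann = ContactAnnotation(baseline_noise=5e-12)
        ann = find_contact_point(curve, ann)
        assert ann.snap_in_depth == pytest.approx(80e-12, rel=0.05)
        assert 69 <= ann.contact_index <= 71

    def test_contact_accuracy_on_synthetic_ensemble(self):
        # 95th percentile of |detected - true| within 2 nm at 10 pN noise
        preset = make_preset("PMC")
        errs = []
        for i in range(100):
            curve, _, truth = generate_curve(preset, [7, i])
            corrected, ann = correct_baseline(curve)
            ann = find_contact_point(corrected, ann)
            if ann.contact_index is None:
                continue
            errs.append(abs(ann.contact_z - truth.contact_z))
        assert len(errs) >= 95
        assert np.percentile(errs, 95) < 2.0 * NM


class TestIndentationAxis:
    def test_indentation_axis_passthrough_is_pure_shift(self):
        z = np.linspace(0, 100e-9, 120)
        f = np.linspace(0, 100e-12, 120)
        curve = ForceCurve(curve_id="i", z=z, force=f, spring_constant=0.03,
                           is_indentation_axis=True)
        ann = ContactAnnotation(baseline_noise=1e-12, contact_index=30,
                                contact_z=float(z[30]))
        delta, ff = to_indentation(curve, ann)
        np.testing.assert_allclose(delta, z[30:] - z[30], atol=1e-18)

    def test_rigid_substrate_gives_zero_indentation(self):
        # force rising exactly along the cantilever stiffness: delta ~ 0
        k = 0.03
        z = np.linspace(0, 100e-9, 200)
        contact = 100
        f = np.where(np.arange(200) >= contact,
                     (z - z[contact]) * k, 0.0)
        curve = ForceCurve(curve_id="r", z=z, force=f, spring_constant=k)
        ann = ContactAnnotation(baseline_noise=1e-12, contact_index=contact,
                                contact_z=float(z[contact]))
        delta, ff = to_indentation(curve, ann)
        assert np.max(np.abs(delta)) < 1e-15
        assert ff[-1] > 0

    def test_recovered_delta_matches_generator(self):
        # noiseless, baseline-free preset: separation construction inverts
        # the generator's spring-in-series mapping to ~0.1 nm
        preset = make_preset("PMC")
        quiet = type(preset)(**{**preset.__dict__,
                                "noise_rms_pN": 0.0,
                                "baseline_slope_range_pN_nm": (0.0, 0.0),
                                "baseline_offset_range_pN": (0.0, 0.0),
                                "snap_in_prob": 0.0})
        curve, meta, truth = generate_curve(quiet, [5, 1])
        corrected, ann = correct_baseline(curve)
        ann = find_contact_point(corrected, ann)
        delta, ff = to_indentation(corrected, ann, meta)
        # compare against the generator's forward model inversion
        from poremech.fvk import MembraneSpec, indentation_exact
        spec = MembraneSpec(E=truth.E, sigma=truth.sigma,
                            h=meta.bilayer_thickness, R=truth.R)
        pre_rupture = ff > 5e-12
        pre_rupture[np.argmax(ff):] = False
        expected = indentation_exact(ff[pre_rupture], spec)
        err = np.sqrt(np.mean((delta[pre_rupture] - expected) ** 2))
        assert err < 1.0 * NM

    def test_missing_contact_rejected(self):
        curve = _flat_curve()
        with pytest.raises(DataError):
            to_indentation(curve, ContactAnnotation(baseline_noise=1e-12))


class TestBreakthrough:
    def _ann(self):
        return ContactAnnotation(baseline_noise=10e-12)

    def test_single_drop(self):
        f = np.concatenate([np.linspace(0, 400e-12, 40),
                            np.full(20, 50e-12)])
        delta = np.linspace(0, 30e-9, 60)
        ev = find_breakthrough(f, delta, self._ann())
        assert ev is not None
        assert ev.index == 40
        assert ev.bf == pytest.approx(f[39])
        assert ev.delta_at_bf == pytest.approx(delta[39])

    def test_first_of_two_drops_wins(self):
        f = np.concatenate([np.linspace(0, 300e-12, 30),
                            np.full(10, 100e-12),
                            np.linspace(100e-12, 500e-12, 30),
                            np.full(10, 50e-12)])
        delta = np.linspace(0, 40e-9, 80)
        ev = find_breakthrough(f, delta, self._ann())
        assert ev.index == 30
        assert ev.bf == pytest.approx(300e-12)

    def test_subthreshold_drop_returns_none(self):
        # 30-point curve with a 20 pN (2x noise) dip only
        f = np.linspace(0, 150e-12, 30)
        f[20:] -= 20e-12
        ev = find_breakthrough(f, np.linspace(0, 10e-9, 30), self._ann())
        assert ev is None

    def test_single_sample_noise_spike_rejected(self):
        # an isolated negative outlier must not count as a rupture
        f = np.linspace(0, 300e-12, 60)
        f[30] -= 80e-12
        ev = find_breakthrough(f, np.linspace(0, 20e-9, 60), self._ann())
        assert ev is None

    def test_contact_precedes_breakthrough_on_ensemble(self):
        from poremech.analysis import analyze_curve
        preset = make_preset("PMC-")
        for i in range(25):
            curve, meta, _ = generate_curve(preset, [9, i])
            a = analyze_curve(curve, meta)
            if a.event is not None:
                assert a.contact.contact_index < a.event.index

    def test_extracted_bf_matches_generator_distribution(self):
        preset = make_preset("PMC")
        from poremech.analysis import analyze_curve
        from poremech.ensemble import fit_gaussian_peak
        bf = []
        for i in range(120):
            curve, meta, _ = generate_curve(preset, [21, i])
            a = analyze_curve(curve, meta)
            if a.event is not None:
                bf.append(a.event.bf / PN)
        pf = fit_gaussian_peak(np.array(bf), "BF")
        assert abs(pf.peak - preset.BF_mean_pN) < 3 * np.hypot(
            pf.peak_se, preset.BF_sd_pN / np.sqrt(len(bf)))
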