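"""Generator determinism, preset values, ground-truth consistency."""

import dataclasses
import filecmp

import numpy as np
import pytest

from poremech.errors import ConfigError, DataError
from poremech.fvk import MembraneSpec, force_exact
from poremech.synthetic import (SyntheticPreset, generate_curve,
                                generate_dataset, make_preset,
                                microfluidic_inputs)

PN = 1e-12


class TestPresets:
    def test_pmc_central_values(self):
        p = make_preset("PMC")
        assert p.E_mean_MPa == 513.0
        assert p.sigma_mean_mN_m == 5.2
        assert p.h_nm == 6.7
        assert p.BF_mean_pN == 366.0
        assert p.nu == 0.485

    def test_pmc_minus_central_values(self):
        p = make_preset("PMC-")
        assert p.E_mean_MPa == 21.4
        assert p.sigma_mean_mN_m == 2.0
        assert p.h_nm == 6.0
        assert p.BF_mean_pN == 146.0

    def test_unknown_label_raises(self):
        with pytest.raises(ConfigError):
            make_preset("DOPC")

    def test_spread_invariant_enforced(self):
        with pytest.raises(ConfigError):
            dataclasses.replace(make_preset("PMC"), E_sd_MPa=600.0)

    @pytest.mark.parametrize("label", ["PMC", "PMC-"])
    def test_rupture_within_ramp_for_95_percent(self, profile, label):
        assert make_preset(label).validate() >= 0.95

    def test_json_round_trip(self):
        p = make_preset("PMC-")
        assert SyntheticPreset.from_json(p.to_json()) == p


class TestGenerateCurve:
    def test_same_seed_bit_identical(self, profile):
        p = make_preset("PMC")
        c1, m1, t1 = generate_curve(p, [1, 0])
        c2, m2, t2 = generate_curve(p, [1, 0])
        np.testing.assert_array_equal(c1.z, c2.z)
        np.testing.assert_array_equal(c1.force, c2.force)
        assert t1 == t2

    def test_different_seeds_differ(self, profile):
        p = make_preset("PMC")
        c1, _, _ = generate_curve(p, [1, 0])
        c2, _, _ = generate_curve(p, [1, 1])
        assert not np.array_equal(c1.force, c2.force)

    def test_degenerate_preset_equals_forward_model(self, profile):
        # no noise, no baseline, no snap-in: the post-contact force is the
        # exact forward model in series with the spring, up to rupture
        p = dataclasses.replace(
            make_preset("PMC"), noise_rms_pN=0.0,
            baseline_slope_range_pN_nm=(0.0, 0.0),
            baseline_offset_range_pN=(0.0, 0.0), snap_in_prob=0.0)
        curve, meta, truth = generate_curve(p, [2, 3])
        spec = MembraneSpec(E=truth.E, sigma=truth.sigma,
                            h=meta.bilayer_thickness, R=truth.R)
        pre = curve.z <= truth.contact_z
        np.testing.assert_allclose(curve.force[pre], 0.0, atol=1e-20)
        sel = (curve.z > truth.contact_z)
        sel[truth.rupture_index:] = False
        delta = (curve.z[sel] - truth.contact_z
                 - curve.force[sel] / curve.spring_constant)
        np.testing.assert_allclose(curve.force[sel],
                                   force_exact(delta, spec),
                                   atol=0.2e-12)

    def test_rupture_force_distribution_matches_preset(self, profile):
        p = make_preset("PMC")
        bf = [generate_curve(p, [0, i])[2].rupture_force / PN
              for i in range(200)]
        bf = np.array(bf)
        assert np.all(bf > 0)
        se = p.BF_sd_pN / np.sqrt(bf.size)
        # one sampling-resolution step of headroom on top of 3 SE
        assert abs(bf.mean() - p.BF_mean_pN) < 3 * se + 3.0

    def test_ground_truth_annotations_consistent(self, profile):
        p = make_preset("PMC-")
        curve, meta, truth = generate_curve(p, [4, 4])
        assert truth.has_rupture
        assert curve.force.size == p.samples_per_curve
        assert 0 < truth.rupture_index < p.samples_per_curve
        assert truth.rupture_delta < meta.hole_radius


class TestGenerateDataset:
    def test_file_counts_and_truth_rows(self, profile, tmp_path):
        manifest, truth = generate_dataset(make_preset("PMC"), 5, 11,
                                           tmp_path / "d")
        assert len(manifest) == 5
        assert len(truth) == 5
        assert sorted(p.name for p in (tmp_path / "d").glob("*.tsv")) == [
            f"PMC_{i:04d}.tsv" for i in range(5)]
        assert (tmp_path / "d" / "manifest.csv").exists()
        assert (tmp_path / "d" / "ground_truth.csv").exists()

    def test_rerun_is_byte_identical(self, profile, tmp_path):
        generate_dataset(make_preset("PMC-"), 3, 5, tmp_path / "a")
        generate_dataset(make_preset("PMC-"), 3, 5, tmp_path / "b")
        names = [p.name for p in sorted((tmp_path / "a").iterdir())]
        match, mismatch, errors = filecmp.cmpfiles(
            tmp_path / "a", tmp_path / "b", names, shallow=False)
        assert not mismatch and not errors

    def test_invalid_n_rejected(self, tmp_path):
        with pytest.raises(DataError):
            generate_dataset(make_preset("PMC"), 0, 1, tmp_path)


class TestMicrofluidicInputs:
    def test_pmc_pair(self):
        mi = microfluidic_inputs("PMC")
        assert (mi.gamma, mi.theta_deg) == (7.65, 31.81)

    def test_pmc_minus_pair(self):
        mi = microfluidic_inputs("PMC-")
        assert (mi.gamma, mi.theta_deg) == (5.70, 28.70)

    def test_pairs_invert_to_reported_tensions(self):
        # 2 gamma = Gamma + dW and cos(theta) = Gamma/(Gamma + dW)
        for label, Gamma, dW in [("PMC", 13.0, 2.3), ("PMC-", 10.0, 1.4)]:
            mi = microfluidic_inputs(label)
            assert 2 * mi.gamma == pytest.approx(Gamma + dW, rel=1e-3)
            assert np.cos(np.radians(mi.theta_deg)) == pytest.approx(
                Gamma / (Gamma + dW), rel=1e-3)

    def test_unknown_label(self):
        with pytest.raises(ConfigError):
            microfluidic_inputs("GUV")
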