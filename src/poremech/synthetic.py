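"""Seeded synthetic AFM approach curves with ground truth.

The generator emulates the statistical structure of indentation
experiments on pore-spanning bilayers: each curve draws a membrane
(E, sigma, R) and a rupture force from the preset's population
distributions, builds the force-vs-piezo trace with the exact FvK forward
model in series with the cantilever spring, and adds a linear baseline,
an optional snap-in dip just before contact, an abrupt rupture drop and
Gaussian force noise.  Every curve is emitted together with its
:class:`GroundTruth` so parameter-recovery tests can compare against the
generating values.

Two presets mirror the two studied lipid compositions: ``PMC`` (plasma-
membrane-like, with cholesterol and sphingomyelin) and ``PMC-`` (the same
composition without CL/SM); their central values are the fitted ensemble
parameters for those membranes, and the population spreads are package
choices documented in the preset fields.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .fvk import MembraneSpec, get_profile
from .io import (ForceCurve, CurveMetadata, DatasetManifest, write_curve,
                 write_manifest)
from .tension import MonolayerInterface

__all__ = [
    "SyntheticPreset",
    "GroundTruth",
    "make_preset",
    "generate_curve",
    "generate_dataset",
    "microfluidic_inputs",
    "PRESET_LABELS",
]

NM = 1e-9
PN = 1e-12
MPA = 1e6
MN_PER_M = 1e-3

PRESET_LABELS = ("PMC", "PMC-")


@dataclass(frozen=True)
class SyntheticPreset:
    """Generating distributions for one membrane condition.

    Central values (E, sigma, BF, h, nu, hole radii) characterise the
    condition; spreads, noise and ramp geometry define the synthetic
    instrument.  ``validate()`` checks that rupture occurs within the ramp
    for at least 95% of draws.
    """

    label: str
    E_mean_MPa: float
    E_sd_MPa: float
    sigma_mean_mN_m: float
    sigma_sd_mN_m: float
    h_nm: float
    nu: float = 0.485
    R_choices_nm: tuple = (400.0, 600.0)
    R_weights: tuple = (0.5, 0.5)
    BF_mean_pN: float = 300.0
    BF_sd_pN: float = 50.0
    noise_rms_pN: float = 10.0
    baseline_slope_range_pN_nm: tuple = (-0.05, 0.05)
    baseline_offset_range_pN: tuple = (-20.0, 20.0)
    snap_in_prob: float = 0.3
    snap_in_depth_range_pN: tuple = (20.0, 80.0)
    snap_in_width_nm: float = 4.0
    ramp_nm: float = 180.0
    samples_per_curve: int = 720
    spring_constant_N_per_m: float = 0.03
    contact_frac_range: tuple = (0.45, 0.55)

    def __post_init__(self):
        if min(self.E_mean_MPa, self.sigma_mean_mN_m, self.h_nm,
               self.BF_mean_pN, self.ramp_nm) <= 0:
            raise ConfigError("preset scales must be positive")
        if self.noise_rms_pN < 0:
            raise ConfigError("noise_rms_pN must be >= 0")
        if not self.E_sd_MPa < self.E_mean_MPa:
            raise ConfigError("E_sd must be smaller than E_mean")
        if len(self.R_choices_nm) != len(self.R_weights):
            raise ConfigError("R_choices and R_weights lengths differ")
        if self.samples_per_curve < 100:
            raise ConfigError("samples_per_curve must be >= 100")

    def validate(self, n_draws: int = 500) -> float:
        """Fraction of draws whose rupture falls inside the ramp.

        Deterministic check (fixed internal seed); raises when the
        fraction is below 0.95.
        """
        rng = np.random.default_rng(12345)
        ok = 0
        for _ in range(n_draws):
            E, sigma, R, bf = _draw_membrane(self, rng)
            spec = MembraneSpec(E=E, sigma=sigma, h=self.h_nm * NM, R=R,
                                nu=self.nu)
            prof = get_profile(self.nu)
            d = prof.scaled_deflection(bf / (spec.e2d * R), sigma / spec.e2d)
            delta = d * R
            z_needed = delta + bf / self.spring_constant_N_per_m
            budget = (1.0 - self.contact_frac_range[1]) * self.ramp_nm * NM
            ok += z_needed < budget
        frac = ok / n_draws
        if frac < 0.95:
            raise ConfigError(
                f"preset {self.label!r}: rupture falls inside the ramp for "
                f"only {frac:.0%} of draws (need >= 95%)")
        return frac

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticPreset":
        raw = json.loads(text)
        for key in ("R_choices_nm", "R_weights", "baseline_slope_range_pN_nm",
                    "baseline_offset_range_pN", "snap_in_depth_range_pN",
                    "contact_frac_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class GroundTruth:
    """Generating values of one synthetic curve (SI units)."""

    curve_id: str
    E: float
    sigma: float
    R: float
    contact_z: float
    baseline_slope: float     # N per m of z
    baseline_offset: float    # N
    rupture_force: float      # model force at the last pre-drop sample, N
    rupture_delta: float      # m
    rupture_index: int        # sample index of the first post-drop sample
    snap_in_depth: float      # N
    has_rupture: bool


def make_preset(label: str) -> SyntheticPreset:
    """Return the generating preset for a condition label.

    Central values are the fitted ensemble parameters of the two membrane
    compositions; spreads are documented package defaults (E_sd = 15% of
    the mean, sigma_sd = 20%, BF_sd = 60/40 pN, 10 pN RMS force noise).
    """
    if label == "PMC":
        return SyntheticPreset(
            label="PMC", E_mean_MPa=513.0, E_sd_MPa=0.15 * 513.0,
            sigma_mean_mN_m=5.2, sigma_sd_mN_m=0.2 * 5.2, h_nm=6.7,
            BF_mean_pN=366.0, BF_sd_pN=60.0)
    if label == "PMC-":
        return SyntheticPreset(
            label="PMC-", E_mean_MPa=21.4, E_sd_MPa=0.15 * 21.4,
            sigma_mean_mN_m=2.0, sigma_sd_mN_m=0.2 * 2.0, h_nm=6.0,
            BF_mean_pN=146.0, BF_sd_pN=40.0)
    raise ConfigError(f"unknown preset label {label!r}; "
                      f"expected one of {PRESET_LABELS}")


def _draw_membrane(preset: SyntheticPreset, rng: np.random.Generator):
    """Draw per-curve (E, sigma, R, BF) in SI; distributions truncated to
    stay physical (E, sigma) and detectable (BF above 5x noise)."""
    E = -1.0
    while E <= 0.1 * preset.E_mean_MPa:
        E = rng.normal(preset.E_mean_MPa, preset.E_sd_MPa)
    sigma = -1.0
    while sigma <= 0.1 * preset.sigma_mean_mN_m:
        sigma = rng.normal(preset.sigma_mean_mN_m, preset.sigma_sd_mN_m)
    R = rng.choice(np.asarray(preset.R_choices_nm),
                   p=np.asarray(preset.R_weights))
    bf_floor = 5.0 * preset.noise_rms_pN
    bf = -1.0
    while bf <= bf_floor:
        bf = rng.normal(preset.BF_mean_pN, preset.BF_sd_pN)
    return (E * MPA, sigma * MN_PER_M, float(R) * NM, bf * PN)


def generate_curve(preset: SyntheticPreset, seed
                   ) -> tuple[ForceCurve, CurveMetadata, GroundTruth]:
    """Generate one seeded approach curve with its ground truth.

    The same ``seed`` (an int, or the documented ``[base_seed, index]``
    counter pair) always returns a bit-identical curve.
    """
    rng = np.random.default_rng(seed)
    E, sigma, R, bf_drawn = _draw_membrane(preset, rng)
    h = preset.h_nm * NM
    spec = MembraneSpec(E=E, sigma=sigma, h=h, R=R, nu=preset.nu)
    k = preset.spring_constant_N_per_m
    ramp = preset.ramp_nm * NM
    n = preset.samples_per_curve
    contact_z = rng.uniform(*preset.contact_frac_range) * ramp
    slope = rng.uniform(*preset.baseline_slope_range_pN_nm) * PN / NM
    offset = rng.uniform(*preset.baseline_offset_range_pN) * PN
    snap_depth = (rng.uniform(*preset.snap_in_depth_range_pN) * PN
                  if rng.random() < preset.snap_in_prob else 0.0)

    z = np.linspace(0.0, ramp, n)
    signal = np.zeros(n)

    # indentation branch: invert zeta = delta + F(delta)/k on a fine grid
    prof = get_profile(preset.nu)
    e2d = spec.e2d
    s = sigma / e2d
    delta_grid = np.linspace(0.0, 0.35 * R, 3000)
    f_grid = e2d * R * prof.scaled_force(delta_grid / R, s)
    zeta_grid = delta_grid + f_grid / k
    zeta = z - contact_z
    post = zeta > 0
    delta = np.interp(zeta[post], zeta_grid, delta_grid)
    force_post = e2d * R * prof.scaled_force(delta / R, s)

    # rupture: first sample at or above the drawn threshold force
    above = np.flatnonzero(force_post >= bf_drawn)
    has_rupture = above.size > 0
    if has_rupture:
        i_rupt = int(above[0])           # first post-drop sample
        rupture_force = float(force_post[i_rupt - 1]) if i_rupt > 0 else 0.0
        rupture_delta = float(delta[i_rupt - 1]) if i_rupt > 0 else 0.0
        force_post[i_rupt:] = 0.0        # tip shoots into the open pore
        rupture_index = int(np.flatnonzero(post)[0]) + i_rupt
    else:
        rupture_force = rupture_delta = 0.0
        rupture_index = -1
    signal[post] = force_post

    if snap_depth > 0.0:
        w = preset.snap_in_width_nm * NM
        in_dip = (z > contact_z - w) & (z <= contact_z)
        x = (z[in_dip] - (contact_z - w)) / w
        signal[in_dip] -= snap_depth * np.sin(np.pi * x) ** 2

    noise = rng.normal(0.0, preset.noise_rms_pN * PN, n)
    force_total = signal + slope * z + offset + noise

    curve_id = _curve_id(preset.label, seed)
    curve = ForceCurve(curve_id=curve_id, z=z, force=force_total,
                       spring_constant=k, direction="approach",
                       condition_label=preset.label)
    meta = CurveMetadata(hole_radius=R, bilayer_thickness=h,
                         poisson_ratio=preset.nu, ramp_size=ramp,
                         temperature_C=20.0)
    truth = GroundTruth(
        curve_id=curve_id, E=E, sigma=sigma, R=R, contact_z=contact_z,
        baseline_slope=slope, baseline_offset=offset,
        rupture_force=rupture_force, rupture_delta=rupture_delta,
        rupture_index=rupture_index, snap_in_depth=snap_depth,
        has_rupture=has_rupture)
    return curve, meta, truth


def _curve_id(label: str, seed) -> str:
    if isinstance(seed, (list, tuple, np.ndarray)):
        tag = "-".join(str(int(x)) for x in seed)
    else:
        tag = str(int(seed))
    return f"{label}_{tag}"


TRUTH_COLUMNS = [
    "curve_id", "E_MPa", "sigma_mN_m", "R_nm", "contact_z_nm",
    "baseline_slope_pN_nm", "baseline_offset_pN", "rupture_force_pN",
    "rupture_delta_nm", "rupture_index", "snap_in_depth_pN", "has_rupture",
]


def truth_to_row(t: GroundTruth) -> dict:
    return {
        "curve_id": t.curve_id,
        "E_MPa": t.E / MPA,
        "sigma_mN_m": t.sigma / MN_PER_M,
        "R_nm": t.R / NM,
        "contact_z_nm": t.contact_z / NM,
        "baseline_slope_pN_nm": t.baseline_slope * NM / PN,
        "baseline_offset_pN": t.baseline_offset / PN,
        "rupture_force_pN": t.rupture_force / PN,
        "rupture_delta_nm": t.rupture_delta / NM,
        "rupture_index": t.rupture_index,
        "snap_in_depth_pN": t.snap_in_depth / PN,
        "has_rupture": t.has_rupture,
    }


def generate_dataset(preset: SyntheticPreset, n: int, base_seed: int,
                     out_dir) -> tuple[DatasetManifest, pd.DataFrame]:
    """Write ``n`` curves + sidecars, a manifest and a ground-truth table.

    Per-curve seeds follow the documented counter scheme
    ``[base_seed, i]`` for i in 0..n-1, so any single curve can be
    regenerated in isolation; re-running with identical arguments
    reproduces the directory byte for byte.
    """
    if n < 1:
        raise DataError("n must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    safe_label = preset.label.replace("-", "minus")
    entries = []
    truth_rows = []
    for i in range(n):
        curve, meta, truth = generate_curve(preset, [int(base_seed), i])
        fname = f"{safe_label}_{i:04d}.tsv"
        write_curve(curve, meta, out_dir / fname)
        entries.append((out_dir / fname,
                        (out_dir / fname).with_suffix(".json"),
                        preset.label))
        truth_rows.append(truth_to_row(truth))
    manifest = DatasetManifest(entries=entries)
    write_manifest(manifest, out_dir / "manifest.csv", relative_to=out_dir)
    truth_df = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    truth_df.to_csv(out_dir / "ground_truth.csv", index=False)
    (out_dir / "preset.json").write_text(preset.to_json() + "\n",
                                         encoding="utf-8")
    return manifest, truth_df


def microfluidic_inputs(label: str) -> MonolayerInterface:
    """(gamma, theta) scalar inputs of the microfluidic tension analysis.

    The pairs are chosen so that Young's equation and the adhesion-energy
    relation return the reported (Gamma, dW) for each composition:
    2*gamma = Gamma + dW and cos(theta) = Gamma / (Gamma + dW).
    """
    if label == "PMC":
        return MonolayerInterface(gamma=7.65, theta_deg=31.81, label="PMC")
    if label == "PMC-":
        return MonolayerInterface(gamma=5.70, theta_deg=28.70, label="PMC-")
    raise ConfigError(f"unknown label {label!r}; expected one of "
                      f"{PRESET_LABELS}")
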