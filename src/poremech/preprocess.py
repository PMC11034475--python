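"""Per-curve preprocessing: baseline, contact point, indentation axis,
breakthrough event.

The stages mirror the standard AFM force-curve workflow for pore-spanning
membranes: a line fitted to the non-contact part of the approach ramp is
subtracted; the contact point is the onset of sustained positive
deflection, backtracked to the last zero-crossing (a preceding snap-in dip
is recorded); the piezo axis is converted to tip-sample indentation using
the cantilever spring constant; and the first abrupt force drop marks the
membrane rupture, whose preceding force maximum is the breakthrough force
(BF).  Free-standing bilayers rupture at tens to hundreds of pN, so the
rupture threshold is expressed in the noise scale of the individual curve
rather than the nN-scale heuristics used for supported bilayers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigError, DataError
from .io import ForceCurve, CurveMetadata

__all__ = [
    "PreprocessConfig",
    "ContactAnnotation",
    "BreakthroughEvent",
    "correct_baseline",
    "find_contact_point",
    "to_indentation",
    "find_breakthrough",
]

PN = 1e-12


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunable thresholds of the preprocessing stages.

    baseline_fraction
        Fraction of the approach ramp (from its start) treated as
        non-contact and used for the baseline line fit.
    contact_k_sigma, contact_run_length
        Contact onset = first sample after which the force exceeds
        ``contact_k_sigma * noise`` for at least ``contact_run_length``
        consecutive samples.
    rupture_k_sigma, rupture_min_drop_pN, lookahead_samples
        A rupture is a force drop of at least
        ``max(rupture_k_sigma * noise, rupture_min_drop_pN)`` between a
        local force maximum and a sample within the following
        ``lookahead_samples``.
    rupture_confirm_samples
        The mean force over this many samples after the drop must stay
        below the peak by at least half the threshold; rejects
        single-sample noise excursions that would otherwise mimic a
        rupture.
    """

    baseline_fraction: float = 0.4
    contact_k_sigma: float = 3.0
    contact_run_length: int = 10
    rupture_k_sigma: float = 5.0
    rupture_min_drop_pN: float = 30.0
    lookahead_samples: int = 15
    rupture_confirm_samples: int = 5
    contact_refine_window: int = 20

    def __post_init__(self):
        if not 0.05 <= self.baseline_fraction <= 0.9:
            raise ConfigError("baseline_fraction must be in [0.05, 0.9]")
        if self.contact_run_length < 1 or self.lookahead_samples < 1:
            raise ConfigError("run lengths must be >= 1")


@dataclass
class ContactAnnotation:
    """Baseline and contact-point annotation for one curve (SI units)."""

    baseline_slope: float = 0.0     # N/m of z
    baseline_offset: float = 0.0    # N
    baseline_noise: float = 0.0     # robust force-noise scale, N
    contact_index: int | None = None
    contact_z: float | None = None  # m
    snap_in_depth: float = 0.0      # N, magnitude of pre-contact dip


@dataclass
class BreakthroughEvent:
    """First membrane rupture: an abrupt force drop after contact."""

    index: int          # first sample inside the drop (curve indexing)
    bf: float           # breakthrough force = force just before the drop [N]
    delta_at_bf: float  # indentation at rupture [m]
    drop_magnitude: float  # N

    def __post_init__(self):
        if self.bf <= 0 or self.drop_magnitude <= 0:
            raise DataError("breakthrough event requires bf > 0 and "
                            "drop_magnitude > 0")


def _mad_scale(x: np.ndarray) -> float:
    """Robust noise scale: 1.4826 * median absolute deviation."""
    med = np.median(x)
    return 1.4826 * float(np.median(np.abs(x - med)))


def correct_baseline(curve: ForceCurve,
                     config: PreprocessConfig = PreprocessConfig()
                     ) -> tuple[ForceCurve, ContactAnnotation]:
    """Fit and subtract a line over the non-contact region.

    The non-contact region is the first ``baseline_fraction`` of the
    approach ramp.  Returns the corrected curve and a partial annotation
    carrying the fitted line and the robust residual noise scale.
    """
    n = len(curve)
    k = int(round(config.baseline_fraction * n))
    if k < 10:
        raise DataError(f"curve {curve.curve_id}: baseline region has only "
                        f"{k} samples; no baseline detectable")
    z0, f0 = curve.z[:k], curve.force[:k]
    slope, offset = np.polyfit(z0, f0, 1)
    corrected = curve.force - (slope * curve.z + offset)
    noise = _mad_scale(corrected[:k])
    if noise <= 0:
        # noiseless synthetic input; keep annotation usable downstream
        noise = max(1e-3 * PN, float(np.std(corrected[:k])))
    ann = ContactAnnotation(baseline_slope=float(slope),
                            baseline_offset=float(offset),
                            baseline_noise=noise)
    return curve.with_force(corrected), ann


def find_contact_point(curve: ForceCurve, ann: ContactAnnotation,
                       config: PreprocessConfig = PreprocessConfig()
                       ) -> ContactAnnotation:
    """Locate the contact point on a baseline-corrected curve.

    Onset = first index after which the force stays above
    ``contact_k_sigma * noise`` for ``contact_run_length`` samples,
    backtracked to the last zero-crossing.  The crossing is then refined
    by extrapolating a quadratic fitted to the early rise (from the
    crossing until the force clears ~20x noise) down to zero force: the
    raw backtrack systematically places contact where the signal already
    exceeds the noise (late by roughly noise/slope), a straight line
    under-corrects because the membrane's early response is convex, and
    the quadratic root removes most of both effects.  A straight line is
    the fallback when the quadratic has no physical root.  A preceding
    negative dip deeper than the onset threshold is recorded as snap-in.
    Returns a completed annotation; ``contact_index`` stays ``None`` when
    no sustained crossing exists.
    """
    f = curve.force
    n = f.size
    thr = config.contact_k_sigma * ann.baseline_noise
    run = config.contact_run_length
    above = f > thr
    onset = None
    # sustained crossing: a run of `run` consecutive above-threshold samples
    count = 0
    for i in range(n):
        count = count + 1 if above[i] else 0
        if count >= run:
            onset = i - run + 1
            break
    if onset is None:
        return replace(ann, contact_index=None, contact_z=None)

    nonpos = np.flatnonzero(f[:onset + 1] <= 0.0)
    contact = int(nonpos[-1]) + 1 if nonpos.size else 0
    contact_z = float(curve.z[contact])

    # refine: extrapolate the early rise down to zero force; keeps the
    # sub-sample crossing as contact_z.  The fit window runs from the
    # current contact estimate up to where the signal clears ~20x noise,
    # so shallow slopes get a proportionally longer lever arm; two
    # passes let a badly late backtrack recover.
    w = config.contact_refine_window
    strong = np.flatnonzero(f[onset:] > 20.0 * ann.baseline_noise)
    hi = onset + int(strong[0]) + 5 if strong.size else onset + w
    hi = min(max(hi, onset + w), min(onset + 10 * w, n))
    lo_z = curve.z[max(contact - 6 * w, 0)]
    for _ in range(2):
        if hi - contact < 6:
            break
        zz, ff = curve.z[contact:hi] - curve.z[contact], f[contact:hi]
        c2, c1, c0 = np.polyfit(zz, ff, 2)
        root = None
        disc = c1 * c1 - 4.0 * c2 * c0
        if c2 != 0.0 and disc >= 0.0:
            # root of the parabola nearest the window start where the
            # model still rises
            roots = [(-c1 + math.sqrt(disc)) / (2 * c2),
                     (-c1 - math.sqrt(disc)) / (2 * c2)]
            rising = [r for r in roots if c1 + 2 * c2 * r > 0]
            if rising:
                root = min(rising, key=abs)
        if root is None:
            slope, icpt = np.polyfit(zz, ff, 1)
            if slope <= 0:
                break
            root = -icpt / slope
        z_star = float(curve.z[contact] + root)
        if not lo_z <= z_star <= curve.z[min(onset, n - 1)]:
            break
        contact = min(max(int(np.argmin(np.abs(curve.z - z_star))), 0), onset)
        contact_z = z_star

    # snap-in: most negative excursion shortly before contact
    w0 = max(0, contact - 200)
    dip = float(f[w0:contact + 1].min(initial=0.0))
    snap = -dip if -dip > thr else 0.0
    return replace(ann, contact_index=contact, contact_z=contact_z,
                   snap_in_depth=snap)


def to_indentation(curve: ForceCurve, ann: ContactAnnotation,
                   metadata: CurveMetadata | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Build the indentation axis for the post-contact segment.

    For a force-vs-piezo curve, ``delta = (z - z_c) - (F - F_c)/k`` (the
    tip-sample separation construction); when the curve is already on an
    indentation axis, ``delta = z - z_c``.  Returns ``(delta, force)``
    arrays aligned with curve samples from ``contact_index`` on; delta is
    clipped at 0 where noise takes it slightly negative.
    """
    if ann.contact_index is None:
        raise DataError(f"curve {curve.curve_id}: no contact point")
    i0 = ann.contact_index
    z_c = ann.contact_z if ann.contact_z is not None else curve.z[i0]
    z = curve.z[i0:]
    f = curve.force[i0:]
    if curve.is_indentation_axis:
        delta = z - z_c
    else:
        if not curve.spring_constant > 0:
            raise ConfigError("spring constant required for deflection "
                              "correction")
        delta = (z - z_c) - (f - f[0]) / curve.spring_constant
    return np.maximum(delta, 0.0), f


def find_breakthrough(force: np.ndarray, delta: np.ndarray,
                      ann: ContactAnnotation,
                      config: PreprocessConfig = PreprocessConfig(),
                      index_offset: int = 0) -> BreakthroughEvent | None:
    """Detect the first rupture event on the post-contact segment.

    Scans forward for the first sample j lying at least the rupture
    threshold below the maximum of the preceding ``lookahead_samples``
    window; that maximum is the breakthrough point (BF = its force), j is
    the event index, and the drop must be sustained (see
    ``rupture_confirm_samples``).  Ties between equal-magnitude drops
    resolve to the smaller index because the scan is forward.
    ``index_offset`` converts segment indices back to curve indices.
    Returns ``None`` when no drop passes the threshold (a valid outcome:
    the membrane did not rupture within the ramp).
    """
    thr = max(config.rupture_k_sigma * ann.baseline_noise,
              config.rupture_min_drop_pN * PN)
    look = config.lookahead_samples
    confirm = config.rupture_confirm_samples
    n = force.size
    for j in range(1, n):
        w0 = max(0, j - look)
        pre = force[w0:j]
        p_rel = int(np.argmax(pre))
        peak = pre[p_rel]
        if peak <= 0 or peak - force[j] < thr:
            continue
        tail = force[j:j + confirm]
        if tail.mean() > peak - 0.5 * thr:
            continue  # not sustained; likely a noise excursion
        drop = float(peak - force[j:j + look].min())
        # BF from the last pre-drop sample: the window maximum anchors
        # the detection but reading it as BF would take the max of
        # several noisy samples and bias BF upward by ~ the noise scale
        if force[j - 1] <= 0:
            continue
        return BreakthroughEvent(
            index=index_offset + j,
            bf=float(force[j - 1]),
            delta_at_bf=float(delta[j - 1]),
            drop_magnitude=drop,
        )
    return None
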