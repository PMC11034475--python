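"""Per-curve orchestration: preprocess -> indentation -> rupture -> fit.

:func:`analyze_curve` chains the preprocessing stages and the model fit
for one curve and collects everything into a :class:`CurveAnalysis`.
Failures at any stage become flags on the analysis record, never silent
drops: a curve without contact, without rupture, or whose fit did not
converge still appears in the results table with its status.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .fitting import (MembraneIndentationModel, MembraneFitResult,
                      DEFAULT_DELTA_OVER_R_THRESHOLD)
from .fvk import ModelKind
from .io import CurveMetadata, ForceCurve
from .preprocess import (BreakthroughEvent, ContactAnnotation,
                         PreprocessConfig, correct_baseline,
                         find_breakthrough, find_contact_point,
                         to_indentation)

__all__ = ["CurveAnalysis", "AnalysisConfig", "analyze_curve"]

NM = 1e-9
PN = 1e-12
MPA = 1e6
MN_PER_M = 1e-3


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the per-curve pipeline (preprocessing + fitting)."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    model_kind: ModelKind = ModelKind.EXACT
    fit_margin_samples: int = 3
    min_fit_points: int = 20
    threshold_delta_over_R: float = DEFAULT_DELTA_OVER_R_THRESHOLD
    restarts: int = 2
    # pre-contact samples anchoring the contact-offset nuisance of the fit
    pre_contact_samples: int = 40
    fit_contact: bool = True


@dataclass
class CurveAnalysis:
    """Everything derived from one curve, with quality flags."""

    curve_id: str
    condition: str
    R: float
    contact: ContactAnnotation | None = None
    event: BreakthroughEvent | None = None
    fit: MembraneFitResult | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def status(self) -> str:
        """'analyzed' when a converged fit exists, else 'excluded'."""
        if self.fit is not None and self.fit.converged:
            return "analyzed"
        return "excluded"

    def to_row(self) -> dict:
        """One results-CSV row (reporting units; schema in poremech.io)."""
        fit = self.fit
        return {
            "curve_id": self.curve_id,
            "condition": self.condition,
            "contact_index": (None if self.contact is None
                              else self.contact.contact_index),
            "BF_pN": None if self.event is None else self.event.bf / PN,
            "delta_max_nm": None if fit is None else fit.delta_max / NM,
            "delta_over_R": None if fit is None else fit.delta_over_R,
            "E_MPa": None if fit is None else fit.E_MPa,
            "sigma_mN_per_m": None if fit is None else fit.sigma_mN_per_m,
            "E_stderr": None if fit is None else fit.E_stderr / MPA,
            "sigma_stderr": None if fit is None
            else fit.sigma_stderr / MN_PER_M,
            "rss": None if fit is None else fit.rss_pN2,
            "passed_filter": False if fit is None else fit.passed_filter,
            "flags": ";".join(self.flags),
        }


def analyze_curve(curve: ForceCurve, metadata: CurveMetadata,
                  config: AnalysisConfig = AnalysisConfig()) -> CurveAnalysis:
    """Run baseline/contact/indentation/rupture/fit on one curve."""
    out = CurveAnalysis(curve_id=curve.curve_id,
                        condition=curve.condition_label,
                        R=metadata.hole_radius)
    try:
        corrected, ann = correct_baseline(curve, config.preprocess)
    except DataError:
        out.flags.append("no_baseline")
        return out
    ann = find_contact_point(corrected, ann, config.preprocess)
    out.contact = ann
    if ann.contact_index is None:
        out.flags.append("no_contact")
        return out

    delta, force_seg = to_indentation(corrected, ann, metadata)
    event = find_breakthrough(force_seg, delta, ann, config.preprocess,
                              index_offset=ann.contact_index)
    out.event = event
    if event is None:
        out.flags.append("no_rupture")

    seg_event = None
    if event is not None:
        # re-express the event index relative to the post-contact segment
        seg_event = BreakthroughEvent(
            index=event.index - ann.contact_index, bf=event.bf,
            delta_at_bf=event.delta_at_bf,
            drop_magnitude=event.drop_magnitude)
    # pre-contact anchor window (baseline-corrected, snap-in dip masked)
    ci = ann.contact_index
    p0 = max(ci - config.pre_contact_samples, 0)
    pre_x = corrected.z[p0:ci] - ann.contact_z
    pre_f = corrected.force[p0:ci]
    dip_free = pre_f > -2.0 * ann.baseline_noise
    pre_x, pre_f = pre_x[dip_free], pre_f[dip_free]

    try:
        model = MembraneIndentationModel.from_curve(
            force_seg, delta, seg_event,
            h=metadata.bilayer_thickness, R=metadata.hole_radius,
            nu=metadata.poisson_ratio, model_kind=config.model_kind,
            fit_margin_samples=config.fit_margin_samples,
            min_points=config.min_fit_points,
            spring_constant=(None if curve.is_indentation_axis
                             else curve.spring_constant),
            pre_x=pre_x, pre_force=pre_f,
            fit_contact=config.fit_contact)
    except DataError:
        out.flags.append("too_few_fit_points")
        return out
    out.fit = model.fit(restarts=config.restarts)
    if not out.fit.converged:
        out.flags.append("fit_not_converged")
    else:
        if not out.fit.delta_over_R > config.threshold_delta_over_R:
            out.flags.append("below_indentation_threshold")
        if not out.fit.e_identifiable:
            out.flags.append("e_unidentifiable")
    return out
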