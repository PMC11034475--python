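"""Dataset-level pipeline: manifest -> per-curve analyses -> results +
per-condition summaries + log.

The configuration is a flat, schema-validated record
(:class:`PipelineConfig`); unknown keys are rejected.  Every input curve
appears exactly once in the results table with a status, and the run
report satisfies ``n_input == n_analyzed + n_excluded``.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from .analysis import AnalysisConfig, CurveAnalysis, analyze_curve
from .ensemble import EnsembleSummary, summarize_condition
from .errors import ConfigError, DataError
from .fvk import ModelKind
from .io import read_curve, read_manifest, write_results
from .preprocess import PreprocessConfig

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline"]

logger = logging.getLogger("poremech")


class PipelineConfig(BaseModel):
    """Flat, validated configuration of a full pipeline run."""

    model_config = ConfigDict(extra="forbid", protected_namespaces=())

    manifest: Path
    out_dir: Path
    overwrite: bool = False

    baseline_fraction: float = Field(0.4, gt=0.0, lt=1.0)
    contact_k_sigma: float = Field(3.0, gt=0.0)
    contact_run_length: int = Field(10, ge=1)
    rupture_k_sigma: float = Field(5.0, gt=0.0)
    rupture_min_drop_pN: float = Field(30.0, ge=0.0)
    lookahead_samples: int = Field(15, ge=1)
    rupture_confirm_samples: int = Field(5, ge=1)

    model_kind: str = ModelKind.EXACT.value
    fit_margin_samples: int = Field(3, ge=0)
    min_fit_points: int = Field(20, ge=4)
    threshold_delta_over_R: float = Field(0.03, ge=0.0)
    restarts: int = Field(2, ge=0)

    @field_validator("model_kind")
    @classmethod
    def _known_kind(cls, v: str) -> str:
        ModelKind.coerce(v)  # raises ConfigError on unknown values
        return v

    def analysis_config(self) -> AnalysisConfig:
        return AnalysisConfig(
            preprocess=PreprocessConfig(
                baseline_fraction=self.baseline_fraction,
                contact_k_sigma=self.contact_k_sigma,
                contact_run_length=self.contact_run_length,
                rupture_k_sigma=self.rupture_k_sigma,
                rupture_min_drop_pN=self.rupture_min_drop_pN,
                lookahead_samples=self.lookahead_samples,
                rupture_confirm_samples=self.rupture_confirm_samples,
            ),
            model_kind=ModelKind.coerce(self.model_kind),
            fit_margin_samples=self.fit_margin_samples,
            min_fit_points=self.min_fit_points,
            threshold_delta_over_R=self.threshold_delta_over_R,
            restarts=self.restarts,
        )


@dataclass
class PipelineReport:
    """In-memory result of one run (files are written to out_dir)."""

    analyses: list[CurveAnalysis]
    summaries: dict[str, EnsembleSummary]
    n_input: int
    n_analyzed: int
    n_excluded: int
    results_path: Path
    summary_path: Path
    log_path: Path

    def summary_json(self) -> dict:
        return {cond: s.to_json_dict() for cond, s in self.summaries.items()}


def _prepare_out_dir(out_dir: Path, overwrite: bool) -> None:
    if out_dir.exists() and any(out_dir.iterdir()):
        if not overwrite:
            raise ConfigError(
                f"output directory {out_dir} is not empty; pass "
                f"overwrite=True to replace its contents")
        for p in out_dir.glob("*"):
            if p.is_file():
                p.unlink()
    out_dir.mkdir(parents=True, exist_ok=True)


def summarize_analyses(analyses: list[CurveAnalysis],
                       threshold: float, h_by_condition: dict,
                       nu_by_condition: dict) -> dict[str, EnsembleSummary]:
    """Per-condition ensemble summaries from per-curve analyses."""
    summaries = {}
    for cond in sorted({a.condition for a in analyses}):
        group = [a for a in analyses if a.condition == cond]
        bf_values = [a.event.bf for a in group if a.event is not None]
        fits = [a.fit for a in group if a.fit is not None]
        summaries[cond] = summarize_condition(
            cond, bf_values, fits, n_curves=len(group),
            h=h_by_condition[cond], nu=nu_by_condition[cond],
            threshold=threshold)
    return summaries


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Analyse every curve in the manifest and write results + summaries.

    Writes ``results.csv`` (one row per curve), ``summary.json`` (one
    entry per condition), ``config.json`` (snapshot) and ``run.log`` into
    ``config.out_dir``.
    """
    manifest = read_manifest(config.manifest)
    if len(manifest) == 0:
        raise DataError(f"manifest {config.manifest} has no entries")
    manifest.validate_files()

    out_dir = Path(config.out_dir)
    _prepare_out_dir(out_dir, config.overwrite)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    try:
        snapshot = config.model_dump(mode="json")
        (out_dir / "config.json").write_text(
            json.dumps(snapshot, indent=1, sort_keys=True) + "\n",
            encoding="utf-8")
        logger.info("poremech %s starting run at %s", __version__,
                    _dt.datetime.now().isoformat())
        logger.info("config: %s", json.dumps(snapshot, sort_keys=True))

        acfg = config.analysis_config()
        analyses = []
        h_by_cond, nu_by_cond = {}, {}
        for curve_path, meta_path, label in manifest.entries:
            curve, meta = read_curve(curve_path, meta_path)
            curve.condition_label = curve.condition_label or label
            h_by_cond.setdefault(label, meta.bilayer_thickness)
            nu_by_cond.setdefault(label, meta.poisson_ratio)
            analysis = analyze_curve(curve, meta, acfg)
            analyses.append(analysis)
            logger.info("curve %s [%s]: status=%s flags=%s",
                        analysis.curve_id, label, analysis.status,
                        ",".join(analysis.flags) or "-")

        results_path = write_results(analyses, out_dir / "results.csv")
        summaries = summarize_analyses(
            analyses, acfg.threshold_delta_over_R, h_by_cond, nu_by_cond)
        summary_path = out_dir / "summary.json"
        summary_payload = {c: s.to_json_dict() for c, s in summaries.items()}
        summary_path.write_text(
            json.dumps(summary_payload, indent=1, sort_keys=True) + "\n",
            encoding="utf-8")

        n_analyzed = sum(a.status == "analyzed" for a in analyses)
        n_excluded = len(analyses) - n_analyzed
        for cond, s in summaries.items():
            logger.info("condition %s: n=%d kept=%d", cond, s.n_curves,
                        s.n_kept)
        logger.info("done: %d input = %d analyzed + %d excluded",
                    len(analyses), n_analyzed, n_excluded)
        return PipelineReport(
            analyses=analyses, summaries=summaries, n_input=len(analyses),
            n_analyzed=n_analyzed, n_excluded=n_excluded,
            results_path=results_path, summary_path=summary_path,
            log_path=log_path)
    finally:
        logger.removeHandler(handler)
        handler.close()
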