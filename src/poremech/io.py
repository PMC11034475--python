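"""Plain-text I/O for force curves, sidecar metadata, manifests and results.

File dialects
-------------
Curve file
    UTF-8 headered TSV. Required columns ``z_nm`` and ``force_pN``;
    optional ``separation_nm``.  Lines starting with ``#`` are ignored.
Sidecar metadata
    JSON with the same basename and extension ``.json``::

        {curve_id, direction, spring_constant_N_per_m, hole_radius_nm,
         bilayer_thickness_nm, poisson_ratio, condition_label,
         ramp_size_nm, is_indentation_axis?, temperature_C?}

Manifest
    CSV with columns ``curve_path, meta_path, condition_label``; paths are
    resolved relative to the manifest location.
Results
    CSV, one row per analysed curve, columns :data:`RESULTS_COLUMNS`.

All arrays are stored in the reporting units of the field (nm, pN) and
converted to SI (m, N) on read; everything downstream of this module sees
SI values only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, FormatError

__all__ = [
    "ForceCurve",
    "CurveMetadata",
    "DatasetManifest",
    "read_curve",
    "write_curve",
    "read_manifest",
    "write_manifest",
    "write_results",
    "RESULTS_COLUMNS",
]

NM = 1e-9
PN = 1e-12


@dataclass
class ForceCurve:
    """One AFM force trace (approach by default), in SI units.

    ``z`` is the piezo displacement [m] and ``force`` the vertical force
    [N]; if ``is_indentation_axis`` the z array already is the tip-sample
    indentation.  ``z`` must be strictly monotone and at least 50 samples
    long.
    """

    curve_id: str
    z: np.ndarray
    force: np.ndarray
    spring_constant: float  # N/m
    direction: str = "approach"
    is_indentation_axis: bool = False
    condition_label: str = ""

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.z.shape != self.force.shape:
            raise DataError(
                f"curve {self.curve_id}: z and force lengths differ "
                f"({self.z.size} vs {self.force.size})")
        if self.z.size < 50:
            raise DataError(f"curve {self.curve_id}: needs >= 50 samples, "
                            f"got {self.z.size}")
        dz = np.diff(self.z)
        if not (np.all(dz > 0) or np.all(dz < 0)):
            raise DataError(f"curve {self.curve_id}: z is not strictly monotone")
        if not self.spring_constant > 0:
            raise DataError(f"curve {self.curve_id}: spring_constant must be > 0")
        if self.direction not in ("approach", "retract"):
            raise DataError(f"curve {self.curve_id}: direction must be "
                            f"'approach' or 'retract'")

    def with_force(self, force: np.ndarray) -> "ForceCurve":
        return replace(self, force=np.asarray(force, dtype=float))

    def __len__(self) -> int:
        return self.z.size


@dataclass
class CurveMetadata:
    """Per-curve geometry and material assumptions, in SI units."""

    hole_radius: float          # m
    bilayer_thickness: float    # m
    poisson_ratio: float = 0.485
    ramp_size: float | None = None   # m
    temperature_C: float | None = None

    def __post_init__(self):
        if not self.hole_radius > 0:
            raise DataError("hole_radius must be > 0")
        if not self.bilayer_thickness > 0:
            raise DataError("bilayer_thickness must be > 0")
        if not 0 < self.poisson_ratio < 0.5:
            raise DataError("poisson_ratio must be in (0, 0.5)")


@dataclass
class DatasetManifest:
    """List of (curve file, sidecar file, condition label) entries."""

    entries: list[tuple[Path, Path, str]] = field(default_factory=list)

    def __post_init__(self):
        for curve_path, meta_path, label in self.entries:
            if not str(label):
                raise DataError(f"empty condition label for {curve_path}")

    def validate_files(self):
        for curve_path, meta_path, _ in self.entries:
            for p in (curve_path, meta_path):
                if not Path(p).exists():
                    raise DataError(f"manifest references missing file: {p}")

    def __len__(self) -> int:
        return len(self.entries)


def read_curve(path, meta_path=None) -> tuple[ForceCurve, CurveMetadata]:
    """Read one curve TSV plus its JSON sidecar; returns SI quantities."""
    path = Path(path)
    if meta_path is None:
        meta_path = path.with_suffix(".json")
    meta_path = Path(meta_path)
    if not path.exists():
        raise FormatError("curve file not found", path=path)
    if not meta_path.exists():
        raise FormatError("metadata sidecar not found", path=meta_path)

    header = None
    z, f = [], []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if "z_nm" not in header or "force_pN" not in header:
                    raise FormatError(
                        f"missing required columns z_nm/force_pN in header "
                        f"{header}", path=path, line=lineno)
                iz, jf = header.index("z_nm"), header.index("force_pN")
                continue
            try:
                z.append(float(fields[iz]))
                f.append(float(fields[jf]))
            except (ValueError, IndexError):
                raise FormatError(f"malformed data row {fields!r}",
                                  path=path, line=lineno) from None
    if header is None:
        raise FormatError("empty curve file", path=path)
    if len(z) != len(f):  # cannot happen row-wise, kept as a guard
        raise FormatError("z and force columns differ in length", path=path)

    try:
        meta_raw = json.loads(meta_path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"invalid JSON sidecar: {exc}", path=meta_path) from None
    required = ("curve_id", "spring_constant_N_per_m", "hole_radius_nm",
                "bilayer_thickness_nm", "poisson_ratio", "condition_label")
    missing = [k for k in required if k not in meta_raw]
    if missing:
        raise FormatError(f"sidecar missing keys {missing}", path=meta_path)

    try:
        curve = ForceCurve(
            curve_id=str(meta_raw["curve_id"]),
            z=np.asarray(z) * NM,
            force=np.asarray(f) * PN,
            spring_constant=float(meta_raw["spring_constant_N_per_m"]),
            direction=str(meta_raw.get("direction", "approach")),
            is_indentation_axis=bool(meta_raw.get("is_indentation_axis", False)),
            condition_label=str(meta_raw["condition_label"]),
        )
        ramp = meta_raw.get("ramp_size_nm")
        meta = CurveMetadata(
            hole_radius=float(meta_raw["hole_radius_nm"]) * NM,
            bilayer_thickness=float(meta_raw["bilayer_thickness_nm"]) * NM,
            poisson_ratio=float(meta_raw["poisson_ratio"]),
            ramp_size=None if ramp is None else float(ramp) * NM,
            temperature_C=meta_raw.get("temperature_C"),
        )
    except DataError as exc:
        raise FormatError(str(exc), path=path) from None
    return curve, meta


def _fmt(x: float) -> str:
    """Stable shortest-roundtrip float formatting (bit-exact round trips)."""
    return repr(float(x))


def write_curve(curve: ForceCurve, meta: CurveMetadata, path) -> Path:
    """Write a curve TSV + JSON sidecar (nm/pN units).  Deterministic."""
    path = Path(path)
    lines = ["z_nm\tforce_pN"]
    for zi, fi in zip(curve.z / NM, curve.force / PN):
        lines.append(f"{_fmt(zi)}\t{_fmt(fi)}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    sidecar = {
        "curve_id": curve.curve_id,
        "direction": curve.direction,
        "spring_constant_N_per_m": curve.spring_constant,
        "hole_radius_nm": meta.hole_radius / NM,
        "bilayer_thickness_nm": meta.bilayer_thickness / NM,
        "poisson_ratio": meta.poisson_ratio,
        "condition_label": curve.condition_label,
        "ramp_size_nm": None if meta.ramp_size is None else meta.ramp_size / NM,
        "is_indentation_axis": curve.is_indentation_axis,
    }
    if meta.temperature_C is not None:
        sidecar["temperature_C"] = meta.temperature_C
    meta_path = path.with_suffix(".json")
    meta_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True) + "\n",
                         encoding="utf-8")
    return path


def read_manifest(path) -> DatasetManifest:
    """Read a manifest CSV; paths are resolved relative to the manifest."""
    path = Path(path)
    if not path.exists():
        raise FormatError("manifest not found", path=path)
    df = pd.read_csv(path)
    required = {"curve_path", "meta_path", "condition_label"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"manifest must have columns {sorted(required)}, got "
            f"{list(df.columns)}", path=path)
    base = path.parent
    entries = [
        (base / str(r.curve_path), base / str(r.meta_path),
         str(r.condition_label))
        for r in df.itertuples()
    ]
    return DatasetManifest(entries=entries)


def write_manifest(manifest: DatasetManifest, path, relative_to=None) -> Path:
    path = Path(path)
    base = (Path(relative_to) if relative_to is not None
            else path.parent).resolve()

    def _rel(p) -> str:
        return Path(p).resolve().relative_to(base).as_posix()

    rows = [
        {"curve_path": _rel(curve_path), "meta_path": _rel(meta_path),
         "condition_label": label}
        for curve_path, meta_path, label in manifest.entries
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


#: documented results schema, one row per curve, stable column order
RESULTS_COLUMNS = [
    "curve_id", "condition", "contact_index", "BF_pN", "delta_max_nm",
    "delta_over_R", "E_MPa", "sigma_mN_per_m", "E_stderr", "sigma_stderr",
    "rss", "passed_filter", "flags",
]


def write_results(analyses, path) -> Path:
    """Write per-curve results CSV (schema :data:`RESULTS_COLUMNS`).

    ``analyses`` is a non-empty list of objects exposing ``to_row()``
    (see :class:`poremech.analysis.CurveAnalysis`).
    """
    if not analyses:
        raise DataError("write_results called with an empty analysis list")
    rows = [a.to_row() for a in analyses]
    df = pd.DataFrame(rows, columns=RESULTS_COLUMNS)
    path = Path(path)
    df.to_csv(path, index=False)
    return path
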