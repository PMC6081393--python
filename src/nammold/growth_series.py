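"""Growth-guided plate series: from one cast and one detection, plan and
generate the sequence of molding plates that expands the arch along its
fitted ellipse and progressively closes the cleft.

Plate k (k = 1..n) targets the detected ellipse scaled by
``(1+g)^(k * interval_weeks / 4.345)`` — g is the monthly relative growth
fraction — and a residual cleft gap of ``initial_gap x closure(k)``. The
target anatomy is realized by scaling the cast in-plane about the ellipse
center (a passive guiding expansion: no segment rotation by construction)
and bridging the cleft down to the residual gap, after which the plate
pipeline runs unchanged.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .exceptions import BuildError, ParameterError
from .mesh_io import validate_mesh, write_mesh
from .plate_builder import (
    PlateSpec,
    add_retention_pin,
    add_ventilation_hole,
    bridge_gap,
    build_plate,
    select_bridge_regions,
    smooth_plate,
)
from .ridge_detection import (
    CrestCurve,
    DetectionResult,
    EllipseParams,
    detect_ridge,
    measure_gap_width,
)

WEEKS_PER_MONTH = 4.345  # 365.25 / 12 / 7


@dataclass
class GrowthModel:
    """Growth and closure plan of a plate series.

    ``g`` is the monthly relative growth fraction of the arch dimensions.
    The default 0.02/month is an explicit placeholder: the clinically
    grounded value comes from longitudinal measurements of healthy newborns
    and must be supplied by the user; synthetic studies use their own known
    rate. Defaults plan a series of six plates, two weeks apart, with linear
    cleft closure reaching zero at the last plate.
    """

    g: float = 0.02
    n_plates: int = 6
    interval_weeks: float = 2.0
    closure_schedule: str = "linear"

    def validate(self) -> None:
        if self.g <= -1:
            raise ParameterError("growth fraction must be > -1")
        if self.n_plates < 1:
            raise ParameterError("n_plates must be >= 1")
        if self.interval_weeks <= 0:
            raise ParameterError("interval_weeks must be > 0")
        if self.closure_schedule != "linear":
            raise ParameterError(f"unknown closure schedule {self.closure_schedule!r}")

    def scale_factor(self, k: int) -> float:
        """Arch scale of plate k relative to the cast."""
        months = k * self.interval_weeks / WEEKS_PER_MONTH
        return float((1.0 + self.g) ** months)

    def closure_fraction(self, k: int) -> float:
        """Fraction of the initial gap remaining at plate k (0 at plate n)."""
        if self.n_plates == 1:
            return 0.0
        return max(0.0, (self.n_plates - k) / (self.n_plates - 1))


@dataclass
class PlateRecord:
    index: int
    target_ellipse: EllipseParams
    target_gap: float
    path: str | None = None
    report_digest: str | None = None
    measured_axes: tuple[float, float] | None = None  # re-detected (a, b)
    measured_gap: float | None = None
    segment_axes: list[list[float]] | None = None  # per-segment principal dirs

    def to_dict(self) -> dict:
        return {
            "index": self.index,
            "target_ellipse": self.target_ellipse.to_dict(),
            "target_gap": self.target_gap,
            "path": self.path,
            "report_digest": self.report_digest,
            "measured_axes": list(self.measured_axes) if self.measured_axes else None,
            "measured_gap": self.measured_gap,
            "segment_axes": self.segment_axes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlateRecord":
        return cls(
            index=int(d["index"]),
            target_ellipse=EllipseParams.from_dict(d["target_ellipse"]),
            target_gap=float(d["target_gap"]),
            path=d.get("path"),
            report_digest=d.get("report_digest"),
            measured_axes=tuple(d["measured_axes"]) if d.get("measured_axes") else None,
            measured_gap=d.get("measured_gap"),
            segment_axes=d.get("segment_axes"),
        )


@dataclass
class SeriesManifest:
    records: list[PlateRecord] = field(default_factory=list)

    def to_json(self, path=None) -> str:
        text = json.dumps([r.to_dict() for r in self.records], indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SeriesManifest":
        from pathlib import Path

        if isinstance(source, Path) or (
            isinstance(source, (str, bytes)) and not str(source).lstrip().startswith("[")
        ):
            with open(source) as fh:
                data = json.load(fh)
        else:
            data = json.loads(source)
        return cls(records=[PlateRecord.from_dict(d) for d in data])


class SeriesError(BuildError):
    """A plate in the series failed; carries the manifest of completed ones."""

    def __init__(self, message: str, manifest: SeriesManifest):
        super().__init__(message)
        self.manifest = manifest


def _initial_gap(detection: DetectionResult) -> float:
    from .plate_builder import _gap_endpoints

    e_g, e_s = _gap_endpoints(detection)
    return float(np.linalg.norm(e_g - e_s))


def plan_series(
    detection: DetectionResult, model: GrowthModel, initial_gap: float | None = None
) -> SeriesManifest:
    """Plan the target ellipse and residual gap of every plate (no meshes).

    ``initial_gap`` defaults to the chord between the gap-facing crest
    endpoints; callers with the cast at hand may pass the measured surface
    gap instead for a consistent closure metric.
    """
    model.validate()
    if initial_gap is None:
        initial_gap = _initial_gap(detection) if detection.gap_span is not None else 0.0
    records = []
    for k in range(1, model.n_plates + 1):
        f = model.scale_factor(k)
        ell = detection.ellipse
        records.append(
            PlateRecord(
                index=k,
                target_ellipse=EllipseParams(
                    center=ell.center.copy(), a=ell.a * f, b=ell.b * f, theta=ell.theta
                ),
                target_gap=initial_gap * model.closure_fraction(k),
            )
        )
    return SeriesManifest(records=records)


def _scaled_cast_and_detection(
    cast: trimesh.Trimesh, detection: DetectionResult, factor: float
) -> tuple[trimesh.Trimesh, DetectionResult]:
    """Scale the cast and its detection in the occlusal plane about the
    ellipse center (heights unchanged): the guiding-track expansion."""
    frame = detection.frame
    center = detection.ellipse.center

    def warp(points):
        local = frame.to_local(points)
        local[:, :2] = center + factor * (local[:, :2] - center)
        return frame.to_world(local)

    warped = trimesh.Trimesh(warp(cast.vertices), cast.faces.copy(), process=False)
    warped.metadata["name"] = f"{cast.metadata.get('name', 'cast')}_x{factor:.4f}"
    ell = detection.ellipse
    wdet = DetectionResult(
        frame=frame,
        crests=[
            CrestCurve(points=warp(c.points), segment_label=c.segment_label, arc_param=c.arc_param)
            for c in detection.crests
        ],
        ellipse=EllipseParams(center=center.copy(), a=ell.a * factor, b=ell.b * factor, theta=ell.theta),
        rms_residual=detection.rms_residual * factor,
        gap_span=detection.gap_span,  # angles are invariant under uniform scaling
    )
    return warped, wdet


def _segment_axes(detection: DetectionResult) -> list[list[float]]:
    """In-plane principal direction of each crest segment (unit vectors)."""
    out = []
    for c in detection.crests:
        xy = detection.frame.to_local(c.points)[:, :2]
        xy = xy - xy.mean(axis=0)
        _, _, vt = np.linalg.svd(xy, full_matrices=False)
        d = vt[0]
        if d[0] < 0 or (d[0] == 0 and d[1] < 0):  # deterministic sign
            d = -d
        out.append([float(d[0]), float(d[1])])
    return out


def generate_series(
    cast: trimesh.Trimesh,
    detection: DetectionResult,
    model: GrowthModel,
    spec: PlateSpec | None = None,
    out_dir=None,
    with_pin: bool = True,
    with_hole: bool = True,
    with_smoothing: bool = True,
) -> tuple[SeriesManifest, list[trimesh.Trimesh]]:
    """Generate all plates of the series.

    Every plate's target anatomy is the cast scaled to the plate's target
    ellipse with the cleft bridged down to the target gap; the plate
    pipeline (shell, pin, hole, smoothing) then runs per plate. Aborts with
    :class:`SeriesError` carrying the completed manifest if a plate fails.
    """
    spec = spec or PlateSpec()
    initial_gap = None
    if detection.gap_span is not None:
        initial_gap = measure_gap_width(cast, detection)
    manifest = plan_series(detection, model, initial_gap=initial_gap)
    plates: list[trimesh.Trimesh] = []
    for rec in manifest.records:
        try:
            factor = rec.target_ellipse.a / detection.ellipse.a
            warped, wdet = _scaled_cast_and_detection(cast, detection, factor)
            if detection.gap_span is not None:
                regions = select_bridge_regions(warped, wdet)
                bridged = bridge_gap(
                    warped,
                    regions,
                    wdet.ellipse,
                    detection=wdet,
                    residual_gap=rec.target_gap,
                    pitch=spec.voxel_pitch,
                )
            else:
                bridged = warped
            plate = build_plate(bridged, wdet, spec)
            if with_pin:
                plate = add_retention_pin(plate, spec)
            if with_hole:
                plate = add_ventilation_hole(plate, spec)
            if with_smoothing:
                plate = smooth_plate(plate, spec)

            # re-detect on the plate's target anatomy (the intaglio geometry)
            redet = detect_ridge(warped)
            rec.measured_axes = (redet.ellipse.a, redet.ellipse.b)
            rec.segment_axes = _segment_axes(redet)
            if detection.gap_span is None:
                rec.measured_gap = 0.0
            else:
                bdet = detect_ridge(bridged)
                if bdet.gap_span is None:
                    rec.measured_gap = 0.0
                else:
                    rec.measured_gap = measure_gap_width(bridged, bdet)
            report = validate_mesh(plate)
            rec.report_digest = hashlib.sha256(
                json.dumps(report.to_dict(), sort_keys=True).encode()
            ).hexdigest()[:16]
            if out_dir is not None:
                from pathlib import Path

                path = Path(out_dir) / f"plate_{rec.index:02d}.stl"
                write_mesh(plate, path, format="stl-binary")
                rec.path = str(path)
            plates.append(plate)
        except Exception as exc:  # noqa: BLE001 - abort contract
            done = SeriesManifest(records=manifest.records[: rec.index - 1])
            raise SeriesError(f"plate {rec.index} failed: {exc}", done) from exc
    return manifest, plates
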