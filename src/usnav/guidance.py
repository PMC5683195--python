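"""The four surgical augmentations driven by the tumour distance field.

Given the tracked instrument state (tip position and axis in the aid frame)
and the signed distance field of the segmented tumour, this module computes:

* the *traffic light* — a banded proximity alert per instrument; the default
  bands are <2.5 mm (red), 2.5-3.5 mm (yellow), 3.5-5.0 mm (orange) and
  beyond 5.0 mm (green), with boundaries half-open and assigned upward;
* the *compass* — a cone from the instrument tip toward the tumour centre
  whose height equals the tip-to-centre distance;
* the *projected path* — spheres (1 mm diameter, 1 mm apart by default)
  extending the tool axis, each coloured by its own proximity band, plus the
  distance at which the extended axis would first hit the tumour surface;
* the *virtual viewpoint* — the scene as seen by a virtual camera 50 mm from
  the aid along the marker-plane normal, looking straight down at the marker,
  so tumour depth below the (locally planar) surface is read off directly.

An instrument whose tip falls outside the field's grid is, by construction,
farther than the field margin from the tumour, so it is reported green and
flagged out-of-field rather than treated as an error.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .transforms import CameraModel, Point3, RigidTransform
from .volume import SignedDistanceField, SurfaceMesh, query_distance

__all__ = [
    "TrafficLight",
    "ProximityThresholds",
    "InstrumentState",
    "CompassCue",
    "PathSphere",
    "VirtualView",
    "InstrumentGuidance",
    "GuidanceOutput",
    "classify_proximity",
    "compass_cue",
    "projected_path",
    "virtual_viewpoint",
    "guidance_frame",
]


class TrafficLight(str, Enum):
    RED = "red"
    YELLOW = "yellow"
    ORANGE = "orange"
    GREEN = "green"


@dataclass(frozen=True)
class ProximityThresholds:
    """Ascending band cuts in mm.  The colour order (red, yellow, orange,
    green with increasing distance) follows the system's convention and can be
    overridden via ``colors``."""

    cuts: tuple[float, float, float] = (2.5, 3.5, 5.0)
    colors: tuple[TrafficLight, ...] = (TrafficLight.RED, TrafficLight.YELLOW,
                                        TrafficLight.ORANGE, TrafficLight.GREEN)

    def __post_init__(self) -> None:
        c = tuple(float(x) for x in self.cuts)
        if len(c) != 3 or not (0 < c[0] < c[1] < c[2]):
            raise ValueError("cuts must be three strictly ascending positive distances")
        if len(self.colors) != 4:
            raise ValueError("need exactly four band colours")
        object.__setattr__(self, "cuts", c)


@dataclass(frozen=True)
class InstrumentState:
    """Tip position and distal-pointing unit axis in the aid frame."""

    tip: Point3
    axis: np.ndarray
    instrument_id: int = 1

    def __post_init__(self) -> None:
        a = np.asarray(self.axis, dtype=float).reshape(3)
        if abs(np.linalg.norm(a) - 1.0) > 1e-9:
            raise ValueError("instrument axis must be a unit vector")
        object.__setattr__(self, "axis", a)


@dataclass(frozen=True)
class CompassCue:
    """Cone from tip toward the tumour centre; height = tip-to-centre distance."""

    apex: Point3
    direction: np.ndarray
    height: float


@dataclass(frozen=True)
class PathSphere:
    center: Point3
    diameter: float
    state: TrafficLight
    out_of_field: bool = False


@dataclass
class VirtualView:
    """Projected scene data (not pixels) from the virtual overhead camera."""

    camera_pose: RigidTransform          # virtual camera <- N
    offset: float
    camera: CameraModel
    mesh_pixels: np.ndarray | None = None       # (n, 2)
    mesh_depth_below_plane: np.ndarray | None = None  # (n,) mm below marker plane
    instrument_pixels: np.ndarray | None = None  # (k, 2)


@dataclass
class InstrumentGuidance:
    instrument_id: int
    state: TrafficLight
    distance_mm: float | None
    out_of_field: bool
    compass: CompassCue
    path: list[PathSphere]
    hit_mm: float | None

    def to_dict(self) -> dict:
        return {
            "instrument_id": self.instrument_id,
            "state": self.state.value,
            "distance_mm": self.distance_mm,
            "out_of_field": self.out_of_field,
            "compass": {
                "apex": self.compass.apex.coordinates.tolist(),
                "direction": self.compass.direction.tolist(),
                "height_mm": self.compass.height,
            },
            "path": [{"center": s.center.coordinates.tolist(),
                      "diameter_mm": s.diameter, "state": s.state.value,
                      "out_of_field": s.out_of_field} for s in self.path],
            "hit_mm": self.hit_mm,
        }


@dataclass
class GuidanceOutput:
    """Everything one display frame needs, for up to two instruments."""

    instruments: list[InstrumentGuidance]
    virtual_view: VirtualView | None = None
    stale: bool = False

    def to_dict(self) -> dict:
        return {
            "instruments": [g.to_dict() for g in self.instruments],
            "stale": self.stale,
            "virtual_view": None if self.virtual_view is None else {
                "offset_mm": self.virtual_view.offset,
                "camera_pose": self.virtual_view.camera_pose.as_matrix().tolist(),
            },
        }


# ----------------------------------------------------------------------


def classify_proximity(distance: float,
                       th: ProximityThresholds = ProximityThresholds()) -> TrafficLight:
    """Map a signed surface distance to its alert band.

    Bands are half-open, assigned upward: [-inf, c1) -> red, [c1, c2) ->
    yellow, [c2, c3) -> orange, [c3, inf) -> green.  Distances <= 0 (contact
    or penetration) are red.
    """
    if not np.isfinite(distance):
        raise ValueError("distance must be finite")
    k = int(np.searchsorted(np.asarray(th.cuts), distance, side="right"))
    return th.colors[k]


def compass_cue(inst: InstrumentState, centroid: Point3) -> CompassCue:
    """Unit direction and distance from the instrument tip to the tumour centre."""
    if inst.tip.frame != centroid.frame:
        from .errors import FrameMismatchError
        raise FrameMismatchError(
            f"tip in {inst.tip.frame!r} vs centroid in {centroid.frame!r}")
    delta = centroid.coordinates - inst.tip.coordinates
    height = float(np.linalg.norm(delta))
    if height < 1e-6:
        from .errors import DegenerateConfigurationError
        raise DegenerateConfigurationError(
            "instrument tip coincides with the tumour centre; no cue direction")
    return CompassCue(apex=inst.tip, direction=delta / height, height=height)


def projected_path(inst: InstrumentState, sdf: SignedDistanceField,
                   spacing: float = 1.0, diameter: float = 1.0,
                   max_extent: float = 30.0,
                   th: ProximityThresholds = ProximityThresholds(),
                   hit_tol: float = 0.01) -> tuple[list[PathSphere], float | None]:
    """Virtual tool-axis extension with banded spheres and the first surface hit.

    Sphere ``k`` is centred at ``tip + k * spacing * axis``; its colour is the
    proximity band of the field value at its centre (out-of-grid spheres are
    green).  ``hit`` is the smallest ray parameter at which the signed
    distance changes sign along the ray, refined by bisection to ``hit_tol``
    mm; ``None`` when the ray never crosses the surface within the extent.
    """
    if spacing <= 0:
        raise ValueError("sphere spacing must be positive")
    if max_extent <= 0:
        raise ValueError("max_extent must be positive")
    tip = inst.tip.coordinates
    axis = inst.axis

    def sdf_at(t: np.ndarray):
        pts = tip[None, :] + np.asarray(t)[:, None] * axis[None, :]
        ok = sdf.contains(pts)
        vals = np.full(len(pts), np.nan)
        if ok.any():
            vals[ok] = sdf.query(pts[ok])
        return vals, ok

    spheres: list[PathSphere] = []
    ks = np.arange(1, int(np.floor(max_extent / spacing)) + 1)
    if ks.size:
        vals, ok = sdf_at(ks * spacing)
        for k, v, o in zip(ks, vals, ok):
            center = Point3(tip + k * spacing * axis, frame=inst.tip.frame)
            state = classify_proximity(float(v), th) if o else th.colors[-1]
            spheres.append(PathSphere(center=center, diameter=diameter,
                                      state=state, out_of_field=not o))

    # march the ray for the first sign change, then bisect
    step = min(spacing, 4 * hit_tol, 0.25)
    ts = np.arange(0.0, max_extent + step, step)
    vals, ok = sdf_at(ts)
    hit = None
    prev_t = prev_v = None
    for t, v, o in zip(ts, vals, ok):
        if not o:
            prev_t = prev_v = None
            continue
        if prev_v is not None and np.sign(v) != np.sign(prev_v) and prev_v > 0:
            lo_t, hi_t = prev_t, t
            while hi_t - lo_t > hit_tol:
                mid = 0.5 * (lo_t + hi_t)
                mv, _ = sdf_at(np.array([mid]))
                if mv[0] > 0:
                    lo_t = mid
                else:
                    hi_t = mid
            hit = 0.5 * (lo_t + hi_t)
            break
        prev_t, prev_v = t, v
    return spheres, (float(hit) if hit is not None else None)


def virtual_viewpoint(nTc_current: RigidTransform | None = None,
                      mesh: SurfaceMesh | None = None,
                      instruments: Sequence[InstrumentState] = (),
                      offset: float = 50.0,
                      camera: CameraModel | None = None) -> VirtualView:
    """Overhead virtual camera: centred ``offset`` mm from the aid origin along
    the marker-plane normal (+z of N), optical axis perpendicular to the
    marker, looking back at it.

    Returns projected 2D points with per-vertex depth below the marker plane
    (treating the aid as a planar approximation of the local organ surface);
    rendering pixels is deliberately out of scope.
    """
    if offset <= 0:
        raise ValueError("offset must be positive")
    if camera is None:
        camera = CameraModel(fx=500.0, fy=500.0, cx=400.0, cy=400.0,
                             width=800, height=800)
    # Aid frame N has +z pointing into the tissue, so the virtual camera sits
    # at (0, 0, -offset) in N looking along +z_N; its axes coincide with N's.
    # A point d mm below the marker plane (z_N = d) is at camera depth
    # offset + d.
    vTn = RigidTransform(np.eye(3), np.array([0.0, 0.0, offset]),
                         source="N", target="Vcam")
    view = VirtualView(camera_pose=vTn, offset=offset, camera=camera)
    if mesh is not None:
        pc = vTn.apply(mesh.vertices)
        view.mesh_pixels = camera.project_points(pc)
        view.mesh_depth_below_plane = mesh.vertices[:, 2].copy()
    if instruments:
        tips = vTn.apply(np.array([i.tip.coordinates for i in instruments]))
        pix = np.full((len(tips), 2), np.nan)
        visible = tips[:, 2] > 0  # tips above the virtual camera cannot project
        if visible.any():
            pix[visible] = camera.project_points(tips[visible])
        view.instrument_pixels = pix
    return view


def guidance_frame(instruments: Sequence[InstrumentState],
                   sdf: SignedDistanceField,
                   centroid: Point3,
                   th: ProximityThresholds = ProximityThresholds(),
                   spacing: float = 1.0, diameter: float = 1.0,
                   max_extent: float = 30.0, offset: float = 50.0,
                   mesh: SurfaceMesh | None = None,
                   stale: bool = False) -> GuidanceOutput:
    """Assemble all four augmentations for one display frame."""
    instruments = list(instruments)
    if not 1 <= len(instruments) <= 2:
        raise ValueError("guidance needs one or two instruments")
    per_inst = []
    for inst in instruments:
        tip = inst.tip.coordinates
        in_field = bool(sdf.contains(tip[None, :])[0])
        if in_field:
            d = query_distance(sdf, inst.tip)
            state = classify_proximity(d, th)
        else:
            # outside the grid means farther than the field margin: green
            d, state = None, th.colors[-1]
        spheres, hit = projected_path(inst, sdf, spacing=spacing,
                                      diameter=diameter, max_extent=max_extent,
                                      th=th)
        per_inst.append(InstrumentGuidance(
            instrument_id=inst.instrument_id, state=state, distance_mm=d,
            out_of_field=not in_field, compass=compass_cue(inst, centroid),
            path=spheres, hit_mm=hit if in_field else None))
    view = virtual_viewpoint(mesh=mesh, instruments=instruments, offset=offset)
    return GuidanceOutput(instruments=per_inst, virtual_view=view, stale=stale)
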