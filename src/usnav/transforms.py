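"""Frame-labelled rigid-transform algebra and pinhole camera projection.

All positions are in millimetres and all angles in radians.  A
:class:`RigidTransform` labelled ``target=A, source=B`` maps coordinates
expressed in frame ``B`` into frame ``A`` (written ``A<-B``).  The canonical
frame labels of the guidance system are:

====  =======================================================
``N``  navigation aid (barbed marker inserted into the organ)
``C``  calibrated camera (left laparoscope channel)
``K``  KeyDot marker on the ultrasound transducer
``U``  ultrasound image plane
``L``  laparoscope as tracked kinematically by the robot
``I``  surgical instrument
====  =======================================================

Free-form labels are accepted everywhere so synthetic scenes can introduce
their own frames.  The camera frame is right-handed with +z pointing into the
scene; ultrasound pixel ``(row, col)`` maps to the in-plane point
``(x, y, z) = (col * spacing_col, row * spacing_row, 0)`` in frame ``U``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import BehindCameraError, FrameMismatchError

__all__ = [
    "CANONICAL_FRAMES",
    "RigidTransform",
    "Point3",
    "CameraModel",
    "USImageGeometry",
    "compose",
    "invert",
    "transform_point",
    "project",
    "us_pixel_to_aid",
    "instrument_to_aid",
]

#: Frame labels with a fixed meaning in the guidance system.
CANONICAL_FRAMES = {
    "N": "navigation aid",
    "C": "calibrated camera",
    "K": "KeyDot marker",
    "U": "ultrasound image",
    "L": "laparoscope (kinematic)",
    "I": "instrument",
}

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """Rigid map ``target <- source``: ``p_target = rotation @ p_source + translation``."""

    rotation: np.ndarray
    translation: np.ndarray
    source: str = "B"
    target: str = "A"

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        err = np.abs(R @ R.T - np.eye(3)).max()
        if err > 1e-6:
            raise ValueError(f"rotation is not orthonormal (|RR^T - I| = {err:.2e})")
        if err > _ORTHO_TOL:
            # re-project onto SO(3) for drift below the hard failure threshold
            U, _, Vt = np.linalg.svd(R)
            R = U @ Vt
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has determinant -1 (reflection, not rotation)")
        R.flags.writeable = False
        t.flags.writeable = False
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    # -- constructors ---------------------------------------------------
    @classmethod
    def identity(cls, target: str = "A", source: str = "A") -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), source=source, target=target)

    @classmethod
    def from_matrix(cls, matrix: np.ndarray, source: str = "B", target: str = "A") -> "RigidTransform":
        """Build from a 4x4 homogeneous matrix."""
        M = np.asarray(matrix, dtype=float)
        if M.shape != (4, 4):
            raise ValueError(f"expected a 4x4 matrix, got {M.shape}")
        return cls(M[:3, :3], M[:3, 3], source=source, target=target)

    @classmethod
    def from_rotvec(cls, rotvec: Sequence[float], translation: Sequence[float],
                    source: str = "B", target: str = "A") -> "RigidTransform":
        from scipy.spatial.transform import Rotation

        R = Rotation.from_rotvec(np.asarray(rotvec, dtype=float)).as_matrix()
        return cls(R, np.asarray(translation, dtype=float), source=source, target=target)

    @classmethod
    def random(cls, rng: np.random.Generator, max_translation: float = 100.0,
               source: str = "B", target: str = "A") -> "RigidTransform":
        """A uniformly random rotation with a uniform translation in a cube."""
        from scipy.spatial.transform import Rotation

        R = Rotation.random(random_state=rng).as_matrix()
        t = rng.uniform(-max_translation, max_translation, size=3)
        return cls(R, t, source=source, target=target)

    # -- algebra --------------------------------------------------------
    def as_matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        return compose(self, other)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return compose(self, other)

    def inverse(self) -> "RigidTransform":
        return invert(self)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (n, 3) or (3,) array of bare coordinates (no frame check)."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    # -- serialization --------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "source": self.source,
            "target": self.target,
            "matrix": self.as_matrix().tolist(),
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RigidTransform":
        d = json.loads(text)
        return cls.from_matrix(np.array(d["matrix"]), source=d["source"], target=d["target"])

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "RigidTransform":
        with open(path) as fh:
            return cls.from_json(fh.read())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"RigidTransform({self.target}<-{self.source}, "
                f"t={np.array2string(self.translation, precision=3)})")


@dataclass(frozen=True)
class Point3:
    """A 3-vector in millimetres tagged with the frame it is expressed in."""

    coordinates: np.ndarray
    frame: str

    def __post_init__(self) -> None:
        c = np.asarray(self.coordinates, dtype=float).reshape(3)
        if not np.all(np.isfinite(c)):
            raise ValueError("point coordinates must be finite")
        c.flags.writeable = False
        object.__setattr__(self, "coordinates", c)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Point3({np.array2string(self.coordinates, precision=3)} in {self.frame})"


@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera with Brown radial/tangential distortion (OpenCV order)."""

    fx: float
    fy: float
    cx: float
    cy: float
    k1: float = 0.0
    k2: float = 0.0
    p1: float = 0.0
    p2: float = 0.0
    width: int = 1280
    height: int = 720

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point must lie inside the image")

    def distort(self, xy: np.ndarray) -> np.ndarray:
        """Apply distortion to normalized image coordinates, shape (..., 2)."""
        xy = np.asarray(xy, dtype=float)
        x, y = xy[..., 0], xy[..., 1]
        r2 = x * x + y * y
        radial = 1.0 + self.k1 * r2 + self.k2 * r2 * r2
        xd = x * radial + 2 * self.p1 * x * y + self.p2 * (r2 + 2 * x * x)
        yd = y * radial + self.p1 * (r2 + 2 * y * y) + 2 * self.p2 * x * y
        return np.stack([xd, yd], axis=-1)

    def undistort(self, xy: np.ndarray, iterations: int = 20) -> np.ndarray:
        """Invert :meth:`distort` by fixed-point iteration on normalized coords."""
        xy = np.asarray(xy, dtype=float)
        guess = xy.copy()
        for _ in range(iterations):
            delta = self.distort(guess) - guess
            guess = xy - delta
        return guess

    def project_points(self, points: np.ndarray) -> np.ndarray:
        """Project (..., 3) camera-frame points to (..., 2) pixels."""
        p = np.asarray(points, dtype=float)
        z = p[..., 2]
        if np.any(z <= 0):
            raise BehindCameraError("point(s) at non-positive depth cannot be projected")
        norm = p[..., :2] / z[..., None]
        d = self.distort(norm)
        return np.stack([self.fx * d[..., 0] + self.cx,
                         self.fy * d[..., 1] + self.cy], axis=-1)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CameraModel":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class USImageGeometry:
    """Pixel spacings (mm/px) and dimensions of a B-mode ultrasound image."""

    spacing_row: float
    spacing_col: float
    rows: int
    cols: int

    def __post_init__(self) -> None:
        if self.spacing_row <= 0 or self.spacing_col <= 0:
            raise ValueError("pixel spacings must be positive")
        if self.rows < 1 or self.cols < 1:
            raise ValueError("image dimensions must be positive")

    @property
    def width_mm(self) -> float:
        return self.cols * self.spacing_col

    @property
    def depth_mm(self) -> float:
        return self.rows * self.spacing_row

    def pixel_to_plane(self, pixels: np.ndarray) -> np.ndarray:
        """Map (..., 2) ``(row, col)`` pixels to (..., 3) mm points on the z=0 plane."""
        px = np.asarray(pixels, dtype=float)
        x = px[..., 1] * self.spacing_col
        y = px[..., 0] * self.spacing_row
        return np.stack([x, y, np.zeros_like(x)], axis=-1)


# ----------------------------------------------------------------------
# operations


def compose(first: RigidTransform, second: RigidTransform) -> RigidTransform:
    """Chain ``A<-B`` with ``B<-C`` into ``A<-C``."""
    if first.source != second.target:
        raise FrameMismatchError(
            f"cannot compose {first.target}<-{first.source} with "
            f"{second.target}<-{second.source}: inner frames "
            f"{first.source!r} != {second.target!r}")
    R = first.rotation @ second.rotation
    t = first.rotation @ second.translation + first.translation
    return RigidTransform(R, t, source=second.source, target=first.target)


def invert(T: RigidTransform) -> RigidTransform:
    """The inverse map ``B<-A``."""
    R = T.rotation.T
    return RigidTransform(R, -R @ T.translation, source=T.target, target=T.source)


def transform_point(T: RigidTransform, p: Point3) -> Point3:
    if p.frame != T.source:
        raise FrameMismatchError(
            f"point in frame {p.frame!r} cannot be mapped by {T.target}<-{T.source}")
    return Point3(T.rotation @ p.coordinates + T.translation, frame=T.target)


def project(cam: CameraModel, p: Point3) -> tuple[float, float]:
    """Project a camera-frame point to a distorted pixel ``(u, v)``."""
    uv = cam.project_points(p.coordinates)
    return float(uv[0]), float(uv[1])


def _check_chain(*transforms: RigidTransform) -> RigidTransform:
    chain = transforms[0]
    for nxt in transforms[1:]:
        chain = compose(chain, nxt)
    return chain


def us_pixel_to_aid(pixel: tuple[float, float], geom: USImageGeometry,
                    kTu: RigidTransform, cTk: RigidTransform,
                    nTc: RigidTransform) -> Point3:
    """Map an ultrasound pixel into the navigation-aid frame (the P_N chain
    through KeyDot and camera)."""
    row, col = pixel
    if not (0 <= row < geom.rows and 0 <= col < geom.cols):
        raise ValueError(f"pixel {pixel} outside {geom.rows}x{geom.cols} image")
    chain = _check_chain(nTc, cTk, kTu)
    p_u = Point3(geom.pixel_to_plane(np.array([row, col])), frame=kTu.source)
    return transform_point(chain, p_u)


def instrument_to_aid(p_I: Point3, lTi: RigidTransform, cTl: RigidTransform,
                      nTc: RigidTransform) -> Point3:
    """Map an instrument-frame point into the navigation-aid frame (the P_N
    chain through the kinematic laparoscope and camera)."""
    chain = _check_chain(nTc, cTl, lTi)
    return transform_point(chain, p_I)
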