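"""Paired-point rigid registration and FRE/TRE analysis.

Implements the closed-form least-squares (SVD, Arun-style) solution for the
rigid transform between two point clouds, the fiducial registration error
(FRE) of the fit, and the target registration error (TRE) at held-out points.
This is the machinery behind the hand-eye calibration that links the
kinematically tracked laparoscope frame ``L`` to the optically calibrated
camera frame ``C``: the navigation aid is moved to several poses, the
instrument touches known grid points, and the paired points (optical, kinematic)
determine ``C<-L``.

FRE is reported as the *mean* Euclidean residual; the RMS residual is carried
alongside in every result because the two conventions differ by ~8% for
Gaussian errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateConfigurationError
from .report import ErrorReport
from .transforms import RigidTransform

__all__ = [
    "PointCorrespondences",
    "RegistrationResult",
    "RigidRegistration",
    "fit_rigid",
    "compute_tre",
    "calibrate_camera_to_laparoscope",
]

_COLLINEAR_RTOL = 1e-9


@dataclass(frozen=True)
class PointCorrespondences:
    """Paired points (mm): ``points_a[i]`` in frame A corresponds to ``points_b[i]`` in B."""

    points_a: np.ndarray
    points_b: np.ndarray
    frame_a: str = "A"
    frame_b: str = "B"

    def __post_init__(self) -> None:
        a = np.atleast_2d(np.asarray(self.points_a, dtype=float))
        b = np.atleast_2d(np.asarray(self.points_b, dtype=float))
        if a.shape != b.shape or a.shape[1] != 3:
            raise ValueError(f"point arrays must both be (n, 3); got {a.shape} and {b.shape}")
        if a.shape[0] < 3:
            raise DegenerateConfigurationError(
                f"rigid registration needs >= 3 pairs, got {a.shape[0]}")
        object.__setattr__(self, "points_a", a)
        object.__setattr__(self, "points_b", b)

    @property
    def n(self) -> int:
        return self.points_a.shape[0]

    @classmethod
    def from_csv(cls, path, frame_a: str = "A", frame_b: str = "B") -> "PointCorrespondences":
        """Read columns ``frameA_x..z, frameB_x..z`` (header optional)."""
        raw = np.genfromtxt(path, delimiter=",", names=True)
        if raw.dtype.names and len(raw.dtype.names) >= 6:
            cols = list(raw.dtype.names)
            data = np.vstack([raw[c] for c in cols[:6]]).T
        else:  # headerless
            data = np.loadtxt(path, delimiter=",")
        return cls(data[:, :3], data[:, 3:6], frame_a=frame_a, frame_b=frame_b)

    def to_csv(self, path) -> None:
        header = "frameA_x,frameA_y,frameA_z,frameB_x,frameB_y,frameB_z"
        np.savetxt(path, np.hstack([self.points_a, self.points_b]),
                   delimiter=",", header=header, comments="")

    def split(self, n_fit: int) -> tuple["PointCorrespondences", "PointCorrespondences"]:
        """First ``n_fit`` pairs for fitting, the remainder for TRE evaluation."""
        if not (3 <= n_fit <= self.n):
            raise ValueError(f"n_fit must be in [3, {self.n}]")
        fit = PointCorrespondences(self.points_a[:n_fit], self.points_b[:n_fit],
                                   self.frame_a, self.frame_b)
        if n_fit == self.n:
            return fit, None
        test = PointCorrespondences(
            self.points_a[n_fit:], self.points_b[n_fit:], self.frame_a, self.frame_b) \
            if self.n - n_fit >= 3 else _RawPairs(self.points_a[n_fit:], self.points_b[n_fit:],
                                                  self.frame_a, self.frame_b)
        return fit, test


class _RawPairs:
    """Held-out pair container exempt from the n >= 3 fitting precondition."""

    def __init__(self, a, b, frame_a="A", frame_b="B"):
        self.points_a = np.atleast_2d(np.asarray(a, dtype=float))
        self.points_b = np.atleast_2d(np.asarray(b, dtype=float))
        self.frame_a = frame_a
        self.frame_b = frame_b
        self.n = self.points_a.shape[0]


@dataclass
class RegistrationResult:
    """Fitted rigid transform ``A<-B`` plus its residual diagnostics."""

    transform: RigidTransform
    residuals: np.ndarray
    tre: ErrorReport | None = None

    def __post_init__(self) -> None:
        self.residuals = np.asarray(self.residuals, dtype=float).ravel()

    @property
    def fre_mm(self) -> float:
        """Mean Euclidean residual over the fitting pairs."""
        return float(np.mean(self.residuals))

    @property
    def fre_rms_mm(self) -> float:
        """Root-mean-square residual (the alternative FRE convention)."""
        return float(np.sqrt(np.mean(self.residuals ** 2)))

    @property
    def n(self) -> int:
        return int(self.residuals.size)

    def summary(self) -> str:
        lines = [
            "Paired-point rigid registration",
            "===============================",
            f"frames:            {self.transform.target} <- {self.transform.source}",
            f"pairs (fit):       {self.n}",
            f"FRE (mean):        {self.fre_mm:.4f} mm",
            f"FRE (RMS):         {self.fre_rms_mm:.4f} mm",
            f"max residual:      {self.residuals.max():.4f} mm",
            "rotation:",
        ]
        for row in self.transform.rotation:
            lines.append("    [" + "  ".join(f"{v: .6f}" for v in row) + "]")
        t = self.transform.translation
        lines.append(f"translation (mm):  [{t[0]: .4f}  {t[1]: .4f}  {t[2]: .4f}]")
        if self.tre is not None:
            lines.append(f"TRE (held out):    {self.tre.mean:.4f} +/- {self.tre.sd:.4f} mm "
                         f"(n={self.tre.n})")
        return "\n".join(lines)


class RigidRegistration:
    """Model-style front end: build from correspondences, ``fit()`` for a result.

    >>> model = RigidRegistration(corr)
    >>> result = model.fit()
    >>> print(result.summary())
    """

    def __init__(self, correspondences: PointCorrespondences):
        self.correspondences = correspondences

    @classmethod
    def from_arrays(cls, points_a, points_b, frame_a="A", frame_b="B") -> "RigidRegistration":
        return cls(PointCorrespondences(points_a, points_b, frame_a, frame_b))

    def fit(self) -> RegistrationResult:
        return fit_rigid(self.correspondences)


def _check_not_collinear(points: np.ndarray) -> None:
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[0] == 0 or s[1] < _COLLINEAR_RTOL * s[0]:
        raise DegenerateConfigurationError(
            "points are (near-)collinear; the rigid transform is not unique")


def fit_rigid(corr: PointCorrespondences) -> RegistrationResult:
    """Closed-form SVD least-squares rigid fit mapping frame B onto frame A.

    Minimizes ``sum_i || R b_i + t - a_i ||^2`` with the reflection guard
    (smallest-singular-vector sign flip when the optimal orthogonal matrix
    would be a reflection).
    """
    a, b = corr.points_a, corr.points_b
    _check_not_collinear(b)
    _check_not_collinear(a)
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    H = (b - cb).T @ (a - ca)
    U, s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    transform = RigidTransform(R, t, source=corr.frame_b, target=corr.frame_a)
    residuals = np.linalg.norm(transform.apply(b) - a, axis=1)
    return RegistrationResult(transform=transform, residuals=residuals)


def compute_tre(result: RegistrationResult, test) -> ErrorReport:
    """Mean +/- SD Euclidean distance between mapped frame-B test points and
    their frame-A mates, under the already-fitted transform."""
    if test is None or getattr(test, "n", 0) == 0:
        raise ValueError("TRE needs a non-empty held-out set")
    if (test.frame_a, test.frame_b) != (result.transform.target, result.transform.source):
        from .errors import FrameMismatchError
        raise FrameMismatchError(
            f"test pairs are {test.frame_a}<-{test.frame_b} but the transform is "
            f"{result.transform.target}<-{result.transform.source}")
    d = np.linalg.norm(result.transform.apply(test.points_b) - test.points_a, axis=1)
    return ErrorReport(metric="TRE", values=d,
                       config={"n_targets": int(d.size)})


def calibrate_camera_to_laparoscope(
        touch_events: Sequence[tuple[np.ndarray, np.ndarray]] | PointCorrespondences,
        n_fit: int = 12) -> RegistrationResult:
    """Hand-eye calibration ``C<-L`` from grid-touch events.

    Each event pairs a grid point observed optically in the camera frame with
    the instrument-tip position reported kinematically in the laparoscope
    frame.  Following the calibration protocol, the first ``n_fit`` events
    (12 of 23 by default) determine the transform and the remainder, if any,
    are scored as held-out TRE.
    """
    if isinstance(touch_events, PointCorrespondences):
        corr = touch_events
    else:
        events = list(touch_events)
        if len(events) < 3:
            raise DegenerateConfigurationError(
                f"hand-eye calibration needs >= 3 touch events, got {len(events)}")
        cam_pts = np.array([np.asarray(e[0], dtype=float) for e in events])
        kin_pts = np.array([np.asarray(e[1], dtype=float) for e in events])
        corr = PointCorrespondences(cam_pts, kin_pts, frame_a="C", frame_b="L")
    n_fit = min(n_fit, corr.n)
    fit_set, test_set = corr.split(n_fit)
    result = fit_rigid(fit_set)
    if test_set is not None and test_set.n > 0:
        result.tre = compute_tre(result, test_set)
    return result
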