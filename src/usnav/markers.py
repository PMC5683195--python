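"""Circle-grid marker detection and planar pose estimation.

The navigation aid and the KeyDot marker on the ultrasound transducer both
carry a printed black-and-white grid of circles.  Tracking proceeds in two
stages: find the intensity-weighted centroids of the dark circles in a camera
image and order them into the grid topology, then estimate the marker pose
relative to the calibrated camera from the known planar geometry (homography
via normalized DLT, decomposed to R, t and refined by Gauss-Newton on the
reprojection error).

Grid ordering convention: indices are row-major; because a plain grid of
circles is symmetric under a 180-degree rotation (and, through a homography,
under axis flips), the ordering is made canonical by requiring (a) a
positive-orientation homography Jacobian (the marker is seen from the front)
and (b) that the first grid row runs toward +u in the image (toward +v when
perpendicular to u).  Asymmetric dimensions (rows != cols) are recommended so
90-degree rotations cannot alias.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops

from .errors import ConvergenceError, DegenerateConfigurationError, DetectionFailureError
from .transforms import CameraModel, RigidTransform

__all__ = [
    "CircleGridModel",
    "GridObservation",
    "PoseEstimate",
    "detect_grid_centroids",
    "estimate_pose",
    "predict_search_region",
    "read_image",
    "write_image",
]


def read_image(path) -> np.ndarray:
    """Read a grayscale image (PNG/TIFF) as a float array in [0, 1]."""
    from skimage.io import imread
    from skimage.util import img_as_float

    img = imread(str(path))
    if img.ndim == 3:
        img = img.mean(axis=2)
    return img_as_float(img)


def write_image(path, image: np.ndarray) -> None:
    """Write a float grayscale image (clipped to [0, 1]) as 8-bit PNG/TIFF."""
    from skimage.io import imsave

    arr = (np.clip(np.asarray(image, dtype=float), 0, 1) * 255).astype(np.uint8)
    imsave(str(path), arr, check_contrast=False)


@dataclass(frozen=True)
class CircleGridModel:
    """Planar grid of ``rows x cols`` circles, pitch and diameter in mm.

    Model point (i, j) sits at ``(x, y, z) = (j * pitch, i * pitch, 0)`` in the
    marker frame (x along columns, y along rows, marker plane at z = 0).
    """

    rows: int = 4
    cols: int = 5
    pitch: float = 2.5
    diameter: float = 1.25

    def __post_init__(self) -> None:
        if self.rows < 2 or self.cols < 2:
            raise ValueError("grid needs at least 2 rows and 2 columns")
        if not (self.pitch > self.diameter > 0):
            raise ValueError("need pitch > circle diameter > 0")

    @property
    def n(self) -> int:
        return self.rows * self.cols

    def model_points(self) -> np.ndarray:
        """(n, 3) marker-frame points in row-major (i, j) order, z = 0."""
        i, j = np.mgrid[0:self.rows, 0:self.cols]
        return np.stack([j.ravel() * self.pitch, i.ravel() * self.pitch,
                         np.zeros(self.n)], axis=1)

    def indices(self) -> np.ndarray:
        i, j = np.mgrid[0:self.rows, 0:self.cols]
        return np.stack([i.ravel(), j.ravel()], axis=1)


@dataclass
class GridObservation:
    """Ordered circle centroids: ``centroids[k]`` is pixel (u, v) of grid index
    ``indices[k] = (i, j)``."""

    centroids: np.ndarray
    indices: np.ndarray
    image_id: str = ""
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        self.centroids = np.atleast_2d(np.asarray(self.centroids, dtype=float))
        self.indices = np.atleast_2d(np.asarray(self.indices, dtype=int))
        if self.centroids.shape[0] != self.indices.shape[0]:
            raise ValueError("centroids and indices must have equal length")
        tup = {tuple(ij) for ij in self.indices}
        if len(tup) != self.indices.shape[0]:
            raise ValueError("grid indices must be unique")

    @property
    def n(self) -> int:
        return self.centroids.shape[0]

    def to_csv(self, path) -> None:
        data = np.hstack([self.indices, self.centroids])
        np.savetxt(path, data, delimiter=",", header="i,j,u,v", comments="")

    @classmethod
    def from_csv(cls, path) -> "GridObservation":
        data = np.atleast_2d(np.loadtxt(path, delimiter=",", skiprows=1))
        return cls(centroids=data[:, 2:4], indices=data[:, 0:2].astype(int))


@dataclass
class PoseEstimate:
    """Marker pose ``C <- marker`` with its mean reprojection residual."""

    cTm: RigidTransform
    residual_px: float
    grid: CircleGridModel | None = None
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        if self.residual_px < 0:
            raise ValueError("residual must be non-negative")


# ----------------------------------------------------------------------
# homography helpers


def _fit_homography(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Normalized DLT homography mapping (n, 2) src onto (n, 2) dst."""

    def _norm(pts):
        c = pts.mean(axis=0)
        scale = np.sqrt(2.0) / max(np.mean(np.linalg.norm(pts - c, axis=1)), 1e-12)
        T = np.array([[scale, 0, -scale * c[0]],
                      [0, scale, -scale * c[1]],
                      [0, 0, 1.0]])
        return (pts - c) * scale, T

    s, Ts = _norm(np.asarray(src, dtype=float))
    d, Td = _norm(np.asarray(dst, dtype=float))
    n = s.shape[0]
    A = np.zeros((2 * n, 9))
    A[0::2, 0:2] = s
    A[0::2, 2] = 1.0
    A[0::2, 6:8] = -s * d[:, [0]]
    A[0::2, 8] = -d[:, 0]
    A[1::2, 3:5] = s
    A[1::2, 5] = 1.0
    A[1::2, 6:8] = -s * d[:, [1]]
    A[1::2, 8] = -d[:, 1]
    _, sv, Vt = np.linalg.svd(A)
    if sv[-2] < 1e-12 * sv[0]:
        raise DegenerateConfigurationError("homography is under-determined")
    H = Vt[-1].reshape(3, 3)
    H = np.linalg.inv(Td) @ H @ Ts
    return H / H[2, 2]


def _apply_homography(H: np.ndarray, pts: np.ndarray) -> np.ndarray:
    p = np.hstack([pts, np.ones((pts.shape[0], 1))]) @ H.T
    return p[:, :2] / p[:, [2]]


def _check_noncollinear(pts: np.ndarray, what: str) -> None:
    c = pts - pts.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    if s[0] == 0 or s[1] < 1e-9 * s[0]:
        raise DegenerateConfigurationError(f"{what} are (near-)collinear")


# ----------------------------------------------------------------------
# detection


def _candidate_orderings(pts: np.ndarray, rows: int, cols: int):
    """Yield row-major ordering candidates built from the cloud's PCA axes."""
    c = pts - pts.mean(axis=0)
    _, _, Vt = np.linalg.svd(c, full_matrices=False)
    e1, e2 = Vt[0], Vt[1]
    for (row_axis, col_axis), (nr, nc) in (((e2, e1), (rows, cols)),
                                           ((e1, e2), (rows, cols)),
                                           ((e2, e1), (cols, rows)),
                                           ((e1, e2), (cols, rows))):
        if nr != rows:
            continue  # chunking below is by requested rows
        t = c @ row_axis
        s = c @ col_axis
        order = np.argsort(t, kind="stable")
        rows_of = [order[k * cols:(k + 1) * cols] for k in range(rows)]
        idx = np.concatenate([r[np.argsort(s[r], kind="stable")] for r in rows_of])
        yield idx
    # the transposed chunkings, re-expressed row-major
    for row_axis, col_axis in ((e1, e2), (e2, e1)):
        t = c @ row_axis
        s = c @ col_axis
        order = np.argsort(t, kind="stable")
        chunks = [order[k * rows:(k + 1) * rows] for k in range(cols)]
        grid = np.stack([ch[np.argsort(s[ch], kind="stable")] for ch in chunks])  # (cols, rows)
        yield grid.T.ravel()


def _ordering_variants(idx: np.ndarray, rows: int, cols: int):
    g = idx.reshape(rows, cols)
    for flip_r in (False, True):
        for flip_c in (False, True):
            v = g[::-1] if flip_r else g
            v = v[:, ::-1] if flip_c else v
            yield v.ravel()


def _orientation_ok(H: np.ndarray, grid: CircleGridModel) -> bool:
    """True when the marker is seen from the front: the homography preserves
    the planar orientation at the grid centre."""
    cx = 0.5 * (grid.cols - 1) * grid.pitch
    cy = 0.5 * (grid.rows - 1) * grid.pitch
    eps = 1e-3 * grid.pitch
    p0 = _apply_homography(H, np.array([[cx, cy]]))[0]
    px = _apply_homography(H, np.array([[cx + eps, cy]]))[0]
    py = _apply_homography(H, np.array([[cx, cy + eps]]))[0]
    jac = np.array([px - p0, py - p0]).T
    return np.linalg.det(jac) > 0


def _canonical_180(centroids: np.ndarray, indices: np.ndarray,
                   grid: CircleGridModel) -> tuple[np.ndarray, np.ndarray]:
    """Resolve the grid's 180-degree self-symmetry deterministically."""
    lut = {tuple(ij): k for k, ij in enumerate(indices)}
    a = centroids[lut[(0, 0)]]
    b = centroids[lut[(0, grid.cols - 1)]]
    d = b - a
    if d[0] > 1e-9 or (abs(d[0]) <= 1e-9 and d[1] > 0):
        return centroids, indices
    flipped = np.array([[grid.rows - 1 - i, grid.cols - 1 - j] for i, j in indices])
    return centroids, flipped


def order_centroids(points: np.ndarray, grid: CircleGridModel) -> GridObservation:
    """Assign row-major grid indices to an unordered set of ``rows*cols``
    centroids by homography consistency, returning a canonical ordering."""
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] != grid.n:
        raise DetectionFailureError(
            f"need exactly {grid.n} centroids to order, got {pts.shape[0]}")
    model_xy = grid.model_points()[:, :2]
    best = None
    seen = set()
    for base in _candidate_orderings(pts, grid.rows, grid.cols):
        for idx in _ordering_variants(base, grid.rows, grid.cols):
            key = tuple(idx)
            if key in seen:
                continue
            seen.add(key)
            try:
                H = _fit_homography(model_xy, pts[idx])
            except DegenerateConfigurationError:
                continue
            if not _orientation_ok(H, grid):
                continue
            res = np.linalg.norm(_apply_homography(H, model_xy) - pts[idx], axis=1).mean()
            if best is None or res < best[0]:
                best = (res, idx)
    if best is None:
        raise DetectionFailureError("could not order centroids into the grid topology")
    res, idx = best
    # sanity: residual should be well below one pitch interval in pixels
    spacing_px = np.median(np.linalg.norm(np.diff(pts[idx].reshape(
        grid.rows, grid.cols, 2), axis=1), axis=-1))
    if res > 0.5 * spacing_px:
        raise DetectionFailureError(
            f"grid ordering inconsistent (residual {res:.1f}px vs spacing {spacing_px:.1f}px)")
    centroids, indices = _canonical_180(pts[idx], grid.indices(), grid)
    return GridObservation(centroids=centroids, indices=indices)


def detect_grid_centroids(image: np.ndarray, grid: CircleGridModel,
                          roi: tuple[int, int, int, int] | None = None,
                          min_blob_px: int = 4) -> GridObservation:
    """Detect the dark circles of the grid and order them into topology.

    ``roi`` is an inclusive-exclusive pixel box ``(umin, vmin, umax, vmax)``
    (e.g. from :func:`predict_search_region`).  Raises
    :class:`DetectionFailureError` when fewer than ``rows*cols`` circle blobs
    are found — the signal the guidance layer uses to flag occlusion.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a non-empty 2D grayscale image")
    u0 = v0 = 0
    if roi is not None:
        umin, vmin, umax, vmax = (int(x) for x in roi)
        if not (0 <= umin < umax <= img.shape[1] and 0 <= vmin < vmax <= img.shape[0]):
            raise ValueError(f"roi {roi} outside image {img.shape}")
        img = img[vmin:vmax, umin:umax]
        u0, v0 = umin, vmin
    if img.max() - img.min() < 1e-12:
        raise DetectionFailureError("image has no contrast; no circles found")
    tau = threshold_otsu(img)
    dark = img < tau
    labels = sk_label(dark, connectivity=2)
    regions = [r for r in regionprops(labels) if r.area >= min_blob_px]
    # reject blobs touching the image border (clipped circles bias centroids)
    h, w = img.shape
    regions = [r for r in regions
               if r.bbox[0] > 0 and r.bbox[1] > 0 and r.bbox[2] < h and r.bbox[3] < w]
    if len(regions) > grid.n:
        areas = np.array([r.area for r in regions])
        med = np.median(np.sort(areas)[-grid.n:])
        regions = [r for r in regions if 0.3 * med <= r.area <= 3.0 * med]
    if len(regions) != grid.n:
        raise DetectionFailureError(
            f"found {len(regions)} circle blobs, expected {grid.n} "
            "(marker occluded or out of view?)")
    cents = []
    for r in regions:
        rr, cc = r.coords[:, 0], r.coords[:, 1]
        w_dark = np.clip(tau - img[rr, cc], 0.0, None) + 1e-12
        u = np.average(cc, weights=w_dark) + u0
        v = np.average(rr, weights=w_dark) + v0
        cents.append((u, v))
    return order_centroids(np.array(cents), grid)


# ----------------------------------------------------------------------
# pose estimation


def _decompose_homography(H: np.ndarray) -> RigidTransform:
    """Planar homography (model mm -> normalized camera coords) to R, t with
    positive depth and SVD orthonormalization."""
    h1, h2, h3 = H[:, 0], H[:, 1], H[:, 2]
    lam = 2.0 / (np.linalg.norm(h1) + np.linalg.norm(h2))
    if h3[2] * lam < 0:  # enforce marker in front of the camera
        lam = -lam
    r1, r2 = lam * h1, lam * h2
    t = lam * h3
    Q = np.stack([r1, r2, np.cross(r1, r2)], axis=1)
    U, _, Vt = np.linalg.svd(Q)
    R = U @ np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))]) @ Vt
    return RigidTransform(R, t, source="marker", target="C")


def _reproject(cam: CameraModel, T: RigidTransform, model_pts: np.ndarray) -> np.ndarray:
    return cam.project_points(T.apply(model_pts))


def _mean_residual(cam, T, model_pts, uv) -> float:
    return float(np.linalg.norm(_reproject(cam, T, model_pts) - uv, axis=1).mean())


def _refine_pose(cam: CameraModel, T0: RigidTransform, model_pts: np.ndarray,
                 uv: np.ndarray, max_iter: int = 50, step_tol: float = 1e-12):
    """Levenberg-Marquardt on the reprojection error over (rotvec, t)."""
    from scipy.optimize import least_squares

    x0 = np.concatenate([Rotation.from_matrix(T0.rotation).as_rotvec(), T0.translation])

    def residual(params):
        R = Rotation.from_rotvec(params[:3]).as_matrix()
        T = RigidTransform(R, params[3:], source=T0.source, target=T0.target)
        return (_reproject(cam, T, model_pts) - uv).ravel()

    sol = least_squares(residual, x0, method="lm", xtol=step_tol, ftol=1e-14,
                        gtol=1e-14, max_nfev=max_iter * 10)
    if sol.status == 0:
        raise ConvergenceError(
            f"pose refinement did not converge within {max_iter * 10} evaluations")
    return _pack(sol.x, T0)


def _pack(x: np.ndarray, T0: RigidTransform) -> RigidTransform:
    R = Rotation.from_rotvec(x[:3]).as_matrix()
    return RigidTransform(R, x[3:], source=T0.source, target=T0.target)


def estimate_pose(obs: GridObservation, grid: CircleGridModel,
                  cam: CameraModel) -> PoseEstimate:
    """Estimate the marker pose ``C <- marker`` from ordered grid centroids."""
    if obs.n < 4:
        raise DegenerateConfigurationError(f"pose needs >= 4 correspondences, got {obs.n}")
    model_all = grid.model_points()
    lut = {(i, j): k for k, (i, j) in enumerate(grid.indices())}
    rows = [lut[tuple(ij)] for ij in obs.indices]
    model_pts = model_all[rows]
    uv = obs.centroids
    _check_noncollinear(model_pts[:, :2], "model points")
    _check_noncollinear(uv, "observed centroids")
    norm = np.stack([(uv[:, 0] - cam.cx) / cam.fx, (uv[:, 1] - cam.cy) / cam.fy], axis=1)
    norm = cam.undistort(norm)
    H = _fit_homography(model_pts[:, :2], norm)
    T0 = _decompose_homography(H)
    res0 = _mean_residual(cam, T0, model_pts, uv)
    T1 = _refine_pose(cam, T0, model_pts, uv)
    res1 = _mean_residual(cam, T1, model_pts, uv)
    if res1 > res0:  # refinement must never worsen the fit
        T1, res1 = T0, res0
    return PoseEstimate(cTm=T1, residual_px=res1, grid=grid, timestamp=obs.timestamp)


# ----------------------------------------------------------------------
# search-region prediction


def _projected_box(pose: PoseEstimate, cam: CameraModel) -> np.ndarray:
    grid = pose.grid if pose.grid is not None else CircleGridModel()
    uv = cam.project_points(pose.cTm.apply(grid.model_points()))
    return np.array([uv[:, 0].min(), uv[:, 1].min(), uv[:, 0].max(), uv[:, 1].max()])


def predict_search_region(history: Sequence[PoseEstimate], cam: CameraModel,
                          margin: float = 20.0) -> tuple[int, int, int, int]:
    """Predict the pixel box to search for the marker in the next frame.

    Constant-velocity extrapolation of the projected grid bounding box from
    the last two pose estimates, dilated by ``margin`` pixels and clipped to
    the image; with no history the whole image is returned.
    """
    full = (0, 0, cam.width, cam.height)
    if not history:
        return full
    last = history[-1]
    box = _projected_box(last, cam)
    if len(history) >= 2:
        prev = history[-2]
        dt_hist = last.timestamp - prev.timestamp
        box_prev = _projected_box(prev, cam)
        # per-frame velocity; assume the next frame is one history interval ahead
        vel = (box - box_prev) / (dt_hist if dt_hist > 0 else 1.0)
        dt_next = dt_hist if dt_hist > 0 else 1.0
        box = box + vel * dt_next
    box = box + np.array([-margin, -margin, margin, margin])
    umin = int(np.clip(np.floor(box[0]), 0, cam.width))
    vmin = int(np.clip(np.floor(box[1]), 0, cam.height))
    umax = int(np.clip(np.ceil(box[2]), 0, cam.width))
    vmax = int(np.clip(np.ceil(box[3]), 0, cam.height))
    if umax <= umin or vmax <= vmin:
        return full
    return (umin, vmin, umax, vmax)
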