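"""Software autofocus: z-stack sharpness, focal surfaces, z trajectories.

Before the main scan, a z-stack of images is acquired at positions spread
over each well; the sharpest slice marks the focal plane at that (x, y).
Fitting a low-order polynomial surface through the per-position focus
heights yields a focal map z(x, y) that can be evaluated — interpolated
or extrapolated — anywhere in the well, so the z-positioner can track the
uneven well bottom in real time while the stage sweeps its scan lines.

Units: x, y in mm (stage coordinates); z in um (piezo travel).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .plate import Well

__all__ = [
    "ZStack",
    "FocusResult",
    "FocalMap",
    "IndeterminateFocusError",
    "DegenerateGeometryError",
    "focus_score",
    "best_focus",
    "fit_focal_surface",
    "z_trajectory",
    "well_grid_points",
    "synth_zstack",
]


class IndeterminateFocusError(ValueError):
    """Raised when every slice of a stack scores identically."""


class DegenerateGeometryError(ValueError):
    """Raised when control points cannot pin down the surface fit."""


@dataclass
class ZStack:
    """Images acquired at increasing z at one (x, y) stage location."""

    z_positions: np.ndarray  # um, strictly increasing
    images: list[np.ndarray]
    xy_location: tuple[float, float] = (0.0, 0.0)  # mm

    def __post_init__(self) -> None:
        z = np.asarray(self.z_positions, dtype=float)
        if len(z) != len(self.images):
            raise ValueError("z_positions and images must have equal counts")
        if len(z) >= 2 and not np.all(np.diff(z) > 0):
            raise ValueError("z_positions must be strictly increasing")
        self.z_positions = z


@dataclass(frozen=True)
class FocusResult:
    """Best-focus estimate for one stack.

    ``refined`` is False when the score peak sat at a stack endpoint and
    no sub-step parabolic refinement was possible.
    """

    z: float
    refined: bool
    index: int


@dataclass
class FocalMap:
    """A fitted polynomial focal surface z(x, y) over a well.

    degree <= 2; finite everywhere, so evaluation outside the control-
    point hull (extrapolation) is permitted by construction.
    """

    degree: int
    coefficients: np.ndarray
    control_points: np.ndarray  # (n, 3) of x mm, y mm, z um
    residual_rms: float

    def evaluate(self, x, y):
        """Surface height (um) at stage position(s) (x, y) in mm."""
        out = _design(np.asarray(x, float), np.asarray(y, float), self.degree) @ self.coefficients
        if np.ndim(x) == 0 and np.ndim(y) == 0:
            return float(out[0])
        return out

    __call__ = evaluate


def focus_score(image) -> float:
    """Sharpness of one image: variance of the gradient magnitude.

    Zero for constant images, invariant to additive intensity offsets,
    and monotonically decreasing under defocus blur — which is all the
    peak search needs.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 3:
        raise ValueError("focus_score needs a 2-D image of at least 3x3 pixels")
    gy, gx = np.gradient(img)
    return float(np.hypot(gx, gy).var())


def best_focus(stack: ZStack) -> FocusResult:
    """Locate the focal plane of a z-stack to sub-step accuracy.

    The score maximum marks the in-focus slice; an interior peak is
    refined by the vertex of a parabola through (z, log score) of the
    peak and its two neighbours (log flattens the sharply peaked score
    curve toward the quadratic the refinement assumes), clamped to the
    neighbour interval.  A peak at a stack endpoint is returned as-is
    and flagged unrefined.
    """
    n = len(stack.images)
    if n < 3:
        raise ValueError("best_focus needs at least 3 slices")
    scores = np.array([focus_score(im) for im in stack.images])
    if np.ptp(scores) <= 1e-12 * max(scores.max(), np.finfo(float).tiny):
        raise IndeterminateFocusError("all slices score identically; no focus found")
    i = int(np.argmax(scores))
    z = stack.z_positions
    if i == 0 or i == n - 1:
        return FocusResult(z=float(z[i]), refined=False, index=i)
    zs = z[i - 1 : i + 2]
    ss = scores[i - 1 : i + 2]
    ys = np.log(ss) if np.all(ss > 0) else ss
    a, b, _ = np.polyfit(zs, ys, 2)
    if a < 0:
        z_hat = float(np.clip(-b / (2.0 * a), zs[0], zs[2]))
    else:  # numerically flat triplet; keep the grid maximum
        z_hat = float(z[i])
    return FocusResult(z=z_hat, refined=True, index=i)


def _design(x: np.ndarray, y: np.ndarray, degree: int) -> np.ndarray:
    x, y = np.broadcast_arrays(np.atleast_1d(x), np.atleast_1d(y))
    cols = [np.ones_like(x, dtype=float), x, y]
    if degree >= 2:
        cols += [x * x, x * y, y * y]
    return np.stack(cols, axis=-1)


def fit_focal_surface(
    points: Sequence[tuple[float, float, float]], degree: int | None = None
) -> FocalMap:
    """Least-squares polynomial surface through (x, y, z) control points.

    Degree defaults to 2 when at least 6 points are supplied, else 1
    (a plane, needing >= 3 non-collinear points).  Reports the residual
    RMS (um) of the fit.

    Raises
    ------
    DegenerateGeometryError
        If the design matrix is rank-deficient (e.g. collinear points).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array of x, y, z")
    n = len(pts)
    if degree is None:
        degree = 2 if n >= 6 else 1
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    A = _design(pts[:, 0], pts[:, 1], degree)
    nterms = A.shape[1]
    if n < nterms:
        raise DegenerateGeometryError(
            f"{n} points cannot determine a degree-{degree} surface ({nterms} terms)"
        )
    if np.linalg.matrix_rank(A) < nterms:
        raise DegenerateGeometryError(
            "control points are degenerate (collinear or otherwise rank-deficient)"
        )
    coef, *_ = np.linalg.lstsq(A, pts[:, 2], rcond=None)
    resid = A @ coef - pts[:, 2]
    return FocalMap(
        degree=degree,
        coefficients=coef,
        control_points=pts,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def z_trajectory(path: Sequence[tuple[float, float]], fmap: FocalMap) -> np.ndarray:
    """Focus heights (um) along an (x, y) path, in path order."""
    p = np.asarray(path, dtype=float).reshape(-1, 2)
    if len(p) == 0:
        return np.zeros(0)
    return np.atleast_1d(fmap.evaluate(p[:, 0], p[:, 1]))


def well_grid_points(well: Well, k: int = 3) -> list[tuple[float, float]]:
    """A regular k x k sampling grid inside a well disk.

    Realizes "positions equally spread over the well": the grid spans the
    inscribed square so every point lies inside the disk.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    half = well.radius / np.sqrt(2.0)
    offs = np.linspace(-half, half, k) if k > 1 else np.array([0.0])
    return [(well.cx + ox, well.cy + oy) for oy in offs for ox in offs]


def synth_zstack(
    surface: Callable[[float, float], float] | float,
    xy: tuple[float, float],
    z_range: tuple[float, float],
    n_slices: int,
    noise: float = 0.0,
    seed: int = 0,
    size: int = 64,
    base_sigma: float = 0.5,
    blur_per_um: float = 0.5,
) -> tuple[ZStack, float]:
    """Generate a synthetic z-stack with known true focus height.

    A fixed random texture is blurred with a Gaussian whose width grows
    linearly with defocus ``|z - z_true|`` (``base_sigma`` px at perfect
    focus plus ``blur_per_um`` px per um of defocus) and i.i.d. Gaussian
    pixel noise of standard deviation ``noise`` is added per slice.
    ``surface`` is a callable z(x, y) (um, with x, y in mm) or a
    constant.  Returns the stack and the true focus height for recovery
    tests.  ``blur_per_um=0`` with ``noise=0`` reproduces the
    indeterminate-focus condition (identical slices).
    """
    if n_slices < 3:
        raise ValueError("n_slices must be >= 3")
    x, y = xy
    z_true = float(surface(x, y)) if callable(surface) else float(surface)
    z = np.linspace(z_range[0], z_range[1], n_slices)
    rng = np.random.default_rng(seed)
    texture = rng.normal(0.0, 1.0, (size, size))
    images = []
    for zi in z:
        sigma = base_sigma + blur_per_um * abs(zi - z_true)
        img = gaussian_filter(texture, sigma)
        if noise > 0:
            img = img + rng.normal(0.0, noise, (size, size))
        images.append(img)
    return ZStack(z_positions=z, images=images, xy_location=xy), z_true
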