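"""Weighted superposition and RMS primitives.

The path optimizer measures inter-replica distances as best-fit weighted RMS
values: each pair of conformations is optimally superposed (weighted Kabsch)
before the root-mean-square deviation is taken, so that rigid-body differences
do not contribute.  Per-point weights select the reaction region — points with
weight zero are carried along but do not influence the fit or the RMS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize


class GeometryError(ValueError):
    """Raised for incompatible frames or degenerate weighting."""


@dataclass
class Frame:
    """One conformation: labeled 3D points with per-point weights.

    Parameters
    ----------
    labels : list of str
        Per-point identifiers (unique within a frame).
    coords : (n, 3) float array
        Positions in Å.
    weights : (n,) float array, optional
        Non-negative per-point weights (default: all ones).  Used to select
        the region that contributes to superposition and RMS distances.
    """

    labels: list[str]
    coords: np.ndarray
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise GeometryError(f"coords must be (n, 3), got {self.coords.shape}")
        n = self.coords.shape[0]
        if n < 1:
            raise GeometryError("a frame needs at least one point")
        if not np.all(np.isfinite(self.coords)):
            raise GeometryError("coords must be finite")
        if len(self.labels) != n:
            raise GeometryError(f"{len(self.labels)} labels for {n} points")
        if self.weights is None:
            self.weights = np.ones(n)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (n,):
            raise GeometryError(f"weights must be ({n},), got {self.weights.shape}")
        if np.any(self.weights < 0):
            raise GeometryError("weights must be non-negative")

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise GeometryError(f"unknown point label {label!r}") from None

    def copy(self) -> "Frame":
        return Frame(list(self.labels), self.coords.copy(), self.weights.copy())

    def with_coords(self, coords: np.ndarray) -> "Frame":
        return Frame(list(self.labels), np.array(coords, dtype=float), self.weights.copy())


@dataclass
class SuperpositionResult:
    """Optimal rigid transform of a mobile frame onto a reference.

    ``rotation @ x + translation`` maps mobile coordinates onto the reference.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rms: float


def _check_compatible(a: Frame, b: Frame) -> None:
    if a.n_points != b.n_points:
        raise GeometryError(f"point counts differ: {a.n_points} vs {b.n_points}")
    if a.labels != b.labels:
        raise GeometryError("frames have different label orders")


def _effective_rank(coords: np.ndarray, w: np.ndarray) -> int:
    """Rank of the weighted point cloud about its weighted centroid."""
    mask = w > 0
    pts = coords[mask]
    ww = w[mask]
    c = np.average(pts, axis=0, weights=ww)
    centered = (pts - c) * np.sqrt(ww)[:, None]
    return int(np.linalg.matrix_rank(centered, tol=1e-10))


def superpose(mobile: Frame, reference: Frame, use_weights: bool = True) -> SuperpositionResult:
    """Weighted optimal rigid superposition (Kabsch) of ``mobile`` onto ``reference``.

    Returns the proper rotation and translation minimizing the weighted RMS of
    the mobile points onto the reference, together with that minimized RMS.

    Fewer than three effective (positively weighted) points, or a collinear
    weighted set, leave the rotation under-determined; a warning is issued and
    a translation-only fit (identity rotation, centroid match) is returned.
    """
    _check_compatible(mobile, reference)
    w = mobile.weights if use_weights else np.ones(mobile.n_points)
    wsum = w.sum()
    if wsum <= 0:
        raise GeometryError("all weights are zero; superposition undefined")

    ca = np.average(mobile.coords, axis=0, weights=w)
    cb = np.average(reference.coords, axis=0, weights=w)
    a = mobile.coords - ca
    b = reference.coords - cb

    n_eff = int(np.count_nonzero(w > 0))
    if n_eff < 3:
        warnings.warn(
            "fewer than 3 weighted points; returning translation-only fit",
            stacklevel=2,
        )
        rot = np.eye(3)
    else:
        if (_effective_rank(mobile.coords, w) < 2
                or _effective_rank(reference.coords, w) < 2):
            # collinear set: the minimized RMS is well-defined but the
            # rotation about the line is arbitrary
            warnings.warn("collinear weighted points; rotation is not unique",
                          stacklevel=2)
        # weighted covariance; SVD sign-corrected to a proper rotation
        h = (a * w[:, None]).T @ b
        u, _, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(vt.T @ u.T))
        rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T

    diff = a @ rot.T - b
    rms = float(np.sqrt((w * np.einsum("ij,ij->i", diff, diff)).sum() / wsum))
    translation = cb - rot @ ca
    return SuperpositionResult(rotation=rot, translation=translation, rms=rms)


def weighted_rms(a: Frame, b: Frame, fit: bool = True, use_weights: bool = True) -> float:
    """Weighted RMS deviation between two frames, in Å.

    With ``fit`` on this is the best-fit RMS (rigid-body differences removed);
    with ``fit`` off it is the plain weighted root-mean-square deviation
    sqrt(Σ w_j |a_j − b_j|² / Σ w_j).
    """
    _check_compatible(a, b)
    if fit:
        return superpose(a, b, use_weights=use_weights).rms
    w = a.weights if use_weights else np.ones(a.n_points)
    wsum = w.sum()
    if wsum <= 0:
        raise GeometryError("all weights are zero; RMS undefined")
    diff = a.coords - b.coords
    return float(np.sqrt((w * np.einsum("ij,ij->i", diff, diff)).sum() / wsum))


@dataclass
class MinimizeReport:
    converged: bool
    steps: int
    energy: float
    rms_gradient: float
    message: str = ""


def rms_gradient(g: np.ndarray) -> float:
    """Root-mean-square of a gradient vector (per degree of freedom)."""
    g = np.asarray(g, dtype=float)
    return float(np.sqrt(np.mean(g * g)))


def _steepest_descent(surface, x0, grad_tol, max_steps):
    x = np.array(x0, dtype=float)
    e = surface.energy(x)
    step = 0.1
    for it in range(max_steps):
        g = surface.gradient(x)
        if not np.all(np.isfinite(g)) or not np.isfinite(e):
            return x, MinimizeReport(False, it, e, np.nan, "non-finite energy/gradient")
        if rms_gradient(g) <= grad_tol:
            return x, MinimizeReport(True, it, e, rms_gradient(g))
        d = -g
        # Armijo backtracking keeps accepted iterates monotone
        accepted = False
        for _ in range(60):
            x_new = x + step * d
            e_new = surface.energy(x_new)
            if np.isfinite(e_new) and e_new <= e + 1e-4 * step * (g @ d):
                accepted = True
                break
            step *= 0.5
        if not accepted:
            g = surface.gradient(x)
            return x, MinimizeReport(
                rms_gradient(g) <= grad_tol, it, e, rms_gradient(g), "line search stalled"
            )
        x, e = x_new, e_new
        step = min(step * 2.0, 1.0)
    g = surface.gradient(x)
    return x, MinimizeReport(rms_gradient(g) <= grad_tol, max_steps, e, rms_gradient(g), "max_steps")


def _quasi_newton(surface, x0, grad_tol, max_steps):
    x0 = np.array(x0, dtype=float)
    g0 = np.asarray(surface.gradient(x0), dtype=float)
    if rms_gradient(g0) <= grad_tol:
        return x0, MinimizeReport(True, 0, float(surface.energy(x0)), rms_gradient(g0))

    n_iter = 0

    def fun(x):
        return float(surface.energy(x)), np.asarray(surface.gradient(x), dtype=float)

    def cb(xk):
        nonlocal n_iter
        n_iter += 1
        if rms_gradient(surface.gradient(xk)) <= grad_tol:
            raise StopIteration

    res = scipy.optimize.minimize(
        fun,
        x0,
        jac=True,
        method="L-BFGS-B",
        callback=cb,
        options={"maxiter": max_steps, "gtol": 0.0, "ftol": 0.0, "maxls": 100},
    )
    x = np.asarray(res.x, dtype=float)
    g = surface.gradient(x)
    rg = rms_gradient(g)
    if not np.all(np.isfinite(x)) or not np.isfinite(res.fun):
        return x0, MinimizeReport(False, n_iter, float(surface.energy(x0)), rms_gradient(g0), "diverged")
    return x, MinimizeReport(rg <= grad_tol, n_iter, float(surface.energy(x)), rg, str(res.message))


def minimize(surface, x0, method: str = "quasi_newton", grad_tol: float = 1e-4,
             max_steps: int = 10000):
    """Local minimization on a potential surface.

    Parameters
    ----------
    surface : PotentialSurface
        Provides ``energy(x)`` and ``gradient(x)`` on flat configuration vectors.
    x0 : array
        Starting configuration.
    method : {"quasi_newton", "steepest_descent"}
        Quasi-Newton (L-BFGS) with monotone line search, or plain steepest
        descent with Armijo backtracking.
    grad_tol : float
        Convergence threshold on the RMS gradient, energy units per Å.
    max_steps : int
        Iteration cap; exceeding it returns ``converged=False``.

    Returns
    -------
    (x, report) : minimizing configuration and a :class:`MinimizeReport`.
    """
    if grad_tol <= 0:
        raise ValueError("grad_tol must be positive")
    x0 = np.asarray(x0, dtype=float)
    if method == "steepest_descent":
        x, rep = _steepest_descent(surface, x0, grad_tol, max_steps)
    elif method == "quasi_newton":
        x, rep = _quasi_newton(surface, x0, grad_tol, max_steps)
    else:
        raise ValueError(f"unknown method {method!r}")
    # contract: never return a higher-energy point than the start
    if rep.energy > surface.energy(x0) + 1e-12:
        return x0, MinimizeReport(False, rep.steps, float(surface.energy(x0)),
                                  rms_gradient(surface.gradient(x0)), "no decrease found")
    return x, rep
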