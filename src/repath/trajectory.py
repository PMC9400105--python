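"""Trajectory dynamics analysis: alignment, RMSD, RMSF, PCA and DCCM.

The analyses operate on time-ordered point trajectories (one point per
"residue", e.g. a Cα trace).  Fluctuations Δr_i are displacements from the
time-average position after rigid-body alignment; from them come

* per-frame best-fit RMSD against a reference structure,
* per-point RMSF, sqrt(⟨|Δr_i|²⟩),
* essential-dynamics PCA — eigendecomposition of the 3n×3n covariance of
  positional fluctuations, with frame projections and cumulative variance —
* and the dynamic cross-correlation matrix (DCCM)
  C_ij = ⟨Δr_i·Δr_j⟩ / sqrt(⟨Δr_i·Δr_i⟩⟨Δr_j·Δr_j⟩), classified into
  anticorrelated / neutral / correlated bins at the conventional ±0.25
  thresholds (boundary values assigned to the outer bins).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import Frame, GeometryError, superpose


class TrajectoryError(ValueError):
    pass


@dataclass
class Trajectory:
    """Time-ordered congruent frames with named selection masks.

    ``coords`` is the (n_frames, n_points, 3) position array; ``selections``
    maps names (e.g. ``"core"``, ``"mobile"``) to boolean masks over points.
    """

    labels: list[str]
    coords: np.ndarray
    selections: dict[str, np.ndarray] = field(default_factory=dict)
    timestep: float | None = None
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TrajectoryError(f"coords must be (n_frames, n, 3), got {self.coords.shape}")
        if self.coords.shape[1] != len(self.labels):
            raise TrajectoryError("label count does not match point count")
        if not np.all(np.isfinite(self.coords)):
            raise TrajectoryError("coords must be finite")
        for name, mask in self.selections.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != (self.n_points,):
                raise TrajectoryError(f"selection {name!r} has wrong shape")
            self.selections[name] = mask
        if self.weights is None:
            self.weights = np.ones(self.n_points)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_points(self) -> int:
        return self.coords.shape[1]

    def mask(self, selection: str | None) -> np.ndarray:
        if selection is None:
            return np.ones(self.n_points, dtype=bool)
        if selection not in self.selections:
            raise TrajectoryError(
                f"unknown selection {selection!r}; have {sorted(self.selections)}")
        m = self.selections[selection]
        if not m.any():
            raise TrajectoryError(f"selection {selection!r} is empty")
        return m

    def frame(self, i: int) -> Frame:
        return Frame(list(self.labels), self.coords[i].copy(), self.weights.copy())

    def with_coords(self, coords: np.ndarray) -> "Trajectory":
        return Trajectory(list(self.labels), np.asarray(coords, dtype=float),
                          {k: v.copy() for k, v in self.selections.items()},
                          self.timestep,
                          None if self.weights is None else self.weights.copy())


def _fit_frames_onto(coords: np.ndarray, ref: np.ndarray, mask: np.ndarray,
                     labels: list[str]) -> np.ndarray:
    """Superpose every frame onto ``ref`` over the selected points."""
    sel_labels = [l for l, m in zip(labels, mask) if m]
    ref_frame = Frame(sel_labels, ref[mask])
    out = np.empty_like(coords)
    for t in range(coords.shape[0]):
        fit = superpose(Frame(sel_labels, coords[t][mask]), ref_frame)
        out[t] = coords[t] @ fit.rotation.T + fit.translation
    return out


def align_trajectory(traj: Trajectory, selection: str | None = None,
                     reference: str = "mean_iterative", max_iter: int = 50,
                     tol: float = 1e-6) -> Trajectory:
    """Remove rigid-body motion by superposing every frame onto a reference.

    ``reference="first"`` fits onto frame 0; ``"mean_iterative"`` fits onto
    the average structure, re-averaging and re-fitting until the mean moves
    by less than ``tol`` Å per point (the standard iterated-mean convention).
    """
    mask = traj.mask(selection)
    if reference == "first":
        return traj.with_coords(
            _fit_frames_onto(traj.coords, traj.coords[0], mask, traj.labels))
    if reference != "mean_iterative":
        raise TrajectoryError(f"unknown reference {reference!r}")
    coords = _fit_frames_onto(traj.coords, traj.coords[0], mask, traj.labels)
    for _ in range(max_iter):
        ref = coords.mean(axis=0)
        coords = _fit_frames_onto(coords, ref, mask, traj.labels)
        shift = float(np.sqrt(np.mean((coords.mean(axis=0) - ref) ** 2)))
        if shift < tol:
            break
    return traj.with_coords(coords)


def rmsd_series(traj: Trajectory, reference: Frame | None = None,
                selection: str | None = None, fit: bool = True) -> np.ndarray:
    """Best-fit RMSD of every frame against a reference, in frame order.

    Defaults to frame 0 as the reference.  With ``fit`` off, the plain RMSD
    without superposition is returned.
    """
    mask = traj.mask(selection)
    ref = reference if reference is not None else traj.frame(0)
    sel_labels = [l for l, m in zip(traj.labels, mask) if m]
    ref_sel = Frame(sel_labels, ref.coords[mask])
    out = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        f = Frame(sel_labels, traj.coords[t][mask])
        if fit:
            out[t] = superpose(f, ref_sel).rms
        else:
            diff = f.coords - ref_sel.coords
            out[t] = np.sqrt(np.mean(np.einsum("ij,ij->i", diff, diff)))
    return out


def rmsf(traj: Trajectory, selection: str | None = None) -> np.ndarray:
    """Per-point root-mean-square fluctuation about the time-average position.

    Expects an aligned trajectory (rigid-body motion already removed).
    """
    if traj.n_frames < 2:
        raise TrajectoryError("RMSF needs at least 2 frames")
    mask = traj.mask(selection)
    x = traj.coords[:, mask, :]
    d = x - x.mean(axis=0)
    return np.sqrt(np.einsum("tij,tij->i", d, d) / traj.n_frames)


@dataclass
class PcaResult:
    """Essential-dynamics decomposition of positional fluctuations."""

    eigenvalues: np.ndarray        # all 3n, descending, Å²
    eigenvectors: np.ndarray       # (3n, n_modes) retained columns
    projections: np.ndarray        # (n_frames, n_modes)
    cumulative_variance: np.ndarray  # over all modes, ends at 1
    mean: np.ndarray               # (n_sel, 3) average structure


def pca(traj: Trajectory, selection: str | None = None, n_modes: int = 2) -> PcaResult:
    """PCA of the 3n×3n covariance of positional fluctuations.

    The leading eigenvectors are the dominant collective motions; projections
    give each frame's coordinate along the retained modes; cumulative variance
    fractions quantify how much motion the leading modes capture.
    """
    if traj.n_frames <= 3:
        raise TrajectoryError("PCA needs more than 3 frames")
    mask = traj.mask(selection)
    x = traj.coords[:, mask, :].reshape(traj.n_frames, -1)
    mean = x.mean(axis=0)
    d = x - mean
    n_dof = x.shape[1]
    if n_modes > min(traj.n_frames - 1, n_dof):
        warnings.warn(
            f"n_modes={n_modes} exceeds the covariance rank bound; truncating",
            stacklevel=2)
        n_modes = min(traj.n_frames - 1, n_dof)
    cov = (d.T @ d) / traj.n_frames
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    total = evals.sum()
    cum = np.cumsum(evals) / total if total > 0 else np.zeros_like(evals)
    proj = d @ evecs[:, :n_modes]
    return PcaResult(eigenvalues=evals, eigenvectors=evecs[:, :n_modes],
                     projections=proj, cumulative_variance=cum,
                     mean=mean.reshape(-1, 3))


@dataclass
class DccmResult:
    """Normalized cross-correlation matrix with bin classification."""

    matrix: np.ndarray
    labels: list[str]
    bins: np.ndarray               # -1 anticorrelated / 0 neutral / +1 correlated
    top_anticorrelated: pd.DataFrame


def dccm(traj: Trajectory, selection: str | None = None, low: float = -0.25,
         high: float = 0.25, n_top: int = 20) -> DccmResult:
    """Dynamic cross-correlation matrix of the selected points.

    C_ij = ⟨Δr_i·Δr_j⟩ / sqrt(⟨Δr_i·Δr_i⟩⟨Δr_j·Δr_j⟩), Δr taken from the
    time-average position.  Zero-variance points get NaN rows/columns with a
    warning.  ``top_anticorrelated`` ranks pairs ascending by C_ij.
    """
    if traj.n_frames < 2:
        raise TrajectoryError("DCCM needs at least 2 frames")
    mask = traj.mask(selection)
    labels = [l for l, m in zip(traj.labels, mask) if m]
    x = traj.coords[:, mask, :]
    d = x - x.mean(axis=0)
    # ⟨Δr_i · Δr_j⟩ over time
    cov = np.einsum("tik,tjk->ij", d, d) / traj.n_frames
    var = np.diag(cov).copy()
    dead = var <= 0
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} zero-variance point(s); correlations undefined",
            stacklevel=2)
        var[dead] = np.nan
    denom = np.sqrt(np.outer(var, var))
    with np.errstate(invalid="ignore"):
        mat = cov / denom
    np.clip(mat, -1.0, 1.0, out=mat)
    mat[np.diag_indices_from(mat)] = np.where(dead, np.nan, 1.0)
    bins = classify_matrix(mat, low=low, high=high)
    iu = np.triu_indices(mat.shape[0], k=1)
    vals = mat[iu]
    ok = np.isfinite(vals)
    order = np.argsort(vals[ok])[:n_top]
    ii, jj = iu[0][ok][order], iu[1][ok][order]
    top = pd.DataFrame({
        "label_i": [labels[i] for i in ii],
        "label_j": [labels[j] for j in jj],
        "c_ij": vals[ok][order],
    })
    return DccmResult(matrix=mat, labels=labels, bins=bins, top_anticorrelated=top)


def classify_matrix(matrix: np.ndarray, low: float = -0.25, high: float = 0.25
                    ) -> np.ndarray:
    """Three-way classification of correlation values.

    −1 for C ≤ low (anticorrelated), +1 for C ≥ high (correlated), 0 between;
    boundary values go to the outer bins.  NaN entries stay 0.
    """
    if low >= high:
        raise TrajectoryError("low threshold must be below high threshold")
    out = np.zeros(matrix.shape, dtype=int)
    with np.errstate(invalid="ignore"):
        out[matrix <= low] = -1
        out[matrix >= high] = 1
    return out


def classify_correlations(result: DccmResult, low: float = -0.25,
                          high: float = 0.25, n_top: int = 20
                          ) -> tuple[np.ndarray, pd.DataFrame]:
    """Re-bin a DCCM at the given thresholds and export the strongest
    anticorrelated pairs as an edge list (for 3D rendering)."""
    bins = classify_matrix(result.matrix, low=low, high=high)
    iu = np.triu_indices(result.matrix.shape[0], k=1)
    vals = result.matrix[iu]
    ok = np.isfinite(vals) & (vals <= low)
    order = np.argsort(vals[ok])[:n_top]
    edges = pd.DataFrame({
        "label_i": [result.labels[i] for i in iu[0][ok][order]],
        "label_j": [result.labels[j] for j in iu[1][ok][order]],
        "c_ij": vals[ok][order],
    })
    return bins, edges
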