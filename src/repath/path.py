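"""Chain-of-states minimum-energy-pathway optimization.

A reaction path is represented as an ordered chain of replicas (conformations)
connecting a reactant to a product.  The chain is relaxed by minimizing the
sum of per-replica configurational energies plus two penalty terms that keep
the discretization well behaved:

* an RMS-spacing penalty, K_rms · Σ (rms(i, i+1) − ⟨rms⟩)², restraining every
  adjacent-replica best-fit RMS distance toward the chain mean so the path
  stays regularly spaced, and
* an angle penalty that computes the cosine at each interior replica by the
  law of cosines from the triangle of RMS distances and adds
  K_angle · (COSMAX − cos θ)² whenever cos θ falls below COSMAX, preventing
  the path from doubling back on itself.

Defaults follow the protocol used for the ATP-hydrolysis pathways:
16 replicas seeded by linear interpolation, K_rms = 2000 energy/Å²,
K_angle = 100 energy units, COSMAX = 0.95, optimization for up to 10,000
steps or until the convergence rule (RMS gradient < 0.01 and total-energy
change < 1.0 for 30 consecutive steps) is met, with frozen endpoints and
optional refinement that re-interpolates a new chain bracketing the barrier.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import Frame, GeometryError, weighted_rms
from .surfaces import PotentialSurface


class PathError(ValueError):
    pass


@dataclass
class ReplicaPath:
    """Ordered chain of replicas with penalty parameters."""

    replicas: list[Frame]
    k_rms: float = 2000.0
    k_angle: float = 100.0
    cosmax: float = 0.95
    endpoints_fixed: bool = True
    fit: bool = True  # best-fit RMS; turn off for internal-coordinate toys

    def __post_init__(self) -> None:
        if len(self.replicas) < 3:
            raise PathError("a replica path needs at least 3 replicas")
        first = self.replicas[0]
        for i, r in enumerate(self.replicas):
            if r.n_points != first.n_points or r.labels != first.labels:
                raise PathError(f"replica {i} is not congruent with replica 0")
            if not np.array_equal(r.weights, first.weights):
                raise PathError(f"replica {i} has different weights")
        if self.k_rms < 0 or self.k_angle < 0:
            raise PathError("force constants must be non-negative")
        if not (-1.0 < self.cosmax <= 1.0):
            raise PathError("cosmax must lie in (-1, 1]")

    @property
    def n_replicas(self) -> int:
        return len(self.replicas)

    def segment_rms(self) -> np.ndarray:
        """Best-fit (or plain, if ``fit`` off) RMS of each adjacent pair."""
        return np.array([
            weighted_rms(self.replicas[i], self.replicas[i + 1], fit=self.fit)
            for i in range(self.n_replicas - 1)
        ])

    def copy(self) -> "ReplicaPath":
        return replace(self, replicas=[r.copy() for r in self.replicas])


@dataclass
class PathReport:
    steps_taken: int
    objective_history: list[float] = field(default_factory=list)
    rms_gradient_history: list[float] = field(default_factory=list)
    converged: bool = False
    convergence_reason: str = ""


@dataclass
class EnergyProfile:
    per_replica_energy: np.ndarray
    activation_energy: float
    ts_index: int


def interpolate_endpoints(reactant: Frame, product: Frame, n_replicas: int = 16,
                          **path_params) -> ReplicaPath:
    """Seed a chain by linear interpolation of Cartesian coordinates.

    Replica k (1-based) = reactant + (k−1)/(n_replicas−1) · (product − reactant);
    the first and last replicas are exact copies of the inputs.
    """
    if n_replicas < 3:
        raise PathError("n_replicas must be at least 3")
    if reactant.n_points != product.n_points or reactant.labels != product.labels:
        raise PathError("reactant and product frames are not congruent")
    frames = [reactant.copy()]
    delta = product.coords - reactant.coords
    for k in range(1, n_replicas - 1):
        t = k / (n_replicas - 1)
        frames.append(reactant.with_coords(reactant.coords + t * delta))
    frames.append(product.copy())
    return ReplicaPath(frames, **path_params)


def mean_rms(path: ReplicaPath) -> float:
    """Arithmetic mean of the adjacent-replica RMS distances, ⟨rms⟩."""
    return float(path.segment_rms().mean())


def _spacing_from_segments(seg: np.ndarray, k_rms: float) -> float:
    return float(k_rms * np.sum((seg - seg.mean()) ** 2))


def _cosines_from_distances(seg: np.ndarray, skip: np.ndarray) -> np.ndarray:
    """cos θ at interior replicas via the law of cosines.

    ``seg`` holds rms(i, i+1); ``skip`` holds rms(i−1, i+1).  The path angle
    is the supplement of the triangle angle at the vertex, so a straight
    chain (skip = a + b) gives cos θ = 1 and doubling back gives −1.
    """
    a, b = seg[:-1], seg[1:]
    cos = (skip * skip - a * a - b * b) / (2.0 * a * b)
    return np.clip(cos, -1.0, 1.0)


def _angle_from_distances(seg: np.ndarray, skip: np.ndarray, k_angle: float,
                          cosmax: float) -> float:
    cos = _cosines_from_distances(seg, skip)
    short = np.maximum(cosmax - cos, 0.0)
    return float(k_angle * np.sum(short * short))


def rms_spacing_penalty(path: ReplicaPath) -> float:
    """K_rms · Σ_i (rms(i, i+1) − ⟨rms⟩)²; zero iff all segments are equal."""
    return _spacing_from_segments(path.segment_rms(), path.k_rms)


def _skip_rms(path: ReplicaPath) -> np.ndarray:
    return np.array([
        weighted_rms(path.replicas[i - 1], path.replicas[i + 1], fit=path.fit)
        for i in range(1, path.n_replicas - 1)
    ])


def _vertex_cosines(path: ReplicaPath) -> np.ndarray:
    """cos θ at each interior replica, by the law of cosines on RMS distances."""
    seg = path.segment_rms()
    if np.any(seg <= 0):
        i = int(np.argmax(seg <= 0))
        raise PathError(f"zero-length segment at replica {i}; angle undefined")
    return _cosines_from_distances(seg, _skip_rms(path))


def angle_penalty(path: ReplicaPath) -> float:
    """Σ over interior replicas of K_angle · (COSMAX − cos θ)² for cos θ < COSMAX.

    A fully degenerate chain (every replica identical) has no geometry to bend
    and contributes zero; a partially collapsed chain is a geometry error
    naming the offending replica.
    """
    seg = path.segment_rms()
    if np.all(seg == 0):
        return 0.0
    cos = _vertex_cosines(path)
    short = np.maximum(path.cosmax - cos, 0.0)
    return float(path.k_angle * np.sum(short * short))


# ---------------------------------------------------------------------------
# objective over flattened configuration vectors
# ---------------------------------------------------------------------------

def _frame_dim(path: ReplicaPath, surface: PotentialSurface) -> int:
    """Per-replica configuration length; adapts 2D surfaces to 1-point frames."""
    n3 = 3 * path.replicas[0].n_points
    if surface.dimension == n3:
        return n3
    if surface.dimension == 2 and path.replicas[0].n_points == 1:
        return 2
    raise PathError(
        f"surface dimension {surface.dimension} incompatible with "
        f"{path.replicas[0].n_points}-point replicas"
    )


def _frame_to_config(frame: Frame, d: int) -> np.ndarray:
    return frame.coords[0, :2].copy() if d == 2 else frame.coords.ravel().copy()


def _config_to_coords(cfg: np.ndarray, template: Frame, d: int) -> np.ndarray:
    if d == 2:
        c = template.coords.copy()
        c[0, :2] = cfg
        return c
    return cfg.reshape(-1, 3)


def _path_with_configs(path: ReplicaPath, configs: np.ndarray, d: int) -> ReplicaPath:
    frames = [
        r.with_coords(_config_to_coords(configs[i], r, d))
        for i, r in enumerate(path.replicas)
    ]
    return replace(path, replicas=frames)


def path_objective(path: ReplicaPath, surface: PotentialSurface
                   ) -> tuple[float, dict[str, float]]:
    """Total chain objective and its parts.

    total = Σ_i E(replica_i) + rms_spacing_penalty + angle_penalty
    """
    d = _frame_dim(path, surface)
    energies = [surface.energy(_frame_to_config(r, d)) for r in path.replicas]
    e_sum = float(np.sum(energies))
    rp = rms_spacing_penalty(path)
    ap = angle_penalty(path)
    parts = {"sum_replica_energy": e_sum, "rms_penalty": rp, "angle_penalty": ap}
    return e_sum + rp + ap, parts


def _penalty_of_configs(path: ReplicaPath, configs: np.ndarray, d: int,
                        smooth_eps: float = 1e-5) -> float:
    """Spacing + angle penalty straight from the configuration matrix.

    With fit off the RMS distances reduce to weighted Euclidean distances of
    the flat configuration vectors, which vectorizes; with fit on the general
    frame-based superposition route is used.

    Distances are smoothed as sqrt(d² + ε²) with ε = ``smooth_eps`` Å.  This
    is invisible at normal segment lengths (relative effect ε²/2d²) but keeps
    the objective differentiable if a segment collapses during optimization —
    where the raw law-of-cosines term is singular — so a collapsed segment
    shows up as a large, smooth angle-penalty force pushing replicas apart
    rather than as a line-search failure.
    """
    if path.fit:
        p = _path_with_configs(path, configs, d)
        seg = p.segment_rms()
        skip = _skip_rms(p)
    else:
        w = path.replicas[0].weights
        if d == 2:  # single weighted point: rms is the plain 2D distance
            wv, wsum = np.ones(2), 1.0
        else:
            wv, wsum = np.repeat(w, 3), w.sum()

        def dist(x, y):
            diff = x - y
            return np.sqrt((diff * diff * wv).sum(axis=1) / wsum)

        seg = dist(configs[1:], configs[:-1])
        skip = dist(configs[2:], configs[:-2])
    seg = np.sqrt(seg * seg + smooth_eps * smooth_eps)
    return (_spacing_from_segments(seg, path.k_rms)
            + _angle_from_distances(seg, skip, path.k_angle, path.cosmax))


def _objective_and_gradient(path: ReplicaPath, surface: PotentialSurface,
                            configs: np.ndarray, free: np.ndarray, d: int,
                            fd_h: float = 1e-6) -> tuple[float, np.ndarray]:
    """Objective and gradient w.r.t. the free replicas' configurations.

    Surface gradients are analytic; the penalty gradient is taken by central
    differences (the penalties are cheap, surface-free functions of the
    chain geometry).
    """
    n = configs.shape[0]
    energies = np.array([surface.energy(configs[i]) for i in range(n)])
    pen = _penalty_of_configs(path, configs, d)
    total = float(energies.sum() + pen)

    grad = np.zeros((free.sum(), d))
    row = 0
    for i in range(n):
        if not free[i]:
            continue
        grad[row] = surface.gradient(configs[i])
        for j in range(d):
            cp = configs.copy()
            cm = configs.copy()
            cp[i, j] += fd_h
            cm[i, j] -= fd_h
            grad[row, j] += (_penalty_of_configs(path, cp, d)
                             - _penalty_of_configs(path, cm, d)) / (2.0 * fd_h)
        row += 1
    return total, grad.ravel()


def optimize_path(path: ReplicaPath, surface: PotentialSurface,
                  max_steps: int = 10000, grad_tol: float = 0.01,
                  energy_tol: float = 1.0, patience: int = 30
                  ) -> tuple[ReplicaPath, PathReport]:
    """Relax the chain by combined minimization of energies plus penalties.

    All replica coordinates are optimized simultaneously as one flattened
    variable vector under a quasi-Newton (L-BFGS) minimizer with monotone
    line search.  Endpoints are frozen when ``path.endpoints_fixed``.

    Convergence requires the total-pathway RMS gradient to stay below
    ``grad_tol`` *and* the per-step change in total pathway objective to stay
    below ``energy_tol`` for ``patience`` consecutive accepted steps;
    otherwise the run stops at ``max_steps``.
    """
    import scipy.optimize

    d = _frame_dim(path, surface)
    n = path.n_replicas
    free = np.ones(n, dtype=bool)
    if path.endpoints_fixed:
        free[0] = free[-1] = False
    configs0 = np.array([_frame_to_config(r, d) for r in path.replicas])

    def unpack(x: np.ndarray) -> np.ndarray:
        cfg = configs0.copy()
        cfg[free] = x.reshape(free.sum(), d)
        return cfg

    report = PathReport(steps_taken=0)
    streak = 0
    state = {"last_obj": None}

    def fun(x):
        cfg = unpack(x)
        total, grad = _objective_and_gradient(path, surface, cfg, free, d)
        if np.isnan(total) or np.any(np.isnan(grad)):
            raise FloatingPointError("non-finite path objective")
        if np.isinf(total) or np.any(np.isinf(grad)):
            # overflowing line-search probe: hand the minimizer a huge finite
            # value so it backtracks instead of aborting
            total = 1e300
            grad = np.nan_to_num(grad, posinf=1e150, neginf=-1e150)
        state["cache"] = (x.copy(), total, grad)
        return total, grad

    def callback(xk):
        nonlocal streak
        xc, total, grad = state["cache"]
        if not np.array_equal(xc, xk):
            cfg = unpack(xk)
            total, grad = _objective_and_gradient(path, surface, cfg, free, d)
        rg = float(np.sqrt(np.mean(grad * grad)))
        report.objective_history.append(total)
        report.rms_gradient_history.append(rg)
        report.steps_taken += 1
        de = (abs(total - state["last_obj"])
              if state["last_obj"] is not None else np.inf)
        state["last_obj"] = total
        if rg < grad_tol and de < energy_tol:
            streak += 1
        else:
            streak = 0
        if streak >= patience:
            report.converged = True
            report.convergence_reason = (
                f"RMS gradient < {grad_tol} and |ΔE| < {energy_tol} "
                f"for {patience} consecutive steps"
            )
            raise StopIteration

    x0 = configs0[free].ravel()
    obj0, grad0 = _objective_and_gradient(path, surface, configs0, free, d)
    state["last_obj"] = obj0
    if x0.size == 0:
        report.converged = True
        report.convergence_reason = "no free replicas"
        return path.copy(), report

    # L-BFGS can halt on internal stagnation before the patience rule has had
    # its `patience` consecutive steps; restart with a fresh Hessian so the
    # step count keeps accumulating until the stated rule (or max_steps) fires.
    x_best = x0
    last_msg = ""
    try:
        while not report.converged and report.steps_taken < max_steps:
            res = scipy.optimize.minimize(
                fun, x_best, jac=True, method="L-BFGS-B", callback=callback,
                options={"maxiter": max_steps - report.steps_taken,
                         "gtol": 0.0, "ftol": 0.0, "maxls": 100},
            )
            moved = not np.array_equal(res.x, x_best)
            x_best = np.asarray(res.x, dtype=float)
            last_msg = str(res.message)
            if not moved:
                break  # true fixed point of the minimizer
    except FloatingPointError as exc:
        raise PathError(f"path optimization diverged: {exc}") from exc
    if not report.converged:
        if report.steps_taken >= max_steps:
            report.convergence_reason = f"stopped at max_steps = {max_steps}"
        else:
            report.convergence_reason = f"minimizer stalled: {last_msg}"

    out = _path_with_configs(path, unpack(x_best), d)
    if path.endpoints_fixed:
        # endpoints bitwise-preserved
        out.replicas[0] = path.replicas[0].copy()
        out.replicas[-1] = path.replicas[-1].copy()
    return out, report


def energy_profile(path: ReplicaPath, surface: PotentialSurface) -> EnergyProfile:
    """Per-replica energies, activation energy (max − first) and TS index.

    Ties in the maximum resolve to the lowest replica index.
    """
    d = _frame_dim(path, surface)
    e = np.array([surface.energy(_frame_to_config(r, d)) for r in path.replicas])
    ts = int(np.argmax(e))
    return EnergyProfile(per_replica_energy=e,
                         activation_energy=float(e[ts] - e[0]),
                         ts_index=ts)


def refine_endpoints(path: ReplicaPath, surface: PotentialSurface, window: int = 2,
                     n_replicas: int = 16) -> ReplicaPath:
    """Re-interpolate a fresh chain bracketing the current barrier.

    Takes the replicas ``window`` places before and after the highest-energy
    replica (clamped to the chain) as new endpoints and re-seeds a linear
    interpolation with the same penalty parameters.  Refuses when the barrier
    sits on an endpoint (nothing to bracket).
    """
    prof = energy_profile(path, surface)
    if prof.ts_index in (0, path.n_replicas - 1):
        raise PathError(
            f"transition-state replica is an endpoint (index {prof.ts_index}); "
            "cannot bracket for refinement"
        )
    lo = max(prof.ts_index - window, 0)
    hi = min(prof.ts_index + window, path.n_replicas - 1)
    return interpolate_endpoints(
        path.replicas[lo], path.replicas[hi], n_replicas=n_replicas,
        k_rms=path.k_rms, k_angle=path.k_angle, cosmax=path.cosmax,
        endpoints_fixed=path.endpoints_fixed, fit=path.fit,
    )


def monitor_distances(path: ReplicaPath, pairs: dict[str, tuple[str, str]]
                      ) -> pd.DataFrame:
    """Euclidean distances of named label pairs across the chain.

    Returns one row per replica (column ``replica``) and one column per named
    pair, e.g. R1 = (Pg, Os), R2 = (Pg, Ow), in replica order.
    """
    ref = path.replicas[0]
    idx = {}
    for name, (la, lb) in pairs.items():
        idx[name] = (ref.index(la), ref.index(lb))  # raises GeometryError on unknown
    rows = []
    for k, r in enumerate(path.replicas):
        row = {"replica": k + 1}
        for name, (ia, ib) in idx.items():
            row[name] = float(np.linalg.norm(r.coords[ia] - r.coords[ib]))
        rows.append(row)
    return pd.DataFrame(rows)


def first_crossing(monitor: pd.DataFrame, column: str, threshold: float,
                   above: bool = True) -> int | None:
    """First replica (1-based) where a monitored distance crosses a threshold.

    ``above=True`` finds the first replica with value > threshold (e.g. a
    breaking bond passing its rupture length); ``above=False`` the first with
    value < threshold (a forming bond entering bonding range).  None if the
    column never crosses.
    """
    vals = monitor[column].to_numpy()
    hits = np.nonzero(vals > threshold if above else vals < threshold)[0]
    return int(monitor["replica"].iloc[hits[0]]) if hits.size else None
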