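"""Independent oracles used by the test suite.

Each oracle deliberately takes a different computational route from the
implementation it checks: rotation-grid search instead of Kabsch SVD, a
naive double-loop Pearson instead of vectorized covariance, scipy root-finding
on finite-difference gradients instead of the package's Newton census.
"""

from __future__ import annotations

import numpy as np
import scipy.optimize
from scipy.spatial.transform import Rotation


def brute_force_superpose_rms(mobile: np.ndarray, reference: np.ndarray,
                              weights: np.ndarray | None = None,
                              n_grid: int = 31) -> float:
    """Minimum weighted RMS over a dense Euler-angle grid + local refinement."""
    w = np.ones(len(mobile)) if weights is None else np.asarray(weights, float)
    ca = np.average(mobile, axis=0, weights=w)
    cb = np.average(reference, axis=0, weights=w)
    a, b = mobile - ca, reference - cb

    def rms(angles):
        r = Rotation.from_euler("zyx", angles).as_matrix()
        d = a @ r.T - b
        return float(np.sqrt((w * np.einsum("ij,ij->i", d, d)).sum() / w.sum()))

    grid = np.linspace(-np.pi, np.pi, n_grid)
    best_val, best_ang = np.inf, None
    for z in grid:
        for y in grid:
            for x in grid:
                v = rms([z, y, x])
                if v < best_val:
                    best_val, best_ang = v, [z, y, x]
    res = scipy.optimize.minimize(rms, best_ang, method="Nelder-Mead",
                                  options={"xatol": 1e-12, "fatol": 1e-15,
                                           "maxiter": 50000})
    return float(res.fun)


def naive_dccm(coords: np.ndarray) -> np.ndarray:
    """Double-loop Pearson correlation of displacement vectors.

    coords: (n_frames, n_points, 3).  C_ij = <d_i·d_j>/sqrt(<d_i·d_i><d_j·d_j>)
    with displacements taken from the time-average position.
    """
    d = coords - coords.mean(axis=0)
    n = coords.shape[1]
    c = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            num = (d[:, i, :] * d[:, j, :]).sum(axis=1).mean()
            di = (d[:, i, :] * d[:, i, :]).sum(axis=1).mean()
            dj = (d[:, j, :] * d[:, j, :]).sum(axis=1).mean()
            c[i, j] = num / np.sqrt(di * dj)
    return c


def fd_gradient(energy, x: np.ndarray, h: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of a scalar function."""
    x = np.asarray(x, dtype=float)
    g = np.empty_like(x)
    for i in range(x.size):
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        g[i] = (energy(xp) - energy(xm)) / (2 * h)
    return g


def grid_stationary_points(energy, bounds, n_grid: int = 24,
                           h: float = 1e-6) -> list[dict]:
    """Stationary points of a 2D scalar field: grid of starts + root refinement.

    Uses only the energy callable (gradients by finite differences) and
    scipy.optimize.root from every lattice start — an independent route from
    any in-package census.  Returns entries with x, energy and n_negative
    (Hessian negative-eigenvalue count: 0 = minimum, 1 = saddle).
    """
    xs = np.linspace(bounds[0][0], bounds[0][1], n_grid)
    ys = np.linspace(bounds[1][0], bounds[1][1], n_grid)

    def grad(p):
        return fd_gradient(energy, p, h=h)

    found = []
    for x in xs:
        for y in ys:
            sol = scipy.optimize.root(grad, np.array([x, y]),
                                      method="hybr", tol=1e-12)
            if not sol.success or np.linalg.norm(grad(sol.x)) > 1e-6:
                continue
            p = sol.x
            if not (bounds[0][0] <= p[0] <= bounds[0][1]
                    and bounds[1][0] <= p[1] <= bounds[1][1]):
                continue
            if any(np.linalg.norm(p - f["x"]) < 1e-4 for f in found):
                continue
            hess = np.empty((2, 2))
            for k in range(2):
                pp, pm = p.copy(), p.copy()
                pp[k] += 1e-4
                pm[k] -= 1e-4
                hess[:, k] = (grad(pp) - grad(pm)) / 2e-4
            hess = 0.5 * (hess + hess.T)
            ev = np.linalg.eigvalsh(hess)
            if np.any(np.abs(ev) < 1e-8):
                continue
            found.append({"x": p, "energy": float(energy(p)),
                          "n_negative": int(np.sum(ev < 0))})
    found.sort(key=lambda f: f["energy"])
    return found


def mb_reference_points():
    """Frozen stationary points of the Müller–Brown surface.

    Values computed with grid_stationary_points (n_grid=160, bounds
    x ∈ [−1.7, 1.3], y ∈ [−0.5, 2.2]) and cross-checked against the package
    census; frozen here to keep the expensive grid out of every test.
    """
    minima = [
        {"x": np.array([-0.558223634633024, 1.441725841804669]),
         "energy": -146.699517209954},
        {"x": np.array([0.623499404930877, 0.028037758528686]),
         "energy": -108.166724116852},
        {"x": np.array([-0.050010822998206, 0.466694104871972]),
         "energy": -80.767818129659},
    ]
    saddles = [
        {"x": np.array([0.212486582000662, 0.292988325107368]),
         "energy": -72.248940112325},
        {"x": np.array([-0.822001558732732, 0.624312802814871]),
         "energy": -40.664843508657},
    ]
    return minima, saddles
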