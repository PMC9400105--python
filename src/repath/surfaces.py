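"""Pluggable analytic potential-energy surfaces.

These closed-form surfaces stand in for expensive quantum-chemical energies so
that the path-finding and driving algorithms can be exercised and validated at
desk scale: the Müller–Brown benchmark, harmonic wells, and a two-coordinate
"bond-swap" surface emulating a dissociative ligand-exchange reaction
(one bond must break before another forms).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .geometry import Frame


class SurfaceError(ValueError):
    """Raised for invalid surface parameters or evaluation failures."""


@dataclass
class PotentialSurface:
    """Contract for an energy surface: energy and gradient on flat vectors.

    ``dimension`` is the number of degrees of freedom; ``energy`` maps a flat
    configuration vector to a scalar and ``gradient`` to a same-length vector.
    ``probe_bounds`` (low, high) bracket a sensible region for random probes.
    """

    name: str
    dimension: int
    energy: Callable[[np.ndarray], float]
    gradient: Callable[[np.ndarray], np.ndarray]
    probe_bounds: tuple[float, float] = (-2.0, 2.0)


def harmonic(k: float = 1.0, center: Sequence[float] = (0.0,)) -> PotentialSurface:
    """Isotropic harmonic well k·|x − center|² (exact quadratic reference)."""
    c = np.asarray(center, dtype=float)

    def energy(x):
        d = np.asarray(x, dtype=float) - c
        return float(k * (d @ d))

    def gradient(x):
        return 2.0 * k * (np.asarray(x, dtype=float) - c)

    return PotentialSurface("harmonic", c.size, energy, gradient)


# Standard four-Gaussian Müller–Brown constants.
_MB_A = np.array([-200.0, -100.0, -170.0, 15.0])
_MB_a = np.array([-1.0, -1.0, -6.5, 0.7])
_MB_b = np.array([0.0, 0.0, 11.0, 0.6])
_MB_c = np.array([-10.0, -10.0, -6.5, 0.7])
_MB_x0 = np.array([1.0, 0.0, -0.5, -1.0])
_MB_y0 = np.array([0.0, 0.5, 1.5, 1.0])


def muller_brown() -> PotentialSurface:
    """The Müller–Brown two-dimensional benchmark surface.

    Three minima and two first-order saddles; the classic test bed for
    minimum-energy-pathway algorithms.
    """

    # exponents capped at 200 (energies ~1e88) purely as an overflow guard for
    # line searches probing far outside the benchmark region; the surface is
    # unmodified anywhere below that astronomically high energy
    def _terms(p):
        x, y = np.asarray(p, dtype=float)
        dx, dy = x - _MB_x0, y - _MB_y0
        expo = np.minimum(_MB_a * dx * dx + _MB_b * dx * dy + _MB_c * dy * dy, 200.0)
        return dx, dy, _MB_A * np.exp(expo)

    def energy(p):
        _, _, e = _terms(p)
        return float(np.sum(e))

    def gradient(p):
        dx, dy, e = _terms(p)
        gx = np.sum(e * (2.0 * _MB_a * dx + _MB_b * dy))
        gy = np.sum(e * (_MB_b * dx + 2.0 * _MB_c * dy))
        return np.array([gx, gy])

    return PotentialSurface("muller_brown", 2, energy, gradient, probe_bounds=(-1.5, 1.5))


@dataclass
class BondSwapParams:
    """Parameters of the two-coordinate bond-swap surface.

    R1 is the breaking-bond length and R2 the forming-bond length (Å).  Each
    bond is a Morse well (depth D, width a, equilibrium r_eq); ``coupling``
    sets the strength of a repulsive term that penalizes both bonds being
    formed at once, which carves the single Morse-sum minimum into a reactant
    basin (R1 bonded, R2 long), a product basin (R2 bonded, R1 long) and one
    connecting saddle.
    """

    D1: float = 80.0
    D2: float = 90.0
    a1: float = 1.5
    a2: float = 2.0
    r1_eq: float = 1.6
    r2_eq: float = 1.6
    coupling: float = 220.0
    cage_k: float = 10.0
    cage_span: float = 5.0

    def __post_init__(self):
        for name in ("D1", "D2", "a1", "a2", "r1_eq", "r2_eq", "coupling",
                     "cage_k", "cage_span"):
            if getattr(self, name) <= 0:
                raise SurfaceError(f"{name} must be positive")


def _morse(r, D, a, re):
    u = 1.0 - np.exp(-a * (r - re))
    return D * (u * u - 1.0)


def _morse_grad(r, D, a, re):
    e = np.exp(-a * (r - re))
    return 2.0 * D * a * e * (1.0 - e)


def bond_swap_surface(params: BondSwapParams | None = None, validate: bool = True) -> PotentialSurface:
    """Two-basin surface over internal coordinates (R1, R2).

    E(R1, R2) = Morse(R1) + Morse(R2)
              + coupling · e^{−a1(R1−r1_eq)} · e^{−a2(R2−r2_eq)}
              + cage_k · (R1 + R2 − cage_span)²

    The repulsive coupling penalizes both bonds being made at once; the weak
    cage term models the active-site pocket that holds the non-bonded partner
    at a finite distance (without it the unbound atom has no finite-distance
    minimum).  Default parameters place the saddle at elongated R1 with R2 still long —
    the breaking bond is mostly gone before the forming bond is made, i.e. a
    dissociative ordering by construction.  With ``validate`` on, the
    stationary-point census (exactly two minima, one first-order saddle) is
    checked numerically and a :class:`SurfaceError` with the census is raised
    if it fails.
    """
    p = params or BondSwapParams()

    def energy(x):
        r1, r2 = np.asarray(x, dtype=float)
        rep = p.coupling * np.exp(-p.a1 * (r1 - p.r1_eq)) * np.exp(-p.a2 * (r2 - p.r2_eq))
        cage = p.cage_k * (r1 + r2 - p.cage_span) ** 2
        return float(_morse(r1, p.D1, p.a1, p.r1_eq) + _morse(r2, p.D2, p.a2, p.r2_eq)
                     + rep + cage)

    def gradient(x):
        r1, r2 = np.asarray(x, dtype=float)
        rep = p.coupling * np.exp(-p.a1 * (r1 - p.r1_eq)) * np.exp(-p.a2 * (r2 - p.r2_eq))
        gc = 2.0 * p.cage_k * (r1 + r2 - p.cage_span)
        g1 = _morse_grad(r1, p.D1, p.a1, p.r1_eq) - p.a1 * rep + gc
        g2 = _morse_grad(r2, p.D2, p.a2, p.r2_eq) - p.a2 * rep + gc
        return np.array([g1, g2])

    surf = PotentialSurface("bond_swap", 2, energy, gradient, probe_bounds=(1.2, 4.5))
    if validate:
        census = stationary_census(surf, bounds=((1.2, 4.5), (1.2, 4.5)), n_grid=90)
        n_min = len(census["minima"])
        n_sad = len(census["saddles"])
        if n_min != 2 or n_sad != 1:
            raise SurfaceError(
                f"bond_swap parameters yield {n_min} minima and {n_sad} saddles "
                f"(need 2 and 1); census: {census}"
            )
    return surf


def bond_swap_frames(params: BondSwapParams | None = None,
                     r1_product: float = 3.4, r2_reactant: float = 3.4
                     ) -> tuple[Frame, Frame]:
    """Reactant and product endpoint frames for the Cartesian bond-swap system.

    Three collinear labeled points — the leaving group Os, the central atom Pg
    and the incoming nucleophile Ow — arranged on the x axis so that
    R1 = |Pg − Os| and R2 = |Pg − Ow| take the requested basin values.
    """
    p = params or BondSwapParams()
    labels = ["Os", "Pg", "Ow"]

    def frame(r1, r2):
        coords = np.array([[0.0, 0.0, 0.0], [r1, 0.0, 0.0], [r1 + r2, 0.0, 0.0]])
        return Frame(labels, coords)

    return frame(p.r1_eq, r2_reactant), frame(r1_product, p.r2_eq)


def cartesian_bond_swap(params: BondSwapParams | None = None) -> PotentialSurface:
    """Bond-swap surface over the Cartesian coordinates of three labeled points.

    Configuration vector = raveled (3, 3) coordinates of (Os, Pg, Ow);
    the energy is the internal-coordinate bond-swap energy evaluated at
    R1 = |Pg − Os|, R2 = |Pg − Ow|.  Rigid motions are exact zero modes.
    """
    inner = bond_swap_surface(params, validate=False)

    def split(x):
        c = np.asarray(x, dtype=float).reshape(3, 3)
        v1 = c[1] - c[0]
        v2 = c[1] - c[2]
        return c, v1, v2, np.linalg.norm(v1), np.linalg.norm(v2)

    def energy(x):
        _, _, _, r1, r2 = split(x)
        return inner.energy(np.array([r1, r2]))

    def gradient(x):
        _, v1, v2, r1, r2 = split(x)
        g1, g2 = inner.gradient(np.array([r1, r2]))
        u1 = v1 / r1
        u2 = v2 / r2
        g = np.zeros((3, 3))
        g[1] += g1 * u1 + g2 * u2
        g[0] -= g1 * u1
        g[2] -= g2 * u2
        return g.ravel()

    return PotentialSurface("bond_swap_cartesian", 9, energy, gradient, probe_bounds=(0.5, 5.0))


def gradient_check(surface: PotentialSurface, n_points: int = 100, h: float = 1e-5,
                   seed: int = 0) -> float:
    """Worst relative central-difference discrepancy of the analytic gradient.

    Probes ``n_points`` random configurations inside ``surface.probe_bounds``;
    deterministic for a fixed seed.  Non-finite energies at a probe raise a
    :class:`SurfaceError` naming the probe.
    """
    if h <= 0:
        raise ValueError("h must be positive")
    rng = np.random.default_rng(seed)
    lo, hi = surface.probe_bounds
    worst = 0.0
    for _ in range(n_points):
        x = rng.uniform(lo, hi, size=surface.dimension)
        g = np.asarray(surface.gradient(x), dtype=float)
        fd = np.empty_like(g)
        for i in range(surface.dimension):
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            ep, em = surface.energy(xp), surface.energy(xm)
            if not (np.isfinite(ep) and np.isfinite(em)):
                raise SurfaceError(f"non-finite energy near probe {x}")
            fd[i] = (ep - em) / (2.0 * h)
        scale = max(np.linalg.norm(fd), 1.0)
        worst = max(worst, float(np.linalg.norm(g - fd) / scale))
    return worst


def stationary_census(surface: PotentialSurface,
                      bounds: Sequence[tuple[float, float]] | None = None,
                      n_grid: int = 120, refine_tol: float = 1e-10
                      ) -> dict[str, list[dict]]:
    """Locate and classify stationary points of a 2D surface.

    Dense-grid seeding followed by Newton refinement on the gradient
    (finite-difference Hessian of the analytic gradient), classification by
    Hessian eigenvalue signs, and de-duplication.  Returns
    ``{"minima": [...], "saddles": [...], "maxima": [...]}`` with each entry
    carrying ``x`` and ``energy``, sorted by energy.
    """
    if surface.dimension != 2:
        raise SurfaceError("stationary_census supports 2D surfaces only")
    if bounds is None:
        lo, hi = surface.probe_bounds
        bounds = ((lo, hi), (lo, hi))
    xs = np.linspace(bounds[0][0], bounds[0][1], n_grid)
    ys = np.linspace(bounds[1][0], bounds[1][1], n_grid)

    def hess(x, h=1e-6):
        H = np.empty((2, 2))
        for i in range(2):
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            H[:, i] = (surface.gradient(xp) - surface.gradient(xm)) / (2 * h)
        return 0.5 * (H + H.T)

    gnorm = np.empty((n_grid, n_grid))
    for i, x in enumerate(xs):
        for j, y in enumerate(ys):
            gnorm[i, j] = np.linalg.norm(surface.gradient(np.array([x, y])))

    # seed from local minima of |grad| on the grid
    seeds = []
    for i in range(1, n_grid - 1):
        for j in range(1, n_grid - 1):
            v = gnorm[i, j]
            if v <= gnorm[i - 1:i + 2, j - 1:j + 2].min():
                seeds.append(np.array([xs[i], ys[j]]))

    found: list[dict] = []
    for s in seeds:
        x = s.copy()
        ok = True
        for _ in range(80):
            g = surface.gradient(x)
            if np.linalg.norm(g) < refine_tol:
                break
            try:
                step = np.linalg.solve(hess(x), -g)
            except np.linalg.LinAlgError:
                ok = False
                break
            if np.linalg.norm(step) > 0.5:
                step *= 0.5 / np.linalg.norm(step)
            x = x + step
            if not np.all(np.isfinite(x)):
                ok = False
                break
        if not ok or np.linalg.norm(surface.gradient(x)) > 1e-7:
            continue
        if not (bounds[0][0] - 1e-9 <= x[0] <= bounds[0][1] + 1e-9
                and bounds[1][0] - 1e-9 <= x[1] <= bounds[1][1] + 1e-9):
            continue
        if any(np.linalg.norm(x - f["x"]) < 1e-4 for f in found):
            continue
        ev = np.linalg.eigvalsh(hess(x))
        if np.any(np.abs(ev) < 1e-8):
            continue
        kind = {0: "minima", 1: "saddles", 2: "maxima"}[int(np.sum(ev < 0))]
        found.append({"x": x, "energy": float(surface.energy(x)), "kind": kind})

    out: dict[str, list[dict]] = {"minima": [], "saddles": [], "maxima": []}
    for f in found:
        out[f["kind"]].append({"x": f["x"], "energy": f["energy"]})
    for k in out:
        out[k].sort(key=lambda d: d["energy"])
    return out


_REGISTRY: dict[str, Callable[..., PotentialSurface]] = {}


def register_surface(name: str, factory: Callable[..., PotentialSurface]) -> None:
    """Register a surface factory for config-file lookup."""
    _REGISTRY[name] = factory


def make_surface(name: str, **params) -> PotentialSurface:
    """Instantiate a surface by registered name with a parameter block."""
    if name == "muller_brown":
        return muller_brown()
    if name == "harmonic":
        return harmonic(**params)
    if name == "bond_swap":
        return bond_swap_surface(BondSwapParams(**params) if params else None)
    if name == "bond_swap_cartesian":
        return cartesian_bond_swap(BondSwapParams(**params) if params else None)
    if name in _REGISTRY:
        return _REGISTRY[name](**params)
    raise SurfaceError(f"unknown surface {name!r}")
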