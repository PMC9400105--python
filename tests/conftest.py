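import numpy as np
import pytest

from repath.geometry import Frame
from repath.surfaces import muller_brown


@pytest.fixture(scope="session")
def mb_surface():
    return muller_brown()


@pytest.fixture(scope="session")
def mb_points():
    """Frozen oracle stationary points of the Müller–Brown surface."""
    from oracles import mb_reference_points

    minima, saddles = mb_reference_points()
    return {"minima": minima, "saddles": saddles}


def single_point_frame(xy) -> Frame:
    """One-point frame embedding a 2D configuration (z = 0)."""
    return Frame(["X"], np.array([[xy[0], xy[1], 0.0]]))


@pytest.fixture(scope="session")
def mb_optimized(mb_surface, mb_points):
    """One shared protocol run on Müller–Brown: optimize, then refine.

    Endpoints are the two adjacent oracle minima separated by the low saddle;
    reused by several tests to keep the suite fast.
    """
    from repath.path import interpolate_endpoints, optimize_path, refine_endpoints

    m_mid = mb_points["minima"][2]   # (-0.050, 0.467)
    m_right = mb_points["minima"][1]  # (0.623, 0.028)
    saddle = mb_points["saddles"][0]  # (0.212, 0.293)
    chain = interpolate_endpoints(single_point_frame(m_mid["x"]),
                                  single_point_frame(m_right["x"]),
                                  n_replicas=16, fit=False)
    opt, report = optimize_path(chain, mb_surface)
    refined_seed = refine_endpoints(opt, mb_surface, window=2)
    refined, refined_report = optimize_path(refined_seed, mb_surface)
    return {
        "start": m_mid, "end": m_right, "saddle": saddle,
        "initial": chain, "optimized": opt, "report": report,
        "refined": refined, "refined_report": refined_report,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
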