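"""Shared fixtures: synthetic tube models and the calibrated three-age study.

The full study fixture runs the complete calibrated pipeline once per test
session (a few minutes); unit tests use small synthetic tubes instead.
"""

from __future__ import annotations

import numpy as np
import pytest

from aortaflow.geometry import AortoTree, VesselSegment
from aortaflow.inflow import InflowSpec
from aortaflow.solver import Model, SolverConfig, SupportMap, WindkesselBC
from aortaflow.units import L_PER_MIN
from aortaflow.wall import BLOOD_DENSITY, LinearizedWall, tube_law


def make_tube_tree(length: float = 1.0, radius: float = 0.01,
                   outlet: str = "out") -> AortoTree:
    """Single uniform tube on the aortic axis with one terminal outlet."""
    seg = VesselSegment("t0", "infrarenal-abdominal", length, radius, radius,
                        s_range=(0.0, 1.0), outlet_id=outlet)
    return AortoTree({"t0": seg}, {}, "t0", age=30,
                     trunk_knots=(np.array([0.0, 1.0]),
                                  np.array([radius, radius])))


def make_bifurcation_tree(parent_len=0.5, child_len=0.5, r_parent=0.01,
                          r_child=None) -> AortoTree:
    """Parent tube splitting into two identical daughters."""
    if r_child is None:
        r_child = r_parent / np.sqrt(2.0)   # area-matched by default
    segs = {
        "p": VesselSegment("p", "infrarenal-abdominal", parent_len,
                           r_parent, r_parent, s_range=(0.0, 1.0)),
        "c1": VesselSegment("c1", "branch", child_len, r_child, r_child,
                            attach_s=1.0, outlet_id="o1"),
        "c2": VesselSegment("c2", "branch", child_len, r_child, r_child,
                            attach_s=1.0, outlet_id="o2"),
    }
    return AortoTree(segs, {"p": ["c1", "c2"]}, "p", age=30,
                     trunk_knots=(np.array([0.0, 1.0]),
                                  np.array([r_parent, r_parent])))


STD_WALL = dict(k_tt=0.5e6, k_zz=0.5e6, thickness=1.5e-3, radius=0.01)


@pytest.fixture
def std_wall() -> LinearizedWall:
    return LinearizedWall(**STD_WALL)


def matched_outlet(wall: LinearizedWall, r_dist: float = 1.0e8,
                   compliance: float = 1e-8) -> WindkesselBC:
    """RCR with proximal resistance equal to the characteristic impedance."""
    c = tube_law(wall).wave_speed
    z = BLOOD_DENSITY * c / (np.pi * wall.radius ** 2)
    return WindkesselBC(r_prox=z, r_dist=r_dist, compliance=compliance)


def tube_model(wall: LinearizedWall, *, length=1.0, mean_flow=5.0 * L_PER_MIN,
               r_dist=1.0e8, compliance=1e-8, support: SupportMap | None = None,
               inflow: InflowSpec | None = None, config: SolverConfig | None = None,
               p_ref: float | None = "auto") -> Model:
    """Uniform tube with a matched-impedance RCR outlet, operating (by
    default) at its reference pressure."""
    tree = make_tube_tree(length=length, radius=wall.radius)
    bc = matched_outlet(wall, r_dist=r_dist, compliance=compliance)
    inflow = inflow or InflowSpec(mean_flow=mean_flow, heart_rate=60,
                                  reverse_fraction=0.0)
    if p_ref == "auto":
        p_ref = (bc.r_prox + bc.r_dist) * inflow.mean_flow
    config = config or SolverConfig(min_cycles=4, max_cycles=10)
    return Model(tree, {"t0": (wall, wall)}, support or SupportMap(),
                 {"out": bc}, inflow, config, p_ref=p_ref)


@pytest.fixture(scope="session")
def study():
    """Calibrated full study for ages 40/60/75 (shared across tests)."""
    from aortaflow.pipeline import full_study

    return full_study()
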