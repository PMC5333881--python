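"""Constitutive model, small-on-large linearization, tube law, and
regional property assignment."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aortaflow.geometry import AgingSpec, age_geometry, build_baseline_tree
from aortaflow.tables import STATION_S, WallTable
from aortaflow.units import MMHG
from aortaflow.wall import (BLOOD_DENSITY, FiberOverflowError, FourFiberParams,
                            InVivoState, LinearizedWall, assign_wall_properties,
                            biaxial_stress, equilibrium_circ_stretch,
                            small_on_large, strain_energy, tube_law)

PARAMS = FourFiberParams(c=20e3, c1=(10e3, 15e3, 12e3, 12e3),
                         c2=(0.5, 1.0, 0.8, 0.8))


def test_energy_vanishes_at_reference_state():
    assert strain_energy(1.0, 1.0, PARAMS) == pytest.approx(0.0, abs=1e-12)


def test_neo_hookean_closed_form_energy():
    p = FourFiberParams(c=30e3, c1=(0, 0, 0, 0), c2=(0, 0, 0, 0))
    lt = 1.2
    expect = 0.5 * 30e3 * (lt ** 2 + 1.0 + lt ** -2 - 3.0)
    assert strain_energy(lt, 1.0, p) == pytest.approx(expect, rel=1e-12)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(lt=st.floats(0.8, 1.5), lz=st.floats(0.8, 1.5))
def test_stress_matches_energy_gradient(lt, lz):
    h = 1e-6
    dwt = (strain_energy(lt + h, lz, PARAMS) - strain_energy(lt - h, lz, PARAMS)) / (2 * h)
    dwz = (strain_energy(lt, lz + h, PARAMS) - strain_energy(lt, lz - h, PARAMS)) / (2 * h)
    s_tt, s_zz = biaxial_stress(lt, lz, PARAMS)
    assert s_tt == pytest.approx(lt * dwt, rel=1e-6, abs=1e-3)
    assert s_zz == pytest.approx(lz * dwz, rel=1e-6, abs=1e-3)


def test_unloaded_reference_state_is_stress_free():
    s_tt, s_zz = biaxial_stress(1.0, 1.0, PARAMS)
    assert s_tt == pytest.approx(0.0, abs=1e-9)
    assert s_zz == pytest.approx(0.0, abs=1e-9)


def test_isotropic_equibiaxial_symmetry():
    p = FourFiberParams(c=30e3, c1=(0, 0, 0, 0), c2=(0, 0, 0, 0))
    s_tt, s_zz = biaxial_stress(1.3, 1.3, p)
    assert s_tt == pytest.approx(s_zz, rel=1e-12)


def test_equilibrium_stretch_satisfies_laplace_law():
    tp = 90 * MMHG
    r_over_h = 10.0
    lt = equilibrium_circ_stretch(PARAMS, lz=1.1, tp=tp,
                                  radius_over_thickness=r_over_h)
    s_tt, _ = biaxial_stress(lt, 1.1, PARAMS)
    assert abs(s_tt - tp * r_over_h) < 1e-8 * tp * r_over_h + 1e-8


def test_fiber_overflow_names_family():
    p = FourFiberParams(c=1e3, c1=(1e3, 1e3, 1e3, 1e3), c2=(50, 50, 50, 50))
    with pytest.raises(FiberOverflowError, match="fiber family"):
        strain_energy(2.5, 2.5, p)


# -- small on large --------------------------------------------------------


def _state(lt, lz):
    return InVivoState(radius=0.01, thickness=1.5e-3, axial_stretch=lz,
                       circ_stretch=lt, tp=90 * MMHG)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(lt=st.floats(0.9, 1.4), lz=st.floats(0.9, 1.4),
       c=st.floats(5e3, 60e3), c1=st.floats(1e3, 40e3), c2=st.floats(0.05, 2.0))
def test_small_on_large_matches_finite_difference(lt, lz, c, c1, c2):
    p = FourFiberParams(c=c, c1=(c1, 0.8 * c1, 1.2 * c1, 1.2 * c1),
                        c2=(c2, 1.5 * c2, c2, c2))
    lw = small_on_large(_state(lt, lz), p, check_equilibrium=False)
    h = 1e-6
    k_tt_fd = lt * (biaxial_stress(lt + h, lz, p)[0]
                    - biaxial_stress(lt - h, lz, p)[0]) / (2 * h)
    k_zz_fd = lz * (biaxial_stress(lt, lz + h, p)[1]
                    - biaxial_stress(lt, lz - h, p)[1]) / (2 * h)
    assert lw.k_tt == pytest.approx(k_tt_fd, rel=1e-5)
    assert lw.k_zz == pytest.approx(k_zz_fd, rel=1e-5)


def test_neo_hookean_incremental_modulus_closed_form():
    p = FourFiberParams(c=25e3, c1=(0, 0, 0, 0), c2=(0, 0, 0, 0))
    lt, lz = 1.25, 1.1
    lw = small_on_large(_state(lt, lz), p, check_equilibrium=False)
    lr2 = 1.0 / (lt * lz) ** 2
    assert lw.k_tt == pytest.approx(25e3 * (2 * lt ** 2 + 2 * lr2), rel=1e-12)


def test_moduli_are_homogeneous_in_material_constants():
    lw1 = small_on_large(_state(1.2, 1.1), PARAMS, check_equilibrium=False)
    doubled = FourFiberParams(c=2 * PARAMS.c,
                              c1=tuple(2 * v for v in PARAMS.c1), c2=PARAMS.c2)
    lw2 = small_on_large(_state(1.2, 1.1), doubled, check_equilibrium=False)
    assert lw2.k_tt == pytest.approx(2 * lw1.k_tt, rel=1e-12)
    assert lw2.k_zz == pytest.approx(2 * lw1.k_zz, rel=1e-12)


def test_non_equilibrium_state_is_rejected():
    with pytest.raises(ValueError, match="equilibrium"):
        small_on_large(_state(2.0, 1.0), PARAMS)


# -- tube law --------------------------------------------------------------


def test_tube_law_wave_speed_matches_hand_value():
    # 40 yo proximal descending thoracic aorta station values:
    # c = sqrt(K h / (2 rho R)) = sqrt(0.5e6 * 1.7e-3 / (2*1060*11.63e-3))
    wall = LinearizedWall(k_tt=0.50e6, k_zz=0.46e6, thickness=1.70e-3,
                          radius=11.63e-3)
    tl = tube_law(wall, k_s=0.0, rho=1060.0)
    assert tl.wave_speed == pytest.approx(5.87, abs=0.02)


def test_tube_law_is_moens_korteweg_form():
    wall = LinearizedWall(k_tt=0.8e6, k_zz=0.5e6, thickness=2e-3, radius=0.012)
    k_s = 3e5
    tl = tube_law(wall, k_s=k_s)
    expect = math.sqrt((wall.k_tt * wall.thickness / wall.radius
                        + k_s * wall.radius) / (2 * BLOOD_DENSITY))
    assert tl.wave_speed == pytest.approx(expect, rel=1e-12)


def test_rigid_support_limit_kills_compliance():
    wall = LinearizedWall(k_tt=0.5e6, k_zz=0.5e6, thickness=1.5e-3, radius=0.01)
    assert tube_law(wall, k_s=1e15).dadp < 1e-15


def test_wave_speed_monotone_in_support_stiffness():
    wall = LinearizedWall(k_tt=0.5e6, k_zz=0.5e6, thickness=1.5e-3, radius=0.01)
    speeds = [tube_law(wall, k_s=k).wave_speed for k in (0.0, 1e5, 1e6, 1e7)]
    assert all(a < b for a, b in zip(speeds, speeds[1:]))


# -- regional assignment ---------------------------------------------------


@pytest.fixture(scope="module")
def aged_trees():
    spec = AgingSpec()
    base = build_baseline_tree(spec)
    return {a: age_geometry(base, 30, a, spec) for a in (40, 60, 75)}


def test_station_cells_reproduced_exactly(aged_trees):
    table = WallTable()
    for age in (40, 60, 75):
        for st_name, s in STATION_S.items():
            row = table.row(age, st_name)
            assert float(table.k_tt(age, s)) == pytest.approx(row.k_tt, rel=1e-12)
            assert float(table.thickness(age, s)) == pytest.approx(row.thickness, rel=1e-12)
            assert float(table.k_zz(age, s)) == pytest.approx(row.k_zz, rel=1e-12)
            assert float(table.radius(age, s)) == pytest.approx(row.radius, rel=1e-12)


def test_constant_extrapolation_through_the_iliacs(aged_trees):
    table = WallTable()
    assert float(table.k_tt(60, 0.88)) == pytest.approx(1.66e6)
    assert float(table.k_tt(60, 1.1)) == pytest.approx(1.66e6)


def test_renal_stiffness_is_age_invariant(aged_trees):
    w40 = assign_wall_properties(aged_trees[40], 40)
    w75 = assign_wall_properties(aged_trees[75], 75)
    assert w40["right_renal"][0].k_tt == w75["right_renal"][0].k_tt
    # and equals the 75 yo infrarenal aortic value
    assert w40["right_renal"][0].k_tt == pytest.approx(2.14e6)


def test_midpoint_interpolation_between_stations(aged_trees):
    table = WallTable()
    # s = 0.26 is midway between the ATA (0.12) and DTA (0.4) stations at
    # 40 yo: K = (0.40 + 0.50)/2 MPa
    assert float(table.k_tt(40, 0.26)) == pytest.approx(0.45e6)


@pytest.mark.parametrize("age", [40, 75])
def test_circumferential_stiffness_nondecreasing_along_trunk(age):
    table = WallTable()
    s = np.linspace(0, 1, 41)
    k = table.k_tt(age, s)
    assert np.all(np.diff(k) >= -1e-9)


def test_sixty_year_table_has_small_proximal_stiffness_dip():
    # the tabulated 60 yo circumferential stiffness dips ~5% from the ATA
    # (0.75 MPa) to the DTA (0.71 MPa) before tripling toward the IAA, so
    # strict monotonicity holds only distal of the DTA at that age
    table = WallTable()
    k = table.k_tt(60, np.linspace(0, 1, 41))
    assert k.min() > 0.94 * float(table.k_tt(60, 0.0))
    assert np.all(np.diff(table.k_tt(60, np.linspace(0.4, 1.0, 21))) >= -1e-9)


def test_subclavian_shares_carotid_stiffness(aged_trees):
    walls = assign_wall_properties(aged_trees[60], 60)
    assert walls["left_subclavian"][0].k_tt == walls["left_carotid"][0].k_tt


def test_unknown_age_raises(aged_trees):
    with pytest.raises(KeyError):
        assign_wall_properties(aged_trees[40], 55)
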