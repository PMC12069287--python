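"""Bonded-sphere mechanics: contact law, bond law, rupture, integration."""

import math

import numpy as np
import pytest

from stemdem.core import (
    BRANCH,
    CONTACT_PP,
    STEEL,
    BondParams,
    BondState,
    MaterialParams,
    SimConfig,
    bond_create,
    bond_increment,
    bond_rupture_check,
    bond_stresses,
    critical_timestep,
    hertz_mindlin_contact,
)
from stemdem.simulation import Simulation

from .conftest import make_chain

BOND = BondParams(K_n=3.67e10, K_s=3.42e10, sigma_max=5.005e9, tau_max=6.57e8,
                  R_ab_mm=0.78)


# --------------------------------------------------------------- contact law


def test_zero_overlap_zero_force():
    f = hertz_mindlin_contact(0.0, [1.0, 2.0, 3.0], (5e-4, 5e-4),
                              (BRANCH, BRANCH), CONTACT_PP)
    np.testing.assert_array_equal(f, 0.0)


def test_static_normal_force_matches_hertz_closed_form():
    # independent closed form F = (4/3) E* sqrt(R*) d^{3/2}
    r, delta = 5e-4, 2e-5
    E = BRANCH.youngs_modulus
    e_star = 1.0 / (2 * (1 - BRANCH.poisson**2) / E)
    r_star = r / 2
    expected = (4.0 / 3.0) * e_star * math.sqrt(r_star) * delta**1.5
    f = hertz_mindlin_contact(delta, [0.0, 0.0, 0.0], (r, r),
                              (BRANCH, BRANCH), CONTACT_PP)
    assert f[2] == pytest.approx(expected, rel=1e-12)
    assert f[0] == f[1] == 0.0


def test_tangential_force_never_exceeds_coulomb_cap():
    r, delta = 5e-4, 2e-5
    for v_t in (1e-4, 1e-2, 1.0, 10.0):
        f = hertz_mindlin_contact(delta, [v_t, 0.0, 0.0], (r, r),
                                  (BRANCH, BRANCH), CONTACT_PP)
        f_n = abs(f[2])
        assert abs(f[0]) <= CONTACT_PP.static_friction * f_n * (1 + 1e-12)


def test_approach_damping_increases_normal_force():
    r, delta = 5e-4, 2e-5
    f_static = hertz_mindlin_contact(delta, [0, 0, 0], (r, r),
                                     (BRANCH, BRANCH), CONTACT_PP)
    f_approach = hertz_mindlin_contact(delta, [0, 0, -0.1], (r, r),
                                       (BRANCH, BRANCH), CONTACT_PP)
    assert f_approach[2] > f_static[2]


# ----------------------------------------------------------------- bond law


def test_bond_create_distance_filter():
    chain = make_chain(3)  # pitch 1 mm
    bonds = bond_create(chain, BOND)  # search diameter 1.56 mm
    assert len(bonds) == 2
    assert {b.pair for b in bonds} == {(0, 1), (1, 2)}
    far = make_chain(2, pitch_mm=2.0)
    assert bond_create(far, BOND) == []


def test_bond_area_and_polar_moment():
    # A_b = pi R^2 and J = pi R^4 / 2 for the calibrated radius
    assert BOND.A_b == pytest.approx(math.pi * (0.78e-3) ** 2, rel=1e-12)
    assert BOND.A_b == pytest.approx(1.911e-6, rel=1e-3)
    assert BOND.J == pytest.approx(0.5 * math.pi * (0.78e-3) ** 4, rel=1e-12)


def test_bond_increment_zero_rates_noop():
    b = BondState(pair=(0, 1), A_b=BOND.A_b, J=BOND.J)
    b2 = bond_increment(b, 0.0, np.zeros(3), 0.0, np.zeros(3),
                        BOND.K_n, BOND.K_s, 1e-6)
    assert b2.F_n == 0.0 and b2.M_n == 0.0
    np.testing.assert_array_equal(b2.F_t, 0.0)


def test_bond_increment_constant_rate_closed_form():
    b = BondState(pair=(0, 1), A_b=BOND.A_b, J=BOND.J)
    v_n, dt, n = 0.01, 1e-6, 1000
    for _ in range(n):
        b = bond_increment(b, v_n, np.zeros(3), 0.0, np.zeros(3),
                           BOND.K_n, BOND.K_s, dt)
    assert b.F_n == pytest.approx(-v_n * BOND.K_n * BOND.A_b * n * dt, rel=1e-12)


def test_bond_increment_on_broken_bond_warns_noop():
    b = BondState(pair=(0, 1), A_b=BOND.A_b, J=BOND.J, F_n=-1.0, intact=False)
    with pytest.warns(UserWarning, match="broken bond"):
        b2 = bond_increment(b, 1.0, np.zeros(3), 0.0, np.zeros(3),
                            BOND.K_n, BOND.K_s, 1e-6)
    assert b2.F_n == -1.0


def test_rupture_criteria_and_irreversibility():
    b = BondState(pair=(0, 1), A_b=BOND.A_b, J=BOND.J)
    assert bond_rupture_check(b, 1e6, 1e6, BOND.R_ab)  # zero state: intact
    b.F_n = -1e6 * BOND.A_b * 1.01  # tensile stress just over the limit
    assert not bond_rupture_check(b, 1e6, 1e12, BOND.R_ab)
    b.F_n = 0.0
    assert not bond_rupture_check(b, 1e6, 1e12, BOND.R_ab)  # stays broken

    b2 = BondState(pair=(0, 1), A_b=BOND.A_b, J=BOND.J)
    b2.M_n = 1e6 * BOND.J / BOND.R_ab * 1.01  # torsional shear over the limit
    assert not bond_rupture_check(b2, 1e12, 1e6, BOND.R_ab)


def test_bond_stresses_magnitude_convention():
    b = BondState(pair=(0, 1), A_b=BOND.A_b, J=BOND.J,
                  F_n=-2.0, F_t=np.array([3.0, 4.0, 0.0]))
    sigma, tau = bond_stresses(b, BOND.R_ab)
    assert sigma == pytest.approx(2.0 / BOND.A_b)
    assert tau == pytest.approx(5.0 / BOND.A_b)


# ----------------------------------------------------------- critical step


def test_critical_timestep_values_and_scaling():
    out = critical_timestep(5e-4, BRANCH, BOND)
    expected_rayleigh = (
        math.pi * 5e-4 * math.sqrt(984.7 / 6.40e8) / (0.163 * 0.36 + 0.877)
    )
    assert out["rayleigh"] == pytest.approx(expected_rayleigh, rel=1e-12)
    m = 984.7 * 4 / 3 * math.pi * (5e-4) ** 3
    assert out["bond"] == pytest.approx(math.sqrt(m / (BOND.K_n * BOND.A_b)),
                                        rel=1e-12)
    assert out["dt"] == pytest.approx(0.2 * min(out["rayleigh"], out["bond"]))

    stiffer = MaterialParams(984.7, 0.36, 2 * 6.40e8)
    assert critical_timestep(5e-4, stiffer)["rayleigh"] == pytest.approx(
        expected_rayleigh / math.sqrt(2)
    )
    harder = BondParams(K_n=4 * BOND.K_n, K_s=BOND.K_s, sigma_max=BOND.sigma_max,
                        tau_max=BOND.tau_max, R_ab_mm=BOND.R_ab_mm)
    assert critical_timestep(5e-4, BRANCH, harder)["dt"] <= out["dt"]


# ---------------------------------------------------- integrated trajectories


def test_free_fall_matches_kinematics():
    model = make_chain(1)
    sim = Simulation(model, BOND, SimConfig(damping=0.0, gravity=-9.81))
    z0 = sim.pos[0, 2]
    n = 5000
    sim.run(n, rec_every=n)
    t = n * sim.dt
    z = sim.pos[0, 2] - z0
    # semi-implicit Euler: z = g dt^2 n(n+1)/2, within O(dt) of g t^2 / 2
    assert z == pytest.approx(-0.5 * 9.81 * t**2, rel=2e-3)


def test_bonded_pair_at_rest_stays_at_rest(two_particle_model):
    sim = Simulation(two_particle_model, BOND, SimConfig(damping=0.0))
    p0 = sim.pos.copy()
    sim.run(2000, rec_every=2000)
    np.testing.assert_allclose(sim.pos, p0, atol=1e-15)


def test_momentum_conserved_in_free_collision():
    # two free particles approaching: contact forces are equal and opposite
    model = make_chain(2, pitch_mm=1.2)
    tiny = BondParams(K_n=1e9, K_s=1e9, sigma_max=1e5, tau_max=1e5, R_ab_mm=0.1)
    sim = Simulation(model, tiny, SimConfig(damping=0.0))
    assert len(sim.bond_pairs) == 0
    sim.vel[0] = (0, 0, 0.2)
    sim.vel[1] = (0, 0, -0.2)
    p_before = sim.vel.sum(axis=0)
    sim.run(20000, rec_every=20000)
    np.testing.assert_allclose(sim.vel.sum(axis=0), p_before, atol=1e-12)
    assert sim.vel[0, 2] < 0.2  # the collision actually happened


def test_two_particle_tension_accumulation_exact(two_particle_model):
    sim = Simulation(two_particle_model, BOND, SimConfig(damping=0.0))
    sim.set_driven([0], (0, 0, 0), record=False)
    v = 0.01
    sim.set_driven([1], (0, 0, v), record=True)
    n = 1000
    sim.run(n, rec_every=n)
    expected = -v * BOND.K_n * BOND.A_b * n * sim.dt
    assert sim.bond_fn[0] == pytest.approx(expected, rel=1e-12)


def test_two_particle_rupture_elongation(two_particle_model):
    # rupture displacement of a pulled bond equals sigma_max / K_n
    bond = BondParams(K_n=3.67e10, K_s=3.42e10, sigma_max=3.67e10 * 2e-4,
                      tau_max=1e12, R_ab_mm=0.78)
    sim = Simulation(two_particle_model, bond, SimConfig(damping=0.0))
    sim.set_driven([0], (0, 0, 0), record=False)
    v = 0.01
    sim.set_driven([1], (0, 0, v), record=True)
    rec = sim.run(60000, rec_every=10)
    assert (rec.broken_bonds > 0).any()
    t_rupture = rec.time[np.argmax(rec.broken_bonds > 0)]
    assert v * t_rupture == pytest.approx(bond.sigma_max / bond.K_n, rel=0.01)


def test_two_particle_compression_follows_bond_plus_hertz_oracle(
    two_particle_model,
):
    sim = Simulation(two_particle_model, BOND, SimConfig(damping=0.0))
    sim.set_driven([0], (0, 0, 0), record=False)
    v = -0.01
    sim.set_driven([1], (0, 0, v), record=True)
    n, rec_every = 20000, 200
    rec = sim.run(n, rec_every=rec_every)
    # recorded forces are interval averages: evaluate the oracle at the
    # midpoint of the last recording interval
    delta = -v * (n - rec_every / 2) * sim.dt
    f_bond = BOND.K_n * BOND.A_b * delta
    e_star = 1.0 / (2 * (1 - BRANCH.poisson**2) / BRANCH.youngs_modulus)
    f_hertz = (4 / 3) * e_star * math.sqrt(sim.r / 2) * delta**1.5
    measured = rec.force[-1, 2]  # reaction on the moving grip, +z
    assert measured == pytest.approx(f_bond + f_hertz, rel=0.01)


def test_rupture_irreversibility_in_trajectory(two_particle_model):
    bond = BondParams(K_n=3.67e10, K_s=3.42e10, sigma_max=3.67e10 * 5e-5,
                      tau_max=1e12, R_ab_mm=0.78)
    sim = Simulation(two_particle_model, bond, SimConfig(damping=0.0))
    sim.set_driven([0], (0, 0, 0), record=False)
    sim.set_driven([1], (0, 0, 0.01), record=True)
    states = []
    for _ in range(40):
        sim.run(500, rec_every=500)
        states.append(sim.bond_ok.copy())
    arr = np.array(states)
    assert arr[-1, 0] == 0  # it broke
    flips = np.diff(arr.astype(int), axis=0)
    assert (flips <= 0).all()  # never back to intact


def test_energy_non_increasing_with_damping():
    model = make_chain(3)
    sim = Simulation(model, BOND, SimConfig(damping=0.2))
    sim.vel[1] = (0.05, 0.0, 0.02)
    rec = sim.run(10000, rec_every=10)
    E = rec.kinetic_energy + rec.strain_energy
    assert np.all(np.diff(E) <= 1e-6 * E[0])
    assert E[-1] < 1e-2 * E[0]


def test_cantilever_tip_stiffness_matches_series_spring_oracle():
    """A clamped bonded chain pushed transversely at its tip must match the
    independent series-spring (Euler-Bernoulli limit) stiffness."""
    N = 15
    model = make_chain(N)
    ell = 1e-3
    # independent static oracle: bending springs k_theta at bond midpoints in
    # series with shear springs k_s
    k_theta = 0.5 * BOND.K_n * BOND.J
    k_s = BOND.K_s * BOND.A_b
    d = np.array([(N - 1.5 - i) * ell for i in range(N - 1)])
    k_oracle = 1.0 / ((d**2 / k_theta).sum() + (N - 1) / k_s)

    sim = Simulation(model, BOND, SimConfig(damping=0.3))
    sim.set_driven([0], (0, 0, 0), record=False)
    v, r_tool = 0.002, 0.5e-3
    tip = sim.pos[N - 1]
    tool = sim.add_cylinder((tip[0] + sim.r + r_tool, tip[1], tip[2]),
                            (0, 1, 0), r_tool, velocity=(-v, 0, 0))
    rec_every = max(1, int(round(0.005e-3 / (v * sim.dt))))
    rec = sim.run(160 * rec_every, rec_every=rec_every, record_wall=tool)
    disp = v * rec.time  # m of tool travel
    F = rec.force[:, 0]
    m = (disp > 0.3e-3) & (disp < 0.75e-3)
    slope = np.linalg.lstsq(
        np.column_stack([disp[m], np.ones(m.sum())]), F[m], rcond=None
    )[0][0]
    assert abs(slope) == pytest.approx(k_oracle, rel=0.15)


def test_instability_detected_with_oversized_step():
    model = make_chain(2)
    sim = Simulation(model, BOND, SimConfig(dt=1e-4, damping=0.0))
    sim.vel[1] = (0, 0, -1.0)
    with pytest.raises(RuntimeError, match="unstable"):
        sim.run(5000, rec_every=10)
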