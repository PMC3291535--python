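"""Free-energy landscape: mixing/conformational entropy, exhaustive-oracle
equivalence, heat capacity, basin detection and Gibbs averaging."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from scipy.special import logsumexp

from mdcm.ensemble import (
    Landscape,
    LandscapeBuilder,
    Macrostate,
    build_landscape,
    conformational_entropy,
    free_energy,
    heat_capacity,
    mixing_entropy,
    native_basin_average,
    sample_macrostate,
)
from mdcm.network import (
    Constraint,
    ConstraintNetwork,
    DCMParameters,
    R_GAS,
    RotatableBond,
)
from mdcm.pebble import run_pebble_game

# ---------------------------------------------------------------------------
# Independent brute-force oracle: explicit loops over all frameworks
# ---------------------------------------------------------------------------


def brute_force_macrostate(net, params, n_nat, n_hb, T):
    """Plain-loop enumeration of a macrostate: frameworks weighted by
    exp(-beta * sum of engaged u_hb), torsion placements uniform."""
    hb_ids = [c.id for c in net.hbonds]
    u_of = {c.id: c.enthalpy for c in net.hbonds}
    gamma_of = {c.id: c.entropy_weight for c in net.hbonds}
    bond_ids = [b.id for b in net.rotatable_bonds]
    beta = 1.0 / (R_GAS * T)

    frameworks = []
    for hb_pat in itertools.combinations(hb_ids, n_hb):
        for nat_pat in itertools.combinations(bond_ids, n_nat):
            w = math.exp(-beta * sum(u_of[i] for i in hb_pat))
            frameworks.append((set(hb_pat), set(nat_pat), w))
    z = sum(w for _, _, w in frameworks)

    mean_u_hb = 0.0
    q_num = {i: 0.0 for i in hb_ids}
    q_den = {i: 0.0 for i in hb_ids}
    nat_ind = dis_ind = 0.0
    fi_sum = None
    for hb_pat, nat_pat, w in frameworks:
        w /= z
        d = run_pebble_game(net, hb_pat, nat_pat)
        mean_u_hb += w * sum(u_of[i] for i in hb_pat)
        for i in hb_pat:
            q_num[i] += w * d.constraint_independence(i)
            q_den[i] += w
        nat_ind += w * d.n_nat_indep
        dis_ind += w * d.n_dis_indep
        fi = np.array([d.bond_f(b) for b in bond_ids])
        fi_sum = w * fi if fi_sum is None else fi_sum + w * fi

    n_dis = len(bond_ids) - n_nat
    q = {i: (q_num[i] / q_den[i] if q_den[i] > 0 else 1.0) for i in hb_ids}
    q_nat = nat_ind / n_nat if n_nat else 1.0
    q_dis = dis_ind / n_dis if n_dis else 1.0
    mean_u = (
        mean_u_hb
        + (len(hb_ids) - n_hb) * params.u_sol
        + n_nat * params.v_nat
        + n_dis * params.v_dis
    )
    s_mix = R_GAS * (
        math.log(math.comb(len(bond_ids), n_nat)) + math.log(math.comb(len(hb_ids), n_hb))
    )
    s_conf = R_GAS * (
        sum(q_den[i] * q[i] * gamma_of[i] for i in hb_ids)
        + q_nat * n_nat * params.delta_nat
        + q_dis * n_dis * params.delta_dis
    )
    g = mean_u - T * (s_mix + s_conf)
    return dict(q=q, q_nat=q_nat, q_dis=q_dis, mean_u=mean_u, s_mix=s_mix,
                s_conf=s_conf, g=g, fi=fi_sum)


# ---------------------------------------------------------------------------
# Mixing entropy
# ---------------------------------------------------------------------------

def test_mixing_entropy_edges_and_binomial():
    assert mixing_entropy(0, 0, 4, 3) == 0.0
    assert mixing_entropy(4, 3, 4, 3) == 0.0
    # N_tor = 4, n_nat = 2 -> torsion contribution R ln 6
    assert mixing_entropy(2, 0, 4, 3) == pytest.approx(R_GAS * math.log(6), rel=1e-12)


@pytest.mark.parametrize("n_nat", range(5))
def test_mixing_entropy_binomial_symmetry(n_nat):
    assert mixing_entropy(n_nat, 0, 4, 2) == pytest.approx(
        mixing_entropy(4 - n_nat, 0, 4, 2), rel=1e-12
    )


# ---------------------------------------------------------------------------
# Conformational entropy and free energy limits
# ---------------------------------------------------------------------------

def _manual_macrostate(q, q_nat, q_dis, pi, n_nat, n_hb):
    return Macrostate(
        n_nat=n_nat, n_hb=n_hb, q=np.asarray(q, float), q_nat=q_nat, q_dis=q_dis,
        pi=np.asarray(pi, float), mean_enthalpy=0.0, s_mix=0.0, s_conf=0.0,
        free_energy=0.0, temperature=300.0, exhaustive=True, n_samples=1,
    )


def test_conformational_entropy_additive_limit():
    """With all q = 1 the entropy reverts to the plain additive sum."""
    p = DCMParameters()
    gamma = np.array([1.0, 2.0, 0.5])
    mac = _manual_macrostate([1, 1, 1], 1.0, 1.0, [1, 1, 1], n_nat=2, n_hb=3)
    s = conformational_entropy(mac, p, gamma, n_tor=5)
    additive = R_GAS * (gamma.sum() + 2 * p.delta_nat + 3 * p.delta_dis)
    assert s == pytest.approx(additive, rel=1e-12)


def test_conformational_entropy_zero_limit():
    p = DCMParameters()
    gamma = np.array([1.0, 2.0])
    mac = _manual_macrostate([0, 0], 0.0, 0.0, [1, 1], n_nat=1, n_hb=2)
    assert conformational_entropy(mac, p, gamma, n_tor=4) == 0.0


def test_free_energy_zero_temperature_is_enthalpy(tiny_net, toy_params):
    mac = sample_macrostate(tiny_net, 2, 1, T=300.0, params=toy_params)
    assert free_energy(mac, 0.0, toy_params) == pytest.approx(mac.mean_enthalpy)


def test_free_energy_linear_in_temperature(tiny_net, toy_params):
    mac = sample_macrostate(tiny_net, 2, 1, T=300.0, params=toy_params)
    g1 = free_energy(mac, 100.0, toy_params)
    g2 = free_energy(mac, 200.0, toy_params)
    g3 = free_energy(mac, 300.0, toy_params)
    assert g3 - g2 == pytest.approx(g2 - g1, rel=1e-9)


def test_raising_u_sol_penalizes_broken_states(tiny_net, toy_params):
    """Raising u_sol (less negative) removes solvent compensation, so the
    fully broken macrostate rises relative to the fully bonded one."""
    T = 300.0
    n_tor, n_hb = tiny_net.n_tor, tiny_net.n_hb_max
    import dataclasses

    def gap(u_sol):
        p = dataclasses.replace(toy_params, u_sol=u_sol)
        b = LandscapeBuilder(tiny_net, p, exhaustive_only=True)
        g_folded = b.evaluate(n_tor, n_hb, T).free_energy
        g_broken = b.evaluate(n_tor, 0, T).free_energy
        return g_broken - g_folded

    assert gap(-1.0) > gap(-2.5)


# ---------------------------------------------------------------------------
# Exhaustive-oracle equivalence
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n_nat,n_hb", [(0, 0), (1, 1), (2, 1), (4, 2), (3, 0)])
def test_macrostate_matches_brute_force(tiny_net, toy_params, n_nat, n_hb):
    T = 320.0
    mac = sample_macrostate(tiny_net, n_nat, n_hb, T=T, params=toy_params, mech=True)
    assert mac.exhaustive
    ref = brute_force_macrostate(tiny_net, toy_params, n_nat, n_hb, T)
    assert mac.mean_enthalpy == pytest.approx(ref["mean_u"], rel=1e-10)
    assert mac.s_mix == pytest.approx(ref["s_mix"], rel=1e-10)
    assert mac.s_conf == pytest.approx(ref["s_conf"], rel=1e-10)
    assert mac.free_energy == pytest.approx(ref["g"], rel=1e-10)
    assert mac.q_nat == pytest.approx(ref["q_nat"], rel=1e-10)
    assert mac.q_dis == pytest.approx(ref["q_dis"], rel=1e-10)
    hb_ids = [c.id for c in tiny_net.hbonds]
    for k, cid in enumerate(hb_ids):
        assert mac.q[k] == pytest.approx(ref["q"][cid], rel=1e-10)
    np.testing.assert_allclose(mac.mech["fi"], ref["fi"], rtol=1e-10)


def test_degenerate_macrostate_zero_zero(tiny_net, toy_params):
    mac = sample_macrostate(tiny_net, 0, 0, T=300.0, params=toy_params)
    # disordered-only network: free rotor chain, all disordered independent
    assert mac.q_dis == 1.0
    assert mac.s_mix == 0.0


def test_seeded_determinism_of_sampling(two_basin_net, toy_params):
    """Monte-Carlo path (forced by a tiny exhaustive cutoff) is bitwise
    reproducible for a fixed seed."""
    def run():
        b = LandscapeBuilder(
            two_basin_net, toy_params, n_samples=50, exhaustive_cutoff=1, seed=9
        )
        return b.evaluate(3, 2, 400.0, mech=True)

    m1, m2 = run(), run()
    assert m1.free_energy == m2.free_energy
    np.testing.assert_array_equal(m1.q, m2.q)
    np.testing.assert_array_equal(m1.mech["fi"], m2.mech["fi"])
    assert not m1.exhaustive and m1.n_samples == 50


def test_landscape_matches_brute_force_grid(tiny_net, toy_params):
    T = 350.0
    b = LandscapeBuilder(tiny_net, toy_params, exhaustive_only=True)
    for n_nat in range(tiny_net.n_tor + 1):
        for n_hb in range(tiny_net.n_hb_max + 1):
            ref = brute_force_macrostate(tiny_net, toy_params, n_nat, n_hb, T)
            mac = b.evaluate(n_nat, n_hb, T)
            assert mac.free_energy == pytest.approx(ref["g"], rel=1e-10)


def test_monte_carlo_agrees_with_enumeration_within_3se(tiny_net, toy_params):
    """The sampling path is an unbiased estimator of the exact path: across
    seeds, macrostate free energies deviate by less than 3 standard errors
    of the replicate mean."""
    T = 350.0
    exact = LandscapeBuilder(tiny_net, toy_params, exhaustive_only=True).evaluate(2, 1, T)
    reps = []
    for seed in range(12):
        b = LandscapeBuilder(tiny_net, toy_params, n_samples=150, exhaustive_cutoff=1, seed=seed)
        reps.append(b.evaluate(2, 1, T).free_energy)
    reps = np.array(reps)
    se = reps.std(ddof=1) / math.sqrt(len(reps))
    assert abs(reps.mean() - exact.free_energy) < 3 * se + 1e-12


# ---------------------------------------------------------------------------
# Heat capacity
# ---------------------------------------------------------------------------

def _two_state_net(u_hb=-3.0):
    """Two free bodies joined by one 6-bar H-bond: an exactly solvable
    two-state system (no covalent bars, no torsions)."""
    net = ConstraintNetwork(n_bodies=2)
    net.constraints.append(
        Constraint(id=0, kind="hbond", edges=((0, 1, 6),), enthalpy=u_hb, entropy_weight=2.0)
    )
    return net


def test_two_state_cp_matches_closed_form():
    p = DCMParameters(u_sol=-1.0)
    net = _two_state_net(u_hb=-3.0)
    b = LandscapeBuilder(net, p, exhaustive_only=True)
    T = np.linspace(150, 1200, 241)
    Ts, cp, tm = heat_capacity(b, T)

    # closed form: bonded state (H1 = u_hb, S1 = R*gamma), broken (H0 = u_sol, S0 = 0)
    dH = -3.0 - (-1.0)
    dS = R_GAS * 2.0  # q = 1: the lone 6-bar H-bond is fully independent
    K = np.exp(-(dH - Ts * dS) / (R_GAS * Ts))   # bonded/broken
    cp_exact = dH**2 / (R_GAS * Ts**2) * K / (1 + K) ** 2
    mask = cp_exact > 0.05 * cp_exact.max()
    mask[0] = mask[-1] = False  # grid endpoints use one-sided differences
    np.testing.assert_allclose(cp[mask], cp_exact[mask], rtol=0.01)
    tm_exact = Ts[np.argmax(cp_exact)]
    assert tm == pytest.approx(tm_exact, abs=10.0)


def test_two_state_tm_near_equal_free_energy_temperature():
    """For a symmetric two-state system the Cp peak sits at the temperature
    equalizing the two macrostate free energies."""
    p = DCMParameters(u_sol=-1.0)
    net = _two_state_net(u_hb=-3.0)
    b = LandscapeBuilder(net, p, exhaustive_only=True)
    T = np.linspace(150, 1200, 241)
    _, _, tm = heat_capacity(b, T)
    t_eq = 2.0 / (R_GAS * 2.0)  # dH / dS
    assert tm == pytest.approx(t_eq, rel=0.05)


def test_cp_nonnegative_on_tested_systems(tiny_net, two_basin_net, toy_params):
    for net in (tiny_net, two_basin_net):
        b = LandscapeBuilder(net, toy_params, exhaustive_only=True)
        _, cp, _ = heat_capacity(b, np.linspace(150, 1000, 35))
        assert np.all(cp >= -1e-12)


def test_cp_peak_at_endpoint_raises(tiny_net, toy_params):
    b = LandscapeBuilder(tiny_net, toy_params, exhaustive_only=True)
    with pytest.raises(ValueError, match="endpoint"):
        heat_capacity(b, np.linspace(900, 1500, 13))
    with pytest.raises(ValueError, match="at least 5"):
        heat_capacity(b, [300, 310, 320])


# ---------------------------------------------------------------------------
# Native basin
# ---------------------------------------------------------------------------

def test_two_basin_structure_detected(two_basin_landscape):
    scape = two_basin_landscape
    assert scape.saddle_free_energy is not None
    assert len(scape.native_basin) >= 2
    rho = np.array(list(scape.native_basin.values()))
    assert rho.sum() == pytest.approx(1.0, abs=1e-12)
    # the native basin sits on the high-engagement side
    j, k = scape.basin_min
    assert j + k > (scape.n_tor + scape.n_hb_max) / 2
    # every basin cell lies below the saddle
    for p in scape.native_basin:
        assert scape.macrostates[p].free_energy < scape.saddle_free_energy


def test_basin_average_is_hand_normalized_gibbs_sum(two_basin_landscape):
    scape = two_basin_landscape
    beta = 1.0 / (R_GAS * scape.temperature)
    cells = list(scape.native_basin)
    g = np.array([scape.macrostates[p].free_energy for p in cells])
    w = np.exp(-beta * (g - g.min()))
    w /= w.sum()
    ref = sum(wi * scape.macrostates[p].mean_enthalpy for wi, p in zip(w, cells))
    got = native_basin_average(scape, "mean_enthalpy")
    assert got == pytest.approx(ref, rel=1e-9)
    # bounded by the min/max of the averaged field
    vals = [scape.macrostates[p].mean_enthalpy for p in cells]
    assert min(vals) - 1e-12 <= got <= max(vals) + 1e-12


def test_single_point_basin_average_is_that_value():
    mac = _stub_macrostate(3, 2, g=-5.0, u=-7.0)
    scape = _stub_landscape({(3, 2): mac}, basin={(3, 2): 1.0})
    assert native_basin_average(scape, "mean_enthalpy") == -7.0


def test_uniform_basin_average_is_plain_mean():
    macs = {
        (2, 1): _stub_macrostate(2, 1, g=-4.0, u=-6.0),
        (3, 1): _stub_macrostate(3, 1, g=-4.0, u=-2.0),
    }
    scape = _stub_landscape(macs, basin={(2, 1): 0.5, (3, 1): 0.5})
    assert native_basin_average(scape, "mean_enthalpy") == pytest.approx(-4.0)


def test_single_basin_raises(tiny_net, toy_params):
    """The tiny 4-rotor net has a smooth single-basin landscape at most
    temperatures: averaging must refuse rather than invent a basin."""
    scape = build_landscape(tiny_net, toy_params, T=300.0)
    if not scape.native_basin:  # single basin detected
        with pytest.raises(ValueError, match="basin"):
            native_basin_average(scape, "mean_enthalpy")
    else:  # pragma: no cover - if a saddle exists, averaging must work
        native_basin_average(scape, "mean_enthalpy")


def test_strongly_bonded_toy_basin_at_max_engagement(toy_params):
    """With every interaction strongly favourable (very negative u_hb and
    v_nat) at low temperature, the free-energy minimum sits at the fully
    engaged corner of the order-parameter grid."""
    import dataclasses

    from mdcm.synthetic import make_ensemble_toy

    params = dataclasses.replace(toy_params, v_nat=-1.1)
    net = make_ensemble_toy(n_rotors=4, n_hbonds=2, params=params, seed=1,
                            u_range=(-20.0, -18.0))
    scape = build_landscape(net, params, T=150.0)
    assert scape.basin_min == (net.n_tor, net.n_hb_max)


def test_grid_stride_keeps_basin_min_on_toy(two_basin_net, toy_params, two_basin_landscape):
    scape2 = build_landscape(
        two_basin_net, toy_params, T=two_basin_landscape.temperature, grid_stride=2
    )
    # strided evaluation still identifies the same native minimum
    assert scape2.basin_min == two_basin_landscape.basin_min


def _stub_macrostate(j, k, g, u):
    return Macrostate(
        n_nat=j, n_hb=k, q=np.zeros(0), q_nat=1.0, q_dis=1.0, pi=np.zeros(0),
        mean_enthalpy=u, s_mix=0.0, s_conf=0.0, free_energy=g, temperature=300.0,
        exhaustive=True, n_samples=1,
    )


def _stub_landscape(macs, basin):
    points = list(macs)
    scape = Landscape(
        temperature=300.0,
        n_tor=max(j for j, _ in points),
        n_hb_max=max(k for _, k in points),
        grid_points=points,
        macrostates=macs,
    )
    scape.native_basin = basin
    scape.basin_min = min(points, key=lambda p: macs[p].free_energy)
    return scape
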