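"""Construction and equilibrium of the GL3 higher-order complex network."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from mbw.binding_models import single_site_complex
from mbw.reaction_network import (
    NetworkConstructionError,
    build_network,
    enumerate_complexes,
    export_sbml,
    fraction_report,
    import_sbml,
    initial_concentrations,
    mass_action_rhs,
    ratio_scan,
    solve_equilibrium,
)

EQUIMOLAR = {"GL3": 1.0, "GL1": 1.0, "TTG1": 1.0}
EQUIMOLAR_TRY = {**EQUIMOLAR, "TRY": 1.0}


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "include_try, include_dimer, n_species, n_pairs, n_complexes",
    [
        (False, False, 6, 4, 3),  # x, y, z, xy, xz, xyz
        (False, True, 22, 46, 13),
        (True, True, 45, 112, 26),
    ],
)
def test_network_sizes(include_try, include_dimer, n_species, n_pairs, n_complexes):
    net = build_network(include_try=include_try, include_gl3_dimer=include_dimer)
    assert net.n_species == n_species
    assert len(net.reversible_pairs) == n_pairs
    assert net.n_reactions == 2 * n_pairs
    assert len(enumerate_complexes(net)) == n_complexes


def test_try_network_complexes_by_brute_force(try_network):
    """Unordered complex count re-derived by enumerating subunit multisets."""
    # subunit states: MYB site in {empty, GL1, TRY} x WD site in {empty, TTG1}
    states = [(m, w) for m in range(3) for w in range(2)]
    singles = len(states) - 1  # exclude the bare monomer
    dimers = len(states) * (len(states) + 1) // 2  # unordered pairs
    assert len(enumerate_complexes(try_network)) == singles + dimers == 26


def test_max_complex_size_is_hexamer(dimer_network, try_network):
    for net in (dimer_network, try_network):
        assert max(sp.n_proteins for sp in net.species) == 6


def test_enumeration_is_deterministic(try_network):
    other = build_network(include_try=True, include_gl3_dimer=True)
    assert enumerate_complexes(other) == enumerate_complexes(try_network)
    assert [sp.ordered_id for sp in other.species] == [
        sp.ordered_id for sp in try_network.species
    ]


def test_missing_kd_raises():
    with pytest.raises(NetworkConstructionError):
        build_network(include_try=False, kds={"GL3-GL1": 0.5})


# ---------------------------------------------------------------------------
# structural invariants
# ---------------------------------------------------------------------------

def test_reactions_conserve_protein_content(try_network):
    drift = try_network.composition_matrix.T @ try_network.stoichiometric_matrix
    assert np.all(drift == 0)


def test_rate_constants_positive(dimer_network):
    assert np.all(dimer_network.rate_constants > 0)


def test_cycle_closure(dimer_network):
    """Equilibrium-constant products agree around all dual binding paths."""
    net = dimer_network
    g = net._weights
    for f, b in net.reversible_pairs:
        rxn = net.reactions[f]
        K = net.equilibrium_constant((f, b))
        lhs = np.prod([g[i] for i in rxn.reactants]) * K
        assert lhs == pytest.approx(g[rxn.products[0]], rel=1e-10)


def test_alpha_affects_only_co_occupied_subunit_events(estimated_kds):
    ind = build_network(include_try=False, kds=estimated_kds, alpha=1.0)
    coop = build_network(include_try=False, kds=estimated_kds, alpha=0.4)
    changed = sum(
        1
        for (fa, ba), (fb, bb) in zip(ind.reversible_pairs, coop.reversible_pairs)
        if ind.reactions[ba].rate != coop.reactions[bb].rate
    )
    # monomer: 2 second-ligand events; dimers: 2 per co-occupied subunit
    # position x 4 partner states x 2 ligand orders = 16; total 18
    assert changed == 18


# ---------------------------------------------------------------------------
# equilibrium
# ---------------------------------------------------------------------------

def test_dimer_only_equilibrium_matches_quadratic(dimer_network):
    """With no ligands, GL3 obeys the scalar homodimerization quadratic."""
    st = solve_equilibrium(dimer_network, {"GL3": 1.0, "GL1": 0.0, "TTG1": 0.0})
    kdim = 0.5
    x = st.free_monomers[dimer_network.proteins.index("GL3")]
    # x + 2 x^2 / kdim = 1
    assert x + 2 * x**2 / kdim == pytest.approx(1.0, abs=1e-10)
    d = st.concentration("GL3_00__GL3_00")
    assert d == pytest.approx(x**2 / kdim, rel=1e-10)
    ligand_bound = [
        sp.ordered_id
        for i, sp in enumerate(dimer_network.species)
        if sp.count("GL1") + sp.count("TTG1") > 0 and st.concentrations[i] > 0
    ]
    assert ligand_bound == []


def test_symmetric_ligands_symmetric_occupancy(estimated_kds):
    kds = {"GL3-GL1": 1.0, "GL3-TTG1": 1.0, "GL3-GL3": 0.5}
    net = build_network(include_try=False, kds=kds, alpha=1.0)
    st = solve_equilibrium(net, EQUIMOLAR)
    assert st.concentration("GL1") == pytest.approx(
        st.concentration("TTG1"), rel=1e-9
    )
    assert st.concentration("GL3_G0") == pytest.approx(
        st.concentration("GL3_0T"), rel=1e-9
    )


def test_conservation_and_detailed_balance_random_draws(rng):
    for _ in range(10):
        kds = {
            k: float(np.exp(rng.uniform(np.log(0.05), np.log(20))))
            for k in ("GL3-GL1", "GL3-TTG1", "GL3-GL3", "GL3-TRY")
        }
        net = build_network(
            include_try=True, kds=kds, alpha=float(np.exp(rng.uniform(-2, 1)))
        )
        totals = {
            p: float(np.exp(rng.uniform(np.log(0.05), np.log(10))))
            for p in net.proteins
        }
        st = solve_equilibrium(net, totals)  # raises if invariants fail
        rec = st.concentrations @ net.composition_matrix
        want = np.array([totals[p] for p in net.proteins])
        assert np.allclose(rec, want, rtol=1e-9, atol=1e-9)


def test_solver_path_equivalence_ode_vs_root(rng):
    """Free-monomer root finding equals long-time mass-action integration."""
    for _ in range(5):
        kds = {
            k: float(np.exp(rng.uniform(np.log(0.2), np.log(5))))
            for k in ("GL3-GL1", "GL3-TTG1", "GL3-GL3")
        }
        net = build_network(
            include_try=False, kds=kds, alpha=float(np.exp(rng.uniform(-2, 0.7)))
        )
        totals = {
            p: float(np.exp(rng.uniform(np.log(0.3), np.log(3))))
            for p in net.proteins
        }
        st = solve_equilibrium(net, totals)
        sol = solve_ivp(
            mass_action_rhs(net),
            (0, 5e3),
            initial_concentrations(net, totals),
            method="LSODA",
            rtol=1e-10,
            atol=1e-12,
        )
        assert np.allclose(sol.y[:, -1], st.concentrations, atol=1e-6)


def test_batched_solve_matches_scalar(dimer_network):
    folds = np.array([0.5, 1.0, 2.0])
    batched = solve_equilibrium(
        dimer_network, {"GL3": 1.0, "GL1": folds, "TTG1": 1.0}
    )
    for i, f in enumerate(folds):
        single = solve_equilibrium(
            dimer_network, {"GL3": 1.0, "GL1": float(f), "TTG1": 1.0}
        )
        assert np.allclose(batched.concentrations[i], single.concentrations,
                           rtol=1e-9, atol=1e-12)


def test_negative_totals_rejected(dimer_network):
    with pytest.raises(ValueError):
        solve_equilibrium(dimer_network, {"GL3": 1.0, "GL1": -1.0, "TTG1": 1.0})


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def test_fraction_report_partitions(try_network):
    st = solve_equilibrium(try_network, EQUIMOLAR_TRY)
    rep = fraction_report(st)
    assert rep.groupings["single_gl3"] + rep.groupings["dimer_gl3"] == pytest.approx(
        100.0, abs=1e-6
    )
    assert rep.table.percent.sum() == pytest.approx(100.0, abs=1e-6)
    assert rep.denominator == "all_complexes"


def test_fraction_report_zero_try(dimer_network):
    st = solve_equilibrium(dimer_network, EQUIMOLAR)
    rep = fraction_report(st)
    assert rep.groupings["try_containing"] == 0.0


def test_ordered_unordered_consistency(try_network):
    """Summing positional microstates then taking fractions equals fractions
    computed on the unordered aggregation directly."""
    st = solve_equilibrium(try_network, EQUIMOLAR_TRY)
    rep = fraction_report(st)
    # aggregate >= 2 protein species independently of the report
    keep = {}
    for i, sp in enumerate(try_network.species):
        if sp.n_proteins >= 2:
            keep[sp.unordered_id] = keep.get(sp.unordered_id, 0.0) + float(
                st.concentrations[i]
            )
    total = sum(keep.values())
    for _, row in rep.table.iterrows():
        assert row.percent == pytest.approx(
            100.0 * keep[row.unordered_id] / total, rel=1e-8
        )


def test_fraction_report_denominators(try_network):
    st = solve_equilibrium(try_network, EQUIMOLAR_TRY)
    single = fraction_report(st, "single_gl3_complexes")
    assert single.groupings["single_gl3"] == pytest.approx(100.0, rel=1e-9)
    with pytest.raises(ValueError):
        fraction_report(st, "not_a_denominator")


def test_hexamer_below_one_percent_at_estimated_parameters(dimer_network):
    st = solve_equilibrium(dimer_network, EQUIMOLAR)
    rep = fraction_report(st)
    assert rep.groupings["hexamer"] < 1.0


def test_ratio_scan_identity_point(try_network):
    scan = ratio_scan(
        try_network,
        EQUIMOLAR_TRY,
        folds={"GL1": [1.0], "TTG1": [1.0], "TRY": [1.0]},
    )
    rep = fraction_report(solve_equilibrium(try_network, EQUIMOLAR_TRY))
    for grouping, pct in rep.groupings.items():
        row = scan[scan.grouping == grouping]
        assert float(row.percent.iloc[0]) == pytest.approx(pct, rel=1e-9)


def test_ratio_scan_rejects_nonpositive_folds(try_network):
    with pytest.raises(ValueError):
        ratio_scan(try_network, EQUIMOLAR_TRY, folds={"GL1": [0.0]})


# ---------------------------------------------------------------------------
# SBML round trip
# ---------------------------------------------------------------------------

def test_sbml_round_trip_small(trimer_network, tmp_path):
    path = tmp_path / "trimer.xml"
    export_sbml(trimer_network, path)
    back = import_sbml(path)
    assert back.n_species == 6
    assert back.n_reactions == 8
    assert len(back.reversible_pairs) == 4


def test_sbml_round_trip_full(dimer_network, tmp_path):
    path = tmp_path / "network.xml"
    export_sbml(dimer_network, path)
    back = import_sbml(path)
    assert back.n_species == 22
    assert back.n_reactions == 92
    # structural identity up to species order
    order = [back.index[sp.ordered_id] for sp in dimer_network.species]
    S1 = dimer_network.stoichiometric_matrix
    S2 = back.stoichiometric_matrix[order]
    # reactions may be permuted; compare as sorted column multisets
    cols1 = sorted(map(tuple, S1.T.tolist()))
    cols2 = sorted(map(tuple, S2.T.tolist()))
    assert cols1 == cols2
    st1 = solve_equilibrium(dimer_network, EQUIMOLAR)
    st2 = solve_equilibrium(back, EQUIMOLAR)
    c2 = np.array(
        [st2.concentrations[back.index[sp.ordered_id]] for sp in dimer_network.species]
    )
    assert np.allclose(st1.concentrations, c2, atol=1e-12)
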