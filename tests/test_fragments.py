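"""Fragment motifs: canonical keys, depth selection, database mixtures."""

import itertools
import math
import random

import networkx as nx
import numpy as np
import pytest

from shiftassign import (
    ShiftGaussian,
    ShiftMixture,
    assign_block,
    attach_db_densities,
    build_db_density,
    index_structure,
    match_entries,
    motif_key,
    select_depth,
    summarize_density,
)
from shiftassign.errors import UsageError, ValidationError
from shiftassign.io import read_database, write_database
from shiftassign.model import (
    KIND_1D,
    KIND_2D,
    DatabaseEntry,
    ExperimentalPeak,
    MoleculeGraph,
    PredictedItem,
    make_block_key,
    partition_blocks,
)


# ---------------------------------------------------------------------------
# canonical keys: reference implementation via networkx isomorphism


def _ball(graph: MoleculeGraph, root: str, depth: int) -> nx.Graph:
    dist = {root: 0}
    frontier = [root]
    for d in range(1, depth + 1):
        nxt = []
        for v in frontier:
            for u, _ in graph.neighbors(v):
                if u not in dist:
                    dist[u] = d
                    nxt.append(u)
        frontier = nxt
    g = nx.Graph()
    for v in dist:
        g.add_node(v, elem=graph.element(v), root=(v == root))
    for v in dist:
        for u, order in graph.neighbors(v):
            if u in dist:
                g.add_edge(v, u, order=order)
    return g


def _rooted_isomorphic(graph_a, root_a, graph_b, root_b, depth) -> bool:
    """Brute-force oracle: root-preserving isomorphism of the depth balls,
    matching element labels and bond orders."""
    ga, gb = _ball(graph_a, root_a, depth), _ball(graph_b, root_b, depth)
    gm = nx.algorithms.isomorphism.GraphMatcher(
        ga, gb,
        node_match=lambda a, b: a["elem"] == b["elem"] and a["root"] == b["root"],
        edge_match=lambda a, b: a["order"] == b["order"],
    )
    return gm.is_isomorphic()


def _shuffled(graph: MoleculeGraph, seed: int) -> MoleculeGraph:
    rng = random.Random(seed)
    atoms = list(graph.atoms)
    rng.shuffle(atoms)
    bonds = [tuple(rng.sample([a, b], 2)) + (o,) for a, b, o in graph.bonds]
    rng.shuffle(bonds)
    return MoleculeGraph(atoms=atoms, bonds=bonds)


def _fixture_library():
    """Small molecules (<= 12 atoms) with rings, multiple bonds, heteroatoms."""
    methane = MoleculeGraph(
        [("C1", "C"), ("H1", "H"), ("H2", "H"), ("H3", "H"), ("H4", "H")],
        [("C1", "H1", 1), ("C1", "H2", 1), ("C1", "H3", 1), ("C1", "H4", 1)],
    )
    ethene = MoleculeGraph(
        [("C1", "C"), ("C2", "C"), ("H1", "H"), ("H2", "H"), ("H3", "H"), ("H4", "H")],
        [("C1", "C2", 2), ("C1", "H1", 1), ("C1", "H2", 1), ("C2", "H3", 1), ("C2", "H4", 1)],
    )
    ethane = MoleculeGraph(
        [("C1", "C"), ("C2", "C")] + [(f"H{i}", "H") for i in range(1, 7)],
        [("C1", "C2", 1)] + [("C1", f"H{i}", 1) for i in range(1, 4)]
        + [("C2", f"H{i}", 1) for i in range(4, 7)],
    )
    cyclopropane = MoleculeGraph(
        [("C1", "C"), ("C2", "C"), ("C3", "C")] + [(f"H{i}", "H") for i in range(1, 7)],
        [("C1", "C2", 1), ("C2", "C3", 1), ("C3", "C1", 1)]
        + [("C1", "H1", 1), ("C1", "H2", 1), ("C2", "H3", 1), ("C2", "H4", 1),
           ("C3", "H5", 1), ("C3", "H6", 1)],
    )
    propane = MoleculeGraph(
        [("C1", "C"), ("C2", "C"), ("C3", "C")] + [(f"H{i}", "H") for i in range(1, 9)],
        [("C1", "C2", 1), ("C2", "C3", 1)]
        + [("C1", f"H{i}", 1) for i in (1, 2, 3)]
        + [("C2", f"H{i}", 1) for i in (4, 5)]
        + [("C3", f"H{i}", 1) for i in (6, 7, 8)],
    )
    furanish = MoleculeGraph(  # aromatic 5-ring with one oxygen
        [("O1", "O"), ("C1", "C"), ("C2", "C"), ("C3", "C"), ("C4", "C")]
        + [(f"H{i}", "H") for i in range(1, 5)],
        [("O1", "C1", 4), ("C1", "C2", 4), ("C2", "C3", 4), ("C3", "C4", 4), ("C4", "O1", 4)]
        + [(f"C{i}", f"H{i}", 1) for i in range(1, 5)],
    )
    return [methane, ethene, ethane, cyclopropane, propane, furanish]


def test_canonical_key_agrees_with_brute_force_isomorphism():
    """Keys are equal iff the rooted environments are isomorphic, across all
    carbon-rooted motif pairs of a library of small graphs, depths 1-3."""
    library = _fixture_library()
    motifs = []
    for gi, g in enumerate(library):
        for atom_id, elem in g.atoms:
            if elem != "C":
                continue
            for depth in (1, 2, 3):
                motifs.append((gi, g, atom_id, depth, motif_key(g, atom_id, depth).key))
    checked_equal = checked_diff = 0
    for (gi, ga, ra, da, ka), (gj, gb, rb, db, kb) in itertools.combinations(motifs, 2):
        if da != db:
            continue
        iso = _rooted_isomorphic(ga, ra, gb, rb, da)
        assert (ka == kb) == iso, (
            f"key mismatch: {ra}@{gi} vs {rb}@{gj} depth {da}: keys "
            f"{'equal' if ka == kb else 'differ'} but isomorphism={iso}"
        )
        checked_equal += iso
        checked_diff += not iso
    assert checked_equal > 10 and checked_diff > 100  # both branches exercised


def test_key_invariant_under_atom_relabelling(ethanol):
    for seed in range(5):
        shuffled = _shuffled(ethanol, seed)
        for atom_id, elem in ethanol.atoms:
            if elem != "C":
                continue
            for depth in (1, 2, 3):
                assert (
                    motif_key(ethanol, atom_id, depth).key
                    == motif_key(shuffled, atom_id, depth).key
                )


def test_ethanol_carbons_distinguished(ethanol):
    assert motif_key(ethanol, "C1", 1).key != motif_key(ethanol, "C2", 1).key


def test_methane_key_matches_any_ch4_carbon(methane):
    other = MoleculeGraph(
        [("X", "C"), ("a", "H"), ("b", "H"), ("c", "H"), ("d", "H")],
        [("X", "a", 1), ("X", "b", 1), ("X", "c", 1), ("X", "d", 1)],
    )
    assert motif_key(methane, "C1", 1).key == motif_key(other, "X", 1).key


def test_unknown_atom_rejected(methane):
    with pytest.raises(ValidationError):
        motif_key(methane, "C9", 1)
    with pytest.raises(UsageError):
        motif_key(methane, "C1", 0)


def test_bond_orders_enter_motif_identity():
    single = MoleculeGraph([("C1", "C"), ("C2", "C")], [("C1", "C2", 1)])
    double = MoleculeGraph([("C1", "C"), ("C2", "C")], [("C1", "C2", 2)])
    assert motif_key(single, "C1", 1).key != motif_key(double, "C1", 1).key


# ---------------------------------------------------------------------------
# depth selection


@pytest.mark.parametrize(
    "counts,expected_depth,expected_warning",
    [
        ({1: 500, 2: 40, 3: 12, 4: 2}, 3, False),
        ({1: 5}, 1, True),
        ({1: 11}, 1, False),
    ],
)
def test_select_depth_rule(counts, expected_depth, expected_warning):
    choice = select_depth(counts, min_occurrences=10)
    assert choice.depth == expected_depth
    assert choice.warning == expected_warning


def test_select_depth_empty_map_rejected():
    with pytest.raises(UsageError):
        select_depth({})


def test_match_counts_non_increasing_in_depth(ethanol):
    """Deeper motifs can only lose matches: an isomorphism of the (w+1)-ball
    restricts to one of the w-ball."""
    w_max = 3
    entries = index_structure(
        ethanol,
        [{"atom_id": a, "nucleus": "13C" if e == "C" else "1H", "shift": 10.0 + i}
         for i, (a, e) in enumerate(ethanol.atoms)],
        w_max=w_max,
    )
    for root in ("C1", "C2"):
        counts = [
            len(match_entries(entries, motif_key(ethanol, root, w).key, w))
            for w in range(1, w_max + 1)
        ]
        assert counts == sorted(counts, reverse=True)
        assert counts[0] >= 1


# ---------------------------------------------------------------------------
# mixture construction and summaries


def _entry(eid, shift, sigma=2.7, nucleus="13C", partner=None, keys=None):
    return DatabaseEntry(
        entry_id=eid, nucleus=nucleus, shift=shift, sigma=sigma,
        motif_keys=keys or {1: "k"}, partner_ref=partner,
    )


def test_single_entry_degenerates_to_gaussian():
    mix = build_db_density([_entry("e1", 59.5, 2.7)])
    assert isinstance(mix, ShiftMixture) and mix.n_components == 1
    g = ShiftGaussian(59.5, 2.7)
    for y in (55.0, 59.5, 61.2):
        assert mix.pdf(y) == pytest.approx(g.pdf(y), rel=1e-12)


def test_two_entry_mixture_center():
    mix = build_db_density([_entry("e1", 59.0, 1.0), _entry("e2", 60.0, 1.0)])
    center, _ = summarize_density(mix)
    assert center == pytest.approx(59.5)


def test_mixture_density_equals_direct_gaussian_sum():
    rng = np.random.default_rng(1)
    shifts = rng.uniform(20, 80, 7)
    sigmas = rng.uniform(0.5, 3.0, 7)
    mix = build_db_density([_entry(f"e{i}", s, g) for i, (s, g) in enumerate(zip(shifts, sigmas))])
    for y in (25.0, 47.3, 61.0):
        direct = np.mean([
            math.exp(-0.5 * ((y - m) / s) ** 2) / (s * math.sqrt(2 * math.pi))
            for m, s in zip(shifts, sigmas)
        ])
        assert mix.pdf(y) == pytest.approx(direct, rel=1e-12)


def test_no_matches_rejected():
    with pytest.raises(ValidationError, match="smaller"):
        build_db_density([])


def test_pair_mode_requires_partner():
    e = _entry("e1", 59.5)
    with pytest.raises(ValidationError, match="partner"):
        build_db_density([e], pair_mode=True, entry_lookup={"e1": e})


def test_summarize_mixture_total_variance():
    mix = ShiftMixture((ShiftGaussian(0.0, 1.0), ShiftGaussian(2.0, 1.0)))
    center, width = summarize_density(mix)
    assert center == pytest.approx(1.0)
    assert width == pytest.approx(math.sqrt(2.0))


def test_summarize_identical_components_width_is_component_sigma():
    mix = ShiftMixture((ShiftGaussian(5.0, 0.8),) * 4)
    center, width = summarize_density(mix)
    assert (center, width) == (pytest.approx(5.0), pytest.approx(0.8))


# ---------------------------------------------------------------------------
# end-to-end DB construction


def _halo_shift_table():
    # site-specific predicted shifts for the halo fixture molecule
    return [
        {"atom_id": "C1", "nucleus": "13C", "shift": 105.0, "sigma": 2.44},
        {"atom_id": "C2", "nucleus": "13C", "shift": 55.0, "sigma": 2.44},
        {"atom_id": "C3", "nucleus": "13C", "shift": 120.0, "sigma": 2.44},
        {"atom_id": "H1", "nucleus": "1H", "shift": 6.1, "sigma": 0.53},
        {"atom_id": "H2", "nucleus": "1H", "shift": 4.2, "sigma": 0.53},
    ]


def test_database_round_trip(tmp_path, halo_molecule):
    entries = index_structure(halo_molecule, _halo_shift_table(), w_max=3, structure_id="Q")
    path = tmp_path / "db.csv"
    write_database(entries, path)
    again = read_database(path)
    assert [(e.entry_id, e.nucleus, e.partner_ref) for e in entries] == [
        (e.entry_id, e.nucleus, e.partner_ref) for e in again
    ]
    for a, b in zip(entries, again):
        assert a.shift == b.shift and a.sigma == b.sigma and a.motif_keys == b.motif_keys


def test_db_mode_degenerates_to_xs_for_self_database(halo_molecule):
    """A database holding exactly the query's own sites as single entries
    reproduces the crystal-structure (single-Gaussian) marginals."""
    shifts = {"C1": 105.0, "C2": 55.0, "C3": 120.0, "H1": 6.1, "H2": 4.2}
    key2 = make_block_key(KIND_2D, "tertiary", "all")
    key1 = make_block_key(KIND_1D, "quaternary", "all")

    def fresh_items(with_density):
        def dens2(c, h):
            from shiftassign import ShiftGaussian2D
            return ShiftGaussian2D(ShiftGaussian(shifts[c], 2.44), ShiftGaussian(shifts[h], 0.53))

        return [
            PredictedItem(item_id="C1H1", kind=KIND_2D, carbon_site="C1", proton_site="H1",
                          block_key=key2, density=dens2("C1", "H1") if with_density else None),
            PredictedItem(item_id="C2H2", kind=KIND_2D, carbon_site="C2", proton_site="H2",
                          block_key=key2, density=dens2("C2", "H2") if with_density else None),
            PredictedItem(item_id="C3", kind=KIND_1D, carbon_site="C3",
                          block_key=key1, density=ShiftGaussian(shifts["C3"], 2.44) if with_density else None),
        ]

    peaks = [
        ExperimentalPeak(peak_id="a", shifts=(104.2, 6.3), block_key=key2),
        ExperimentalPeak(peak_id="b", shifts=(56.5, 4.0), block_key=key2),
        ExperimentalPeak(peak_id="q", shifts=(121.0,), block_key=key1),
    ]

    xs_marginals = [assign_block(b) for b in partition_blocks(fresh_items(True), peaks)]

    entries = index_structure(halo_molecule, _halo_shift_table(), w_max=3)
    db_items = fresh_items(False)
    diags = attach_db_densities(db_items, halo_molecule, entries, min_occurrences=1)
    assert all(d["n_matches"] == 1 for d in diags)  # every motif matches itself only
    db_marginals = [assign_block(b) for b in partition_blocks(db_items, peaks)]

    for mx, md in zip(xs_marginals, db_marginals):
        assert np.abs(mx.P - md.P).max() <= 1e-10


def test_graph_equivalent_sites_share_db_density(ethanol):
    """The three methyl protons of ethanol are graph-equivalent: a database
    indexed from the molecule assigns C1 one pair component per proton, and
    any C1-rooted query matches all of them (the Z'-blindness mechanism)."""
    shift_rows = [
        {"atom_id": "C1", "nucleus": "13C", "shift": 18.0},
        {"atom_id": "C2", "nucleus": "13C", "shift": 58.0},
        {"atom_id": "H1", "nucleus": "1H", "shift": 1.2},
        {"atom_id": "H2", "nucleus": "1H", "shift": 1.2},
        {"atom_id": "H3", "nucleus": "1H", "shift": 1.2},
        {"atom_id": "H4", "nucleus": "1H", "shift": 3.7},
        {"atom_id": "H5", "nucleus": "1H", "shift": 3.7},
    ]
    entries = index_structure(ethanol, shift_rows, w_max=2)
    carbon_entries = [e for e in entries if e.nucleus == "13C" and e.entry_id.startswith("S:C1")]
    assert len(carbon_entries) == 3  # one pair entry per attached proton
    key = motif_key(ethanol, "C1", 2).key
    assert len(match_entries(entries, key, 2, require_partner=True)) == 3
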