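"""Fragment motifs and database-derived mixture densities (the DB branch).

A *fragment motif* is the covalent neighbourhood within ``w`` bonds of a
target atom: the induced subgraph on all atoms at graph distance ≤ w from
the root, with element labels and bond orders, the root distinguished, and
ring closures preserved.  Two rooted environments receive the same canonical
key iff they are isomorphic by a root-preserving, element- and
bond-order-respecting isomorphism.

Keys are computed by iterative neighbourhood refinement (Morgan-style
invariants seeded with element and distance-from-root) followed by
individualisation when symmetry leaves colour classes unresolved; the
serialisation of the final discrete colouring is the key.  This is exact
canonicalisation — deterministic and independent of atom input order.

Matching a query site against a shift database proceeds depth-first: the
deepest motif that still retains a statistically significant number of
database occurrences (by default at least 10) is chosen, and the matched
entries' predicted shifts and uncertainties become the components of a
uniform-weight Gaussian mixture.  For 2D cross-peaks the carbon and proton
components of one matched fragment stay paired.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import math

import pandas as pd

from .densities import (
    Density1D,
    ShiftGaussian,
    ShiftMixture,
    ShiftMixture2D,
)
from .errors import UsageError, ValidationError
from .model import (
    C13,
    DEFAULT_SIGMA_PPM,
    H1,
    KIND_2D,
    DatabaseEntry,
    MoleculeGraph,
    PredictedItem,
)

#: Default minimum number of database occurrences a motif must retain.
MIN_OCCURRENCES = 10


@dataclass(frozen=True)
class FragmentMotif:
    """Canonical key of the depth-w covalent neighbourhood rooted at an atom."""

    root_atom_id: str
    depth: int
    key: str


# ---------------------------------------------------------------------------
# canonical rooted-subgraph keys


def _refine(colors: dict, adj: dict) -> dict:
    """Iterative colour refinement until the partition is stable."""
    while True:
        sigs = {
            v: (colors[v], tuple(sorted((order, colors[u]) for u, order in adj[v])))
            for v in colors
        }
        ranking = {s: r for r, s in enumerate(sorted(set(sigs.values())))}
        new = {v: ranking[sigs[v]] for v in colors}
        if new == colors:
            return colors
        colors = new


def _serialize(order: list, dist: dict, elem: dict, adj: dict) -> str:
    rank = {v: r for r, v in enumerate(order)}
    nodes = ",".join(f"{elem[v]}:{dist[v]}" for v in order)
    edges = sorted(
        (min(rank[a], rank[b]), max(rank[a], rank[b]), o)
        for a in order
        for b, o in adj[a]
        if rank[a] < rank[b]
    )
    return nodes + ";" + ",".join(f"{a}-{b}:{o}" for a, b, o in edges)


def _canonical(colors: dict, dist: dict, elem: dict, adj: dict) -> str:
    """Individualisation–refinement: smallest serialisation over symmetry."""
    colors = _refine(colors, adj)
    cells: dict[int, list] = {}
    for v, c in colors.items():
        cells.setdefault(c, []).append(v)
    target = None
    for c in sorted(cells):
        if len(cells[c]) > 1:
            target = cells[c]
            break
    if target is None:
        order = sorted(colors, key=colors.get)
        return _serialize(order, dist, elem, adj)
    best = None
    for v in target:
        branched = {u: (colors[u], 1 if u == v else 0) for u in colors}
        ranking = {s: r for r, s in enumerate(sorted(set(branched.values())))}
        key = _canonical({u: ranking[branched[u]] for u in colors}, dist, elem, adj)
        if best is None or key < best:
            best = key
    return best


def motif_key(graph: MoleculeGraph, atom_id: str, depth: int) -> FragmentMotif:
    """Canonical key of the induced subgraph within ``depth`` bonds of ``atom_id``."""
    if depth < 1:
        raise UsageError(f"motif depth must be >= 1, got {depth}")
    if atom_id not in set(graph.atom_ids):
        raise ValidationError(f"unknown atom {atom_id}")
    # BFS ball of radius `depth`
    dist = {atom_id: 0}
    frontier = [atom_id]
    for d in range(1, depth + 1):
        nxt = []
        for v in frontier:
            for u, _ in graph.neighbors(v):
                if u not in dist:
                    dist[u] = d
                    nxt.append(u)
        frontier = nxt
    adj = {
        v: [(u, o) for u, o in graph.neighbors(v) if u in dist] for v in dist
    }
    elem = {v: graph.element(v) for v in dist}
    init_sigs = {v: (dist[v], elem[v]) for v in dist}
    ranking = {s: r for r, s in enumerate(sorted(set(init_sigs.values())))}
    key = _canonical({v: ranking[init_sigs[v]] for v in dist}, dist, elem, adj)
    return FragmentMotif(root_atom_id=atom_id, depth=depth, key=f"w{depth}|{key}")


# ---------------------------------------------------------------------------
# depth selection and mixture construction


@dataclass(frozen=True)
class DepthChoice:
    depth: int
    warning: bool = False  # True when even depth 1 is below min_occurrences


def select_depth(match_counts: dict[int, int], min_occurrences: int = MIN_OCCURRENCES) -> DepthChoice:
    """Largest depth whose motif still has at least ``min_occurrences`` matches.

    Falls back to depth 1 (with a warning flag) when even the shallowest
    motif is rarer than requested.
    """
    if not match_counts:
        raise UsageError("empty match-count map")
    qualifying = [w for w, c in match_counts.items() if c >= min_occurrences]
    if not qualifying:
        return DepthChoice(depth=1, warning=True)
    return DepthChoice(depth=max(qualifying), warning=False)


def match_entries(
    entries: list[DatabaseEntry],
    key: str,
    depth: int,
    nucleus: str = C13,
    require_partner: bool = False,
) -> list[DatabaseEntry]:
    """Database entries of the given nucleus whose depth-``depth`` key equals ``key``."""
    return [
        e
        for e in entries
        if e.nucleus == nucleus
        and e.motif_keys.get(depth) == key
        and (e.partner_ref is not None or not require_partner)
    ]


def build_db_density(
    entries: list[DatabaseEntry],
    pair_mode: bool = False,
    entry_lookup: Optional[dict[str, DatabaseEntry]] = None,
) -> Union[ShiftMixture, ShiftMixture2D]:
    """Uniform-weight mixture with one component (or component pair) per match."""
    if not entries:
        raise ValidationError(
            "no matched database entries; try a smaller motif depth"
        )
    if not pair_mode:
        return ShiftMixture(tuple(ShiftGaussian(e.shift, e.sigma) for e in entries))
    if entry_lookup is None:
        raise UsageError("pair_mode requires an entry lookup for partner resolution")
    components = []
    for e in entries:
        if not e.partner_ref:
            raise ValidationError(f"entry {e.entry_id}: pair mode requires a partner_ref")
        partner = entry_lookup.get(e.partner_ref)
        if partner is None:
            raise ValidationError(
                f"entry {e.entry_id}: partner {e.partner_ref!r} not in the database"
            )
        components.append(
            (ShiftGaussian(e.shift, e.sigma), ShiftGaussian(partner.shift, partner.sigma))
        )
    return ShiftMixture2D(tuple(components))


def summarize_density(density: Density1D) -> tuple[float, float]:
    """(center, width) of a 1D density: mixture mean and total standard deviation.

    For a uniform mixture the variance follows the law of total variance:
    mean of component variances plus variance of component means.
    """
    if isinstance(density, ShiftGaussian):
        return density.mean, density.sigma
    if isinstance(density, ShiftMixture):
        means = [c.mean for c in density.components]
        sigmas = [c.sigma for c in density.components]
        k = len(means)
        center = sum(means) / k
        var = sum(s * s for s in sigmas) / k + sum((m - center) ** 2 for m in means) / k
        return center, math.sqrt(var)
    raise UsageError("summarize_density expects a 1D density")


# ---------------------------------------------------------------------------
# query-side matching and database construction


def attach_db_densities(
    items: list[PredictedItem],
    graph: MoleculeGraph,
    entries: list[DatabaseEntry],
    min_occurrences: int = MIN_OCCURRENCES,
    w_max: Optional[int] = None,
) -> list[dict]:
    """Attach DB-mode mixture densities to items by fragment matching.

    For each item the carbon site's motif keys are computed for depths
    1..w_max, the deepest depth retaining ``min_occurrences`` matches is
    selected, and the matched entries become the mixture components (paired
    carbon/proton components for 2D items).  Returns per-item diagnostics
    (chosen depth, number of matches, low-occurrence warning).

    Note: graph-equivalent sites — including corresponding atoms of the two
    molecules of a Z' = 2 crystal — receive exactly the same density; this
    is an intrinsic limitation of the database route, reproduced here on
    purpose.
    """
    if not entries:
        raise ValidationError("empty database")
    if w_max is None:
        w_max = min(max(e.motif_keys) for e in entries)
    entry_lookup = {e.entry_id: e for e in entries}
    diagnostics = []
    for item in items:
        pair_mode = item.kind == KIND_2D
        keys = {w: motif_key(graph, item.carbon_site, w).key for w in range(1, w_max + 1)}
        matched_by_w = {
            w: match_entries(entries, keys[w], w, nucleus=C13, require_partner=pair_mode)
            for w in range(1, w_max + 1)
        }
        counts = {w: len(m) for w, m in matched_by_w.items()}
        choice = select_depth(counts, min_occurrences=min_occurrences)
        matched = matched_by_w[choice.depth]
        if not matched:
            raise ValidationError(
                f"site {item.carbon_site}: no database match at any depth 1..{w_max}"
            )
        item.density = build_db_density(matched, pair_mode=pair_mode, entry_lookup=entry_lookup)
        diagnostics.append(
            {
                "item_id": item.item_id,
                "depth": choice.depth,
                "n_matches": counts[choice.depth],
                "low_occurrence_warning": choice.warning,
            }
        )
    return diagnostics


def _shift_rows(shifts) -> list[dict]:
    if isinstance(shifts, pd.DataFrame):
        required = {"atom_id", "nucleus", "shift"}
        missing = required - set(shifts.columns)
        if missing:
            raise ValidationError(f"shift table missing column(s): {', '.join(sorted(missing))}")
        return shifts.to_dict("records")
    return list(shifts)


def index_structure(
    graph: MoleculeGraph,
    shifts,
    w_max: int,
    structure_id: str = "S",
) -> list[DatabaseEntry]:
    """Build database entries for one structure (the indexing pass).

    ``shifts`` is a table (DataFrame or list of dicts) with columns atom_id,
    nucleus, shift and optional sigma (defaulting to the predictor accuracy
    for that nucleus).  Each proton-bearing carbon produces one entry per
    attached proton with a shift, so a CH2 contributes two carbon–proton pair
    components; quaternary carbons produce a single unpaired entry.  Proton
    entries point back to their carbon.
    """
    if w_max < 1:
        raise UsageError("w_max must be >= 1")
    by_atom: dict[str, tuple[str, float, float]] = {}
    for row in _shift_rows(shifts):
        atom_id = str(row["atom_id"]).strip()
        nucleus = str(row["nucleus"]).strip()
        if nucleus not in (C13, H1):
            raise ValidationError(f"atom {atom_id}: unknown nucleus {nucleus!r}")
        sigma_raw = row.get("sigma", "")
        sigma = (
            DEFAULT_SIGMA_PPM[nucleus]
            if sigma_raw in ("", None) or (isinstance(sigma_raw, float) and math.isnan(sigma_raw))
            else float(sigma_raw)
        )
        by_atom[atom_id] = (nucleus, float(row["shift"]), sigma)

    atom_ids = set(graph.atom_ids)
    for atom_id in by_atom:
        if atom_id not in atom_ids:
            raise ValidationError(f"shift table references unknown atom {atom_id!r}")

    keys_cache: dict[str, dict[int, str]] = {}

    def keys_for(atom_id: str) -> dict[int, str]:
        if atom_id not in keys_cache:
            keys_cache[atom_id] = {
                w: motif_key(graph, atom_id, w).key for w in range(1, w_max + 1)
            }
        return keys_cache[atom_id]

    entries: list[DatabaseEntry] = []
    for atom_id, elem in graph.atoms:
        if atom_id not in by_atom:
            continue
        nucleus, shift, sigma = by_atom[atom_id]
        if nucleus == H1:
            carbon = next(
                (
                    u
                    for u, _ in graph.neighbors(atom_id)
                    if graph.element(u) == "C" and u in by_atom and by_atom[u][0] == C13
                ),
                None,
            )
            entries.append(
                DatabaseEntry(
                    entry_id=f"{structure_id}:{atom_id}",
                    nucleus=H1,
                    shift=shift,
                    sigma=sigma,
                    motif_keys=keys_for(atom_id),
                    # back-reference to the carbon–proton pair entry this
                    # proton participates in, when that carbon is indexed
                    partner_ref=f"{structure_id}:{carbon}-{atom_id}" if carbon else None,
                )
            )
            continue
        protons = [
            u
            for u, _ in graph.neighbors(atom_id)
            if graph.element(u) == "H" and u in by_atom
        ]
        if not protons:
            entries.append(
                DatabaseEntry(
                    entry_id=f"{structure_id}:{atom_id}",
                    nucleus=nucleus,
                    shift=shift,
                    sigma=sigma,
                    motif_keys=keys_for(atom_id),
                )
            )
        else:
            for h in sorted(protons):
                entries.append(
                    DatabaseEntry(
                        entry_id=f"{structure_id}:{atom_id}-{h}",
                        nucleus=nucleus,
                        shift=shift,
                        sigma=sigma,
                        motif_keys=keys_for(atom_id),
                        partner_ref=f"{structure_id}:{h}",
                    )
                )
    if not entries:
        raise ValidationError("no database entries produced (no shifts matched the graph)")
    return entries
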