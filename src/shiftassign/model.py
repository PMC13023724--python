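"""Domain types: predicted items, experimental peaks, blocks, molecules, database entries.

An *assignment block* is the unit the Bayesian engine works on: a set of
predicted items and a set of experimental peaks, of equal size, between which
a bijection is sought.  Blocks are formed by exact equality of a *block key*
``(nuclei, multiplicity, region)`` — carbon multiplicity (quaternary /
tertiary / secondary / primary) and spectral region (e.g. aromatic vs
aliphatic) are the two classifications used to subdivide peaks during
post-processing.  A molecule copy label (for crystals with more than one
molecule in the asymmetric unit, Z' > 1) deliberately does **not** enter the
block key: the copies compete for the same peaks inside one block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .densities import Density, is_2d
from .errors import ValidationError

C13 = "13C"
H1 = "1H"

#: Default prediction uncertainties (ppm) applied when a sigma column is
#: absent: the reported accuracies of the machine-learned shift predictor
#: for 13C and 1H.
DEFAULT_SIGMA_PPM = {C13: 2.44, H1: 0.53}

KIND_1D = "C_quaternary_1D"
KIND_2D = "CH_pair_2D"

#: Conventional display order of multiplicity classes; unknown labels sort after.
MULTIPLICITY_ORDER = {"quaternary": 0, "tertiary": 1, "secondary": 2, "primary": 3}

BlockKey = tuple[tuple[str, ...], str, str]


def make_block_key(kind: str, multiplicity: str, region: str) -> BlockKey:
    nuclei = (C13,) if kind == KIND_1D else (C13, H1)
    return (nuclei, str(multiplicity), str(region))


def block_key_str(key: BlockKey) -> str:
    nuclei, mult, region = key
    return f"{'-'.join(nuclei)}|{mult}|{region}"


def block_sort_key(key: BlockKey):
    nuclei, mult, region = key
    return (MULTIPLICITY_ORDER.get(mult, 99), mult, region, len(nuclei))


@dataclass
class PredictedItem:
    """One assignable unit: a quaternary carbon (1D) or a bonded C–H pair (2D).

    ``density`` may be ``None`` for items read in DB mode before fragment
    matching has attached a mixture density.
    """

    item_id: str
    kind: str
    carbon_site: str
    block_key: BlockKey
    proton_site: str = ""
    density: Optional[Density] = None
    molecule_copy: str = ""

    def __post_init__(self) -> None:
        if self.kind not in (KIND_1D, KIND_2D):
            raise ValidationError(f"unknown item kind {self.kind!r}")
        if not self.block_key or len(self.block_key) != 3:
            raise ValidationError("block_key must be a (nuclei, multiplicity, region) tuple")
        if self.kind == KIND_2D and not self.proton_site:
            raise ValidationError(f"item {self.item_id}: 2D CH pair needs a proton site")
        if self.density is not None:
            if is_2d(self.density) != (self.kind == KIND_2D):
                raise ValidationError(
                    f"item {self.item_id}: density dimensionality does not match kind {self.kind}"
                )

    @property
    def ndim(self) -> int:
        return 2 if self.kind == KIND_2D else 1


@dataclass
class ExperimentalPeak:
    """An observed resonance: one ¹³C shift (1D) or a (¹³C, ¹H) cross-peak (2D).

    ``label`` is the alphabetical within-block label assigned in order of
    decreasing ¹³C shift (a, b, c, ...).
    """

    peak_id: str
    shifts: tuple[float, ...]
    block_key: BlockKey
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.shifts) not in (1, 2):
            raise ValidationError(f"peak {self.peak_id}: needs 1 or 2 shifts")
        if not all(math.isfinite(s) for s in self.shifts):
            raise ValidationError(f"peak {self.peak_id}: non-finite shift value")
        expected = len(self.block_key[0])
        if len(self.shifts) != expected:
            raise ValidationError(
                f"peak {self.peak_id}: {len(self.shifts)} shifts but block expects {expected}"
            )

    @property
    def c_shift(self) -> float:
        return self.shifts[0]

    @property
    def h_shift(self) -> Optional[float]:
        return self.shifts[1] if len(self.shifts) == 2 else None

    @property
    def ndim(self) -> int:
        return len(self.shifts)


@dataclass
class AssignmentBlock:
    """Equal-cardinality items and peaks sharing one block key (bijection domain)."""

    block_key: BlockKey
    items: list[PredictedItem]
    peaks: list[ExperimentalPeak]

    def __post_init__(self) -> None:
        if len(self.items) != len(self.peaks):
            raise ValidationError(
                f"block {block_key_str(self.block_key)}: {len(self.items)} items vs "
                f"{len(self.peaks)} peaks (a bijection requires equal counts)"
            )
        if len(self.items) == 0:
            raise ValidationError(f"block {block_key_str(self.block_key)}: empty")
        for it in self.items:
            if it.block_key != self.block_key:
                raise ValidationError(f"item {it.item_id} does not belong to this block")
        for pk in self.peaks:
            if pk.block_key != self.block_key:
                raise ValidationError(f"peak {pk.peak_id} does not belong to this block")
        ndims = {it.ndim for it in self.items} | {pk.ndim for pk in self.peaks}
        if len(ndims) != 1:
            raise ValidationError(
                f"block {block_key_str(self.block_key)}: mixed dimensionality"
            )

    @property
    def size(self) -> int:
        return len(self.items)

    @property
    def ndim(self) -> int:
        return self.items[0].ndim


def partition_blocks(
    items: list[PredictedItem], peaks: list[ExperimentalPeak]
) -> list[AssignmentBlock]:
    """Group items and peaks into assignment blocks by exact block-key equality.

    Raises
    ------
    ValidationError
        If a block key occurs on only one side (orphan), or if the item and
        peak counts within a block differ.
    """
    items_by_key: dict[BlockKey, list[PredictedItem]] = {}
    for it in items:
        items_by_key.setdefault(it.block_key, []).append(it)
    peaks_by_key: dict[BlockKey, list[ExperimentalPeak]] = {}
    for pk in peaks:
        peaks_by_key.setdefault(pk.block_key, []).append(pk)

    only_items = set(items_by_key) - set(peaks_by_key)
    only_peaks = set(peaks_by_key) - set(items_by_key)
    if only_items or only_peaks:
        parts = []
        if only_items:
            parts.append(
                "block keys with items but no peaks: "
                + ", ".join(sorted(block_key_str(k) for k in only_items))
            )
        if only_peaks:
            parts.append(
                "block keys with peaks but no items: "
                + ", ".join(sorted(block_key_str(k) for k in only_peaks))
            )
        raise ValidationError("; ".join(parts))

    blocks = []
    for key in sorted(items_by_key, key=block_sort_key):
        bi, bp = items_by_key[key], peaks_by_key[key]
        if len(bi) != len(bp):
            raise ValidationError(
                f"block {block_key_str(key)}: {len(bi)} items vs {len(bp)} peaks"
            )
        blocks.append(AssignmentBlock(block_key=key, items=bi, peaks=bp))
    return blocks


@dataclass
class MoleculeGraph:
    """Covalent connectivity with explicit hydrogens.

    atoms: list of (atom_id, element symbol); bonds: (atom_a, atom_b, order)
    with integer order (aromatic encoded as 4).
    """

    atoms: list[tuple[str, str]]
    bonds: list[tuple[str, str, int]]
    _adj: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        ids = [a for a, _ in self.atoms]
        idset = set(ids)
        if len(ids) != len(idset):
            raise ValidationError("duplicate atom ids in molecule")
        seen = set()
        adj: dict[str, list[tuple[str, int]]] = {a: [] for a in ids}
        for a, b, order in self.bonds:
            if a not in idset or b not in idset:
                raise ValidationError(f"bond ({a}, {b}) references a nonexistent atom")
            if a == b:
                raise ValidationError(f"self-bond on atom {a}")
            edge = frozenset((a, b))
            if edge in seen:
                raise ValidationError(f"duplicate bond ({a}, {b})")
            seen.add(edge)
            adj[a].append((b, int(order)))
            adj[b].append((a, int(order)))
        self._adj = adj
        self._elements = dict(self.atoms)

    def element(self, atom_id: str) -> str:
        return self._elements[atom_id]

    def neighbors(self, atom_id: str) -> list[tuple[str, int]]:
        """Bonded neighbours of an atom as (neighbour_id, bond_order)."""
        if atom_id not in self._adj:
            raise ValidationError(f"unknown atom {atom_id}")
        return list(self._adj[atom_id])

    @property
    def atom_ids(self) -> list[str]:
        return [a for a, _ in self.atoms]


@dataclass
class DatabaseEntry:
    """One database atom: predicted shift, uncertainty, and its motif keys per depth."""

    entry_id: str
    nucleus: str
    shift: float
    sigma: float
    motif_keys: dict[int, str]
    partner_ref: Optional[str] = None

    def __post_init__(self) -> None:
        if not (self.sigma > 0 and math.isfinite(self.sigma)):
            raise ValidationError(f"entry {self.entry_id}: sigma must be > 0")
        depths = sorted(self.motif_keys)
        if depths != list(range(1, len(depths) + 1)):
            raise ValidationError(
                f"entry {self.entry_id}: motif keys must cover depths 1..w_max contiguously"
            )
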