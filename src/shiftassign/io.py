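"""Readers and writers for the tabular interchange formats.

All tables are comma-separated UTF-8 text with a mandatory header row and
"." as the decimal separator.  Axis order for 2D cross-peaks is fixed as
(¹³C ppm, ¹H ppm) everywhere, in files and in memory.

predicted.csv columns
    item_id, carbon_site, proton_site, kind, multiplicity, region,
    molecule_copy, c_shift, c_sigma, h_shift, h_sigma
    (``carbon_site``/``proton_site``/``molecule_copy`` and the sigma columns
    are optional; sigmas default to the predictor accuracies 2.44 ppm for
    ¹³C and 0.53 ppm for ¹H.  In DB mode the shift columns are ignored —
    densities come from fragment matching against the database.)

peaks.csv columns
    peak_id, multiplicity, region, c_shift, h_shift (h_shift empty for 1D)

database.csv columns
    entry_id, nucleus, shift, sigma, partner_ref, key_w1, key_w2, ...

Molecular connectivity is read either from a MOL V2000 file (parsed with
RDKit, hydrogens kept explicit, no sanitisation so raw bond orders are
preserved) or from an atoms.csv (atom_id, element) / bonds.csv
(atom_a, atom_b, order) pair.
"""

from __future__ import annotations

import json
import math
import re
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .densities import ShiftGaussian, ShiftGaussian2D
from .errors import FormatError, UsageError, ValidationError
from .model import (
    C13,
    DEFAULT_SIGMA_PPM,
    H1,
    KIND_1D,
    KIND_2D,
    DatabaseEntry,
    ExperimentalPeak,
    MoleculeGraph,
    PredictedItem,
    block_key_str,
    block_sort_key,
    make_block_key,
)

_KIND_ALIASES = {
    "quaternary": KIND_1D,
    "c": KIND_1D,
    "c_quaternary_1d": KIND_1D,
    "1d": KIND_1D,
    "ch": KIND_2D,
    "ch_pair": KIND_2D,
    "ch_pair_2d": KIND_2D,
    "2d": KIND_2D,
}

PREDICTED_COLUMNS = [
    "item_id", "carbon_site", "proton_site", "kind", "multiplicity", "region",
    "molecule_copy", "c_shift", "c_sigma", "h_shift", "h_sigma",
]
PEAK_COLUMNS = ["peak_id", "multiplicity", "region", "c_shift", "h_shift"]


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: could not parse CSV ({exc})") from exc
    df.columns = [str(c).strip() for c in df.columns]
    return df


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")


def _get(row, col: str) -> str:
    v = row.get(col, "")
    return "" if v is None else str(v).strip()


def _parse_float(value: str, what: str, rownum: int, path) -> float:
    try:
        x = float(value)
    except ValueError:
        raise ValidationError(f"{path} row {rownum}: {what} is not a number: {value!r}")
    if not math.isfinite(x):
        raise ValidationError(f"{path} row {rownum}: {what} must be finite")
    return x


def _parse_sigma(value: str, nucleus: str, rownum: int, path,
                 defaults: dict[str, float]) -> float:
    if value == "":
        return defaults[nucleus]
    x = _parse_float(value, f"{nucleus} sigma", rownum, path)
    if x <= 0:
        raise ValidationError(f"{path} row {rownum}: {nucleus} sigma must be > 0, got {value}")
    return x


def _apply_reference(shift: float, nucleus: str,
                     reference: Optional[dict[str, tuple[float, float]]]) -> float:
    """Optional affine conversion (slope, intercept) per nucleus, e.g. shielding→shift."""
    if reference and nucleus in reference:
        slope, intercept = reference[nucleus]
        return slope * shift + intercept
    return shift


def read_predicted_table(
    path,
    mode: str = "xs",
    sigma_defaults: Optional[dict[str, float]] = None,
    reference: Optional[dict[str, tuple[float, float]]] = None,
) -> list[PredictedItem]:
    """Read predicted items (one per row, order preserved).

    In ``xs`` mode each row carries predicted shifts and a single-Gaussian
    density is built (2D rows get the product of the carbon and proton
    marginals).  In ``db`` mode only the identity/block columns are needed;
    densities are attached later by fragment matching.
    """
    if mode not in ("xs", "db"):
        raise UsageError(f"unknown mode {mode!r}")
    defaults = dict(DEFAULT_SIGMA_PPM)
    if sigma_defaults:
        defaults.update(sigma_defaults)
    df = _read_csv(path)
    required = ["item_id", "kind", "multiplicity", "region"]
    if mode == "xs":
        required.append("c_shift")
    else:
        required.append("carbon_site")
    _require_columns(df, required, path)

    items: list[PredictedItem] = []
    seen_ids: set[str] = set()
    for n, (_, row) in enumerate(df.iterrows(), start=2):  # header is line 1
        item_id = _get(row, "item_id")
        if not item_id:
            raise ValidationError(f"{path} row {n}: empty item_id")
        if item_id in seen_ids:
            raise ValidationError(f"{path} row {n}: duplicate item_id {item_id!r}")
        seen_ids.add(item_id)
        kind_raw = _get(row, "kind").lower()
        if kind_raw not in _KIND_ALIASES:
            raise ValidationError(f"{path} row {n}: unknown kind {kind_raw!r}")
        kind = _KIND_ALIASES[kind_raw]
        carbon_site = _get(row, "carbon_site") or item_id
        proton_site = _get(row, "proton_site")
        if kind == KIND_2D and not proton_site and mode == "db":
            raise ValidationError(f"{path} row {n}: CH pair needs a proton_site in db mode")
        if kind == KIND_2D and not proton_site:
            proton_site = item_id + ".H"
        key = make_block_key(kind, _get(row, "multiplicity"), _get(row, "region"))

        density = None
        if mode == "xs":
            c_shift = _apply_reference(
                _parse_float(_get(row, "c_shift"), "c_shift", n, path), C13, reference
            )
            c_sigma = _parse_sigma(_get(row, "c_sigma"), C13, n, path, defaults)
            c_gauss = ShiftGaussian(c_shift, c_sigma)
            if kind == KIND_2D:
                h_raw = _get(row, "h_shift")
                if h_raw == "":
                    raise ValidationError(f"{path} row {n}: CH pair is missing h_shift")
                h_shift = _apply_reference(
                    _parse_float(h_raw, "h_shift", n, path), H1, reference
                )
                h_sigma = _parse_sigma(_get(row, "h_sigma"), H1, n, path, defaults)
                density = ShiftGaussian2D(c_gauss, ShiftGaussian(h_shift, h_sigma))
            else:
                density = c_gauss

        items.append(
            PredictedItem(
                item_id=item_id,
                kind=kind,
                carbon_site=carbon_site,
                proton_site=proton_site,
                block_key=key,
                density=density,
                molecule_copy=_get(row, "molecule_copy"),
            )
        )
    return items


def write_predicted_table(items: list[PredictedItem], path) -> None:
    """Write items with single-Gaussian (XS-style) densities back to CSV."""
    rows = []
    for it in items:
        row = {
            "item_id": it.item_id,
            "carbon_site": it.carbon_site,
            "proton_site": it.proton_site,
            "kind": it.kind,
            "multiplicity": it.block_key[1],
            "region": it.block_key[2],
            "molecule_copy": it.molecule_copy,
            "c_shift": "", "c_sigma": "", "h_shift": "", "h_sigma": "",
        }
        d = it.density
        if isinstance(d, ShiftGaussian):
            row["c_shift"], row["c_sigma"] = repr(d.mean), repr(d.sigma)
        elif isinstance(d, ShiftGaussian2D):
            row["c_shift"], row["c_sigma"] = repr(d.carbon.mean), repr(d.carbon.sigma)
            row["h_shift"], row["h_sigma"] = repr(d.proton.mean), repr(d.proton.sigma)
        elif d is not None:
            raise UsageError(
                f"item {it.item_id}: mixture densities have no tabular shift form"
            )
        rows.append(row)
    pd.DataFrame(rows, columns=PREDICTED_COLUMNS).to_csv(path, index=False)


def _peak_labels(n: int) -> list[str]:
    """a, b, ..., z, aa, ab, ... (base-26, lowercase)."""
    labels = []
    for i in range(n):
        s = ""
        k = i
        while True:
            s = chr(ord("a") + k % 26) + s
            k = k // 26 - 1
            if k < 0:
                break
        labels.append(s)
    return labels


def read_peak_table(path) -> list[ExperimentalPeak]:
    """Read experimental peaks; within each block peaks are sorted by
    decreasing ¹³C shift (ties: increasing ¹H shift, then file order) and
    labelled alphabetically in that order."""
    df = _read_csv(path)
    _require_columns(df, ["peak_id", "multiplicity", "region", "c_shift"], path)
    has_h = "h_shift" in df.columns

    raw: list[tuple[ExperimentalPeak, int]] = []
    seen_ids: set[str] = set()
    for n, (_, row) in enumerate(df.iterrows(), start=2):
        peak_id = _get(row, "peak_id")
        if not peak_id:
            raise ValidationError(f"{path} row {n}: empty peak_id")
        if peak_id in seen_ids:
            raise ValidationError(f"{path} row {n}: duplicate peak_id {peak_id!r}")
        seen_ids.add(peak_id)
        c_shift = _parse_float(_get(row, "c_shift"), "c_shift", n, path)
        h_raw = _get(row, "h_shift") if has_h else ""
        if h_raw == "":
            shifts: tuple[float, ...] = (c_shift,)
            kind = KIND_1D
        else:
            shifts = (c_shift, _parse_float(h_raw, "h_shift", n, path))
            kind = KIND_2D
        key = make_block_key(kind, _get(row, "multiplicity"), _get(row, "region"))
        raw.append((ExperimentalPeak(peak_id=peak_id, shifts=shifts, block_key=key), n))

    # dimensionality must be uniform within a (multiplicity, region) group
    dims_by_group: dict[tuple[str, str], set[int]] = {}
    for pk, _ in raw:
        dims_by_group.setdefault((pk.block_key[1], pk.block_key[2]), set()).add(pk.ndim)
    for group, dims in dims_by_group.items():
        if len(dims) > 1:
            raise ValidationError(
                f"{path}: mixed 1D/2D peaks within block (multiplicity={group[0]!r}, "
                f"region={group[1]!r})"
            )

    by_key: dict = {}
    for pk, n in raw:
        by_key.setdefault(pk.block_key, []).append((pk, n))

    out: list[ExperimentalPeak] = []
    for key in sorted(by_key, key=block_sort_key):
        group = by_key[key]
        group.sort(key=lambda t: (-t[0].c_shift, t[0].h_shift or 0.0, t[1]))
        labels = _peak_labels(len(group))
        for (pk, _), label in zip(group, labels):
            pk.label = label
            out.append(pk)
    return out


def write_peak_table(peaks: list[ExperimentalPeak], path) -> None:
    rows = []
    for pk in peaks:
        rows.append({
            "peak_id": pk.peak_id,
            "multiplicity": pk.block_key[1],
            "region": pk.block_key[2],
            "c_shift": repr(pk.c_shift),
            "h_shift": "" if pk.h_shift is None else repr(pk.h_shift),
        })
    pd.DataFrame(rows, columns=PEAK_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# molecular connectivity


_RDKIT_ORDER = {"SINGLE": 1, "DOUBLE": 2, "TRIPLE": 3, "AROMATIC": 4}


def read_molfile(path, atoms_path=None) -> MoleculeGraph:
    """Read molecular connectivity.

    ``path`` may be a MOL/SDF V2000 file, or a bonds.csv (atom_a, atom_b,
    order) in which case ``atoms_path`` must name the atoms.csv
    (atom_id, element) table.  Atom ids for MOL input are per-element
    counters in file order: C1, C2, ..., H1, H2, ...
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    if path.suffix.lower() in (".mol", ".sdf", ".mdl"):
        return _read_mol_v2000(path)
    if atoms_path is None:
        raise FormatError(
            f"{path}: bond-list input needs a companion atom table (atoms_path)"
        )
    return read_bondlist(atoms_path, path)


def _read_mol_v2000(path: Path) -> MoleculeGraph:
    from rdkit import Chem, RDLogger

    RDLogger.DisableLog("rdApp.*")
    mol = Chem.MolFromMolBlock(
        path.read_text(), sanitize=False, removeHs=False, strictParsing=True
    )
    if mol is None:
        raise FormatError(f"{path}: malformed MOL V2000 block")
    counters: dict[str, int] = {}
    ids: list[str] = []
    atoms: list[tuple[str, str]] = []
    for atom in mol.GetAtoms():
        elem = atom.GetSymbol()
        counters[elem] = counters.get(elem, 0) + 1
        aid = f"{elem}{counters[elem]}"
        ids.append(aid)
        atoms.append((aid, elem))
    bonds: list[tuple[str, str, int]] = []
    for bond in mol.GetBonds():
        name = str(bond.GetBondType())
        if name in _RDKIT_ORDER:
            order = _RDKIT_ORDER[name]
        else:
            order = int(round(bond.GetBondTypeAsDouble()))
            if order <= 0:
                raise FormatError(f"{path}: unsupported bond type {name}")
        bonds.append((ids[bond.GetBeginAtomIdx()], ids[bond.GetEndAtomIdx()], order))
    return MoleculeGraph(atoms=atoms, bonds=bonds)


def read_bondlist(atoms_path, bonds_path) -> MoleculeGraph:
    """Read an atoms.csv (atom_id, element) / bonds.csv (atom_a, atom_b, order) pair."""
    adf = _read_csv(atoms_path)
    _require_columns(adf, ["atom_id", "element"], atoms_path)
    bdf = _read_csv(bonds_path)
    _require_columns(bdf, ["atom_a", "atom_b", "order"], bonds_path)
    atoms = [(_get(r, "atom_id"), _get(r, "element")) for _, r in adf.iterrows()]
    bonds = []
    for n, (_, r) in enumerate(bdf.iterrows(), start=2):
        order_raw = _get(r, "order") or "1"
        try:
            order = int(order_raw)
        except ValueError:
            raise FormatError(f"{bonds_path} row {n}: bond order is not an integer: {order_raw!r}")
        bonds.append((_get(r, "atom_a"), _get(r, "atom_b"), order))
    try:
        return MoleculeGraph(atoms=atoms, bonds=bonds)
    except ValidationError as exc:
        raise FormatError(f"{bonds_path}: {exc}") from exc


# ---------------------------------------------------------------------------
# shift database


_KEY_COL = re.compile(r"^key_w(\d+)$")


def read_database(path) -> list[DatabaseEntry]:
    df = _read_csv(path)
    _require_columns(df, ["entry_id", "nucleus", "shift", "sigma"], path)
    depth_cols = sorted(
        ((int(m.group(1)), c) for c in df.columns if (m := _KEY_COL.match(c))),
    )
    if not depth_cols:
        raise FormatError(f"{path}: no motif key columns (key_w1, key_w2, ...)")
    entries = []
    seen: set[str] = set()
    for n, (_, row) in enumerate(df.iterrows(), start=2):
        entry_id = _get(row, "entry_id")
        if entry_id in seen:
            raise ValidationError(f"{path} row {n}: duplicate entry_id {entry_id!r}")
        seen.add(entry_id)
        sigma = _parse_float(_get(row, "sigma"), "sigma", n, path)
        if sigma <= 0:
            raise ValidationError(f"{path} row {n}: sigma must be > 0")
        motif_keys = {}
        for depth, col in depth_cols:
            key = _get(row, col)
            if not key:
                raise ValidationError(f"{path} row {n}: empty motif key {col}")
            motif_keys[depth] = key
        entries.append(
            DatabaseEntry(
                entry_id=entry_id,
                nucleus=_get(row, "nucleus"),
                shift=_parse_float(_get(row, "shift"), "shift", n, path),
                sigma=sigma,
                motif_keys=motif_keys,
                partner_ref=_get(row, "partner_ref") or None,
            )
        )
    return entries


def write_database(entries: list[DatabaseEntry], path) -> None:
    if not entries:
        raise UsageError("refusing to write an empty database")
    w_max = max(max(e.motif_keys) for e in entries)
    cols = ["entry_id", "nucleus", "shift", "sigma", "partner_ref"] + [
        f"key_w{w}" for w in range(1, w_max + 1)
    ]
    rows = []
    for e in entries:
        row = {
            "entry_id": e.entry_id,
            "nucleus": e.nucleus,
            "shift": repr(e.shift),
            "sigma": repr(e.sigma),
            "partner_ref": e.partner_ref or "",
        }
        for w in range(1, w_max + 1):
            row[f"key_w{w}"] = e.motif_keys.get(w, "")
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# results


def write_marginals_csv(marginals, path) -> None:
    """Long-form marginal table: one row per (item, peak) pair."""
    rows = []
    for mm in marginals:
        key = block_key_str(mm.block.block_key) if mm.block else ""
        for i, item_id in enumerate(mm.item_ids):
            jmap = mm.map_assignment[i]
            for j, peak_id in enumerate(mm.peak_ids):
                rows.append({
                    "block_key": key,
                    "item_id": item_id,
                    "peak_id": peak_id,
                    "probability": repr(float(mm.P[i, j])),
                    "is_map": int(j == jmap),
                    "tie_flag": int(mm.map_tie),
                })
    pd.DataFrame(
        rows, columns=["block_key", "item_id", "peak_id", "probability", "is_map", "tie_flag"]
    ).to_csv(path, index=False)


def summary_dict(marginals, confidence_threshold: float = 0.90) -> dict:
    """Machine-readable per-block summary (MAP, per-item argmax, ambiguous sites)."""
    blocks = {}
    for mm in marginals:
        key = block_key_str(mm.block.block_key) if mm.block else f"block{len(blocks)}"
        items = {}
        ambiguous = []
        for i, item_id in enumerate(mm.item_ids):
            j, tie = mm.argmax_row(i)
            prob = float(mm.P[i, j])
            items[item_id] = {
                "best_peak": mm.peak_ids[j],
                "probability": prob,
                "tie": bool(tie),
            }
            if tie or prob < confidence_threshold:
                ambiguous.append(item_id)
        blocks[key] = {
            "map_assignment": {
                item_id: mm.peak_ids[mm.map_assignment[i]]
                for i, item_id in enumerate(mm.item_ids)
            },
            "map_log_posterior": float(mm.map_log_posterior),
            "map_tie": bool(mm.map_tie),
            "items": items,
            "ambiguous_sites": ambiguous,
        }
    return {"confidence_threshold": confidence_threshold, "blocks": blocks}


def write_summary_json(marginals, path, confidence_threshold: float = 0.90) -> None:
    with open(path, "w") as fh:
        json.dump(summary_dict(marginals, confidence_threshold), fh, indent=2, sort_keys=True)
        fh.write("\n")


def report_text(marginals, confidence_threshold: float = 0.90) -> str:
    """Human-readable report: per site, top assignments sorted by probability
    (to 0.1%); sites below the confidence threshold are flagged as candidates
    for targeted additional experiments."""
    lines = []
    for mm in marginals:
        key = block_key_str(mm.block.block_key) if mm.block else "block"
        lines.append(f"Block {key}  (n = {mm.n})")
        if mm.map_tie:
            lines.append("  note: MAP assignment is tied; lexicographically smallest reported")
        for i, item_id in enumerate(mm.item_ids):
            order = np.argsort(-mm.P[i], kind="stable")
            tops = ", ".join(
                f"{mm.peak_ids[j]} {100.0 * mm.P[i, j]:.1f}%"
                for j in order[: min(3, mm.n)]
            )
            j0, tie = mm.argmax_row(i)
            flag = ""
            if tie:
                flag = "  [AMBIGUOUS: tied]"
            elif mm.P[i, j0] < confidence_threshold:
                flag = "  [AMBIGUOUS: below threshold]"
            lines.append(f"  {item_id}: {tops}{flag}")
        lines.append("")
    return "\n".join(lines)


def read_marginals_csv(path) -> pd.DataFrame:
    df = _read_csv(path)
    _require_columns(df, ["block_key", "item_id", "peak_id", "probability"], path)
    df["probability"] = df["probability"].astype(float)
    return df


def _natural_key(s: str):
    return [int(t) if t.isdigit() else t for t in re.split(r"(\d+)", s)]


def _block_label_key(block_key: str):
    from .model import MULTIPLICITY_ORDER

    parts = block_key.split("|")
    mult = parts[1] if len(parts) == 3 else ""
    return (MULTIPLICITY_ORDER.get(mult, 99), block_key)


def report_matrix(df: pd.DataFrame, decimals: int = 1) -> str:
    """Render marginals as probability-map tables, one per block.

    Blocks are ordered quaternary, tertiary, secondary, primary (then other
    labels); within a block rows (sites) and columns (peaks) are ordered by
    natural sort of their ids, so the output is independent of input row
    order.  When peak ids are the alphabetical within-block labels the
    column order is the decreasing-¹³C order.  Values are percentages to 0.1.
    """
    out = []
    for block_key in sorted(df["block_key"].unique(), key=_block_label_key):
        sub = df[df["block_key"] == block_key]
        items = sorted(sub["item_id"].unique(), key=_natural_key)
        peaks = sorted(sub["peak_id"].unique(), key=_natural_key)
        mat = sub.pivot_table(
            index="item_id", columns="peak_id", values="probability", aggfunc="first"
        ).reindex(index=items, columns=peaks)
        out.append(f"Block {block_key}")
        width = max([len(p) for p in peaks] + [6])
        iw = max(len(i) for i in items)
        out.append(" " * (iw + 2) + "  ".join(p.rjust(width) for p in peaks))
        for item in items:
            cells = "  ".join(
                f"{100.0 * mat.loc[item, p]:.{decimals}f}".rjust(width) for p in peaks
            )
            out.append(f"{item.ljust(iw)}  {cells}")
        out.append("")
    return "\n".join(out)
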