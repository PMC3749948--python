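"""Evaluate predicted contacts against a reference 3D structure.

A pair of alignment columns counts as a native contact when the minimal
distance between any two non-hydrogen atoms of the mapped residues is
below the cutoff (default 8 Å, strict inequality).  The column-to-residue
mapping is supplied explicitly as a TSV (column, chain, residue number,
optional insertion code); unmapped columns are excluded from evaluation
without consuming prediction ranks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser

logger = logging.getLogger(__name__)

DEFAULT_CONTACT_CUTOFF = 8.0


@dataclass
class DistanceMap:
    """Minimal heavy-atom inter-residue distances over mapped columns.

    ``d[i, j]`` (0-based column indices) is NaN when either column is
    unmapped; ``mapping`` holds 1-based column → residue id.
    """

    d: np.ndarray
    mapping: dict[int, tuple[str, int, str]]
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF

    @property
    def L(self) -> int:
        return self.d.shape[0]

    def is_contact(self, i: int, j: int, cutoff: float | None = None) -> bool:
        """True when columns i, j (1-based) are mapped and closer than the cutoff."""
        c = self.contact_cutoff if cutoff is None else cutoff
        v = self.d[i - 1, j - 1]
        return bool(np.isfinite(v) and v < c)


def read_mapping_tsv(path: str | Path) -> dict[int, tuple[str, int, str]]:
    """Column↔residue mapping: TSV with columns column, chain, resnum[, icode]."""
    mapping: dict[int, tuple[str, int, str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("column"):
                continue
            parts = line.split("\t")
            col, chain, resnum = int(parts[0]), parts[1], int(parts[2])
            icode = parts[3] if len(parts) > 3 and parts[3] else " "
            mapping[col] = (chain, resnum, icode)
    return mapping


def _residue_coords(structure, chain_id: str):
    """Heavy-atom coordinates per residue of a chain; altLoc by highest occupancy."""
    model = next(structure.get_models())  # first model only
    if chain_id not in [c.id for c in model]:
        raise KeyError(f"chain {chain_id!r} not found in structure")
    chain = model[chain_id]
    coords: dict[tuple[int, str], np.ndarray] = {}
    for res in chain:
        atoms = {}
        for atom in res.get_unpacked_list():  # all altLoc copies
            if atom.element == "H":
                continue
            name = atom.get_name()
            prev = atoms.get(name)
            if prev is None or (atom.get_occupancy() or 0) > (prev.get_occupancy() or 0):
                atoms[name] = atom
        if atoms:
            het, resnum, icode = res.get_id()
            coords[(resnum, icode)] = np.array([a.get_coord() for a in atoms.values()])
    return coords


def distance_map(pdb_path: str | Path, chain: str,
                 mapping: dict[int, tuple[str, int, str]] | str | Path,
                 L: int | None = None,
                 contact_cutoff: float = DEFAULT_CONTACT_CUTOFF) -> DistanceMap:
    """Minimal non-hydrogen atom distances between all mapped column pairs.

    Raises ``KeyError`` listing any mapped residue absent from the
    structure.  ``L`` defaults to the largest mapped column index.
    """
    if not isinstance(mapping, dict):
        mapping = read_mapping_tsv(mapping)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(pdb_path))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords_by_chain = {}
        for col, (ch, resnum, icode) in mapping.items():
            if ch not in coords_by_chain:
                coords_by_chain[ch] = _residue_coords(structure, ch)

    missing = [f"{ch}/{num}{icode.strip()}" for col, (ch, num, icode) in mapping.items()
               if (num, icode) not in coords_by_chain[ch]]
    if missing:
        raise KeyError(f"residues absent from structure: {', '.join(sorted(set(missing)))}")

    if L is None:
        L = max(mapping)
    d = np.full((L, L), np.nan)
    cols = sorted(c for c in mapping if c <= L)
    res_coords = {c: coords_by_chain[mapping[c][0]][(mapping[c][1], mapping[c][2])]
                  for c in cols}
    for ci in cols:
        d[ci - 1, ci - 1] = 0.0
    for idx, ci in enumerate(cols):
        for cj in cols[idx + 1:]:
            xi, xj = res_coords[ci], res_coords[cj]
            dmin = np.sqrt(((xi[:, None, :] - xj[None, :, :])**2).sum(-1)).min()
            d[ci - 1, cj - 1] = d[cj - 1, ci - 1] = dmin
    n_unmapped = L - len(cols)
    if n_unmapped:
        logger.info("distance_map: %d of %d columns unmapped, excluded", n_unmapped, L)
    return DistanceMap(d=d, mapping=dict(mapping), contact_cutoff=contact_cutoff)


def tp_rate_curve(predictions, dmap: DistanceMap,
                  cutoff: float | None = None,
                  min_separation: int | None = None) -> np.ndarray:
    """True-positive fraction among the top-n predictions, for n = 1..N.

    ``predictions`` is the ranked pair list from contact scoring (1-based
    (i, j[, score]) tuples).  Pairs with an unmapped endpoint are skipped
    and do not consume a rank.  Contact means distance strictly below the
    cutoff.
    """
    if not len(predictions):
        raise ValueError("empty prediction list")
    cutoff = dmap.contact_cutoff if cutoff is None else cutoff
    hits = []
    for pred in predictions:
        i, j = pred[0], pred[1]
        if min_separation is not None and abs(i - j) < min_separation:
            continue
        v = dmap.d[i - 1, j - 1]
        if not np.isfinite(v):
            continue
        hits.append(v < cutoff)
    hits = np.asarray(hits, dtype=float)
    if hits.size == 0:
        raise ValueError("no mapped predictions to evaluate")
    return np.cumsum(hits) / np.arange(1, hits.size + 1)


def write_tp_curve_csv(tp: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        fh.write("n,tp_rate\n")
        for n, v in enumerate(tp, 1):
            fh.write(f"{n},{v:.12g}\n")
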