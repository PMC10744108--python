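"""Confidence scoring and contact analysis of predicted protein complexes.

Three readouts of a structure-prediction run are covered:

* interface confidence: the mean predicted aligned error (PAE) over a
  rectangular block of the PAE matrix — rows from one residue interval,
  columns from another — read from the standard JSON layouts;
* per-residue pLDDT, stored by predicted models in the B-factor field;
* atomic contacts by van-der-Waals overlap: two atoms are in contact when

      overlap = r_i + r_j - d >= cutoff

  with the mild default cutoff of -0.4 Å (atoms may be up to 0.4 Å short of
  VDW touching), the convention of interactive "find contacts" tools.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "PaeMatrix",
    "ResidueInterval",
    "AtomSet",
    "ContactRecord",
    "read_pae",
    "pae_region_mean",
    "plddt_track",
    "find_contacts",
    "interface_residues",
    "VDW_RADII",
    "DEFAULT_OVERLAP_CUTOFF",
]

#: Element van-der-Waals radii in Å (Bondi 1964, with common extensions for
#: metals).  Override per call via the ``radii`` argument.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "SE": 1.90, "B": 1.92, "SI": 2.10,
    "NA": 2.27, "K": 2.75, "MG": 1.73, "CA": 2.31, "ZN": 1.39,
    "FE": 2.00, "MN": 2.00, "CU": 1.40, "NI": 1.63, "CO": 2.00,
}

#: Default VDW-overlap cutoff (Å) defining a contact; inclusive.
DEFAULT_OVERLAP_CUTOFF = -0.4

#: Non-hydrogen atom pairs closer than this (Å) are treated as covalently
#: bonded and excluded from contact lists.
BOND_DISTANCE = 1.9

_CMP_EPS = 1e-9


@dataclass(frozen=True)
class ResidueInterval:
    """1-based inclusive residue interval on one chain."""

    chain: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid interval {self.start}-{self.end}")

    @classmethod
    def parse(cls, text: str) -> "ResidueInterval":
        """Parse ``CHAIN:START-END``, e.g. ``A:128-173``."""
        chain, _, span = text.partition(":")
        start, _, end = span.partition("-")
        return cls(chain, int(start), int(end or start))


@dataclass(frozen=True)
class PaeMatrix:
    """Square expected-position-error matrix with chain ranges.

    ``chain_ranges`` maps chain id to its 1-based inclusive interval in
    matrix coordinates; the ranges must partition ``1..L``.
    """

    values: np.ndarray
    chain_ranges: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"PAE matrix must be square, got shape {v.shape}")
        if (v < 0).any():
            raise ValueError("PAE entries must be nonnegative")
        length = v.shape[0]
        covered = np.zeros(length, dtype=bool)
        for chain, (s, e) in self.chain_ranges.items():
            if not 1 <= s <= e <= length:
                raise ValueError(f"chain {chain!r} range {s}-{e} outside 1..{length}")
            if covered[s - 1 : e].any():
                raise ValueError(f"chain {chain!r} range overlaps another chain")
            covered[s - 1 : e] = True
        if not covered.all():
            raise ValueError("chain ranges do not partition the matrix length")
        object.__setattr__(self, "values", v)

    @property
    def length(self) -> int:
        return self.values.shape[0]

    def global_indices(self, interval: ResidueInterval) -> np.ndarray:
        """0-based matrix indices of a chain-local interval."""
        if interval.chain not in self.chain_ranges:
            raise KeyError(f"unknown chain {interval.chain!r}")
        cs, ce = self.chain_ranges[interval.chain]
        chain_len = ce - cs + 1
        if interval.end > chain_len:
            raise ValueError(
                f"interval {interval.start}-{interval.end} exceeds chain "
                f"{interval.chain!r} length {chain_len}"
            )
        return np.arange(cs - 1 + interval.start - 1, cs - 1 + interval.end)


def _extract_matrix(payload) -> np.ndarray:
    """Pull the PAE matrix out of the known JSON layouts."""
    if isinstance(payload, list):
        if len(payload) != 1:
            raise ValueError("expected a single PAE record in list-wrapped JSON")
        payload = payload[0]
    if not isinstance(payload, dict):
        raise ValueError("unrecognized PAE JSON layout")
    for key in ("predicted_aligned_error", "pae"):
        if key in payload:
            values = np.asarray(payload[key], dtype=float)
            if values.ndim == 1:  # flat row-major dialect
                n = int(round(np.sqrt(values.size)))
                if n * n != values.size:
                    raise ValueError(f"flat PAE list of length {values.size} is not square")
                values = values.reshape(n, n)
            return values
    if {"residue1", "residue2", "distance"} <= payload.keys():
        r1 = np.asarray(payload["residue1"], dtype=int)
        r2 = np.asarray(payload["residue2"], dtype=int)
        d = np.asarray(payload["distance"], dtype=float)
        n = int(max(r1.max(), r2.max()))
        mat = np.full((n, n), np.nan)
        mat[r1 - 1, r2 - 1] = d
        if np.isnan(mat).any():
            raise ValueError("flat PAE triplets do not cover the full matrix")
        return mat
    raise ValueError("no PAE matrix found in JSON payload")


def read_pae(
    path: str | Path,
    chain_ranges: dict[str, tuple[int, int]] | None = None,
    model: str | Path | None = None,
) -> PaeMatrix:
    """Read a PAE matrix from JSON (flat-triplet or nested-list dialects).

    Chain ranges come either from ``chain_ranges`` directly or from a
    companion model file (chain order and lengths as in the model); with
    neither, the whole matrix is one chain ``"A"``.
    """
    payload = json.loads(Path(path).read_text())
    values = _extract_matrix(payload)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"PAE matrix is not square: shape {values.shape}")
    if chain_ranges is None and model is not None:
        chain_ranges = {}
        pos = 1
        for chain, n_res in _model_chain_lengths(model):
            chain_ranges[chain] = (pos, pos + n_res - 1)
            pos += n_res
    if chain_ranges is None:
        chain_ranges = {"A": (1, values.shape[0])}
    return PaeMatrix(values=values, chain_ranges=chain_ranges)


def pae_region_mean(
    pae: PaeMatrix,
    a: ResidueInterval,
    b: ResidueInterval,
    symmetric: bool = False,
) -> float:
    """Mean PAE over the block rows(a) x cols(b).

    A "PAE plot area" is one rectangle of the matrix: rows from interval
    ``a``, columns from interval ``b``.  With ``symmetric=True`` the mean is
    taken over the union of both rectangles rows(a) x cols(b) and
    rows(b) x cols(a) — the PAE matrix is generally asymmetric, so the two
    differ.
    """
    ia, ib = pae.global_indices(a), pae.global_indices(b)
    block = pae.values[np.ix_(ia, ib)]
    if not symmetric:
        return float(block.mean())
    block2 = pae.values[np.ix_(ib, ia)]
    return float(np.concatenate([block.ravel(), block2.ravel()]).mean())


def _read_structure(path: str | Path) -> gemmi.Structure:
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"no models in structure file {path}")
    return st


def _model_chain_lengths(path: str | Path) -> list[tuple[str, int]]:
    model = _read_structure(path)[0]
    return [(chain.name, len(chain)) for chain in model]


def plddt_track(path: str | Path) -> dict[str, np.ndarray]:
    """Per-residue pLDDT from a predicted model's B-factor field.

    Returns one array per chain, indexed from the chain's first to last
    residue number; the representative atom is CA for polymer residues, the
    first atom otherwise.  Residue numbers absent from the model appear as
    NaN gaps.
    """
    model = _read_structure(path)[0]
    tracks: dict[str, np.ndarray] = {}
    for chain in model:
        per_res: dict[int, float] = {}
        for res in chain:
            ca = res.find_atom("CA", "*")
            atom = ca if ca is not None else (res[0] if len(res) else None)
            if atom is not None:
                per_res[res.seqid.num] = atom.b_iso
        if not per_res:
            continue
        lo, hi = min(per_res), max(per_res)
        track = np.full(hi - lo + 1, np.nan)
        for num, b in per_res.items():
            track[num - lo] = b
        tracks[chain.name] = track
    if not tracks:
        raise ValueError(f"no residues with atoms in {path}")
    return tracks


@dataclass(frozen=True)
class AtomSet:
    """Flat arrays of atoms for contact detection."""

    elements: np.ndarray  # str, upper-case element symbols
    xyz: np.ndarray  # (n, 3) float, Å
    chains: np.ndarray  # str
    res_nums: np.ndarray  # int
    atom_names: np.ndarray  # str

    def __post_init__(self) -> None:
        n = len(self.elements)
        if self.xyz.shape != (n, 3):
            raise ValueError("xyz must be (n, 3)")
        if not np.isfinite(self.xyz).all():
            raise ValueError("non-finite atom coordinates")

    def __len__(self) -> int:
        return len(self.elements)

    @classmethod
    def from_file(cls, path: str | Path) -> "AtomSet":
        """Load all atoms of the first model of a PDB or mmCIF file."""
        model = _read_structure(path)[0]
        elements, xyz, chains, res_nums, names = [], [], [], [], []
        for chain in model:
            for res in chain:
                for atom in res:
                    elements.append(atom.element.name.upper())
                    xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    chains.append(chain.name)
                    res_nums.append(res.seqid.num)
                    names.append(atom.name)
        if not elements:
            raise ValueError(f"no atoms in {path}")
        return cls(
            elements=np.asarray(elements, dtype=object),
            xyz=np.asarray(xyz, dtype=float),
            chains=np.asarray(chains, dtype=object),
            res_nums=np.asarray(res_nums, dtype=int),
            atom_names=np.asarray(names, dtype=object),
        )


@dataclass(frozen=True)
class ContactRecord:
    """One atom pair in contact, with its distance and VDW overlap."""

    i: int
    j: int
    chain_i: str
    res_i: int
    atom_i: str
    chain_j: str
    res_j: int
    atom_j: str
    distance: float
    overlap: float


def _radii_for(atoms: AtomSet, radii: dict[str, float]) -> np.ndarray:
    out = np.empty(len(atoms))
    for k, el in enumerate(atoms.elements):
        try:
            out[k] = radii[el]
        except KeyError:
            raise KeyError(f"no VDW radius for element {el!r}") from None
    return out


def find_contacts(
    atoms: AtomSet,
    overlap_cutoff: float = DEFAULT_OVERLAP_CUTOFF,
    radii: dict[str, float] | None = None,
) -> list[ContactRecord]:
    """All atom pairs with VDW overlap ≥ ``overlap_cutoff`` (inclusive).

    Pairs within one residue, and pairs of non-hydrogen atoms closer than
    1.9 Å (taken as covalently bonded), are excluded.  Candidate pairs are
    found with a k-d tree at the maximal contact distance, so results equal
    the all-pairs computation exactly.
    """
    r = _radii_for(atoms, radii or VDW_RADII)
    max_dist = 2.0 * r.max() - overlap_cutoff + _CMP_EPS
    tree = cKDTree(atoms.xyz)
    pairs = tree.query_pairs(max_dist, output_type="ndarray")
    records: list[ContactRecord] = []
    for i, j in pairs:
        if atoms.chains[i] == atoms.chains[j] and atoms.res_nums[i] == atoms.res_nums[j]:
            continue
        d = float(np.linalg.norm(atoms.xyz[i] - atoms.xyz[j]))
        if d < BOND_DISTANCE and atoms.elements[i] != "H" and atoms.elements[j] != "H":
            continue
        overlap = r[i] + r[j] - d
        if overlap >= overlap_cutoff - _CMP_EPS:
            records.append(
                ContactRecord(
                    i=int(i), j=int(j),
                    chain_i=str(atoms.chains[i]), res_i=int(atoms.res_nums[i]),
                    atom_i=str(atoms.atom_names[i]),
                    chain_j=str(atoms.chains[j]), res_j=int(atoms.res_nums[j]),
                    atom_j=str(atoms.atom_names[j]),
                    distance=d, overlap=float(overlap),
                )
            )
    records.sort(key=lambda c: (c.chain_i, c.res_i, c.atom_i, c.chain_j, c.res_j, c.atom_j))
    return records


def interface_residues(
    contacts: Sequence[ContactRecord], chain_a: str, chain_b: str
) -> dict[str, dict]:
    """Residues of each chain involved in inter-chain contacts.

    Returns, per chain, the sorted unique residue numbers and the minimal
    covering interval (empty list and ``None`` when there is no inter-chain
    contact).
    """
    res_a: set[int] = set()
    res_b: set[int] = set()
    for c in contacts:
        if c.chain_i == chain_a and c.chain_j == chain_b:
            res_a.add(c.res_i)
            res_b.add(c.res_j)
        elif c.chain_i == chain_b and c.chain_j == chain_a:
            res_b.add(c.res_i)
            res_a.add(c.res_j)
    out = {}
    for chain, residues in ((chain_a, res_a), (chain_b, res_b)):
        ordered = sorted(residues)
        out[chain] = {
            "residues": ordered,
            "interval": (ordered[0], ordered[-1]) if ordered else None,
        }
    return out
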