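"""Sequence-level feature analysis: IDR consensus, conservation, charge states.

Intrinsically disordered regions (IDRs) are called by a two-track consensus:
a residue is disordered when its disorder score is above 0.5 *or* its pLDDT
is below 50 (both comparisons strict); maximal runs of at least ``min_len``
flagged residues become segments.

Conservation profiles score each alignment column restricted to the reference
sequence's residues; the default score is the fraction of non-gap residues
sharing the reference residue's physicochemical class (hydrophobic AVLIMFWYC,
positive KRH, negative DE, polar STNQ, special GP), with the fraction
identical to the reference as an option.  Scoring against the reference keeps
the profile monotone under adding reference-like sequences and ties every
score to the residue the coordinate system is built on.

Charge classification follows the diagram-of-states for polyampholytes:
f+ and f- are the fractions of {K, R} and {D, E} (histidine is treated as
neutral at physiological pH), FCR = f+ + f-, NCPR = f+ - f-, and the five
regions range from weak polyampholytes (R1) through boundary "Janus"
sequences (R2) to strong polyampholytes (R3) and polyelectrolytes (R4/R5).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO

__all__ = [
    "IdrSegment",
    "ChargeProfile",
    "call_idrs",
    "conservation_profile",
    "charge_classify",
    "DISORDER_THRESHOLD",
    "PLDDT_THRESHOLD",
    "PHYSICOCHEMICAL_CLASSES",
]

#: A residue counts as disordered when its disorder score is strictly above this.
DISORDER_THRESHOLD = 0.5
#: ... or its pLDDT is strictly below this.
PLDDT_THRESHOLD = 50.0

PHYSICOCHEMICAL_CLASSES: dict[str, str] = {
    "hydrophobic": "AVLIMFWYC",
    "positive": "KRH",
    "negative": "DE",
    "polar": "STNQ",
    "special": "GP",
}

_CLASS_OF = {aa: name for name, aas in PHYSICOCHEMICAL_CLASSES.items() for aa in aas}

_POSITIVE = set("KR")
_NEGATIVE = set("DE")
_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class IdrSegment:
    """One disordered segment, 1-based inclusive."""

    start: int
    end: int
    mean_disorder: float
    mean_plddt: float

    def __len__(self) -> int:
        return self.end - self.start + 1


def disorder_flags(disorder=None, plddt=None) -> np.ndarray:
    """Per-residue consensus flags: disorder > 0.5 OR pLDDT < 50 (strict).

    Either track may be absent, in which case the rule degrades to the track
    present.  NaN entries never flag a residue.
    """
    if disorder is None and plddt is None:
        raise ValueError("at least one of disorder and pLDDT is required")
    if disorder is not None:
        disorder = np.asarray(disorder, dtype=float)
        finite = disorder[np.isfinite(disorder)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("disorder scores must lie in [0, 1]")
    if plddt is not None:
        plddt = np.asarray(plddt, dtype=float)
        finite = plddt[np.isfinite(plddt)]
        if finite.size and (finite.min() < 0 or finite.max() > 100):
            raise ValueError("pLDDT values must lie in [0, 100]")
    if disorder is not None and plddt is not None and disorder.shape != plddt.shape:
        raise ValueError("disorder and pLDDT tracks differ in length")
    length = len(disorder) if disorder is not None else len(plddt)
    flags = np.zeros(length, dtype=bool)
    if disorder is not None:
        flags |= disorder > DISORDER_THRESHOLD
    if plddt is not None:
        flags |= plddt < PLDDT_THRESHOLD
    return flags


def call_idrs(disorder=None, plddt=None, min_len: int = 5) -> list[IdrSegment]:
    """Maximal runs of consensus-flagged residues, of length ≥ ``min_len``.

    ``min_len`` suppresses single-residue flips of the per-residue rule; set
    it to 1 to recover the raw rule.
    """
    if min_len < 1:
        raise ValueError("min_len must be ≥ 1")
    flags = disorder_flags(disorder, plddt)
    segments: list[IdrSegment] = []
    start = None
    for i, f in enumerate(np.append(flags, False)):
        if f and start is None:
            start = i
        elif not f and start is not None:
            if i - start >= min_len:
                sl = slice(start, i)
                segments.append(
                    IdrSegment(
                        start=start + 1,
                        end=i,
                        mean_disorder=(
                            float(np.nanmean(np.asarray(disorder, float)[sl]))
                            if disorder is not None
                            else float("nan")
                        ),
                        mean_plddt=(
                            float(np.nanmean(np.asarray(plddt, float)[sl]))
                            if plddt is not None
                            else float("nan")
                        ),
                    )
                )
            start = None
    return segments


def _load_msa(msa) -> list[tuple[str, str]]:
    if isinstance(msa, (str, Path)):
        aln = AlignIO.read(str(msa), "fasta")
        return [(rec.id, str(rec.seq).upper()) for rec in aln]
    pairs = [(str(i), str(s).upper()) for i, s in msa]
    return pairs


def conservation_profile(
    msa,
    reference_id: str,
    threshold: float = 0.8,
    metric: str = "class",
) -> pd.DataFrame:
    """Per-column conservation restricted to the reference's residues.

    ``msa`` is an aligned-FASTA path or an iterable of ``(id, sequence)``
    pairs (equal lengths, gap ``-``).  Columns where the reference carries a
    gap are dropped, so row ``i`` of the profile corresponds to reference
    residue ``i+1``.  ``metric="class"`` scores the fraction of non-gap
    residues sharing the reference residue's physicochemical class;
    ``metric="identity"`` the fraction identical to the reference residue.
    Returns a frame with ``position`` (1-based reference numbering),
    ``reference_aa``, ``score``, ``gap_fraction`` and ``conserved``
    (score ≥ threshold).
    """
    pairs = _load_msa(msa)
    if not pairs:
        raise ValueError("empty alignment")
    lengths = {len(s) for _, s in pairs}
    if len(lengths) != 1:
        raise ValueError("alignment rows differ in length")
    by_id = dict(pairs)
    if reference_id not in by_id:
        raise KeyError(f"reference {reference_id!r} not in alignment")
    ref = by_id[reference_id]
    if metric not in ("class", "identity"):
        raise ValueError(f"unknown metric {metric!r}")

    rows = []
    position = 0
    n_seq = len(pairs)
    for col_idx, ref_aa in enumerate(ref):
        if ref_aa == "-":
            continue
        position += 1
        column = [s[col_idx] for _, s in pairs]
        residues = [aa for aa in column if aa != "-"]
        gap_fraction = 1.0 - len(residues) / n_seq
        if not residues:
            score = 0.0
        elif metric == "identity":
            score = sum(aa == ref_aa for aa in residues) / len(residues)
        else:
            ref_class = _CLASS_OF.get(ref_aa, "other")
            score = sum(
                _CLASS_OF.get(aa, "other") == ref_class for aa in residues
            ) / len(residues)
        rows.append(
            {
                "position": position,
                "reference_aa": ref_aa,
                "score": float(score),
                "gap_fraction": float(gap_fraction),
                "conserved": bool(score >= threshold),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ChargeProfile:
    """Charge composition and diagram-of-states region of a sequence."""

    f_plus: float
    f_minus: float
    fcr: float
    ncpr: float
    region: str
    region_label: str
    length: int


_REGION_LABELS = {
    "R1": "weak polyampholyte/polyelectrolyte",
    "R2": "Janus/boundary polyampholyte",
    "R3": "strong polyampholyte",
    "R4": "negative polyelectrolyte",
    "R5": "positive polyelectrolyte",
}


def classify_charge_fractions(f_plus: float, f_minus: float) -> str:
    """Diagram-of-states region from charge fractions.

    The regions are evaluated in priority order so the assignment is
    exhaustive and mutually exclusive over the whole simplex
    ``f+ + f- ≤ 1``:

    * R1 — f+ < 0.25 and f- < 0.25 (weak);
    * R2 — otherwise, FCR ≤ 0.35 (Janus/boundary; here FCR ≥ 0.25 holds);
    * R3 — otherwise, |NCPR| ≤ 0.35 (strong polyampholyte);
    * R4/R5 — otherwise, negative or positive polyelectrolyte by the sign of
      NCPR.
    """
    if not (0 <= f_plus <= 1 and 0 <= f_minus <= 1 and f_plus + f_minus <= 1 + 1e-12):
        raise ValueError("charge fractions must be nonnegative with f+ + f- ≤ 1")
    fcr = f_plus + f_minus
    ncpr = f_plus - f_minus
    if f_plus < 0.25 and f_minus < 0.25:
        return "R1"
    if fcr <= 0.35:
        return "R2"
    if abs(ncpr) <= 0.35:
        return "R3"
    return "R4" if ncpr < 0 else "R5"


def charge_classify(sequence: str, on_nonstandard: str = "error") -> ChargeProfile:
    """Charge fractions and diagram-of-states region of a protein sequence.

    f+ counts K and R, f- counts D and E; histidine is excluded from both
    (neutral-pH convention).  ``on_nonstandard`` controls handling of letters
    outside the 20 standard amino acids: ``"error"`` raises, ``"skip"`` drops
    them from the sequence before computing fractions.
    """
    seq = "".join(sequence.split()).upper()
    if not seq:
        raise ValueError("empty sequence")
    nonstandard = [aa for aa in seq if aa not in _STANDARD_AA]
    if nonstandard:
        if on_nonstandard == "error":
            raise ValueError(f"non-standard residues {sorted(set(nonstandard))}")
        if on_nonstandard != "skip":
            raise ValueError(f"unknown on_nonstandard mode {on_nonstandard!r}")
        seq = "".join(aa for aa in seq if aa in _STANDARD_AA)
        if not seq:
            raise ValueError("no standard residues left after skipping")
    n = len(seq)
    f_plus = sum(aa in _POSITIVE for aa in seq) / n
    f_minus = sum(aa in _NEGATIVE for aa in seq) / n
    region = classify_charge_fractions(f_plus, f_minus)
    return ChargeProfile(
        f_plus=f_plus,
        f_minus=f_minus,
        fcr=f_plus + f_minus,
        ncpr=f_plus - f_minus,
        region=region,
        region_label=_REGION_LABELS[region],
        length=n,
    )
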