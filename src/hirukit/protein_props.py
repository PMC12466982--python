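"""Physicochemical property calculators for mature (signal-peptide-free) proteins.

Implements the three classic ProtParam-style statistics used to characterise
mature hirudins:

* GRAVY — grand average of hydropathicity, the mean Kyte–Doolittle score.
* Instability index — the Guruprasad dipeptide-weight statistic,
  II = (10/L) * sum of DIWV(x_i, x_{i+1}) over adjacent residue pairs.
* Isoelectric point — the pH of zero net charge under a
  Henderson–Hasselbalch charge model with the Bjellqvist pKa set, solved by
  bisection.

The Kyte–Doolittle scale and the published DIWV dipeptide matrix are taken
from :mod:`Bio.SeqUtils.ProtParamData`; the formulas are computed here.
Cysteines are treated as fully reduced (no disulfide correction), the
ProtParam default, even though native hirudins carry three disulfide bonds.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

from Bio.SeqUtils.ProtParamData import DIWV, kd as KYTE_DOOLITTLE

__all__ = [
    "MatureProtein",
    "ProteinProperties",
    "BJELLQVIST_PKA",
    "gravy",
    "instability_index",
    "charge_at_pH",
    "isoelectric_point",
    "classify_acid_base",
    "remove_signal_peptide",
    "properties",
]

AA20 = frozenset("ACDEFGHIKLMNPQRSTVWY")

# Bjellqvist pKa values (the set behind ProtParam's pI), including the
# residue-specific N- and C-terminal adjustments.
BJELLQVIST_PKA: dict[str, Mapping[str, float]] = {
    "positive": {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98},
    "negative": {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0},
    "nterm_by_residue": {
        "A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7,
    },
    "cterm_by_residue": {"D": 4.55, "E": 4.75},
}


@dataclass(frozen=True)
class MatureProtein:
    """An ungapped mature amino-acid sequence (signal peptide removed)."""

    protein_id: str
    sequence: str
    signal_peptide_removed: bool = False

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 2:
            raise ValueError(
                f"protein {self.protein_id!r}: sequence length {len(seq)} < 2 "
                "(instability index needs at least one dipeptide)"
            )
        for pos, aa in enumerate(seq, start=1):
            if aa not in AA20:
                raise ValueError(
                    f"protein {self.protein_id!r}: non-standard residue {aa!r} "
                    f"at position {pos}"
                )


@dataclass(frozen=True)
class ProteinProperties:
    protein_id: str
    pI: float
    instability_index: float
    gravy: float

    @property
    def unstable(self) -> bool:
        """Guruprasad stability label (II > 40); reported, never asserted."""
        return self.instability_index > 40.0


def _validate_seq(sequence: str) -> str:
    seq = sequence.upper()
    for pos, aa in enumerate(seq, start=1):
        if aa not in AA20:
            raise ValueError(f"non-standard residue {aa!r} at position {pos}")
    return seq


def _seq(protein: "MatureProtein | str") -> str:
    if isinstance(protein, MatureProtein):
        return protein.sequence
    return _validate_seq(protein)


def gravy(protein: "MatureProtein | str") -> float:
    """Mean Kyte–Doolittle hydropathy over all residues."""
    seq = _seq(protein)
    if not seq:
        raise ValueError("empty sequence")
    return sum(KYTE_DOOLITTLE[aa] for aa in seq) / len(seq)


def instability_index(protein: "MatureProtein | str") -> float:
    """Guruprasad instability index, (10/L) * sum of dipeptide weights.

    Dipeptides absent from the published DIWV table weigh 1.0 (the ProtParam
    convention; the shipped table is complete for the 20 standard residues).
    """
    seq = _seq(protein)
    if len(seq) < 2:
        raise ValueError("instability index needs length >= 2")
    total = 0.0
    for i in range(len(seq) - 1):
        total += DIWV.get(seq[i], {}).get(seq[i + 1], 1.0)
    return 10.0 / len(seq) * total


def charge_at_pH(protein: "MatureProtein | str", pH: float) -> float:
    """Net charge from Henderson–Hasselbalch terms (Bjellqvist pKa set).

    Positive groups (N-terminus, K, R, H) contribute +1/(1+10^(pH-pKa));
    negative groups (C-terminus, D, E, C, Y) contribute -1/(1+10^(pKa-pH)).
    The terminal pKas use the residue-specific Bjellqvist adjustments where
    the terminal residue has one.
    """
    seq = _seq(protein)
    comp = Counter(seq)
    pka = BJELLQVIST_PKA
    nterm_pk = pka["nterm_by_residue"].get(seq[0], pka["positive"]["Nterm"])
    cterm_pk = pka["cterm_by_residue"].get(seq[-1], pka["negative"]["Cterm"])

    charge = 1.0 / (1.0 + 10.0 ** (pH - nterm_pk))
    for aa in ("K", "R", "H"):
        charge += comp[aa] / (1.0 + 10.0 ** (pH - pka["positive"][aa]))
    charge -= 1.0 / (1.0 + 10.0 ** (cterm_pk - pH))
    for aa in ("D", "E", "C", "Y"):
        charge -= comp[aa] / (1.0 + 10.0 ** (pka["negative"][aa] - pH))
    return charge


def isoelectric_point(protein: "MatureProtein | str", tol: float = 1e-4) -> float:
    """pH of zero net charge, by bisection on [0, 14].

    The net charge is strictly decreasing in pH, so the zero crossing is
    unique.  The returned pI satisfies |charge(pI)| < 1e-3 for any sequence
    over the 20 standard residues.
    """
    seq = _seq(protein)
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if charge_at_pH(seq, mid) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def classify_acid_base(pI_values: Iterable[float]) -> dict[str, int]:
    """Counts of acidic (pI < 7), alkaline (pI > 7) and neutral (pI == 7)."""
    values = list(pI_values)
    if not values:
        raise ValueError("empty pI list")
    return {
        "acidic": sum(v < 7.0 for v in values),
        "alkaline": sum(v > 7.0 for v in values),
        "neutral": sum(v == 7.0 for v in values),
    }


def remove_signal_peptide(
    sequence: str, cleavage_position: int, protein_id: str = "protein"
) -> MatureProtein:
    """Drop the signal peptide: keep residues after ``cleavage_position``.

    ``cleavage_position`` is the 1-based index of the last signal-peptide
    residue (the cleavage site itself is an annotation input; signal-peptide
    prediction is out of scope here).
    """
    seq = _validate_seq(sequence)
    if not 1 <= cleavage_position < len(seq):
        raise ValueError(
            f"cleavage position {cleavage_position} out of range for a "
            f"{len(seq)}-residue sequence"
        )
    return MatureProtein(
        protein_id=protein_id,
        sequence=seq[cleavage_position:],
        signal_peptide_removed=True,
    )


def properties(protein: MatureProtein) -> ProteinProperties:
    """All three statistics for one mature protein."""
    return ProteinProperties(
        protein_id=protein.protein_id,
        pI=isoelectric_point(protein),
        instability_index=instability_index(protein),
        gravy=gravy(protein),
    )
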