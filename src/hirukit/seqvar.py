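"""Sequence-diversity statistics for multigene-family alignments.

Computes, per gene, the number of variable (segregating) sites, the number of
distinct haplotypes, and per-site Watterson's theta, at both the nucleotide
and the amino-acid level.  Input alignments are assumed pre-aligned; this
module validates shape and alphabet but never aligns.

Two conventions for the sample-size term of Watterson's correction are
supported: ``haplotype_n`` (the harmonic sum runs over the number of distinct
haplotypes, the convention used for the reference study tables) and
``sequence_n`` (the textbook convention, over the number of sequences).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal

from Bio.Data import CodonTable

__all__ = [
    "AlignmentRow",
    "GeneAlignment",
    "HaplotypeSet",
    "VariationSummary",
    "count_variable_sites",
    "collapse_haplotypes",
    "harmonic_correction",
    "watterson_theta_per_site",
    "translate_alignment",
    "summarize_gene",
]

DNA_ALPHABET = frozenset("ACGT-")
DNA_AMBIGUOUS = frozenset("N")
AA20 = frozenset("ACDEFGHIKLMNPQRSTVWY")
PROTEIN_ALPHABET = AA20 | frozenset("*-")
PROTEIN_AMBIGUOUS = frozenset("X")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_STANDARD_TABLE.forward_table)
_CODON_TO_AA.update({c: "*" for c in _STANDARD_TABLE.stop_codons})

ThetaConvention = Literal["haplotype_n", "sequence_n"]


@dataclass(frozen=True)
class AlignmentRow:
    """One aligned sequence, keyed by sample and species."""

    sample_id: str
    species_id: str
    sequence: str
    internal_stop: bool = False  # set by translate_alignment when a premature stop appears


@dataclass
class GeneAlignment:
    """Equal-length aligned sequences for one gene.

    ``level`` selects the alphabet: ``dna`` permits A, C, G, T, the gap ``-``
    and the ambiguity code N; ``protein`` permits the 20 standard amino
    acids, the stop ``*``, the gap ``-`` and the ambiguity code X.
    """

    gene_id: str
    level: Literal["dna", "protein"]
    rows: list[AlignmentRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError(f"alignment {self.gene_id!r} is empty")
        if self.level not in ("dna", "protein"):
            raise ValueError(f"unknown alignment level {self.level!r}")
        length = len(self.rows[0].sequence)
        if length < 1:
            raise ValueError(f"alignment {self.gene_id!r} has zero-length rows")
        seen: set[str] = set()
        if self.level == "dna":
            allowed = DNA_ALPHABET | DNA_AMBIGUOUS
        else:
            allowed = PROTEIN_ALPHABET | PROTEIN_AMBIGUOUS
        for row in self.rows:
            if len(row.sequence) != length:
                raise ValueError(
                    f"ragged alignment {self.gene_id!r}: row {row.sample_id!r} has "
                    f"length {len(row.sequence)}, expected {length}"
                )
            if row.sample_id in seen:
                raise ValueError(
                    f"duplicate sample id {row.sample_id!r} in alignment {self.gene_id!r}"
                )
            seen.add(row.sample_id)
            bad = set(row.sequence.upper()) - allowed
            if bad:
                raise ValueError(
                    f"row {row.sample_id!r} of {self.gene_id!r} contains symbols "
                    f"{sorted(bad)} outside the {self.level} alphabet"
                )

    @property
    def length(self) -> int:
        return len(self.rows[0].sequence)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def sequences(self) -> list[str]:
        return [row.sequence.upper() for row in self.rows]


@dataclass(frozen=True)
class HaplotypeSet:
    """Distinct full-length sequences with their multiplicities.

    Ordered by descending frequency, ties broken by first occurrence.
    """

    haplotypes: tuple[str, ...]
    frequencies: tuple[int, ...]

    @property
    def k(self) -> int:
        return len(self.haplotypes)

    @property
    def n(self) -> int:
        return sum(self.frequencies)


@dataclass(frozen=True)
class VariationSummary:
    """Per-gene diversity at DNA and protein level (one output-table row)."""

    gene_id: str
    L_dna: int
    S_dna: int
    k_dna: int
    a_dna: float
    theta_dna: float
    L_prot: int
    S_prot: int
    k_prot: int
    a_prot: float
    theta_prot: float


def _ambiguity(level: str) -> frozenset[str]:
    return DNA_AMBIGUOUS if level == "dna" else PROTEIN_AMBIGUOUS


def count_variable_sites(alignment: GeneAlignment) -> int:
    """Number of columns with at least two distinct non-ambiguous symbols.

    A gap counts as a distinct state.  Columns whose only differences involve
    ambiguity codes (N at the DNA level, X at the protein level) are not
    counted as variable, so sequencing uncertainty never inflates S.
    """
    ambiguous = _ambiguity(alignment.level)
    seqs = alignment.sequences()
    count = 0
    for col in zip(*seqs):
        states = set(col) - ambiguous
        if len(states) >= 2:
            count += 1
    return count


def collapse_haplotypes(alignment: GeneAlignment) -> HaplotypeSet:
    """Deduplicate full-length sequences into haplotypes with frequencies."""
    counts = Counter(alignment.sequences())
    first_seen = {}
    for i, seq in enumerate(alignment.sequences()):
        first_seen.setdefault(seq, i)
    ordered = sorted(counts, key=lambda s: (-counts[s], first_seen[s]))
    return HaplotypeSet(
        haplotypes=tuple(ordered),
        frequencies=tuple(counts[s] for s in ordered),
    )


def harmonic_correction(k: int) -> float:
    """Harmonic number a = sum_{i=1}^{k-1} 1/i of Watterson's estimator.

    Returns 0 for k = 1 (a single haplotype carries no information).
    """
    if not isinstance(k, (int,)) or isinstance(k, bool):
        raise TypeError(f"k must be an integer, got {k!r}")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return sum(1.0 / i for i in range(1, k))


def watterson_theta_per_site(S: int, k: int, L: int) -> float:
    """Per-site Watterson's theta, theta = S / (a_{k-1} * L).

    ``k`` is the sample-size term of the harmonic correction; pass the
    haplotype count for the study-table convention or the sequence count for
    the textbook estimator.  Returns 0.0 when k == 1 (and requires S == 0
    in that case).
    """
    if S < 0:
        raise ValueError(f"S must be >= 0, got {S}")
    if L < 1:
        raise ValueError(f"L must be >= 1, got {L}")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k == 1:
        if S > 0:
            raise ValueError(f"inconsistent inputs: k=1 but S={S} > 0")
        return 0.0
    return S / (harmonic_correction(k) * L)


def _translate_codon(codon: str) -> str:
    if "-" in codon:
        return "-"
    if "N" in codon:
        return "X"
    try:
        return _CODON_TO_AA[codon]
    except KeyError:  # pragma: no cover - alphabet validation precludes this
        raise ValueError(f"untranslatable codon {codon!r}")


def translate_alignment(alignment: GeneAlignment) -> GeneAlignment:
    """Codon-wise translation of a DNA alignment to a protein alignment.

    The terminal stop codon is rendered ``*`` and retained as a column, so
    the protein alignment length is exactly L/3.  Codons containing a gap
    translate to a gap.  Internal (premature) stop codons do not abort the
    translation but set ``internal_stop`` on the affected row, since they
    would indicate a pseudogene.
    """
    if alignment.level != "dna":
        raise ValueError("translate_alignment expects a dna-level alignment")
    if alignment.length % 3 != 0:
        raise ValueError(
            f"alignment {alignment.gene_id!r} length {alignment.length} is not "
            "divisible by 3"
        )
    new_rows = []
    for row in alignment.rows:
        seq = row.sequence.upper()
        aas = [_translate_codon(seq[i : i + 3]) for i in range(0, len(seq), 3)]
        internal_stop = "*" in aas[:-1]
        if internal_stop:
            warnings.warn(
                f"internal stop codon in {alignment.gene_id!r} row {row.sample_id!r}"
                " (possible pseudogene)",
                stacklevel=2,
            )
        new_rows.append(
            AlignmentRow(
                sample_id=row.sample_id,
                species_id=row.species_id,
                sequence="".join(aas),
                internal_stop=internal_stop,
            )
        )
    return GeneAlignment(gene_id=alignment.gene_id, level="protein", rows=new_rows)


def summarize_gene(
    alignment: GeneAlignment,
    theta_convention: ThetaConvention = "haplotype_n",
) -> VariationSummary:
    """Full diversity summary (S, k, theta) at DNA and protein level.

    The protein level is computed on the codon-wise translation, with the
    terminal stop retained as an alignment column.
    """
    if alignment.level != "dna":
        raise ValueError("summarize_gene expects a dna-level alignment")
    protein = translate_alignment(alignment)
    out = {}
    for level_name, aln in (("dna", alignment), ("prot", protein)):
        S = count_variable_sites(aln)
        haps = collapse_haplotypes(aln)
        if theta_convention == "haplotype_n":
            n_term = haps.k
        elif theta_convention == "sequence_n":
            n_term = aln.n_rows
        else:
            raise ValueError(f"unknown theta convention {theta_convention!r}")
        a = harmonic_correction(n_term)
        theta = watterson_theta_per_site(S, n_term, aln.length) if S or n_term > 1 else 0.0
        out[level_name] = (aln.length, S, haps.k, a, theta)
    return VariationSummary(
        gene_id=alignment.gene_id,
        L_dna=out["dna"][0],
        S_dna=out["dna"][1],
        k_dna=out["dna"][2],
        a_dna=out["dna"][3],
        theta_dna=out["dna"][4],
        L_prot=out["prot"][0],
        S_prot=out["prot"][1],
        k_prot=out["prot"][2],
        a_prot=out["prot"][3],
        theta_prot=out["prot"][4],
    )
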