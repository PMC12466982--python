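"""Expression-weighted potency integration.

Combines per-gene mean expression E (TPM) with per-unit antithrombin
activity A (ATU/mg) into E x A products and species-level weighted sums,
under the explicit working assumption that transcript abundance is
proportional to secreted protein amount.  A sensitivity exponent on E
(default 1, i.e. strict linearity) lets that assumption be stress-tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "GenePotency",
    "PotencyScore",
    "SpeciesComparison",
    "gene_potency",
    "species_potency",
    "score_species",
    "compare_species",
]


def gene_potency(E: float, A: float, exponent: float = 1.0) -> float:
    """Per-gene potency contribution E**exponent * A.

    Genes with zero activity (or zero expression) contribute exactly 0.
    """
    if E < 0:
        raise ValueError(f"expression must be >= 0, got {E}")
    if A < 0:
        raise ValueError(f"activity must be >= 0, got {A}")
    if A == 0.0 or E == 0.0:
        return 0.0
    return E**exponent * A


def species_potency(gene_products: Sequence[float]) -> float:
    """Species-level weighted sum: the plain sum of per-gene products."""
    if len(gene_products) == 0:
        raise ValueError("species potency needs at least one gene")
    if any(p < 0 for p in gene_products):
        raise ValueError("gene products must be >= 0")
    return float(sum(gene_products))


@dataclass(frozen=True)
class GenePotency:
    gene_id: str
    expression: float
    activity: float
    product: float


@dataclass(frozen=True)
class PotencyScore:
    species_id: str
    per_gene: tuple[GenePotency, ...]
    total: float

    def shares(self) -> dict[str, float]:
        """Each gene's fraction of the species total (0 when total is 0)."""
        if self.total == 0:
            return {g.gene_id: 0.0 for g in self.per_gene}
        return {g.gene_id: g.product / self.total for g in self.per_gene}

    def dominant_gene(self) -> str | None:
        if self.total == 0:
            return None
        return max(self.per_gene, key=lambda g: g.product).gene_id


def score_species(
    species_id: str,
    expression: Mapping[str, float],
    activity: Mapping[str, float],
    exponent: float = 1.0,
) -> PotencyScore:
    """Score one species from per-gene mean expression and mean activity."""
    if not expression:
        raise ValueError("empty gene set")
    missing = sorted(set(expression) - set(activity))
    if missing:
        raise ValueError(f"genes without activity values: {missing}")
    per_gene = tuple(
        GenePotency(
            gene_id=g,
            expression=expression[g],
            activity=activity[g],
            product=gene_potency(expression[g], activity[g], exponent),
        )
        for g in expression
    )
    return PotencyScore(
        species_id=species_id,
        per_gene=per_gene,
        total=species_potency([g.product for g in per_gene]),
    )


@dataclass(frozen=True)
class SpeciesComparison:
    score_a: PotencyScore
    score_b: PotencyScore
    ratio: float  # total_a / total_b; inf when b is 0
    winner: str  # species id or "tie"
    warnings: tuple[str, ...] = field(default=())

    def decomposition(self) -> dict[str, dict[str, float]]:
        return {
            self.score_a.species_id: self.score_a.shares(),
            self.score_b.species_id: self.score_b.shares(),
        }


def compare_species(
    score_a: PotencyScore,
    score_b: PotencyScore,
    fold_claims: Sequence[tuple[str, str, float]] = (),
) -> SpeciesComparison:
    """Compare two species' weighted sums.

    ``fold_claims`` are optional externally stated expression fold changes
    (gene_hi, gene_lo, fold) to cross-check against the inputs; a claim whose
    direction contradicts the supplied expression values is surfaced as a
    warning flag, never corrected.
    """
    if score_a.total == 0 and score_b.total == 0:
        raise ValueError("no activity in either species")
    warnings: list[str] = []
    if score_b.total == 0:
        ratio = math.inf
        warnings.append(f"{score_b.species_id} has zero total potency; ratio infinite")
    else:
        ratio = score_a.total / score_b.total
    if math.isclose(score_a.total, score_b.total, rel_tol=1e-12, abs_tol=0.0):
        winner = "tie"
    elif score_a.total > score_b.total:
        winner = score_a.species_id
    else:
        winner = score_b.species_id

    expr = {g.gene_id: g.expression for g in score_a.per_gene + score_b.per_gene}
    for gene_hi, gene_lo, fold in fold_claims:
        if gene_hi not in expr or gene_lo not in expr:
            warnings.append(f"fold claim on unknown gene(s): {gene_hi}/{gene_lo}")
            continue
        if expr[gene_lo] == 0:
            continue
        observed = expr[gene_hi] / expr[gene_lo]
        if observed < 1.0 <= fold:
            warnings.append(
                f"claimed {gene_hi} ~{fold:g}-fold of {gene_lo}, but supplied "
                f"expression gives {observed:.3g} (direction reversed)"
            )
    return SpeciesComparison(
        score_a=score_a,
        score_b=score_b,
        ratio=ratio,
        winner=winner,
        warnings=tuple(warnings),
    )
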