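"""Study-shaped synthetic data with planted ground truth.

Generates the three kinds of input the analysis pipeline consumes, each with
known truth so recovery can be tested end to end without any deposited data:

* coding-sequence alignments with an exactly planted number of segregating
  sites and haplotypes, at both the DNA and the protein level;
* gene x sample TPM matrices with log-normal, moment-matched per-gene
  distributions (positive and right-skewed, like the observed expression);
* noisy triplicate titration series produced by running the coarse-to-fine
  half-coagulation search on a latent clotting model.

Default parameters are the published study conditions (2 species x 3 genes x
12 individuals, the tabulated diversity counts, TPM means/SDs, protein
concentrations and activity means).  One master seed expands into
per-component child seeds through a fixed ``numpy.random.SeedSequence``
spawn order (alignments by gene id, then expression, then titrations by
protein id), so a bundle is reproducible from the master seed alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import reference
from .assay import CoagulationModel, TitrationSeries, series_from_replicates, titrate_half_coagulation
from .seqvar import AlignmentRow, GeneAlignment, _CODON_TO_AA

__all__ = [
    "StudyConfig",
    "StudyBundle",
    "generate_alignment",
    "generate_expression_matrix",
    "generate_titration_series",
    "generate_study",
    "default_config",
]

# Codon prefixes whose third position is fourfold degenerate: any third base
# keeps the amino acid, so synonymous mutations are always available.
_FOURFOLD_PREFIXES = ("GC", "GG", "CC", "AC", "GT", "CT", "CG", "TC")
_BASES = "ACGT"


@dataclass(frozen=True)
class PlantedGene:
    """Planted truth for one synthetic gene alignment."""

    gene_id: str
    species_id: str
    length: int
    n_individuals: int
    S_dna: int
    k_dna: int
    S_prot: int
    k_prot: int


@dataclass
class StudyConfig:
    """Parameters of a full synthetic study.

    ``genes`` maps gene id to (species, aligned CDS length, planted S, k,
    nonsynonymous site count, protein haplotype count).  ``expression`` maps
    gene id to (mean TPM, SD); ``activity`` and ``concentration`` map protein
    id to the true specific activity (ATU/mg) and solution concentration
    (mg/mL).  ``titration_noise_sd`` is the relative SD of the latent
    half-coagulation threshold across replicates.
    """

    genes: dict[str, tuple[str, int, int, int, int, int]]
    expression: dict[str, tuple[float, float]]
    activity: dict[str, float]
    concentration: dict[str, float]
    n_individuals: int = reference.N_INDIVIDUALS
    replicates: int = 3
    titration_noise_sd: float = 0.03
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("study config needs at least one gene")
        for gene_id, (species, L, S, k, n_nonsyn, k_prot) in self.genes.items():
            if L % 3 != 0:
                raise ValueError(f"{gene_id}: CDS length {L} not divisible by 3")
            if not (1 <= k <= self.n_individuals):
                raise ValueError(f"{gene_id}: k={k} outside [1, n]")
            if k == 1 and S != 0:
                raise ValueError(f"{gene_id}: k=1 requires S=0")
            if S > L:
                raise ValueError(f"{gene_id}: S={S} exceeds L={L}")
        for gene_id, (m, sd) in self.expression.items():
            if m < 0 or sd < 0:
                raise ValueError(f"{gene_id}: expression mean/sd must be >= 0")
        if self.titration_noise_sd < 0:
            raise ValueError("titration noise SD must be >= 0")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


def default_config(master_seed: int = 0) -> StudyConfig:
    """The published study conditions as a ready-to-run configuration.

    Nonsynonymous site counts and protein haplotype counts are set so the
    planted protein-level diversity matches the tabulated values gene by
    gene (e.g. ten of Hnip1's thirteen variable sites alter the protein).
    """
    genes = {
        g.gene_id: (g.species_id, g.aligned_length, g.S_dna, g.k_dna, g.S_prot, g.k_prot)
        for g in reference.GENES.values()
    }
    return StudyConfig(
        genes=genes,
        expression=dict(reference.EXPRESSION_TPM),
        activity={p: m for p, (m, _) in reference.ACTIVITY_MEANS.items()},
        concentration=dict(reference.CONCENTRATIONS_MG_PER_ML),
        master_seed=master_seed,
    )


def _random_fourfold_codon(rng: np.random.Generator) -> str:
    prefix = _FOURFOLD_PREFIXES[rng.integers(len(_FOURFOLD_PREFIXES))]
    return prefix + _BASES[rng.integers(4)]


def _nonsyn_substitution(codon: str, rng: np.random.Generator) -> tuple[int, str]:
    """A (position, base) change altering the amino acid without a stop."""
    old_aa = _CODON_TO_AA[codon]
    candidates = []
    for pos in (0, 1):
        for base in _BASES:
            if base == codon[pos]:
                continue
            new = codon[:pos] + base + codon[pos + 1 :]
            aa = _CODON_TO_AA[new]
            if aa != "*" and aa != old_aa:
                candidates.append((pos, base))
    pos, base = candidates[rng.integers(len(candidates))]
    return pos, base


def _syn_substitution(codon: str, rng: np.random.Generator) -> tuple[int, str]:
    """A third-position change on a fourfold codon (always synonymous)."""
    options = [b for b in _BASES if b != codon[2]]
    return 2, options[rng.integers(len(options))]


def generate_alignment(
    L: int,
    n: int,
    S: int,
    k: int,
    n_nonsyn: int | None = None,
    k_prot: int | None = None,
    seed: "int | np.random.SeedSequence" = 0,
    gene_id: str = "gene",
    species_id: str = "species",
) -> tuple[GeneAlignment, PlantedGene]:
    """Alignment with exactly S segregating sites and k haplotypes planted.

    The ancestral CDS starts with ATG, ends with a TAA stop and has no
    internal stop; its middle codons come from fourfold-degenerate families
    so synonymous variants always exist.  Each planted mutation occupies its
    own codon, and the k-1 derived haplotypes carry disjoint, non-empty
    mutation sets, so S and k are exact by construction.  ``n_nonsyn`` of
    the S mutations alter the protein (each in a distinct codon, so the
    protein level has exactly ``n_nonsyn`` variable sites), and ``k_prot``
    of the DNA haplotypes remain distinct after translation (haplotypes
    assigned only synonymous changes collapse onto the ancestral protein).
    """
    if L % 3 != 0:
        raise ValueError(f"L={L} not divisible by 3")
    ncod = L // 3
    if ncod < 3:
        raise ValueError(f"L={L} leaves no mutable codon between start and stop")
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, n={n}]")
    if k == 1 and S != 0:
        raise ValueError("k=1 requires S=0")
    if k > 1 and S < k - 1:
        raise ValueError(
            f"infeasible: {k} haplotypes need at least k-1={k - 1} mutations "
            f"(disjoint non-empty sets), got S={S}"
        )
    if S > ncod - 2:
        raise ValueError(
            f"infeasible: S={S} exceeds the {ncod - 2} mutable codons of a "
            f"{L}-bp CDS (one planted mutation per codon)"
        )
    if k_prot is None:
        k_prot = k
    if not 1 <= k_prot <= k:
        raise ValueError(f"k_prot={k_prot} outside [1, k={k}]")
    p = k_prot - 1  # derived haplotypes distinct at the protein level
    q = (k - 1) - p  # derived haplotypes collapsing onto the ancestral protein
    if n_nonsyn is None:
        n_nonsyn = max(p, S // 2) if S else 0
    n_syn = S - n_nonsyn
    if n_nonsyn < p:
        raise ValueError(
            f"infeasible: k_prot={k_prot} needs >= {p} nonsynonymous sites, got {n_nonsyn}"
        )
    if p == 0 and n_nonsyn > 0:
        raise ValueError("infeasible: k_prot=1 admits no nonsynonymous sites")
    if n_syn < q:
        raise ValueError(
            f"infeasible: {q} synonymous-only haplotypes need >= {q} synonymous "
            f"sites, got {n_syn}"
        )
    if k == 1 and (n_nonsyn or k_prot != 1):
        raise ValueError("k=1 admits no mutations")

    rng = np.random.default_rng(seed)
    codons = ["ATG"] + [_random_fourfold_codon(rng) for _ in range(ncod - 2)] + ["TAA"]
    ancestral = "".join(codons)

    # one mutation per codon: draw S distinct mutable codon indices
    mutable = rng.choice(np.arange(1, ncod - 1), size=S, replace=False)
    nonsyn_codons = list(mutable[:n_nonsyn])
    syn_codons = list(mutable[n_nonsyn:])

    # allocate mutations to the k-1 derived haplotype groups
    groups: list[list[tuple[int, int, str]]] = [[] for _ in range(k - 1)]

    def plant(codon_idx: int, synonymous: bool, group: int) -> None:
        codon = codons[codon_idx]
        pos, base = (
            _syn_substitution(codon, rng) if synonymous else _nonsyn_substitution(codon, rng)
        )
        groups[group].append((codon_idx * 3 + pos, pos, base))

    # protein-distinct groups are the first p; each gets one nonsyn seed site
    for g in range(p):
        plant(nonsyn_codons.pop(), synonymous=False, group=g)
    for g in range(p, k - 1):  # synonymous-only groups
        plant(syn_codons.pop(), synonymous=True, group=g)
    for i, c in enumerate(nonsyn_codons):  # leftovers round-robin
        plant(c, synonymous=False, group=i % p if p else 0)
    for i, c in enumerate(syn_codons):
        plant(c, synonymous=True, group=i % (k - 1) if k > 1 else 0)

    rows = []
    for i in range(n):
        seq = ancestral
        if i < k - 1:  # one carrier row per derived haplotype, rest ancestral
            chars = list(ancestral)
            for site, _pos, base in groups[i]:
                chars[site] = base
            seq = "".join(chars)
        rows.append(
            AlignmentRow(
                sample_id=f"{species_id}_{i + 1:02d}",
                species_id=species_id,
                sequence=seq,
            )
        )
    alignment = GeneAlignment(gene_id=gene_id, level="dna", rows=rows)
    truth = PlantedGene(
        gene_id=gene_id,
        species_id=species_id,
        length=L,
        n_individuals=n,
        S_dna=S,
        k_dna=k,
        S_prot=n_nonsyn,
        k_prot=k_prot,
    )
    return alignment, truth


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given mean and SD (moment match)."""
    if mean <= 0:
        raise ValueError("log-normal moment matching needs mean > 0")
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def generate_expression_matrix(
    gene_params: Mapping[str, tuple[float, float]],
    n_samples: int,
    seed: "int | np.random.SeedSequence" = 0,
) -> pd.DataFrame:
    """Gene x sample TPM matrix with per-gene log-normal draws.

    Each gene's (mean, SD) is moment-matched on the natural scale.  An SD of
    zero yields a constant row; a zero mean requires a zero SD and yields a
    zero row.  Each gene's row holds draws for that gene's own species'
    individuals; columns are positional individual labels.
    """
    rng = np.random.default_rng(seed)
    rows = {}
    for gene_id, (mean, sd) in gene_params.items():
        if mean < 0 or sd < 0:
            raise ValueError(f"{gene_id}: mean and sd must be >= 0")
        if mean == 0:
            if sd > 0:
                raise ValueError(f"{gene_id}: sd > 0 with mean 0 is undefined")
            rows[gene_id] = np.zeros(n_samples)
        elif sd == 0:
            rows[gene_id] = np.full(n_samples, mean)
        else:
            mu, sigma = lognormal_params(mean, sd)
            rows[gene_id] = rng.lognormal(mu, sigma, size=n_samples)
    samples = [f"ind{i + 1:02d}" for i in range(n_samples)]
    mat = pd.DataFrame(rows, index=samples).T
    mat.index.name = "gene"
    return mat


def generate_titration_series(
    true_activity: float,
    C: float,
    noise_sd: float = 0.0,
    replicates: int = 3,
    seed: "int | np.random.SeedSequence" = 0,
    protein_id: str = "protein",
) -> TitrationSeries:
    """Triplicate-style activities from the simulated titration pipeline.

    Each replicate perturbs the latent half-coagulation threshold by a
    relative Gaussian factor of SD ``noise_sd`` and runs the full
    coarse-to-fine volume search; the reported activity follows from the
    found volume through the protocol formula.  Zero true activity yields
    all-zero replicates.
    """
    if true_activity < 0:
        raise ValueError("true activity must be >= 0")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    values = []
    for _ in range(replicates):
        eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        d50 = max(1.0 + eps, 0.05)
        model = CoagulationModel(
            specific_activity=true_activity, concentration=C, d50=d50
        )
        result = titrate_half_coagulation(model)
        values.append(round(result.atu(C), 3))
    return series_from_replicates(protein_id, values)


@dataclass
class StudyBundle:
    """One complete synthetic study plus its ground-truth manifest."""

    config: StudyConfig
    alignments: dict[str, GeneAlignment]
    expression: pd.DataFrame
    titrations: dict[str, TitrationSeries]
    manifest: dict = field(default_factory=dict)

    def species_of(self) -> dict[str, str]:
        return {g: spec[0] for g, spec in self.config.genes.items()}


def generate_study(config: StudyConfig | None = None) -> StudyBundle:
    """Generate the full study bundle from one configuration.

    Child seeds are spawned from the master seed in a fixed order —
    alignments (sorted by gene id), expression matrix, titrations (sorted by
    protein id) — so every component is reproducible independently.
    """
    if config is None:
        config = default_config()
    gene_ids = sorted(config.genes)
    ss = np.random.SeedSequence(config.master_seed)
    children = ss.spawn(len(gene_ids) + 1 + len(sorted(config.activity)))

    alignments: dict[str, GeneAlignment] = {}
    planted: dict[str, PlantedGene] = {}
    for child, gene_id in zip(children, gene_ids):
        species, L, S, k, n_nonsyn, k_prot = config.genes[gene_id]
        aln, truth = generate_alignment(
            L=L,
            n=config.n_individuals,
            S=S,
            k=k,
            n_nonsyn=n_nonsyn,
            k_prot=k_prot,
            seed=child,
            gene_id=gene_id,
            species_id=species,
        )
        alignments[gene_id] = aln
        planted[gene_id] = truth

    expression = generate_expression_matrix(
        config.expression, config.n_individuals, seed=children[len(gene_ids)]
    )

    titrations: dict[str, TitrationSeries] = {}
    protein_ids = sorted(config.activity)
    for child, protein_id in zip(children[len(gene_ids) + 1 :], protein_ids):
        titrations[protein_id] = generate_titration_series(
            true_activity=config.activity[protein_id],
            C=config.concentration[protein_id],
            noise_sd=config.titration_noise_sd,
            replicates=config.replicates,
            seed=child,
            protein_id=protein_id,
        )

    manifest = {
        "master_seed": config.master_seed,
        "n_individuals": config.n_individuals,
        "genes": {
            g: {
                "species": planted[g].species_id,
                "length": planted[g].length,
                "S_dna": planted[g].S_dna,
                "k_dna": planted[g].k_dna,
                "S_prot": planted[g].S_prot,
                "k_prot": planted[g].k_prot,
            }
            for g in gene_ids
        },
        "expression": {g: list(config.expression[g]) for g in config.expression},
        "activity": dict(config.activity),
        "concentration": dict(config.concentration),
        "titration_noise_sd": config.titration_noise_sd,
    }
    return StudyBundle(
        config=config,
        alignments=alignments,
        expression=expression,
        titrations=titrations,
        manifest=manifest,
    )
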