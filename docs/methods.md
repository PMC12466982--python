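# Methods

This note records the models, conventions and parameter defaults behind
each `hirukit` module, and the scope and limits of the synthetic-study
generator.

## 1. Sequence variation (`hirukit.seqvar`)

**Input.** A gapped coding-sequence alignment of n individuals for one
gene. Rows must be equal length; the length L must be a multiple of 3 and
each row must translate to `M…*` with no internal stop (checked by
`translate_alignment`).

**Variable sites.** A column is variable when it holds at least two
distinct non-ambiguous states. A gap (`-`) is a distinct state; ambiguity
codes (`N` at the nucleotide level, `X` at the protein level) are ignored —
a column that differs only by ambiguity codes is not variable. S is the
count of variable columns.

**Haplotypes.** Rows are collapsed on exact string identity of the full
sequence; k is the number of distinct sequences. Collapse is idempotent
and order-independent.

**Watterson's θ per site.** θ = S / (a · L) with the harmonic number
a = Σ_{i=1}^{m−1} 1/i. By default m is the *haplotype count* k
(`theta_convention="haplotype_n"`), the convention under which the package's
reference tables are internally consistent; the textbook convention m = n
(number of sequences sampled) is available as `"sequence_n"`. With k = 1
(monomorphic gene), θ = 0 by definition.

**Protein level.** The alignment is translated codon-by-codon (standard
code, via Biopython's codon table) *keeping the terminal stop as a column*,
so L_prot = L/3. S and k are then recomputed on the translated rows. A
nucleotide haplotype that differs only synonymously collapses into the same
protein haplotype, so k_prot ≤ k_dna and S_prot ≤ S_dna.

## 2. Protein physicochemistry (`hirukit.protein_props`)

- **GRAVY**: mean Kyte–Doolittle hydropathy over all residues.
- **Instability index** (Guruprasad): 10/L · Σ DIWV(x_i, x_{i+1}) over all
  dipeptides, using the published dipeptide weight table (imported from
  `Bio.SeqUtils.ProtParamData`); a protein is flagged unstable above 40.
- **Isoelectric point**: Bjellqvist charge model. Positive groups
  (N-terminus 7.50 by default, Lys 10.0, Arg 12.0, His 5.98) contribute
  +1/(1+10^(pH−pKa)); negative groups (C-terminus 3.55 by default, Asp 4.05,
  Glu 4.45, Cys 9.0, Tyr 10.0) contribute −1/(1+10^(pKa−pH)). The terminal
  pKas are adjusted by the identity of the terminal residue
  (N-terminal A/M/S/P/T/V/E; C-terminal D → 4.55, E → 4.75). The pI is the
  zero-crossing of total charge, found by bisection on [0, 14] to 1e-4.
  Note: because the C-terminal pKa depends on the final residue, appending
  an acidic residue can *raise* the pI of a very acidic peptide — charge
  monotonicity claims only hold for interior insertions.
- **Classification**: acidic if pI < 7, basic otherwise; hirudin maturation
  is modelled as removal of a given signal-peptide length.

All three calculators are cross-checked against Biopython in the test
suite; the pI cross-check widens Biopython's default bisection bracket
([4.05, 12]), which otherwise clamps very acidic peptides.

## 3. Antithrombin assay model (`hirukit.assay`)

**Definition.** One antithrombin unit neutralises the thrombin that clots a
standard fibrinogen aliquot. For a titration in which V µL of sample at
concentration C mg/mL is the smallest volume preventing coagulation,
specific activity is ATU/mg = 2500 / (V · C) × K (K a dilution factor,
default 1).

**Latent clot model.** A sample of true activity A neutralises
V·C·A/2500 "units" of the thrombin challenge; the observed clot fraction is
logistic((d50 − V·C·A/2500)/s) with d50 = 1 (the challenge) and s = 0.05.
Clot fraction > 0.95 is complete coagulation; [0.30, 0.70] is the
semi-coagulation window that the bench protocol reads as the endpoint.
A = 0 gives clot fraction exactly 1.

**Titration search.** A coarse-to-fine schedule (20, 10, 2 µL steps, grids
anchored at 0 so refinements nest) finds the semi-coagulation volume; the
pipetting floor is 2 µL. A sample whose clot fraction at 100 µL is still
above 0.70 is declared inactive. The estimate is quantised by the 2 µL
grid, so recovered activity is accurate to the grid, not exactly A;
replicate summaries report mean and sample (n−1) SD.

## 4. Expression statistics (`hirukit.expression_stats`)

All tests report statistic, Z (where applicable), df and a two-sided p.

- **KS normality screen**: D is the supremum distance between the empirical
  CDF and a normal with the sample mean and (n−1) SD. Because those
  parameters are estimated from the same sample, the default p-value is the
  Lilliefors-corrected one (statsmodels' table implementation); the power of
  the screen at study-scale n (≈12 individuals per gene) depends on the
  correction — the uncorrected asymptotic Kolmogorov p (`method="classical"`)
  has empirical size below 2% and power ≈0.15 against a strongly skewed
  lognormal at n = 12, versus ≈0.8 with the correction.
- **Mann–Whitney U**: reports min(U₁, U₂); Z = (U₁ − n₁n₂/2)/σ with the
  tie-corrected variance, no continuity correction by default
  (`continuity_correction=True` available; it is the variant that converges
  to the exact-enumeration p at small n). `exact=True` enumerates all
  C(n₁+n₂, n₁) group assignments.
- **Friedman**: mid-ranks within blocks, chi-square with the standard tie
  correction, df = k−1. With three treatments and three concordant blocks
  the statistic is exactly 6.000 (p ≈ 0.0498).
- **Wilcoxon signed-rank**: zero differences dropped, tie-corrected
  variance, Z from W⁺; `exact=True` enumerates all 2^n sign assignments.
  With three pairs the most extreme |Z| is 1.604 (untied) or √3 ≈ 1.732
  (fully tied), so triplicate-vs-triplicate comparisons can never reach
  p < 0.05 under the normal approximation — the battery therefore gates
  pairwise Wilcoxon tests on a significant Friedman omnibus.

**Battery** (`run_battery`): per-gene KS screens (constant rows skipped),
a species-total Mann–Whitney on per-sample column sums, all cross-species
gene pairs, a Friedman omnibus per species (blocks = individuals), and
within-species Wilcoxon pairs only where the omnibus is significant at α
(default 0.05). Type-I behaviour and power are property-tested on null and
planted-shift matrices.

## 5. Potency integration (`hirukit.potency`)

Per-gene potency is expression × activity (an optional exponent weights
expression); species potency is the sum over the family. The comparison
reports the winner, the ratio of totals, per-gene shares, and checks any
claimed fold-differences between named genes, emitting a warning (never a
correction) when a claim's direction contradicts the computed values.
Scores are scale-equivariant in both inputs, and zero-activity genes
contribute nothing regardless of expression.

## 6. Synthetic-study generator (`hirukit.synthetic`)

**Alignments with exact planted diversity.** The ancestral CDS is built
from fourfold-degenerate codons (after `ATG`, before `TAA`), so any
third-position change is synonymous and first/second-position changes are
nonsynonymous. Each derived haplotype receives a non-empty mutation set
disjoint from every other haplotype's, one mutation per codon; therefore
the realised segregating sites are exactly S, haplotypes exactly k,
nonsynonymous variable sites exactly `n_nonsyn` (each in a distinct codon,
protein-level S), and the protein haplotype count exactly `k_prot`
(haplotypes assigned only synonymous changes collapse to the ancestral
protein). Infeasible parameter combinations (S < k−1, S exceeding mutable
codons, k outside [1, n], k = 1 with S > 0, nonsynonymous counts
incompatible with k_prot) raise informative `ValueError`s rather than
silently degrading.

**Expression.** Per-gene TPM rows are log-normal with moment matching on
the natural scale: σ² = ln(1 + (sd/mean)²), μ = ln(mean) − σ²/2. A zero SD
yields a constant row; mean 0 requires SD 0.

**Titrations.** The true activity is perturbed multiplicatively per
replicate (normal noise, default SD 0.03) and pushed through the full
titration search, so replicates inherit the 2 µL quantisation of the assay.

**Determinism.** A study is generated from one master seed via
`numpy.random.SeedSequence.spawn` in a fixed order (genes sorted, then
expression, then proteins sorted), so every artefact is reproducible from
`--seed` and sub-streams are independent.

**Scope and limits.** The generator plants *counts*, not evolutionary
process: no recombination, no selection, no within-haplotype linkage
structure beyond the disjoint mutation sets, and haplotype frequencies are
as equal as n allows. It is designed for pipeline validation (planted-truth
recovery), not for population-genetic inference benchmarks.

## 7. Numerical choices

- θ and derived quantities are reported at five decimals (table precision);
  formatting lives in `hirukit.io`, computation is full precision.
- pI bisection tolerance 1e-4; activity tables rounded to 3 decimals.
- All SDs are sample (n−1) SDs.
- Seeds are kept below 2³¹ and all randomness flows through
  `numpy.random.default_rng` / `SeedSequence`.

## 8. Limitations

- The clot model's logistic slope (s = 0.05) and window [0.30, 0.70] are
  stylised; real turbidimetric endpoints have instrument-specific shapes.
- The haplotype-count θ convention is not the textbook estimator; both are
  implemented, and the choice must be stated when reporting θ.
- The Wilcoxon/Mann–Whitney normal approximations are poor below ~10
  effective observations; use `exact=True` there (the battery's pairwise
  stage at n = 12 individuals is comfortably above this).
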