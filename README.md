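# hirukit

Comparative analysis toolkit for leech hirudin multigene families. The
package models a complete desk-to-bench study comparing two *Hirudo*
species — *H. nipponia* (genes `Hnip1–3`) and *H. tianjinensis*
(`Htia1–3`) — each carrying a family of three hirudin-like anticoagulant
genes, and asks which species packs more antithrombin punch and which gene
carries that punch.

It implements the full analysis chain:

1. **Sequence variation** (`hirukit.seqvar`) — variable (segregating) sites,
   haplotype collapse and per-site Watterson's θ on coding-sequence
   alignments, at both the nucleotide and the translated-protein level.
2. **Protein physicochemistry** (`hirukit.protein_props`) — GRAVY
   (Kyte–Doolittle), the Guruprasad instability index, and a
   Bjellqvist-model isoelectric point with residue-specific terminal pKa
   adjustments, plus acidic/basic classification of mature hirudins.
3. **Antithrombin assay model** (`hirukit.assay`) — the thrombin-titration
   definition of antithrombin units (ATU/mg = 2500 / (V·C) × K), a latent
   clot-formation model, and a coarse-to-fine titration search that mimics a
   bench protocol (20 → 10 → 2 µL steps, 2 µL pipetting floor).
4. **Expression statistics** (`hirukit.expression_stats`) — the
   non-parametric battery used on per-individual TPM matrices:
   Kolmogorov–Smirnov normality screen (Lilliefors-corrected by default),
   Mann–Whitney U, Friedman, and Wilcoxon signed-rank tests, with
   tie-corrected normal approximations and exact-enumeration options.
5. **Potency integration** (`hirukit.potency`) — expression-weighted potency
   scores (Σ expression × activity per gene), per-gene shares, species
   comparison and consistency checks of claimed fold-differences.
6. **Synthetic studies** (`hirukit.synthetic`) — a planted-truth generator
   that produces alignments with *exactly* specified segregating-site and
   haplotype counts (at both levels), log-normal expression matrices
   moment-matched to target means/SDs, and noisy simulated titrations, all
   reproducible from one master seed.
7. **I/O and CLI** (`hirukit.io`, `hirukit.cli`) — FASTA and TSV readers and
   writers and a `hirukit` command-line pipeline.

## Worked example

Generate and analyse one synthetic study end to end:

```bash
hirukit all --seed 1 --outdir demo
```

`demo/variation.tsv` (per-gene diversity; θ shown at table precision):

```text
gene	L_dna	S_dna	k_dna	theta_dna	L_prot	S_prot	k_prot	theta_prot
Hnip1	204	13	4	0.03476	68	10	4	0.08021
Hnip2	252	2	2	0.00794	84	1	2	0.01190
Hnip3	207	4	4	0.01054	69	4	4	0.03162
Htia1	270	0	1	0.00000	90	0	1	0.00000
Htia2	252	8	6	0.01390	84	5	5	0.02857
Htia3	207	15	7	0.02958	69	7	7	0.04141
```

`demo/activity.tsv` (simulated triplicate titrations, ATU/mg):

```text
protein	repeat_1	repeat_2	repeat_3	mean	sd	active
Hnip1	231.997	185.598	231.997	216.531	26.788	True
Hnip2	65.288	65.288	65.288	65.288	0.000	True
Hnip3	0.000	0.000	0.000	0.000	0.000	False
Htia1	16.919	16.919	16.919	16.919	0.000	True
Htia2	7.473	7.473	7.473	7.473	0.000	True
Htia3	0.000	0.000	0.000	0.000	0.000	False
```

`demo/potency.txt` (expression-weighted verdict):

```text
species totals: H_nipponia=359114.7, H_tianjinensis=71137.9
ratio: 5.048
winner: H_nipponia
```

The same analyses are available as a Python API:

```python
from hirukit.synthetic import default_config, generate_study
from hirukit.seqvar import summarize_gene
from hirukit.expression_stats import run_battery

bundle = generate_study(default_config(master_seed=1))
summary = summarize_gene(bundle.alignments["Hnip1"])
print(summary.S_dna, summary.k_dna, round(summary.theta_dna, 5))
# 13 4 0.03476

report = run_battery(bundle.expression, bundle.species_of())
print(report.to_frame().head(3))
```

Individual pipeline stages are exposed as subcommands: `hirukit simulate`,
`variation`, `props`, `assay`, `expression`, `potency`. Every run writes a
`run_manifest.json` recording the subcommand, options and package version.

## Conventions worth knowing

- **Watterson's θ** uses the *haplotype count* k in the harmonic correction
  a = Σ_{i<k} 1/i by default (`theta_convention="haplotype_n"`); the
  textbook sequence-count convention is available as `"sequence_n"`. With a
  single haplotype θ = 0.
- **Protein-level diversity** keeps the stop codon as an alignment column,
  so the protein length is exactly L/3.
- Gaps count as a distinct state at a site; ambiguity codes (N/X) are
  ignored when deciding whether a site is variable.
- The **KS normality screen** defaults to the Lilliefors-corrected p-value
  (the parameters of the null normal are fitted to the sample);
  `method="classical"` gives the uncorrected asymptotic Kolmogorov p.
- The Mann–Whitney and Wilcoxon Z statistics use tie-corrected variances
  without a continuity correction by default; both tests take
  `exact=True` (full enumeration) and Mann–Whitney additionally
  `continuity_correction=True`.

## Documentation

See [docs/methods.md](docs/methods.md) for the model assumptions, parameter
defaults and numerical choices.
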