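"""Readers and writers for the pipeline's file formats.

Sequences travel as FASTA with ``>sampleID|speciesID`` headers (one file per
gene); tables as UTF-8 TSV with a header row; manifests as JSON.  Display
rounding follows the study tables (theta to 5 decimals, activities to 3,
pI/instability to 2, GRAVY to 3) while in-memory values keep full precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .assay import TitrationSeries
from .potency import SpeciesComparison
from .protein_props import ProteinProperties
from .seqvar import AlignmentRow, GeneAlignment, VariationSummary

__all__ = [
    "read_alignment_fasta",
    "write_alignment_fasta",
    "write_variation_table",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_species_map",
    "read_replicate_table",
    "write_activity_table",
    "write_properties_table",
    "write_potency_report",
    "write_manifest",
]


def read_alignment_fasta(
    path: "str | Path", gene_id: str | None = None, level: str = "dna"
) -> GeneAlignment:
    """Read one gene's aligned FASTA; headers must be ``sampleID|speciesID``."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty FASTA (no records)")
    rows = []
    for rec in records:
        if "|" not in rec.id:
            raise ValueError(
                f"{path}: malformed header {rec.id!r} (expected 'sampleID|speciesID')"
            )
        sample_id, species_id = rec.id.split("|", 1)
        if not sample_id or not species_id:
            raise ValueError(f"{path}: header {rec.id!r} has an empty field")
        rows.append(
            AlignmentRow(sample_id=sample_id, species_id=species_id, sequence=str(rec.seq))
        )
    return GeneAlignment(gene_id=gene_id or path.stem, level=level, rows=rows)


def write_alignment_fasta(alignment: GeneAlignment, path: "str | Path") -> None:
    records = [
        SeqRecord(
            Seq(row.sequence), id=f"{row.sample_id}|{row.species_id}", description=""
        )
        for row in alignment.rows
    ]
    SeqIO.write(records, str(path), "fasta")


def write_variation_table(
    summaries: Iterable[VariationSummary], path: "str | Path"
) -> pd.DataFrame:
    """Diversity-table TSV: one row per gene, theta to 5 decimals."""
    rows = [
        {
            "gene": s.gene_id,
            "L_dna": s.L_dna,
            "S_dna": s.S_dna,
            "k_dna": s.k_dna,
            "theta_dna": f"{s.theta_dna:.5f}",
            "L_prot": s.L_prot,
            "S_prot": s.S_prot,
            "k_prot": s.k_prot,
            "theta_prot": f"{s.theta_prot:.5f}",
        }
        for s in summaries
    ]
    frame = pd.DataFrame(rows)
    frame.to_csv(path, sep="\t", index=False)
    return frame


def read_expression_tsv(path: "str | Path") -> pd.DataFrame:
    """Gene x sample TPM matrix (first column = gene id)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.empty:
        raise ValueError(f"{path}: empty expression matrix")
    return frame


def write_expression_tsv(matrix: pd.DataFrame, path: "str | Path") -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


def read_species_map(path: "str | Path") -> dict[str, str]:
    """Two-column TSV mapping gene id to species id."""
    frame = pd.read_csv(path, sep="\t")
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: species map needs two columns (gene, species)")
    return dict(zip(frame.iloc[:, 0], frame.iloc[:, 1]))


def read_replicate_table(path: "str | Path") -> dict[str, list[float]]:
    """Replicate activity TSV: protein_id then one column per repeat."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.empty:
        raise ValueError(f"{path}: empty replicate table")
    return {str(pid): [float(v) for v in row.dropna()] for pid, row in frame.iterrows()}


def write_activity_table(
    series: Mapping[str, TitrationSeries], path: "str | Path"
) -> pd.DataFrame:
    """Activity-summary TSV shaped like the study's replicate table."""
    rows = []
    for pid, s in series.items():
        row = {"protein": pid}
        for i, v in enumerate(s.replicates, start=1):
            row[f"repeat_{i}"] = f"{v:.3f}"
        row["mean"] = f"{s.mean:.3f}"
        row["sd"] = f"{s.sd:.3f}"
        row["active"] = s.active
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame.to_csv(path, sep="\t", index=False)
    return frame


def write_properties_table(
    props: Iterable[ProteinProperties], path: "str | Path"
) -> pd.DataFrame:
    rows = [
        {
            "protein": p.protein_id,
            "pI": f"{p.pI:.2f}",
            "instability_index": f"{p.instability_index:.2f}",
            "gravy": f"{p.gravy:.3f}",
            "stability_label": "unstable" if p.unstable else "stable",
        }
        for p in props
    ]
    frame = pd.DataFrame(rows)
    frame.to_csv(path, sep="\t", index=False)
    return frame


def write_potency_report(comparison: SpeciesComparison, path: "str | Path") -> None:
    """Potency TSV (per-gene decomposition) plus a plain-text verdict."""
    rows = []
    for score in (comparison.score_a, comparison.score_b):
        shares = score.shares()
        for g in score.per_gene:
            rows.append(
                {
                    "species": score.species_id,
                    "gene": g.gene_id,
                    "expression_tpm": g.expression,
                    "activity_atu_per_mg": g.activity,
                    "product": g.product,
                    "share": shares[g.gene_id],
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    verdict = Path(path).with_suffix(".txt")
    lines = [
        f"species totals: {comparison.score_a.species_id}="
        f"{comparison.score_a.total:.1f}, {comparison.score_b.species_id}="
        f"{comparison.score_b.total:.1f}",
        f"ratio: {comparison.ratio:.3f}",
        f"winner: {comparison.winner}",
    ]
    lines += [f"warning: {w}" for w in comparison.warnings]
    verdict.write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_manifest(manifest: dict, path: "str | Path") -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")
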