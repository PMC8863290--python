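"""Plain-text writers for the synthetic catalog (VCF, GTF, TSV, JSON).

All writers are pure functions of their inputs, so a fixed simulation
seed reproduces every output file byte for byte.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from ..annotation import GeneModel
from ..ld import HaplotypePanel
from .config import TruthRecord

__all__ = [
    "write_vcf",
    "write_gtf",
    "write_gwas_tsv",
    "write_qtl_tsv",
    "write_ase_tsv",
    "write_expression_tsv",
    "write_alias_tsv",
    "write_truth_json",
]

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID={chrom}>\n"
)


def write_vcf(panel: HaplotypePanel, path: str | Path, phased: bool = True) -> None:
    """Write the panel as a biallelic SNV VCF v4.2 (1-based POS; phased
    '|' genotypes, or unphased '/' for dosage-oriented use)."""
    sep = "|" if phased else "/"
    sample_names = [f"S{i:04d}" for i in range(panel.n_samples)]
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(chrom=panel.chrom))
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names)
            + "\n"
        )
        h = panel.haplotypes
        for j in range(panel.n_variants):
            ref = panel.ref[j] if panel.ref else "A"
            alt = panel.alt[j] if panel.alt else "G"
            gts = [
                f"{h[2 * s, j]}{sep}{h[2 * s + 1, j]}"
                for s in range(panel.n_samples)
            ]
            fh.write(
                f"{panel.chrom}\t{panel.positions[j]}\t{panel.variant_ids[j]}\t"
                f"{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def write_gtf(genes: list[GeneModel], path: str | Path, source: str = "locuslens") -> None:
    """Write gene/transcript/exon features with gene_id, transcript_id and
    transcript_biotype attributes (Ensembl dialect)."""
    with open(path, "w") as fh:
        for g in genes:
            span = g.span
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.symbol}";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{span[0]}\t{span[1]}\t.\t"
                f"{g.transcripts[0].strand}\t.\t{attrs}\n"
            )
            for t in g.transcripts:
                tattrs = (
                    f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'transcript_biotype "{t.biotype}";'
                )
                fh.write(
                    f"{t.chrom}\t{source}\ttranscript\t{t.start}\t{t.end}\t.\t"
                    f"{t.strand}\t.\t{tattrs}\n"
                )
                for s, e in t.exons or [(t.start, t.end)]:
                    fh.write(
                        f"{t.chrom}\t{source}\texon\t{s}\t{e}\t.\t{t.strand}\t.\t"
                        f"{tattrs}\n"
                    )


def write_gwas_tsv(gwas: pd.DataFrame, path: str | Path) -> None:
    gwas.to_csv(path, sep="\t", index=False)


def write_qtl_tsv(qtls: pd.DataFrame, path: str | Path) -> None:
    qtls.to_csv(path, sep="\t", index=False)


def write_ase_tsv(observations, path: str | Path) -> None:
    rows = [
        {
            "SAMPLE_ID": o.sample_id,
            "TISSUE_ID": o.tissue_id,
            "VARIANT_ID": o.variant_id,
            "REF_COUNT": o.ref_count,
            "ALT_COUNT": o.alt_count,
            "REF_RATIO": round(o.ref_ratio, 6) if o.total > 0 else "",
            "NULL_RATIO": o.null_ratio,
        }
        for o in observations
    ]
    pd.DataFrame(
        rows,
        columns=[
            "SAMPLE_ID", "TISSUE_ID", "VARIANT_ID",
            "REF_COUNT", "ALT_COUNT", "REF_RATIO", "NULL_RATIO",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_expression_tsv(expression: pd.DataFrame, path: str | Path) -> None:
    expression.to_csv(path, sep="\t", index_label="sample")


def write_alias_tsv(alias: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(alias.items()), columns=["rs_id", "variant_key"]
    ).to_csv(path, sep="\t", index=False)


def write_truth_json(truth: list[TruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([t.to_dict() for t in truth], fh, indent=2, sort_keys=True)
        fh.write("\n")
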