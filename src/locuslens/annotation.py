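"""Gene and transcript models, coding-status classification, and
strand-agnostic positional candidate-gene lookup.

Coding status follows fixed controlled-vocabulary lists of transcript
biotypes (Ensembl/BioMart dialect). A gene is non-coding only if every one
of its transcripts is non-coding; a single protein-coding transcript makes
the gene coding. Positional candidates are genes with any transcript whose
genomic span (introns included) covers the queried variant position,
regardless of strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

__all__ = [
    "TranscriptModel",
    "GeneModel",
    "UnknownBiotypeError",
    "CODING_BIOTYPES",
    "NONCODING_BIOTYPES",
    "classify_transcript_biotype",
    "gene_coding_status",
    "positional_candidate_genes",
    "PositionalIndex",
    "read_gtf",
]

# Transcript biotypes treated as protein-coding (normalised form:
# lower-case, spaces mapped to underscores).
CODING_BIOTYPES = frozenset(
    {
        "igc_gene",
        "igd_gene",
        "ig_gene",
        "igj_gene",
        "iglv_gene",
        "igm_gene",
        "igv_gene",
        "igz_gene",
        "nonsense_mediated_decay",
        "nontranslating_cds",
        "non_stop_decay",
        "polymorphic_pseudogene",
        "trc_gene",
        "trd_gene",
        "trj_gene",
        "protein_coding",
        "tec",
    }
)

# Everything else with a recognised annotation is non-coding.
NONCODING_BIOTYPES = frozenset(
    {
        "disrupted_domain",
        "igc_pseudogene",
        "igj_pseudogene",
        "ig_pseudogene",
        "igv_pseudogene",
        "processed_pseudogene",
        "transcribed_processed_pseudogene",
        "transcribed_unitary_pseudogene",
        "transcribed_unprocessed_pseudogene",
        "translated_processed_pseudogene",
        "trj_pseudogene",
        "unprocessed_pseudogene",
        "unitary_pseudogene",
        "3prime_overlapping_ncrna",
        "ambiguous_orf",
        "antisense",
        "antisense_rna",
        "lincrna",
        "ncrna_host",
        "processed_transcript",
        "sense_intronic",
        "sense_overlapping",
        "lncrna",
        "retained_intron",
        "mirna",
        "mirna_pseudogene",
        "miscrna",
        "miscrna_pseudogene",
        "mt_rrna",
        "mt_trna",
        "rrna",
        "scrna",
        "snlrna",
        "snorna",
        "snrna",
        "trna",
        "trna_pseudogene",
        "rrna_pseudogene",
    }
)


class UnknownBiotypeError(ValueError):
    """Biotype found in neither the coding nor the non-coding list."""


def _normalize_biotype(biotype: str) -> str:
    return biotype.strip().lower().replace(" ", "_").replace("-", "_")


def classify_transcript_biotype(biotype: str) -> str:
    """Map a transcript biotype to "coding" or "noncoding".

    Normalisation is case-insensitive and treats spaces, hyphens and
    underscores alike. A biotype absent from both controlled lists raises
    :class:`UnknownBiotypeError`; there is no silent default.
    """
    if not biotype or not biotype.strip():
        raise ValueError("biotype must be a non-empty string")
    key = _normalize_biotype(biotype)
    if key in CODING_BIOTYPES:
        return "coding"
    if key in NONCODING_BIOTYPES:
        return "noncoding"
    raise UnknownBiotypeError(f"unrecognised transcript biotype: {biotype!r}")


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    biotype: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"transcript {self.transcript_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.exons = sorted(self.exons)
        prev_end = None
        for s, e in self.exons:
            if s > e or s < self.start or e > self.end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exon ({s}, {e}) outside span"
                )
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"transcript {self.transcript_id}: overlapping exons")
            prev_end = e

    def contains(self, pos: int) -> bool:
        """Span overlap, introns included; both ends inclusive."""
        return self.start <= pos <= self.end

    def is_coding(self) -> bool:
        return classify_transcript_biotype(self.biotype) == "coding"


@dataclass
class GeneModel:
    gene_id: str
    symbol: str
    chrom: str
    transcripts: list[TranscriptModel]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        for t in self.transcripts:
            if t.chrom != self.chrom:
                raise ValueError(
                    f"gene {self.gene_id}: transcript {t.transcript_id} on {t.chrom}"
                )

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(t.start for t in self.transcripts),
            max(t.end for t in self.transcripts),
        )


def gene_coding_status(gene: GeneModel) -> str:
    """"noncoding" iff every transcript is non-coding, else "coding"."""
    return (
        "noncoding"
        if all(not t.is_coding() for t in gene.transcripts)
        else "coding"
    )


class PositionalIndex:
    """Interval index over transcript spans for repeated position queries."""

    def __init__(self, genes: list[GeneModel]):
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            for t in g.transcripts:
                tree = self._trees.setdefault(t.chrom, IntervalTree())
                # interval tree is half-open; +1 keeps the end inclusive
                tree.addi(t.start, t.end + 1, g.gene_id)

    def query(self, chrom: str, pos: int) -> set[str]:
        tree = self._trees.get(chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.at(pos)}


def positional_candidate_genes(
    chrom: str, pos: int, genes: list[GeneModel]
) -> set[str]:
    """Gene ids with >=1 transcript whose [start, end] span covers ``pos``.

    Strand is ignored, so antisense-overlapping genes are returned too; an
    empty set is a valid answer.
    """
    return PositionalIndex(genes).query(chrom, pos)


def read_gtf(path: str) -> list[GeneModel]:
    """Parse gene models from a GTF file.

    Accepts both ``transcript_biotype`` and ``transcript_type`` attribute
    keys (Ensembl vs GENCODE). Feature rows other than gene/transcript/exon
    are skipped. Transcripts missing a biotype attribute fall back to the
    gene-level biotype key.
    """
    import gffutils

    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    def _attr(feat, *keys: str) -> str | None:
        for k in keys:
            if k in feat.attributes:
                return feat.attributes[k][0]
        return None

    transcripts: dict[str, TranscriptModel] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    gene_symbol: dict[str, str] = {}
    for feat in db.all_features():
        if feat.featuretype == "gene":
            gid = _attr(feat, "gene_id")
            if gid:
                gene_symbol[gid] = _attr(feat, "gene_name") or gid
        elif feat.featuretype == "transcript":
            tid = _attr(feat, "transcript_id")
            gid = _attr(feat, "gene_id")
            bt = _attr(feat, "transcript_biotype", "transcript_type", "biotype")
            if tid is None or gid is None or bt is None:
                raise ValueError(f"transcript row missing required attributes: {feat}")
            transcripts[tid] = TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                chrom=feat.seqid,
                strand=feat.strand,
                start=feat.start,
                end=feat.end,
                biotype=bt,
            )
        elif feat.featuretype == "exon":
            tid = _attr(feat, "transcript_id")
            if tid is not None:
                exons.setdefault(tid, []).append((feat.start, feat.end))

    by_gene: dict[str, list[TranscriptModel]] = {}
    for tid, t in transcripts.items():
        if tid in exons:
            t = TranscriptModel(
                transcript_id=t.transcript_id,
                gene_id=t.gene_id,
                chrom=t.chrom,
                strand=t.strand,
                start=t.start,
                end=t.end,
                biotype=t.biotype,
                exons=sorted(exons[tid]),
            )
        by_gene.setdefault(t.gene_id, []).append(t)

    genes = []
    for gid, ts in by_gene.items():
        genes.append(
            GeneModel(
                gene_id=gid,
                symbol=gene_symbol.get(gid, gid),
                chrom=ts[0].chrom,
                transcripts=sorted(ts, key=lambda t: t.transcript_id),
            )
        )
    return sorted(genes, key=lambda g: g.gene_id)
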