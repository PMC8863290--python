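"""Candidate-gene reprioritization for GWAS loci.

Each GWAS locus carries one or more marker variants and a set of
GWAS-annotated genes G. Exact-match lookup against significant cis-QTL
tables (eQTL and sQTL, any tissue) plus strand-agnostic positional overlap
yields the evidence gene set Q. Loci are then classified:

* Tier 1  — Q is non-empty and introduces nothing beyond G (Q ⊆ G):
            the GWAS annotation is supported, no new genes.
* Tier 2A — new genes appear and every GWAS gene is supported (G ⊆ Q).
* Tier 2B — new genes appear and some but not all GWAS genes supported.
* Tier 2C — new genes appear and no GWAS gene is supported.
* Tier 3  — no QTL and no positional overlap at all (Q empty): the
            annotation is neither supported nor contradicted.

For Tier-3 loci, `expand_markers` searches a haplotype panel for proxy
variants in strong LD (r² > 0.8 by default) within a 1 Mb window so the
QTL lookup can be repeated on the expanded marker set.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ld import HaplotypePanel, r2_phased

__all__ = [
    "Variant",
    "GwasLocus",
    "QtlRecord",
    "EvidenceTable",
    "TierAssignment",
    "VariantIdentityError",
    "normalize_variant_id",
    "match_qtls",
    "build_evidence",
    "assign_tier",
    "expand_markers",
    "summarize_tiers",
    "classify_catalog",
    "read_gwas_tsv",
    "read_qtl_tsv",
]

TIERS = ("1", "2A", "2B", "2C", "3")


class VariantIdentityError(ValueError):
    """A variant could not be resolved to normalized chrom:pos:ref:alt."""


def normalize_variant_id(
    variant: str, alias: dict[str, str] | None = None
) -> str:
    """Normalize a variant identity to ``chrom:pos:ref:alt``.

    Accepts GTEx-style ``chr10_89243088_C_T_b38``, colon-separated
    ``10:89243088:C:T`` and rsIDs (resolved through ``alias``, a mapping
    rsID -> normalized id). Raises VariantIdentityError for an rsID with
    no alias entry.
    """
    v = variant.strip()
    if v.lower().startswith("rs"):
        if alias and v in alias:
            return normalize_variant_id(alias[v])
        raise VariantIdentityError(
            f"rsID {v!r} has no coordinate entry in the alias table"
        )
    if "_" in v:
        parts = v.split("_")
        if parts[-1].startswith("b"):  # build suffix, e.g. _b38
            parts = parts[:-1]
        if len(parts) != 4:
            raise VariantIdentityError(f"cannot parse variant id {variant!r}")
        chrom, pos, ref, alt = parts
    elif ":" in v:
        parts = v.split(":")
        if len(parts) != 4:
            raise VariantIdentityError(f"cannot parse variant id {variant!r}")
        chrom, pos, ref, alt = parts
    else:
        raise VariantIdentityError(f"cannot parse variant id {variant!r}")
    chrom = chrom.removeprefix("chr")
    return f"{chrom}:{int(pos)}:{ref.upper()}:{alt.upper()}"


@dataclass(frozen=True)
class Variant:
    """A GWAS marker with both naming systems attached."""

    rs_id: str
    chrom: str
    pos: int
    ref: str
    alt: str

    @property
    def key(self) -> str:
        return f"{self.chrom.removeprefix('chr')}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class GwasLocus:
    locus_label: str
    variants: list[Variant]
    gwas_genes: set[str]
    odds_ratio: dict[str, float] = field(default_factory=dict)  # per rs_id
    risk_allele_freq: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValueError(f"locus {self.locus_label} has no variants")


@dataclass(frozen=True)
class QtlRecord:
    variant_id: str  # normalized chrom:pos:ref:alt
    gene_id: str
    tissue: str
    qtl_type: str  # "eQTL" | "sQTL"
    slope: float
    pval_nominal: float

    def __post_init__(self) -> None:
        if self.qtl_type not in {"eQTL", "sQTL"}:
            raise ValueError(f"qtl_type must be eQTL or sQTL, got {self.qtl_type!r}")
        if not (0 < self.pval_nominal <= 1):
            raise ValueError(f"pval_nominal out of (0, 1]: {self.pval_nominal}")


@dataclass
class EvidenceTable:
    """Per-locus map gene -> evidence sources (tissue lists + position)."""

    locus_label: str
    eqtl_tissues: dict[str, set[str]] = field(default_factory=dict)
    sqtl_tissues: dict[str, set[str]] = field(default_factory=dict)
    positional: set[str] = field(default_factory=set)

    @property
    def genes(self) -> set[str]:
        return set(self.eqtl_tissues) | set(self.sqtl_tissues) | self.positional

    def sources_for(self, gene_id: str) -> set[str]:
        s = set()
        if gene_id in self.eqtl_tissues:
            s.add("eQTL")
        if gene_id in self.sqtl_tissues:
            s.add("sQTL")
        if gene_id in self.positional:
            s.add("position")
        return s

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in sorted(self.genes):
            rows.append(
                {
                    "locus": self.locus_label,
                    "gene_id": g,
                    "sources": ";".join(sorted(self.sources_for(g))),
                    "eqtl_tissues": ";".join(sorted(self.eqtl_tissues.get(g, set()))),
                    "sqtl_tissues": ";".join(sorted(self.sqtl_tissues.get(g, set()))),
                }
            )
        return pd.DataFrame(
            rows, columns=["locus", "gene_id", "sources", "eqtl_tissues", "sqtl_tissues"]
        )


@dataclass
class TierAssignment:
    locus_label: str
    tier: str  # "1" | "2A" | "2B" | "2C" | "3"
    supported_gwas_genes: set[str]
    new_genes: set[str]

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise ValueError(f"invalid tier {self.tier!r}")


def match_qtls(
    locus: GwasLocus,
    qtl_table: pd.DataFrame,
    alias: dict[str, str] | None = None,
) -> list[QtlRecord]:
    """Exact-identity QTL lookup for a locus's marker variants.

    Only records whose normalized variant identity equals one of the locus
    variants are returned — no LD-based relaxation. A variant that appears
    as both eQTL and sQTL in the same tissue yields two records.
    """
    keys = {v.key for v in locus.variants}
    records = []
    for row in qtl_table.itertuples(index=False):
        vid = normalize_variant_id(str(row.variant_id), alias)
        if vid in keys:
            records.append(
                QtlRecord(
                    variant_id=vid,
                    gene_id=str(row.gene_id),
                    tissue=str(row.tissue),
                    qtl_type=str(row.qtl_type),
                    slope=float(row.slope),
                    pval_nominal=float(row.pval_nominal),
                )
            )
    return records


def build_evidence(
    locus: GwasLocus,
    qtl_records: list[QtlRecord],
    positional_genes: dict[str, set[str]] | set[str] | None = None,
) -> EvidenceTable:
    """Aggregate QTL and positional evidence over all of a locus's variants.

    ``positional_genes`` maps each variant key to the genes whose
    transcript spans cover it (or is a flat set applying to the locus).
    Evidence is unioned across the locus's variants; a locus gets one tier
    even when Table-style reporting lists per-SNP rows.
    """
    ev = EvidenceTable(locus_label=locus.locus_label)
    keys = {v.key for v in locus.variants}
    for rec in qtl_records:
        if rec.variant_id not in keys:
            raise ValueError(
                f"QTL record {rec.variant_id} does not belong to locus "
                f"{locus.locus_label}"
            )
        target = ev.eqtl_tissues if rec.qtl_type == "eQTL" else ev.sqtl_tissues
        target.setdefault(rec.gene_id, set()).add(rec.tissue)
    if positional_genes:
        if isinstance(positional_genes, set):
            ev.positional |= positional_genes
        else:
            for key, genes in positional_genes.items():
                if key in keys:
                    ev.positional |= genes
    return ev


def assign_tier(
    locus_label: str, gwas_genes: set[str], evidence_genes: set[str]
) -> TierAssignment:
    """Classify a locus by agreement between GWAS annotation G and
    QTL/position evidence Q.

    Q = ∅ → Tier 3. Q ⊆ G (Q non-empty) → Tier 1. Otherwise new genes
    exist: G ⊆ Q → 2A; G ∩ Q ≠ ∅ → 2B; G ∩ Q = ∅ → 2C. The degenerate
    G = ∅ with Q ≠ ∅ falls to 2C (all evidence genes are new).
    """
    g, q = set(gwas_genes), set(evidence_genes)
    supported = g & q
    new = q - g
    if not q:
        tier = "3"
    elif not new:
        tier = "1"
    elif g and g <= q:
        tier = "2A"
    elif supported:
        tier = "2B"
    else:
        tier = "2C"
    return TierAssignment(
        locus_label=locus_label,
        tier=tier,
        supported_gwas_genes=supported,
        new_genes=new,
    )


def expand_markers(
    variant_id: str,
    panel: HaplotypePanel,
    window: int = 1_000_000,
    r2_min: float = 0.8,
) -> set[str]:
    """Proxy-SNP expansion for a marker: the query plus all panel variants
    within ±window/2 whose r² with the query exceeds ``r2_min`` (strict).

    Re-running the QTL lookup on the expanded set is the caller's
    follow-up step.
    """
    qi = panel.index_of(variant_id)
    qpos = int(panel.positions[qi])
    half = window // 2
    out = {variant_id}
    for j in range(panel.n_variants):
        if j == qi:
            continue
        if abs(int(panel.positions[j]) - qpos) > half:
            continue
        if r2_phased(panel, qi, j) > r2_min:
            out.add(panel.variant_ids[j])
    return out


def summarize_tiers(
    assignments: list[TierAssignment],
    evidence: list[EvidenceTable] | None = None,
) -> dict:
    """Tally loci per tier, and (when evidence tables are supplied)
    new-gene additions per source: genes implicated by exactly one of
    eQTL/sQTL/position are counted under that source, genes with several
    sources under "combination".
    """
    tier_counts = Counter(a.tier for a in assignments)
    out = {
        "n_loci": len(assignments),
        "tier_counts": {t: int(tier_counts.get(t, 0)) for t in TIERS},
    }
    if evidence is not None:
        by_label = {e.locus_label: e for e in evidence}
        source_counts = Counter()
        new_total = 0
        for a in assignments:
            ev = by_label.get(a.locus_label)
            if ev is None:
                continue
            for gene in a.new_genes:
                srcs = ev.sources_for(gene)
                new_total += 1
                if len(srcs) == 1:
                    source_counts[next(iter(srcs))] += 1
                else:
                    source_counts["combination"] += 1
        out["new_genes_total"] = new_total
        out["new_genes_by_source"] = {
            k: int(source_counts.get(k, 0))
            for k in ("eQTL", "sQTL", "position", "combination")
        }
    return out


def classify_catalog(
    loci: list[GwasLocus],
    qtl_table: pd.DataFrame,
    positional_genes: dict[str, set[str]],
    alias: dict[str, str] | None = None,
) -> tuple[list[TierAssignment], list[EvidenceTable]]:
    """End-to-end: match QTLs, build evidence and assign a tier per locus."""
    assignments, tables = [], []
    for locus in loci:
        recs = match_qtls(locus, qtl_table, alias)
        ev = build_evidence(locus, recs, positional_genes)
        tables.append(ev)
        assignments.append(assign_tier(locus.locus_label, locus.gwas_genes, ev.genes))
    return assignments, tables


def read_gwas_tsv(path: str) -> list[GwasLocus]:
    """Read a GWAS hit table (locus, rs_id, chrom, pos, effect_allele,
    other_allele, OR, annotated_genes) into loci, merging per-SNP rows that
    share a locus label."""
    df = pd.read_csv(path, sep="\t", dtype={"locus": str, "chrom": str})
    loci = []
    for label, sub in df.groupby("locus", sort=True):
        variants, ors, rafs = [], {}, {}
        genes: set[str] = set()
        for row in sub.itertuples(index=False):
            v = Variant(
                rs_id=str(row.rs_id),
                chrom=str(row.chrom).removeprefix("chr"),
                pos=int(row.pos),
                ref=str(row.other_allele),
                alt=str(row.effect_allele),
            )
            variants.append(v)
            if not np.isnan(float(getattr(row, "OR", np.nan))):
                ors[v.rs_id] = float(row.OR)
            raf = float(getattr(row, "risk_allele_freq", np.nan))
            if not np.isnan(raf):
                rafs[v.rs_id] = raf
            ann = str(getattr(row, "annotated_genes", "") or "")
            genes |= {g for g in ann.split(";") if g}
        loci.append(
            GwasLocus(
                locus_label=str(label),
                variants=variants,
                gwas_genes=genes,
                odds_ratio=ors,
                risk_allele_freq=rafs,
            )
        )
    return loci


def read_qtl_tsv(path: str) -> pd.DataFrame:
    """Read a QTL TSV (variant_id, rs_id, gene_id, tissue, slope,
    pval_nominal, qtl_type)."""
    df = pd.read_csv(path, sep="\t")
    required = {"variant_id", "gene_id", "tissue", "slope", "pval_nominal", "qtl_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"QTL table missing columns: {sorted(missing)}")
    return df
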