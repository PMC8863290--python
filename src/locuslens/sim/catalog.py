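"""Full synthetic locus catalog with planted tier structure.

Builds, for each requested tier, a GWAS locus whose evidence pattern
forces that tier by construction:

* Tier 1  — two marker SNPs (a multi-SNP locus), both eQTLs for the single
            GWAS-annotated gene, which the lead SNP also sits inside.
* Tier 2A — the marker supports the GWAS gene and adds a non-coding
            neighbour.
* Tier 2B — two GWAS genes, the marker supports one and adds a new gene.
* Tier 2C — the marker implicates only a gene GWAS did not annotate.
* Tier 3  — no QTL at all and the marker overlaps no transcript.

Each locus occupies its own region of chromosome 1 with a private pair of
founder blocks (one strong-LD block containing the markers, one weak-LD
block of control variants), so LD-based follow-ups (proxy expansion,
strong/weak AEI controls) have planted structure to find. The Tier-1
locus also carries the planted expression effect (single causal variant,
one independent signal) and an allelic-imbalance site.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ..aei import AseObservation
from ..annotation import GeneModel, TranscriptModel, positional_candidate_genes
from ..ld import HaplotypePanel
from ..reprioritize import GwasLocus, Variant
from . import io as sim_io
from .ase import simulate_ase
from .config import AseSpec, CausalGene, SimulationConfig, TruthRecord
from .expression import simulate_expression
from .haplotypes import simulate_haplotypes

__all__ = ["LocusCatalog", "simulate_locus_catalog"]

_REGION_SPAN = 10_000_000
_BLOCK_LEN = 6
_SPACING = 4_000

DEFAULT_TIER_PLAN = ("1", "2A", "2B", "2C", "3")

EQTL_TISSUES = ("Blood", "Liver", "Lung")
SQTL_TISSUES = ("Blood",)


@dataclass
class LocusCatalog:
    """Everything the pipeline consumes, plus the planted truth."""

    config: SimulationConfig
    loci: list[GwasLocus]
    gwas: pd.DataFrame
    qtls: pd.DataFrame
    genes: list[GeneModel]
    panel: HaplotypePanel
    alias: dict[str, str]
    ase: list[AseObservation]
    expression: pd.DataFrame
    truth: list[TruthRecord]
    positional: dict[str, set[str]] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write every artefact as plain text; returns the path map."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": out / "panel.vcf",
            "gtf": out / "genes.gtf",
            "gwas": out / "gwas.tsv",
            "eqtl": out / "eqtl.tsv",
            "sqtl": out / "sqtl.tsv",
            "ase": out / "ase.tsv",
            "expression": out / "expression.tsv",
            "alias": out / "alias.tsv",
            "truth": out / "truth.json",
        }
        sim_io.write_vcf(self.panel, paths["vcf"])
        sim_io.write_gtf(self.genes, paths["gtf"])
        sim_io.write_gwas_tsv(self.gwas, paths["gwas"])
        sim_io.write_qtl_tsv(
            self.qtls[self.qtls.qtl_type == "eQTL"].reset_index(drop=True),
            paths["eqtl"],
        )
        sim_io.write_qtl_tsv(
            self.qtls[self.qtls.qtl_type == "sQTL"].reset_index(drop=True),
            paths["sqtl"],
        )
        sim_io.write_ase_tsv(self.ase, paths["ase"])
        sim_io.write_expression_tsv(self.expression, paths["expression"])
        sim_io.write_alias_tsv(self.alias, paths["alias"])
        sim_io.write_truth_json(self.truth, paths["truth"])
        return paths


def _gene(
    gene_id: str, chrom: str, start: int, end: int, biotypes: tuple[str, ...],
    strand: str = "+",
) -> GeneModel:
    transcripts = [
        TranscriptModel(
            transcript_id=f"{gene_id}.t{i + 1}",
            gene_id=gene_id,
            chrom=chrom,
            strand=strand if i % 2 == 0 else ("-" if strand == "+" else "+"),
            start=start,
            end=end,
            biotype=bt,
            exons=[(start, start + 500), (end - 500, end)],
        )
        for i, bt in enumerate(biotypes)
    ]
    return GeneModel(gene_id=gene_id, symbol=gene_id, chrom=chrom, transcripts=transcripts)


def _gtex_id(chrom: str, pos: int, ref: str, alt: str) -> str:
    return f"chr{chrom}_{pos}_{ref}_{alt}_b38"


def simulate_locus_catalog(
    config: SimulationConfig,
    tier_plan: tuple[str, ...] = DEFAULT_TIER_PLAN,
) -> LocusCatalog:
    """Generate a catalog with one locus per entry of ``tier_plan``.

    An empty plan yields an empty-but-valid catalog. A fixed config gives
    byte-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    chrom = "1"
    n = config.n_samples

    loci: list[GwasLocus] = []
    genes: list[GeneModel] = []
    truth: list[TruthRecord] = []
    alias: dict[str, str] = {}
    gwas_rows, qtl_rows = [], []
    panels: list[HaplotypePanel] = []
    causal_spec: list[CausalGene] = list(config.causal_spec)
    ase_obs: list[AseObservation] = []
    rs_counter = 1000

    for i, tier in enumerate(tier_plan):
        if tier not in {"1", "2A", "2B", "2C", "3"}:
            raise ValueError(f"unknown tier {tier!r} in plan")
        region = 1_000_000 + i * _REGION_SPAN
        label = f"L{i + 1:02d}"
        sub = replace(
            config,
            block_spec=((_BLOCK_LEN, 1), (_BLOCK_LEN, 1)),
        )
        panel = simulate_haplotypes(
            sub, chrom=chrom, start_pos=region, spacing=_SPACING, rng=rng
        )
        panels.append(panel)
        lead = 0  # first variant of the strong-LD block marks the locus

        def _variant(j: int) -> tuple[Variant, str]:
            nonlocal rs_counter
            rs = f"rs{rs_counter}"
            rs_counter += 1
            v = Variant(
                rs_id=rs,
                chrom=chrom,
                pos=int(panel.positions[j]),
                ref=panel.ref[j],
                alt=panel.alt[j],
            )
            alias[rs] = v.key
            return v, rs

        v_lead, rs_lead = _variant(lead)
        marker_variants = [v_lead]
        if tier == "1":
            v2, _ = _variant(1)  # second SNP of the same tight block
            marker_variants.append(v2)

        gene_a = f"G{i + 1:02d}A"
        gene_b = f"G{i + 1:02d}B"
        gene_c = f"G{i + 1:02d}C"
        block_start = int(panel.positions[0])
        block_end = int(panel.positions[_BLOCK_LEN - 1])
        far = region + 2_000_000  # transcripts here cannot overlap markers

        def _emit_qtl(variant: Variant, gene_id: str, qtl_type: str,
                      tissues: tuple[str, ...], slope: float) -> None:
            for t in tissues:
                qtl_rows.append(
                    {
                        "variant_id": _gtex_id(variant.chrom, variant.pos,
                                               variant.ref, variant.alt),
                        "rs_id": variant.rs_id,
                        "gene_id": gene_id,
                        "tissue": t,
                        "slope": slope,
                        "pval_nominal": 1e-10,
                        "qtl_type": qtl_type,
                    }
                )

        if tier == "1":
            genes.append(_gene(gene_a, chrom, block_start - 2_000, block_end + 2_000,
                               ("protein_coding", "retained_intron")))
            gwas_genes = {gene_a}
            for v in marker_variants:
                _emit_qtl(v, gene_a, "eQTL", EQTL_TISSUES, 0.4)
            _emit_qtl(v_lead, gene_a, "sQTL", SQTL_TISSUES, -0.3)
            causal_spec.append(
                CausalGene(gene_id=gene_a, effects=((panel.variant_ids[lead], 0.2),))
            )
            dos = panel.dosages()[:, lead]
            het = [f"S{s:04d}" for s in np.flatnonzero(dos == 1)]
            spec = AseSpec(
                depth_mean=config.ase_spec.depth_mean,
                depth_dispersion=config.ase_spec.depth_dispersion,
                fold_change=2.0,
                ref_bias=config.ase_spec.ref_bias,
            )
            ase_obs.extend(
                simulate_ase(het, panel.variant_ids[lead], "Liver", spec, rng)
            )
            truth.append(
                TruthRecord(
                    locus_id=label,
                    causal_variants=[panel.variant_ids[lead]],
                    target_genes=[gene_a],
                    tier="1",
                    n_signals={f"{gene_a}|Blood": 1},
                    allelic_fold_change={panel.variant_ids[lead]: 2.0},
                )
            )
        elif tier == "2A":
            genes.append(_gene(gene_a, chrom, block_start - 2_000, block_end + 2_000,
                               ("protein_coding",)))
            genes.append(_gene(gene_b, chrom, far, far + 20_000, ("lincRNA",)))
            gwas_genes = {gene_a}
            _emit_qtl(v_lead, gene_a, "eQTL", EQTL_TISSUES, 0.35)
            _emit_qtl(v_lead, gene_b, "eQTL", ("Blood",), -0.2)
            truth.append(TruthRecord(label, [panel.variant_ids[lead]],
                                     [gene_a, gene_b], "2A"))
        elif tier == "2B":
            genes.append(_gene(gene_a, chrom, block_start - 2_000, block_end + 2_000,
                               ("protein_coding",)))
            genes.append(_gene(gene_b, chrom, far, far + 20_000, ("protein_coding",)))
            genes.append(_gene(gene_c, chrom, far + 50_000, far + 60_000, ("antisense",),
                               strand="-"))
            gwas_genes = {gene_a, gene_b}
            _emit_qtl(v_lead, gene_a, "eQTL", ("Blood",), 0.3)
            _emit_qtl(v_lead, gene_c, "sQTL", SQTL_TISSUES, 0.25)
            truth.append(TruthRecord(label, [panel.variant_ids[lead]],
                                     [gene_a, gene_c], "2B"))
        elif tier == "2C":
            genes.append(_gene(gene_a, chrom, far, far + 20_000, ("protein_coding",)))
            genes.append(_gene(gene_b, chrom, far + 50_000, far + 70_000, ("lincRNA",)))
            gwas_genes = {gene_a}
            _emit_qtl(v_lead, gene_b, "eQTL", ("Lung",), 0.28)
            truth.append(TruthRecord(label, [panel.variant_ids[lead]],
                                     [gene_b], "2C"))
        else:  # Tier 3: no QTLs, marker overlaps nothing
            genes.append(_gene(gene_a, chrom, far, far + 20_000, ("protein_coding",)))
            genes.append(_gene(gene_b, chrom, far + 50_000, far + 70_000, ("lincRNA",)))
            gwas_genes = {gene_a, gene_b}
            truth.append(TruthRecord(label, [], [], "3"))

        loci.append(
            GwasLocus(
                locus_label=label,
                variants=marker_variants,
                gwas_genes=gwas_genes,
                odds_ratio={v.rs_id: 1.05 for v in marker_variants},
                risk_allele_freq={
                    v.rs_id: float(panel.dosages()[:, panel.index_of(v.key)].mean() / 2)
                    for v in marker_variants
                },
            )
        )
        for v in marker_variants:
            gwas_rows.append(
                {
                    "locus": label,
                    "rs_id": v.rs_id,
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "effect_allele": v.alt,
                    "other_allele": v.ref,
                    "OR": 1.05,
                    "risk_allele_freq": round(
                        float(panel.dosages()[:, panel.index_of(v.key)].mean() / 2), 4
                    ),
                    "annotated_genes": ";".join(sorted(gwas_genes)),
                }
            )

    # merge per-locus panels (same chromosomes, disjoint regions)
    if panels:
        panel_all = HaplotypePanel(
            variant_ids=[v for p in panels for v in p.variant_ids],
            positions=np.concatenate([p.positions for p in panels]),
            haplotypes=np.hstack([p.haplotypes for p in panels]),
            ref=[r for p in panels for r in p.ref],
            alt=[a for p in panels for a in p.alt],
            chrom=chrom,
        )
    else:
        panel_all = HaplotypePanel(
            variant_ids=[],
            positions=np.array([], dtype=np.int64),
            haplotypes=np.zeros((2 * n, 0), dtype=np.int8),
            ref=[],
            alt=[],
            chrom=chrom,
        )

    expression = simulate_expression(
        panel_all.dosages(),
        panel_all.variant_ids,
        tuple(causal_spec),
        config.noise_sd,
        rng,
        n_null_genes=1,
    )
    expression.index = [f"S{s:04d}" for s in range(n)]

    positional = {
        v.key: positional_candidate_genes(v.chrom, v.pos, genes)
        for locus in loci
        for v in locus.variants
    }

    gwas_cols = ["locus", "rs_id", "chrom", "pos", "effect_allele", "other_allele",
                 "OR", "risk_allele_freq", "annotated_genes"]
    qtl_cols = ["variant_id", "rs_id", "gene_id", "tissue", "slope",
                "pval_nominal", "qtl_type"]
    return LocusCatalog(
        config=config,
        loci=loci,
        gwas=pd.DataFrame(gwas_rows, columns=gwas_cols),
        qtls=pd.DataFrame(qtl_rows, columns=qtl_cols),
        genes=genes,
        panel=panel_all,
        alias=alias,
        ase=ase_obs,
        expression=expression,
        truth=truth,
        positional=positional,
    )
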