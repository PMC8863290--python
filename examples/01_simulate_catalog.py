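"""Generate a synthetic locus catalog with planted tier structure.

Builds one GWAS locus per tier class (1, 2A, 2B, 2C, 3) with matching
haplotype panel, gene models, QTL tables, allelic counts and expression,
writes everything as plain text, and prints what was planted. Every file
is reproducible byte for byte from the seed.
"""

from pathlib import Path

from locuslens.sim import SimulationConfig, simulate_locus_catalog

config = SimulationConfig(seed=42, n_samples=300)
catalog = simulate_locus_catalog(config)

outdir = Path("scratch/catalog")
paths = catalog.write(outdir)

print(f"wrote {len(paths)} files to {outdir}/")
print(f"{len(catalog.loci)} loci, {len(catalog.genes)} genes, "
      f"{catalog.panel.n_variants} panel variants, "
      f"{len(catalog.qtls)} QTL records, {len(catalog.ase)} ASE rows")
for t in catalog.truth:
    print(f"  locus {t.locus_id}: planted tier {t.tier}, "
          f"targets {t.target_genes or '-'}")
# Each truth record is the label the downstream classifier must recover;
# the Tier-1 locus also carries the planted expression effect and an
# allelic-fold-change-2 imbalance site.
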