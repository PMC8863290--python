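"""Classify GWAS loci into tiers from QTL and positional evidence.

First reproduces the published worked example: the seven coronary-artery-
disease loci whose annotation is fully supported by QTL or position, each
of which must classify Tier 1. Then runs the same classifier end to end
on a synthetic catalog and checks it recovers every planted tier.
"""

from locuslens.datasets import tier1_worked_example
from locuslens.reprioritize import assign_tier, classify_catalog, summarize_tiers
from locuslens.sim import SimulationConfig, simulate_locus_catalog

print("worked example (published Tier-1 loci):")
for locus in tier1_worked_example():
    a = assign_tier(locus.locus, set(locus.gwas_genes), set(locus.evidence_genes))
    print(f"  locus {a.locus_label}: tier {a.tier}, "
          f"supported={sorted(a.supported_gwas_genes)}")
n_tier1 = sum(
    assign_tier(l.locus, set(l.gwas_genes), set(l.evidence_genes)).tier == "1"
    for l in tier1_worked_example()
)
print(f"distinct Tier-1 loci: {n_tier1}  (all seven supported loci classify Tier 1)")

print("\nsynthetic catalog:")
catalog = simulate_locus_catalog(SimulationConfig(seed=7, n_samples=200))
assignments, evidence = classify_catalog(
    catalog.loci, catalog.qtls, catalog.positional, catalog.alias
)
for a, t in zip(assignments, catalog.truth):
    mark = "ok" if a.tier == t.tier else "MISMATCH"
    print(f"  locus {a.locus_label}: assigned {a.tier} / planted {t.tier}  [{mark}]")
print(summarize_tiers(assignments, evidence))
# tier_counts tallies loci per class; new_genes_by_source attributes each
# newly implicated gene to eQTL, sQTL, position, or a combination.
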