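"""Configuration and truth-record types for the synthetic-data generator."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class CausalGene:
    """Planted additive cis effect: for each causal variant with fractional
    effect delta, expected expression at dosage g in {0, 1, 2} contributes
    mu·delta·(g − 1), so genotype-class means are mu(1−delta), mu,
    mu(1+delta) for a single causal variant (delta = 0.2 spreads the
    homozygote means 40% apart)."""

    gene_id: str
    effects: tuple[tuple[str, float], ...]  # (variant_id, delta >= 0)
    mu: float = 10.0

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        for vid, delta in self.effects:
            if delta < 0:
                raise ValueError(f"delta must be >= 0 for {vid}, got {delta}")


@dataclass(frozen=True)
class AseSpec:
    """Allelic-count model: total depth ~ NegBin(depth_mean, dispersion);
    REF_COUNT ~ Binomial(depth, p) with p the bias-adjusted reference
    share. fold_change a > 0 is the allelic fold-change of the reference
    haplotype's allele; ref_bias rho in (0, 1) is the multiplicative
    mapping bias toward the reference allele. The emitted NULL_RATIO is
    the value of p at a = 1 (= rho), so bias alone gives zero deviation.
    Accurate imbalance calls need robust coverage; the default mean depth
    of 50 sits above the ~30-read floor where ratio estimates stabilise.
    """

    depth_mean: float = 50.0
    depth_dispersion: float = 5.0  # NB size parameter; larger = less overdispersed
    fold_change: float = 1.0
    ref_bias: float = 0.5

    def __post_init__(self) -> None:
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth parameters must be positive")
        if self.fold_change <= 0:
            raise ValueError("fold_change must be > 0")
        if not (0 < self.ref_bias < 1):
            raise ValueError(f"ref_bias must be in (0, 1), got {self.ref_bias}")


@dataclass(frozen=True)
class PhenotypeSpec:
    """Additive logistic disease model: logit P(case) = intercept +
    sum_v log_or[v]·dosage_v + covariate effects (age is standardised
    before entering the linear predictor)."""

    intercept: float = -1.0
    log_or: tuple[tuple[str, float], ...] = ()  # (variant_id, per-allele log OR)
    beta_age: float = 0.02
    beta_sex: float = 0.3


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs for the full synthetic catalog.

    block_spec entries are (variants per block, founder haplotypes k):
    within a block every chromosome copies one of k derived founder
    haplotypes or the ancestral background, giving high within-block LD;
    founder choice is independent across blocks, giving near-zero
    cross-block LD. ld_tightness is the probability that a variant tags
    the same founder subset as its predecessor (runs of perfect LD, as in
    real haplotype blocks). maf_range bounds every variant's empirical
    minor allele frequency.
    """

    seed: int = 0
    n_samples: int = 500
    block_spec: tuple[tuple[int, int], ...] = ((8, 4), (8, 4), (8, 4))
    maf_range: tuple[float, float] = (0.1, 0.5)
    ld_tightness: float = 0.8
    causal_spec: tuple[CausalGene, ...] = ()
    noise_sd: float = 1.0
    ase_spec: AseSpec = field(default_factory=AseSpec)
    phenotype_spec: PhenotypeSpec = field(default_factory=PhenotypeSpec)

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not self.block_spec:
            raise ValueError("block_spec must be non-empty")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must sit inside (0, 0.5], got {self.maf_range}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not (0 <= self.ld_tightness <= 1):
            raise ValueError("ld_tightness must be in [0, 1]")
        for length, k in self.block_spec:
            if length < 1 or k < 1:
                raise ValueError(f"bad block spec entry ({length}, {k})")


@dataclass
class TruthRecord:
    """Planted ground truth for one synthetic locus."""

    locus_id: str
    causal_variants: list[str]
    target_genes: list[str]
    tier: str
    n_signals: dict[str, int] = field(default_factory=dict)  # "gene|tissue" -> count
    allelic_fold_change: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "locus_id": self.locus_id,
            "causal_variants": list(self.causal_variants),
            "target_genes": list(self.target_genes),
            "tier": self.tier,
            "n_signals": dict(self.n_signals),
            "allelic_fold_change": dict(self.allelic_fold_change),
        }
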