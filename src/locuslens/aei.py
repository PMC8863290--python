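"""Allelic expression imbalance (AEI) at heterozygous sites.

At a heterozygous transcribed SNP, RNA-seq reads split between the two
alleles. Under purely trans-acting regulation both alleles are expressed
equally and the reference-read fraction REF_RATIO should match NULL_RATIO,
the expected reference fraction under allelic balance (NULL_RATIO absorbs
mapping/reference bias, so bias alone gives zero deviation). A consistent
deviation of REF_RATIO from NULL_RATIO across heterozygous carriers marks
a cis-acting regulatory variant on one haplotype.

The per-sample imbalance call is a two-sided exact binomial test of
REF_COUNT against NULL_RATIO. Because a systematic artefact (e.g.
preferential amplification of one allele) can mimic imbalance, the
LD-stratified control compares imbalance enrichment at nearby sites in
strong LD (expected to share true AEI) versus weak LD (expected to be
balanced): enrichment at weak-LD sites too points to bias rather than a
cis effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest

__all__ = [
    "AseObservation",
    "AeiSummary",
    "deviation",
    "call_sample_aei",
    "summarize_variant_tissue",
    "ld_stratified_control",
    "read_ase_tsv",
    "deviation_table",
]

CALL_REF_HIGH = "imbalanced_ref_high"
CALL_REF_LOW = "imbalanced_ref_low"
CALL_BALANCED = "balanced"
CALL_INSUFFICIENT = "insufficient"


@dataclass(frozen=True)
class AseObservation:
    """One sample's allelic read counts at one heterozygous site."""

    sample_id: str
    tissue_id: str
    variant_id: str
    ref_count: int
    alt_count: int
    null_ratio: float

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("allelic counts must be non-negative")
        if not (0 < self.null_ratio < 1):
            raise ValueError(f"null_ratio must be in (0, 1), got {self.null_ratio}")

    @property
    def total(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def ref_ratio(self) -> float:
        if self.total == 0:
            raise ValueError("ref_ratio undefined at zero total depth")
        return self.ref_count / self.total


@dataclass
class AeiSummary:
    """Per-variant-per-tissue AEI summary across heterozygous samples."""

    variant_id: str
    tissue_id: str
    n_samples: int
    n_informative: int
    n_called_imbalanced: int
    consistency: float | None  # max(share ref_high, share ref_low); None if no calls
    median_deviation: float | None
    sufficient: bool
    all_informative_imbalanced: bool

    @property
    def imbalance_fraction(self) -> float:
        """Fraction of informative samples called imbalanced (0 if none)."""
        if self.n_informative == 0:
            return 0.0
        return self.n_called_imbalanced / self.n_informative


def deviation(obs: AseObservation) -> float:
    """REF_RATIO − NULL_RATIO, in [−1, 1]; errors at zero depth."""
    return obs.ref_ratio - obs.null_ratio


def call_sample_aei(
    obs: AseObservation, alpha: float = 0.05, min_total: int = 8
) -> str:
    """Two-sided exact binomial call of one sample's allelic imbalance.

    Tests REF_COUNT ~ Binomial(total, NULL_RATIO). Returns "insufficient"
    below ``min_total`` reads, otherwise "imbalanced_ref_high" /
    "imbalanced_ref_low" when p < alpha (direction from the deviation
    sign) and "balanced" when not rejected.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if obs.total < min_total:
        return CALL_INSUFFICIENT
    p = binomtest(obs.ref_count, obs.total, obs.null_ratio).pvalue
    if p >= alpha:
        return CALL_BALANCED
    return CALL_REF_HIGH if deviation(obs) > 0 else CALL_REF_LOW


def summarize_variant_tissue(
    observations: list[AseObservation],
    alpha: float = 0.05,
    min_total: int = 8,
    min_samples: int = 5,
) -> AeiSummary:
    """Summarise AEI calls for one variant in one tissue.

    Consistency is the larger directional share among imbalanced calls
    (in [0.5, 1]); it is None when nothing is called. Tissues with fewer
    than ``min_samples`` samples are flagged insufficient rather than
    dropped. ``all_informative_imbalanced`` is a marker-quality
    annotation: a marker SNP in imperfect LD with the functional variant
    is expected to leave some heterozygous carriers balanced, so even one
    balanced sample suggests the marker is not itself the functional
    variant — it is reported, never used as a filter.
    """
    if not observations:
        raise ValueError("no observations")
    variants = {o.variant_id for o in observations}
    tissues = {o.tissue_id for o in observations}
    if len(variants) > 1 or len(tissues) > 1:
        raise ValueError(
            f"mixed variant/tissue in summary input: {variants} x {tissues}"
        )
    calls = [call_sample_aei(o, alpha=alpha, min_total=min_total) for o in observations]
    informative = [c for c in calls if c != CALL_INSUFFICIENT]
    n_high = sum(c == CALL_REF_HIGH for c in informative)
    n_low = sum(c == CALL_REF_LOW for c in informative)
    n_imb = n_high + n_low
    consistency = max(n_high, n_low) / n_imb if n_imb else None
    devs = [deviation(o) for o in observations if o.total > 0]
    return AeiSummary(
        variant_id=next(iter(variants)),
        tissue_id=next(iter(tissues)),
        n_samples=len(observations),
        n_informative=len(informative),
        n_called_imbalanced=n_imb,
        consistency=consistency,
        median_deviation=float(np.median(devs)) if devs else None,
        sufficient=len(observations) >= min_samples,
        all_informative_imbalanced=bool(informative) and n_imb == len(informative),
    )


LABEL_TRUE_AEI = "true_aei"
LABEL_SUSPECTED_BIAS = "suspected_bias"
LABEL_INCONCLUSIVE = "inconclusive"


def ld_stratified_control(
    target: AeiSummary,
    strong_partners: list[AeiSummary],
    weak_partners: list[AeiSummary],
    enrichment_threshold: float = 0.5,
) -> str:
    """Distinguish cis-regulatory AEI from locus-wide artefact.

    ``strong_partners`` are co-located sites in strong LD (r² > 0.9) with
    the target, ``weak_partners`` sites in weak LD (r² < 0.1). A site is
    imbalance-enriched when its imbalance fraction (calls / informative
    samples) is >= ``enrichment_threshold``. Verdicts:

    * true_aei        — majority of strong partners enriched AND majority
                        of weak partners not enriched;
    * suspected_bias  — majority of weak partners enriched (the artefact
                        reaches sites that share no haplotype);
    * inconclusive    — empty partner list on either side, or mixed
                        pattern.
    """
    if not target.sufficient:
        raise ValueError("target summary has insufficient samples")
    if not strong_partners or not weak_partners:
        return LABEL_INCONCLUSIVE

    def _enriched(s: AeiSummary) -> bool:
        return s.imbalance_fraction >= enrichment_threshold

    strong_frac = np.mean([_enriched(s) for s in strong_partners])
    weak_frac = np.mean([_enriched(s) for s in weak_partners])
    if weak_frac > 0.5:
        return LABEL_SUSPECTED_BIAS
    if strong_frac > 0.5 and weak_frac <= 0.5:
        return LABEL_TRUE_AEI
    return LABEL_INCONCLUSIVE


def read_ase_tsv(path: str) -> list[AseObservation]:
    """Read an ASE table (SAMPLE_ID, TISSUE_ID, VARIANT_ID, REF_COUNT,
    ALT_COUNT, REF_RATIO, NULL_RATIO)."""
    df = pd.read_csv(path, sep="\t")
    obs = []
    for row in df.itertuples(index=False):
        obs.append(
            AseObservation(
                sample_id=str(row.SAMPLE_ID),
                tissue_id=str(row.TISSUE_ID),
                variant_id=str(row.VARIANT_ID),
                ref_count=int(row.REF_COUNT),
                alt_count=int(row.ALT_COUNT),
                null_ratio=float(row.NULL_RATIO),
            )
        )
    return obs


def deviation_table(observations: list[AseObservation]) -> pd.DataFrame:
    """Long per-sample deviation table (for plotting distributions of
    REF_RATIO − NULL_RATIO per variant and tissue). Zero-depth rows are
    kept but flagged uninformative."""
    rows = []
    for o in observations:
        informative = o.total > 0
        rows.append(
            {
                "sample_id": o.sample_id,
                "tissue_id": o.tissue_id,
                "variant_id": o.variant_id,
                "ref_count": o.ref_count,
                "alt_count": o.alt_count,
                "total": o.total,
                "ref_ratio": o.ref_ratio if informative else np.nan,
                "null_ratio": o.null_ratio,
                "deviation": deviation(o) if informative else np.nan,
                "informative": informative,
            }
        )
    return pd.DataFrame(rows)
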