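"""Binomial allelic counts with allelic fold-change and reference bias.

For a heterozygous carrier whose reference-haplotype allele is expressed
a-fold relative to the alternate (allelic fold-change a), the reference
expression share is x = a / (1 + a). Sequencing maps a fraction rho of
truly-balanced reads to the reference allele (multiplicative reference
bias), so the observed reference-read probability is

    p = rho·x / (rho·x + (1 − rho)·(1 − x)).

Total depth is negative-binomial; REF_COUNT ~ Binomial(depth, p). The
emitted NULL_RATIO is p evaluated at a = 1, i.e. rho — the expected
reference ratio under allelic balance including mapping bias, so bias
alone yields zero deviation.
"""

from __future__ import annotations

import numpy as np

from ..aei import AseObservation
from .config import AseSpec

__all__ = ["simulate_ase", "biased_ref_probability"]


def biased_ref_probability(fold_change: float, ref_bias: float) -> float:
    """Reference-read probability under fold-change a and bias rho."""
    if fold_change <= 0:
        raise ValueError("fold_change must be > 0")
    if not (0 < ref_bias < 1):
        raise ValueError("ref_bias must be in (0, 1)")
    x = fold_change / (1.0 + fold_change)
    return ref_bias * x / (ref_bias * x + (1.0 - ref_bias) * (1.0 - x))


def simulate_ase(
    sample_ids: list[str],
    variant_id: str,
    tissue_id: str,
    spec: AseSpec,
    rng: np.random.Generator | int,
    null_ratio: float | None = None,
) -> list[AseObservation]:
    """One observation per heterozygous sample.

    ``null_ratio`` overrides the emitted NULL_RATIO (default: the
    bias-only probability rho, the correct null). Passing a mis-specified
    value emulates an artefact the null fails to absorb. Zero-depth rows
    are emitted; downstream summaries flag them uninformative.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    p = biased_ref_probability(spec.fold_change, spec.ref_bias)
    emit_null = spec.ref_bias if null_ratio is None else null_ratio
    n = len(sample_ids)
    # NB parameterised by mean m and size r: p_nb = r / (r + m)
    r = spec.depth_dispersion
    p_nb = r / (r + spec.depth_mean)
    depths = rng.negative_binomial(r, p_nb, size=n)
    refs = rng.binomial(depths, p)
    return [
        AseObservation(
            sample_id=s,
            tissue_id=tissue_id,
            variant_id=variant_id,
            ref_count=int(rc),
            alt_count=int(d - rc),
            null_ratio=emit_null,
        )
        for s, d, rc in zip(sample_ids, depths, refs)
    ]
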