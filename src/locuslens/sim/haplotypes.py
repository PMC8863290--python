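"""Founder-mosaic haplotype simulation.

Each LD block descends from k *derived* founder haplotypes segregating
against an implicit ancestral all-reference background. Every variant's
alternate allele is carried by a non-empty proper subset of the founders,
so variants sharing founder subsets are strongly correlated within a
block, while founder choice is independent across blocks (cross-block
r² ~ 1/(2n)). The special case k = 1 places every variant of the block on
the single derived haplotype, forcing r² = 1 for all within-block pairs.

This is deliberately not a coalescent model: the pipeline only consumes
LD summaries (r² regimes > 0.9, ~0.5, < 0.1), which the mosaic produces
deterministically and cheaply.
"""

from __future__ import annotations

import numpy as np

from ..ld import HaplotypePanel
from .config import SimulationConfig

__all__ = ["simulate_haplotypes", "MafConstraintError"]

_MAX_RETRIES = 30
_BASES = ("A", "C", "G", "T")


class MafConstraintError(RuntimeError):
    """A variant's empirical MAF could not be brought inside maf_range."""


def _block_genotypes(
    rng: np.random.Generator,
    n_chrom: int,
    length: int,
    k: int,
    maf_lo: float,
    maf_hi: float,
    variant_offset: int,
    ld_tightness: float,
) -> np.ndarray:
    """Alleles (n_chrom x length) for one block; raises MafConstraintError."""
    if k == 1:
        # one derived haplotype carrying the alt allele at every site
        f = rng.uniform(maf_lo, maf_hi)
        carrier = rng.random(n_chrom) < f
        block = np.tile(carrier[:, None], (1, length)).astype(np.int8)
        freq = block[:, 0].mean()
        if not (maf_lo <= min(freq, 1 - freq) <= maf_hi):
            # single retry budget: redraw carrier assignment
            for _ in range(_MAX_RETRIES):
                carrier = rng.random(n_chrom) < f
                freq = carrier.mean()
                if maf_lo <= min(freq, 1 - freq) <= maf_hi:
                    break
            else:
                raise MafConstraintError(
                    f"variant {variant_offset}: cannot satisfy MAF in "
                    f"[{maf_lo}, {maf_hi}] with a single founder at frequency {f:.3f}"
                )
            block = np.tile(carrier[:, None], (1, length)).astype(np.int8)
        return block

    # founder index per chromosome (0 = ancestral background, 1..k derived)
    founder_of = rng.integers(0, k + 1, size=n_chrom)
    usage = np.bincount(founder_of, minlength=k + 1) / n_chrom
    block = np.empty((n_chrom, length), dtype=np.int8)
    prev_carriers: np.ndarray | None = None
    for v in range(length):
        if prev_carriers is not None and rng.random() < ld_tightness:
            # tag the previous variant's haplotype subset: r^2 = 1 pair
            block[:, v] = np.isin(founder_of, prev_carriers).astype(np.int8)
            continue
        target = rng.uniform(maf_lo, maf_hi)
        ok = False
        for _ in range(_MAX_RETRIES):
            n_alt = int(np.clip(round(target * (k + 1)), 1, k))
            carriers = rng.choice(np.arange(1, k + 1), size=n_alt, replace=False)
            freq = float(usage[carriers].sum())
            if maf_lo <= min(freq, 1 - freq) <= maf_hi:
                ok = True
                break
            target = rng.uniform(maf_lo, maf_hi)
        if not ok:
            raise MafConstraintError(
                f"variant {variant_offset + v}: cannot satisfy MAF in "
                f"[{maf_lo}, {maf_hi}] with k={k} founders after "
                f"{_MAX_RETRIES} retries"
            )
        block[:, v] = np.isin(founder_of, carriers).astype(np.int8)
        prev_carriers = carriers
    return block


def simulate_haplotypes(
    config: SimulationConfig,
    *,
    chrom: str = "1",
    start_pos: int = 10_000,
    spacing: int = 5_000,
    rng: np.random.Generator | None = None,
) -> HaplotypePanel:
    """Simulate a phased panel of 2·n_samples chromosomes.

    Variant ids are normalized ``chrom:pos:ref:alt`` keys; positions are
    evenly spaced from ``start_pos``. Identical config (and no external
    rng) reproduces the panel bit for bit.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_chrom = 2 * config.n_samples
    maf_lo, maf_hi = config.maf_range

    blocks = []
    offset = 0
    for length, k in config.block_spec:
        blocks.append(
            _block_genotypes(
                rng, n_chrom, length, k, maf_lo, maf_hi, offset, config.ld_tightness
            )
        )
        offset += length
    haplotypes = np.hstack(blocks)

    m = haplotypes.shape[1]
    positions = start_pos + spacing * np.arange(m, dtype=np.int64)
    ref_idx = rng.integers(0, 4, size=m)
    alt_shift = rng.integers(1, 4, size=m)
    ref = [_BASES[i] for i in ref_idx]
    alt = [_BASES[(i + s) % 4] for i, s in zip(ref_idx, alt_shift)]
    variant_ids = [
        f"{chrom}:{p}:{r}:{a}" for p, r, a in zip(positions, ref, alt)
    ]
    return HaplotypePanel(
        variant_ids=variant_ids,
        positions=positions,
        haplotypes=haplotypes,
        ref=ref,
        alt=alt,
        chrom=chrom,
    )
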