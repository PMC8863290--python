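"""Tissue expression with planted additive cis effects.

For a target gene with causal variants v (fractional effect delta_v) and
baseline mu, a sample with dosages g_v has expected expression

    mu · (1 + sum_v delta_v · (g_v − 1)),

i.e. genotype-class means mu(1−delta), mu, mu(1+delta) for one causal
variant, plus Gaussian noise. Non-target genes are noise around their
baseline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CausalGene

__all__ = ["simulate_expression"]


def simulate_expression(
    dosages: np.ndarray,
    variant_ids: list[str],
    causal_spec: tuple[CausalGene, ...] | list[CausalGene],
    noise_sd: float,
    rng: np.random.Generator | int,
    n_null_genes: int = 0,
    null_mu: float = 10.0,
) -> pd.DataFrame:
    """Expression matrix (samples x genes) for the causal-spec genes plus
    ``n_null_genes`` noise-only genes named ``NULL{i}``.

    Raises KeyError when a causal effect names a variant absent from the
    dosage matrix.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    g = np.asarray(dosages, dtype=float)
    n = g.shape[0]
    index = {v: j for j, v in enumerate(variant_ids)}
    cols: dict[str, np.ndarray] = {}
    for gene in causal_spec:
        mean = np.full(n, gene.mu, dtype=float)
        for vid, delta in gene.effects:
            if vid not in index:
                raise KeyError(
                    f"causal variant {vid!r} for gene {gene.gene_id} is not in "
                    "the genotype matrix"
                )
            mean += gene.mu * delta * (g[:, index[vid]] - 1.0)
        cols[gene.gene_id] = mean + rng.normal(0.0, noise_sd, size=n)
    for i in range(n_null_genes):
        cols[f"NULL{i + 1}"] = null_mu + rng.normal(0.0, noise_sd, size=n)
    return pd.DataFrame(cols)
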