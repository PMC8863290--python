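"""Binary disease phenotype with covariates under an additive logistic model."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import PhenotypeSpec

__all__ = ["simulate_phenotype"]


def simulate_phenotype(
    dosages: np.ndarray,
    variant_ids: list[str],
    spec: PhenotypeSpec,
    rng: np.random.Generator | int,
) -> pd.DataFrame:
    """Samples x (disease, age, sex, dosage columns) data frame.

    logit P(case) = intercept + sum log_or·dosage + beta_age·z(age) +
    beta_sex·sex, with age ~ N(60, 8) and sex ~ Bernoulli(0.5).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    g = np.asarray(dosages, dtype=float)
    n = g.shape[0]
    index = {v: j for j, v in enumerate(variant_ids)}
    age = rng.normal(60.0, 8.0, size=n)
    sex = rng.integers(0, 2, size=n)
    eta = np.full(n, spec.intercept, dtype=float)
    eta += spec.beta_age * (age - age.mean()) / age.std(ddof=0)
    eta += spec.beta_sex * sex
    used = {}
    for vid, log_or in spec.log_or:
        if vid not in index:
            raise KeyError(f"phenotype effect names unknown variant {vid!r}")
        eta += log_or * g[:, index[vid]]
        used[vid] = g[:, index[vid]].astype(int)
    disease = rng.binomial(1, expit(eta))
    out = pd.DataFrame({"disease": disease, "age": age, "sex": sex})
    for vid, dos in used.items():
        out[vid] = dos
    return out
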