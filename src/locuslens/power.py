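"""ANOVA-based cis-eQTL power.

Models a biallelic variant under Hardy–Weinberg equilibrium with genotype
class means mu·(1 − delta), mu, mu·(1 + delta) (so delta = 0.2 spreads the
homozygote means 40% apart around the median expression mu) and residual
sd sigma. Power is the upper tail of the noncentral F(2, n − 3) at the
Bonferroni-corrected per-test alpha, with noncentrality

    lambda = n · sum_g w_g (mu_g − mu_bar)^2 / sigma^2,

where w = ((1 − p)^2, 2p(1 − p), p^2) are the HWE genotype weights for
minor-allele frequency p. sigma defaults to a coefficient of variation of
0.3 times mu when not given explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PowerSettings", "eqtl_anova_power", "power_by_tissue"]

DEFAULT_CV = 0.3


@dataclass(frozen=True)
class PowerSettings:
    maf: float
    delta: float
    mu: float
    n: int
    sigma: float | None = None  # default CV * mu
    n_tests: int = 5_000_000
    family_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.maf <= 0.5):
            raise ValueError(f"maf must be in (0, 0.5], got {self.maf}")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n_tests < 1 or not (0 < self.family_alpha < 1):
            raise ValueError("bad multiple-testing settings")

    @property
    def resolved_sigma(self) -> float:
        return self.sigma if self.sigma is not None else DEFAULT_CV * self.mu

    @property
    def per_test_alpha(self) -> float:
        return self.family_alpha / self.n_tests


def eqtl_anova_power(s: PowerSettings) -> float:
    """Power of the one-way ANOVA across the three genotype classes."""
    if s.n < 4:
        raise ValueError("need n >= 4 for a 3-group ANOVA")
    p = s.maf
    w = np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])
    means = s.mu * np.array([1 - s.delta, 1.0, 1 + s.delta])
    grand = float(w @ means)
    lam = s.n * float(w @ (means - grand) ** 2) / s.resolved_sigma**2
    df1, df2 = 2, s.n - 3
    crit = stats.f.isf(s.per_test_alpha, df1, df2)
    if lam == 0.0:
        # central case: power equals the per-test size (ncf is numerically
        # unreliable at zero noncentrality)
        return float(stats.f.sf(crit, df1, df2))
    return float(stats.ncf.sf(crit, df1, df2, lam))


def power_by_tissue(
    template: PowerSettings, tissue_table: pd.DataFrame
) -> pd.DataFrame:
    """Per-tissue power from a table with columns ``tissue``, ``n`` and
    ``median_tpm`` (tissue sample size and median expression), holding the
    template's MAF, effect size and testing burden fixed.

    When the template's sigma is None the coefficient-of-variation default
    scales sigma with each tissue's median expression.
    """
    required = {"tissue", "n", "median_tpm"}
    if tissue_table is None or len(tissue_table) == 0:
        raise ValueError("tissue table is empty")
    missing = required - set(tissue_table.columns)
    if missing:
        raise ValueError(f"tissue table missing columns: {sorted(missing)}")
    rows = []
    for row in tissue_table.itertuples(index=False):
        s = replace(template, mu=float(row.median_tpm), n=int(row.n))
        rows.append(
            {
                "tissue": row.tissue,
                "n": int(row.n),
                "median_tpm": float(row.median_tpm),
                "power": eqtl_anova_power(s),
            }
        )
    return pd.DataFrame(rows)
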