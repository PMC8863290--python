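"""Cis-eQTL scanning and enumeration of independent signals via LD.

Under a single functional variant, the marginal eQTL slope at a proxy SNP
is attenuated by its correlation with the causal site: with standardized
dosages the population slope at a proxy equals r x (causal slope), so
|beta| plotted against r² with the lead eQTL should follow
sqrt(r²)·|beta_lead|. Variants whose |beta| exceeds that expectation while
being in weak LD with every known lead indicate an additional functional
variant; iterating this argument enumerates independent signal clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .ld import LdMatrix

__all__ = [
    "EqtlResult",
    "SignalReport",
    "cis_eqtl_scan",
    "top_eqtl",
    "expected_beta",
    "beta_r2_profile",
    "tight_ld_clusters",
    "count_signals",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EqtlResult:
    variant_id: str
    gene_id: str
    tissue: str
    slope: float
    slope_se: float
    pval: float
    position: int = 0

    def __post_init__(self) -> None:
        if self.slope_se <= 0:
            raise ValueError("slope_se must be positive")
        if not (0 < self.pval <= 1):
            raise ValueError(f"pval out of (0, 1]: {self.pval}")


@dataclass
class SignalReport:
    gene_id: str
    tissue: str
    leads: list[str]  # one lead variant per signal, in discovery order
    clusters: dict[str, int]  # variant -> signal index (0-based)
    unassigned: list[str]
    profile: pd.DataFrame  # variant, r2_with_lead, abs_beta, expected_beta, signal

    @property
    def n_signals(self) -> int:
        return len(self.leads)


def cis_eqtl_scan(
    dosages: np.ndarray,
    variant_ids: list[str],
    positions: np.ndarray,
    expression: np.ndarray,
    gene_id: str,
    tissue: str = "synthetic",
    covariates: np.ndarray | None = None,
    alpha: float = 0.05,
    bonferroni: bool = True,
    standardize: bool = True,
) -> list[EqtlResult]:
    """Per-variant linear eQTL scan: expression ~ dosage (+ covariates).

    Dosages are standardized by default so that slopes are comparable
    across variants with different allele frequencies (required for the
    sqrt(r²) attenuation diagnostic). Variants with a single genotype
    class are skipped with a log entry. With ``bonferroni`` the
    significance filter is alpha / n_tested.
    """
    g = np.asarray(dosages, dtype=float)
    y = np.asarray(expression, dtype=float)
    n, m = g.shape
    if y.shape[0] != n:
        raise ValueError("expression and dosage sample counts differ")
    if covariates is not None:
        c = np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        base = np.column_stack([np.ones(n), c])
        if np.linalg.matrix_rank(base) < base.shape[1]:
            raise ValueError("covariate design is rank-deficient")
    else:
        base = np.ones((n, 1))

    testable = [j for j in range(m) if np.unique(g[:, j]).size >= 2]
    for j in range(m):
        if j not in testable:
            log.info("variant %s has one genotype class; excluded", variant_ids[j])
    results = []
    k = base.shape[1] + 1
    for j in testable:
        x = g[:, j]
        if standardize:
            x = (x - x.mean()) / x.std(ddof=0)
        design = np.column_stack([base, x])
        beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        dof = n - rank
        sigma2 = resid @ resid / dof
        xtx_inv = np.linalg.pinv(design.T @ design)
        se = float(np.sqrt(sigma2 * xtx_inv[-1, -1]))
        slope = float(beta[-1])
        tval = slope / se
        pval = float(2 * stats.t.sf(abs(tval), dof))
        results.append(
            EqtlResult(
                variant_id=variant_ids[j],
                gene_id=gene_id,
                tissue=tissue,
                slope=slope,
                slope_se=se,
                pval=max(pval, np.finfo(float).tiny),
                position=int(positions[j]),
            )
        )
    threshold = alpha / len(testable) if (bonferroni and testable) else alpha
    return [r for r in results if r.pval < threshold]


def top_eqtl(results: list[EqtlResult]) -> EqtlResult:
    """Lead eQTL: minimum p, ties broken by larger |slope| then smaller
    genomic position (fully deterministic)."""
    if not results:
        raise ValueError("no eQTL results")
    return min(results, key=lambda r: (r.pval, -abs(r.slope), r.position))


def expected_beta(r2: float, beta_lead: float) -> float:
    """Single-causal expectation for a proxy's |slope| under standardized
    dosages: sqrt(r²) · |beta_lead|."""
    if not (0 <= r2 <= 1):
        raise ValueError(f"r2 out of [0, 1]: {r2}")
    return float(np.sqrt(r2) * abs(beta_lead))


def beta_r2_profile(
    results: list[EqtlResult], ld: LdMatrix, lead: EqtlResult
) -> pd.DataFrame:
    """One row per significant eQTL: r² with the lead (1 for the lead
    itself), observed |slope| and the single-causal expectation."""
    if lead not in results:
        raise ValueError("lead must be one of the results")
    for r in results:
        if r.variant_id not in ld.variant_ids:
            raise KeyError(f"variant {r.variant_id!r} missing from LD matrix")
    rows = []
    for r in results:
        r2 = ld.lookup(r.variant_id, lead.variant_id)
        rows.append(
            {
                "variant_id": r.variant_id,
                "r2_with_lead": r2,
                "abs_beta": abs(r.slope),
                "expected_beta": expected_beta(r2, lead.slope),
                "pval": r.pval,
            }
        )
    return pd.DataFrame(rows)


def tight_ld_clusters(
    variant_ids: list[str],
    ld: LdMatrix,
    r2_min: float = 0.9,
    dprime_min: float = 0.9,
) -> list[set[str]]:
    """Connected components of the graph with an edge wherever
    r² > r2_min AND D′ > dprime_min (both strict)."""
    if ld.dprime is None:
        raise ValueError("LD matrix lacks D'; build it with with_dprime=True")
    idx = [ld.index_of(v) for v in variant_ids]
    r2 = ld.r2[np.ix_(idx, idx)]
    dp = ld.dprime[np.ix_(idx, idx)]
    adj = (r2 > r2_min) & (dp > dprime_min)
    np.fill_diagonal(adj, True)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    clusters: list[set[str]] = [set() for _ in range(n_comp)]
    for v, lab in zip(variant_ids, labels):
        clusters[lab].add(v)
    return [c for c in clusters if c]


def count_signals(
    results: list[EqtlResult],
    ld: LdMatrix,
    excess_margin: float = 0.25,
    independence_r2: float = 0.5,
    tight_r2: float = 0.9,
    tight_dprime: float = 0.9,
) -> SignalReport:
    """Enumerate independent eQTL signals for one gene-tissue pair.

    Iteratively: (1) the most significant unassigned eQTL seeds a signal
    together with its tight-LD cluster (r² > 0.9 and D′ > 0.9); (2) among
    variants in weak LD (r² < independence_r2) with *all* current leads,
    those whose |slope| exceeds the single-causal expectation
    sqrt(max r² to any lead)·|that lead's slope| by more than
    excess_margin x |first lead's slope| flag a further signal, and the
    most significant of them seeds it. Stops when no excess remains.
    """
    if not results:
        raise ValueError("no significant eQTL results to enumerate")
    results = sorted(results, key=lambda r: (r.pval, -abs(r.slope), r.position))
    all_ids = [r.variant_id for r in results]
    by_id = {r.variant_id: r for r in results}
    for v in all_ids:
        if v not in ld.variant_ids:
            raise KeyError(f"variant {v!r} missing from LD matrix")

    clusters_all = tight_ld_clusters(all_ids, ld, tight_r2, tight_dprime)
    cluster_of = {v: c for c in clusters_all for v in c}

    leads: list[EqtlResult] = []
    assignment: dict[str, int] = {}
    unassigned = set(all_ids)

    def _assign_cluster(lead: EqtlResult, index: int) -> None:
        for v in cluster_of[lead.variant_id]:
            if v in unassigned:
                assignment[v] = index
                unassigned.discard(v)

    first_lead = top_eqtl(results)
    leads.append(first_lead)
    _assign_cluster(first_lead, 0)
    margin = excess_margin * abs(first_lead.slope)

    while unassigned:
        candidates = []
        for v in unassigned:
            r2_to_leads = [ld.lookup(v, l.variant_id) for l in leads]
            if max(r2_to_leads) >= independence_r2:
                continue
            best = int(np.argmax(r2_to_leads))
            exp = expected_beta(r2_to_leads[best], leads[best].slope)
            if abs(by_id[v].slope) - exp > margin:
                candidates.append(by_id[v])
        if not candidates:
            break
        new_lead = top_eqtl(candidates)
        leads.append(new_lead)
        _assign_cluster(new_lead, len(leads) - 1)

    profile = beta_r2_profile(results, ld, first_lead)
    profile["signal"] = [assignment.get(v, -1) for v in profile["variant_id"]]
    return SignalReport(
        gene_id=results[0].gene_id,
        tissue=results[0].tissue,
        leads=[l.variant_id for l in leads],
        clusters=assignment,
        unassigned=sorted(unassigned),
        profile=profile,
    )
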