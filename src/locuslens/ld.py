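"""Pairwise linkage disequilibrium (r², D′) and LD-based clustering.

Works from phased haplotype panels (rows = chromosomes, entries in {0,1})
or from unphased genotype dosages (0/1/2, with an EM step to resolve the
double-heterozygote phase ambiguity). All measures are allele-label
symmetric and bounded in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "HaplotypePanel",
    "LdMatrix",
    "MonomorphicVariantError",
    "EmConvergenceError",
    "r2_phased",
    "d_prime",
    "r2_unphased",
    "ld_matrix",
    "ld_cluster",
    "read_vcf_panel",
    "write_ld_tsv",
]


class MonomorphicVariantError(ValueError):
    """LD is undefined when a variant has a single allele in the panel."""


class EmConvergenceError(RuntimeError):
    """EM haplotype-frequency estimation failed to converge."""

    def __init__(self, iterations: int):
        self.iterations = iterations
        super().__init__(f"EM did not converge within {iterations} iterations")


@dataclass
class HaplotypePanel:
    """Phased biallelic panel: ``haplotypes[c, v]`` is chromosome ``c``'s
    allele (0 = ref, 1 = alt) at variant ``v``.

    Row count must be even (two chromosomes per diploid sample); no
    missing entries are allowed in a phased panel.
    """

    variant_ids: list[str]
    positions: np.ndarray  # 1-based, per variant
    haplotypes: np.ndarray  # (2n, m) int8, entries in {0, 1}
    ref: list[str] = field(default_factory=list)
    alt: list[str] = field(default_factory=list)
    chrom: str = "1"

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be 2-D (chromosomes x variants)")
        if self.haplotypes.shape[0] % 2 != 0:
            raise ValueError("haplotype panel needs an even number of chromosomes")
        if self.haplotypes.shape[1] != len(self.variant_ids):
            raise ValueError("variant_ids length does not match haplotype columns")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("phased alleles must be 0/1 with no missing entries")

    @property
    def n_samples(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]

    def dosages(self) -> np.ndarray:
        """Collapse to per-sample alt-allele dosage (n, m) in {0, 1, 2}."""
        return (self.haplotypes[0::2] + self.haplotypes[1::2]).astype(np.int8)

    def index_of(self, variant_id: str) -> int:
        try:
            return self.variant_ids.index(variant_id)
        except ValueError:
            raise KeyError(f"variant {variant_id!r} not in panel") from None


@dataclass
class LdMatrix:
    """Symmetric pairwise r² (and optionally D′) with unit diagonal."""

    variant_ids: list[str]
    r2: np.ndarray
    dprime: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        m = len(self.variant_ids)
        if self.r2.shape != (m, m):
            raise ValueError("r2 matrix shape does not match variant_ids")
        if not np.allclose(self.r2, self.r2.T, atol=1e-10):
            raise ValueError("r2 matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-10):
            raise ValueError("r2 matrix must have unit diagonal")
        if self.r2.min() < -1e-10 or self.r2.max() > 1 + 1e-10:
            raise ValueError("r2 entries must lie in [0, 1]")

    def index_of(self, variant_id: str) -> int:
        try:
            return self.variant_ids.index(variant_id)
        except ValueError:
            raise KeyError(f"variant {variant_id!r} not in LD matrix") from None

    def lookup(self, a: str, b: str) -> float:
        return float(self.r2[self.index_of(a), self.index_of(b)])


def _hap_freqs(panel: HaplotypePanel, i: int, j: int) -> tuple[float, float, float]:
    """(p_AB, p_A, p_B) where allele "A"/"B" is the alt allele at i/j."""
    hi = panel.haplotypes[:, i]
    hj = panel.haplotypes[:, j]
    for idx, h in ((i, hi), (j, hj)):
        if h.min() == h.max():
            raise MonomorphicVariantError(
                f"variant {panel.variant_ids[idx]!r} is monomorphic; r^2/D' undefined"
            )
    n = hi.shape[0]
    p_ab = float(np.count_nonzero(hi & hj)) / n
    return p_ab, float(hi.mean()), float(hj.mean())


def r2_phased(panel: HaplotypePanel, i: int, j: int) -> float:
    """Squared allelic correlation r² = D² / (p_A q_A p_B q_B) from phased
    haplotype counts, with D = p_AB − p_A·p_B."""
    p_ab, p_a, p_b = _hap_freqs(panel, i, j)
    d = p_ab - p_a * p_b
    return d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))


def d_prime(panel: HaplotypePanel, i: int, j: int) -> float:
    """Lewontin's D′ = |D| / D_max in [0, 1]."""
    p_ab, p_a, p_b = _hap_freqs(panel, i, j)
    d = p_ab - p_a * p_b
    if d == 0:
        return 0.0
    q_a, q_b = 1 - p_a, 1 - p_b
    if d > 0:
        dmax = min(p_a * q_b, q_a * p_b)
    else:
        dmax = min(p_a * p_b, q_a * q_b)
    return abs(d) / dmax


def _em_haplotype_freqs(
    gi: np.ndarray, gj: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, bool]:
    """EM estimate of the four haplotype frequencies (AB, Ab, aB, ab) from
    unphased dosage pairs; "A"/"B" denote alt alleles.

    Only the double heterozygote (1, 1) is phase-ambiguous: it contributes
    either AB+ab or Ab+aB. Returns (freqs, ambiguous_flat_likelihood).
    """
    n = gi.shape[0]
    n_dh = int(np.count_nonzero((gi == 1) & (gj == 1)))
    # Haplotypes are fully determined whenever either locus is homozygous.
    counts = np.zeros(4)  # AB, Ab, aB, ab
    for a in (0, 1, 2):
        for b in (0, 1, 2):
            if a == 1 and b == 1:
                continue
            m = int(np.count_nonzero((gi == a) & (gj == b)))
            if m:
                counts += m * _known_hap_contrib(a, b)
    total = 2.0 * n
    if n_dh == 0:
        return counts / total, False
    # EM over the double-heterozygote split
    f = np.full(4, 0.25)
    prev = f.copy()
    for _ in range(max_iter):
        p_coupling = f[0] * f[3]
        p_repulsion = f[1] * f[2]
        denom = p_coupling + p_repulsion
        w = 0.5 if denom == 0 else p_coupling / denom
        new = counts.copy()
        new[0] += n_dh * w
        new[3] += n_dh * w
        new[1] += n_dh * (1 - w)
        new[2] += n_dh * (1 - w)
        f = new / total
        if np.abs(f - prev).max() < tol:
            ambiguous = counts.sum() == 0  # all samples double-het: flat likelihood
            return f, bool(ambiguous)
        prev = f.copy()
    raise EmConvergenceError(max_iter)


def _known_hap_contrib(a: int, b: int) -> np.ndarray:
    """Haplotype counts (AB, Ab, aB, ab) contributed by one sample with
    unambiguous genotype (a, b) — any genotype except the double het."""
    table = {
        (0, 0): (0, 0, 0, 2),
        (0, 1): (0, 0, 1, 1),
        (0, 2): (0, 0, 2, 0),
        (1, 0): (0, 1, 0, 1),
        (1, 2): (1, 0, 1, 0),
        (2, 0): (0, 2, 0, 0),
        (2, 1): (1, 1, 0, 0),
        (2, 2): (2, 0, 0, 0),
    }
    return np.array(table[(a, b)], dtype=float)


def r2_unphased(
    dosages: np.ndarray,
    i: int,
    j: int,
    method: str = "em",
    *,
    max_iter: int = 1000,
    tol: float = 1e-10,
    min_informative: int = 20,
) -> float:
    """r² from unphased dosages.

    method="em": maximum-likelihood haplotype frequencies via EM over the
    double-heterozygote ambiguity, then the phased closed form.
    method="composite": squared Pearson correlation of dosages.

    Missing dosages (NaN) are pairwise-deleted; fewer than
    ``min_informative`` complete pairs raises ValueError.
    """
    g = np.asarray(dosages, dtype=float)
    gi, gj = g[:, i], g[:, j]
    keep = ~(np.isnan(gi) | np.isnan(gj))
    gi, gj = gi[keep], gj[keep]
    if gi.shape[0] < min_informative:
        raise ValueError(
            f"only {gi.shape[0]} informative samples after pairwise deletion "
            f"(minimum {min_informative})"
        )
    for idx, col in ((i, gi), (j, gj)):
        # all-ref or all-alt columns carry one allele only; an all-het
        # column is still allelically polymorphic
        if col.mean() in (0.0, 2.0):
            raise MonomorphicVariantError(
                f"variant column {idx} is monomorphic; r^2 undefined"
            )
    if method == "composite":
        for idx, col in ((i, gi), (j, gj)):
            if np.unique(col).size < 2:
                raise MonomorphicVariantError(
                    f"variant column {idx} has no dosage variance; composite "
                    "r^2 undefined"
                )
        r = np.corrcoef(gi, gj)[0, 1]
        return float(r * r)
    if method != "em":
        raise ValueError(f"unknown method {method!r}")
    f, ambiguous = _em_haplotype_freqs(gi.astype(int), gj.astype(int), max_iter, tol)
    if ambiguous:
        warnings.warn(
            "all samples are double-heterozygous: haplotype phase is not "
            "identifiable; returning the boundary EM solution",
            stacklevel=2,
        )
    p_a = f[0] + f[1]
    p_b = f[0] + f[2]
    d = f[0] - p_a * p_b
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    if denom == 0:
        raise MonomorphicVariantError("estimated allele frequency on the boundary")
    return float(d * d / denom)


def ld_matrix(panel: HaplotypePanel, with_dprime: bool = True) -> LdMatrix:
    """All-pairs r² (and D′) for a phased panel, vectorised.

    Raises MonomorphicVariantError if any variant is monomorphic.
    """
    h = panel.haplotypes.astype(float)
    p = h.mean(axis=0)
    if (p == 0).any() or (p == 1).any():
        bad = panel.variant_ids[int(np.argmax((p == 0) | (p == 1)))]
        raise MonomorphicVariantError(f"variant {bad!r} is monomorphic")
    n = h.shape[0]
    pab = (h.T @ h) / n
    d = pab - np.outer(p, p)
    denom = np.outer(p * (1 - p), p * (1 - p))
    r2 = np.clip(d * d / denom, 0.0, 1.0)
    np.fill_diagonal(r2, 1.0)
    dp = None
    if with_dprime:
        q = 1 - p
        dmax_pos = np.minimum(np.outer(p, q), np.outer(q, p))
        dmax_neg = np.minimum(np.outer(p, p), np.outer(q, q))
        dmax = np.where(d > 0, dmax_pos, dmax_neg)
        with np.errstate(divide="ignore", invalid="ignore"):
            dp = np.where(d == 0, 0.0, np.abs(d) / dmax)
        dp = np.clip(dp, 0.0, 1.0)
        np.fill_diagonal(dp, 1.0)
        dp = (dp + dp.T) / 2
    return LdMatrix(list(panel.variant_ids), (r2 + r2.T) / 2, dp)


def ld_cluster(
    ld: LdMatrix, cut: float = 0.5, method: str = "average"
) -> tuple[np.ndarray, np.ndarray]:
    """Hierarchical clustering of variants on distance 1 − r².

    Returns (leaf_order, labels): the dendrogram leaf ordering used for
    heatmap rendering and integer cluster labels from cutting the tree at
    distance ``cut``.
    """
    m = len(ld.variant_ids)
    if m < 2:
        raise ValueError("LD clustering needs at least 2 variants")
    dist = 1.0 - ld.r2
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, 1.0)
    z = linkage(squareform(dist, checks=False), method=method)
    order = leaves_list(z)
    labels = fcluster(z, t=cut, criterion="distance")
    return order, labels


def read_vcf_panel(path: str) -> HaplotypePanel:
    """Load a phased biallelic panel from a VCF (GT field, '|' separated).

    Unphased or missing genotypes raise ValueError: LD from unphased data
    should go through :func:`r2_unphased` on dosages instead.
    """
    from cyvcf2 import VCF

    ids, pos, ref, alt, rows = [], [], [], [], []
    chrom = "1"
    for rec in VCF(path):
        if len(rec.ALT) != 1:
            raise ValueError(f"variant {rec.ID} is not biallelic")
        gts = np.asarray(rec.genotype.array())
        if (gts[:, :2] < 0).any():
            raise ValueError(f"missing genotypes at {rec.ID}")
        if not rec.gt_phases.all():
            raise ValueError(f"unphased genotypes at {rec.ID}; use dosage methods")
        chrom = rec.CHROM
        ids.append(rec.ID or f"{rec.CHROM}_{rec.POS}")
        pos.append(rec.POS)
        ref.append(rec.REF)
        alt.append(rec.ALT[0])
        rows.append(gts[:, :2].reshape(-1))
    return HaplotypePanel(
        variant_ids=ids,
        positions=np.array(pos),
        haplotypes=np.array(rows).T,
        ref=ref,
        alt=alt,
        chrom=chrom,
    )


def write_ld_tsv(ld: LdMatrix, path: str, which: str = "r2") -> None:
    """Write an LD matrix as TSV with variant ids as header row/column."""
    mat = ld.r2 if which == "r2" else ld.dprime
    if mat is None:
        raise ValueError("D' matrix not present")
    pd.DataFrame(mat, index=ld.variant_ids, columns=ld.variant_ids).to_csv(
        path, sep="\t", index_label="variant_id"
    )
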