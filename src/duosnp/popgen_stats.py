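"""Per-marker and per-pair population-genetic statistics.

Implements the statistics the panel-selection pipeline filters on: allele
frequencies and call rates, the Hardy-Weinberg exact test, the KING-robust
pairwise kinship estimator, the Weir & Cockerham (1984) two-population
F_ST estimator, composite genotypic LD r-squared, and opposite-homozygosity
(exclusion) counts between two individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .io_formats import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class HweResult:
    marker_id: str
    n_hom_major: int
    n_het: int
    n_hom_minor: int
    p_value: float


@dataclass(frozen=True)
class KinshipEstimate:
    sample_i: str
    sample_j: str
    phi: float  # NaN when the denominator is zero
    n_informative: int


@dataclass(frozen=True)
class FstResult:
    marker_id: str
    fst: float


def allele_stats(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-marker (freq_minor, call_rate) and per-sample missing rate.

    freq_minor = (2*n_hom_minor + n_het) / (2*n_called), folded to <= 0.5.
    Markers with zero called genotypes get NaN frequency.
    """
    d = g.dosages
    called = d != MISSING
    n_called = called.sum(axis=0)
    minor_count = np.where(called, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_called > 0, minor_count / np.maximum(2 * n_called, 1), np.nan)
    freq = np.minimum(freq, 1.0 - freq)
    call_rate = n_called / d.shape[0]
    sample_missing = 1.0 - called.sum(axis=1) / d.shape[1]
    return freq, call_rate, sample_missing


def _hwe_log_probs(n_a: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact log-probabilities of every heterozygote count compatible with
    ``n_a`` copies of the rarer allele among ``n`` diploid genotypes."""
    parity = n_a % 2
    hets = np.arange(parity, min(n_a, 2 * n - n_a) + 1, 2)
    hom_rare = (n_a - hets) // 2
    hom_common = n - hets - hom_rare
    # P(het = h | n_a, n) ∝ n! / (hom_c! h! hom_r!) * 2^h  (conditional on allele counts)
    logp = (gammaln(n + 1) - gammaln(hom_common + 1) - gammaln(hets + 1)
            - gammaln(hom_rare + 1) + hets * np.log(2))
    logp -= logp.max()
    p = np.exp(logp)
    return hets, p / p.sum()


def hwe_exact(n_hom_major: int, n_het: int, n_hom_minor: int, marker_id: str = "") -> HweResult:
    """Two-sided Hardy-Weinberg exact test on genotype counts.

    Enumerates every heterozygote count compatible with the observed allele
    counts and sums the probabilities of configurations no more likely than
    the observed one. Monomorphic markers give p = 1. The test is invariant
    to swapping the homozygote labels.
    """
    if min(n_hom_major, n_het, n_hom_minor) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_major + n_het + n_hom_minor
    if n < 1:
        raise ValueError("at least one genotype required")
    n_a = 2 * min(n_hom_major, n_hom_minor) + n_het  # rarer-allele count
    if n_a == 0:
        return HweResult(marker_id, n_hom_major, n_het, n_hom_minor, 1.0)
    hets, probs = _hwe_log_probs(n_a, n)
    p_obs = probs[np.searchsorted(hets, n_het)]
    p_value = float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))
    return HweResult(marker_id, n_hom_major, n_het, n_hom_minor, p_value)


def hwe_exact_matrix(g: GenotypeMatrix, marker_ids=None) -> np.ndarray:
    """Vector of HWE exact p-values, one per marker (missing calls skipped)."""
    d = g.dosages
    out = np.ones(d.shape[1])
    for j in range(d.shape[1]):
        col = d[:, j]
        col = col[col != MISSING]
        if col.size == 0:
            out[j] = np.nan
            continue
        out[j] = hwe_exact(int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())).p_value
    return out


def king_kinship(g_i: np.ndarray, g_j: np.ndarray,
                 sample_i: str = "i", sample_j: str = "j") -> KinshipEstimate:
    """KING-robust between-family kinship estimate for one pair.

    phi = (N_het,het - 2*N_opp_hom) / (N_het(i) + N_het(j)) over loci called
    in both samples. The estimator is symmetric in the pair; identical
    genotype vectors with at least one heterozygous locus give phi = 0.5.
    """
    g_i = np.asarray(g_i)
    g_j = np.asarray(g_j)
    valid = (g_i != MISSING) & (g_j != MISSING)
    a, b = g_i[valid], g_j[valid]
    het_i = a == 1
    het_j = b == 1
    n_hh = int((het_i & het_j).sum())
    n_opp = int((((a == 0) & (b == 2)) | ((a == 2) & (b == 0))).sum())
    denom = int(het_i.sum() + het_j.sum())
    phi = (n_hh - 2 * n_opp) / denom if denom > 0 else float("nan")
    return KinshipEstimate(sample_i, sample_j, float(phi), int(valid.sum()))


def king_kinship_matrix(g: GenotypeMatrix) -> np.ndarray:
    """All-pairs KING-robust kinship as an (n, n) matrix (NaN diagonal/undefined)."""
    d = g.dosages
    valid = d != MISSING
    het = ((d == 1) & valid).astype(np.float64)
    hom0 = ((d == 0) & valid).astype(np.float64)
    hom2 = ((d == 2) & valid).astype(np.float64)
    v = valid.astype(np.float64)
    n_hh = het @ het.T
    n_opp = hom0 @ hom2.T + hom2 @ hom0.T
    het_i = het @ v.T  # het loci of i that are called in j
    denom = het_i + het_i.T
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(denom > 0, (n_hh - 2 * n_opp) / denom, np.nan)
    np.fill_diagonal(phi, np.nan)
    return phi


def fst_two_pop(g: GenotypeMatrix, pop_labels: np.ndarray, marker_ids=None) -> np.ndarray:
    """Weir & Cockerham (1984) per-marker F_ST between two subpopulations.

    ``pop_labels`` assigns each sample to one of exactly two groups. The
    estimator can be slightly negative; markers uncalled in a group give NaN.
    """
    labels = np.asarray(pop_labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("exactly two population labels required")
    d = g.dosages
    r = 2
    stats = []
    for grp in groups:
        sub = d[labels == grp]
        called = sub != MISSING
        n_i = called.sum(axis=0).astype(float)          # diploid count per marker
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.where(n_i > 0, np.where(called, sub, 0).sum(axis=0) / (2 * n_i), np.nan)
            h_i = np.where(n_i > 0, ((sub == 1) & called).sum(axis=0) / n_i, np.nan)
        stats.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = stats
    with np.errstate(invalid="ignore", divide="ignore"):
        n_bar = (n1 + n2) / r
        n_c = (n1 + n2 - (n1 ** 2 + n2 ** 2) / (n1 + n2)) / (r - 1)
        p_bar = (n1 * p1 + n2 * p2) / (n1 + n2)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        inner = p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4
        a = n_bar / n_c * (s2 - inner / (n_bar - 1))
        b = n_bar / (n_bar - 1) * (p_bar * (1 - p_bar) - (r - 1) / r * s2
                                   - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
        c = h_bar / 2
        denom = a + b + c
        fst = np.where(denom != 0, a / denom, 0.0)
    fst = np.where((n1 > 0) & (n2 > 0), fst, np.nan)
    return fst


def ld_r2(g_a: np.ndarray, g_b: np.ndarray) -> float:
    """Composite genotypic r^2: squared Pearson correlation of dosage codes
    on pairwise-complete samples. NaN when either marker has zero variance
    in the complete subset (callers treat NaN as not exceeding a threshold)."""
    g_a = np.asarray(g_a, dtype=float)
    g_b = np.asarray(g_b, dtype=float)
    valid = (g_a != MISSING) & (g_b != MISSING)
    a, b = g_a[valid], g_b[valid]
    if a.size < 2:
        raise ValueError("need >= 2 pairwise-complete observations")
    va = a.var()
    vb = b.var()
    if va == 0 or vb == 0:
        return float("nan")
    cov = ((a - a.mean()) * (b - b.mean())).mean()
    return float(cov * cov / (va * vb))


def ld_r2_window(d: np.ndarray) -> np.ndarray:
    """Pairwise composite r^2 for a (n_samples, n_markers) dosage block.

    Missing codes are handled by pairwise-complete statistics (matching
    :func:`ld_r2` pair by pair). Pairs with < 2 complete observations or
    zero variance yield NaN.
    """
    x = d.astype(np.float64)
    m = (d != MISSING).astype(np.float64)
    xm = np.where(d != MISSING, x, 0.0)
    n = m.T @ m
    s_a = xm.T @ m          # s_a[i,j] = sum of x_i over samples complete in (i,j)
    s_aa = (xm * xm).T @ m
    s_ab = xm.T @ xm
    with np.errstate(invalid="ignore", divide="ignore"):
        mu_a = s_a / n
        cov = s_ab / n - mu_a * mu_a.T
        var_a = s_aa / n - mu_a ** 2
        r2 = cov * cov / (var_a * var_a.T)
        r2 = np.where((n >= 2) & (var_a > 0) & (var_a.T > 0), r2, np.nan)
    return r2


def opposite_homozygosity(g_i: np.ndarray, g_j: np.ndarray) -> int:
    """Count loci where the pair are homozygous for different alleles
    (dosage pairs {0,2} or {2,0}); missing loci are skipped. A mutation-free
    true parent-child pair always counts 0."""
    g_i = np.asarray(g_i)
    g_j = np.asarray(g_j)
    valid = (g_i != MISSING) & (g_j != MISSING)
    return int((((g_i == 0) & (g_j == 2)) | ((g_i == 2) & (g_j == 0)))[valid].sum())
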