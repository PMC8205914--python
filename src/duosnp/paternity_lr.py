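"""Paternity-index likelihood ratios for alleged-parent/child pairs.

The per-marker paternity index for a duo is
PI = Pr(child genotype | alleged father is a parent, random mate under HWE)
   / Pr(child genotype | the two are unrelated, HWE),
computed from first principles by enumerating the transmitted parental
allele and the mate's HWE allele. Opposite homozygotes give PI = 0
(exclusion; no mutation model). The combined evidence is the product over
markers, reported as log10LR; one exclusion drives it to -infinity. The
decision rule is log10LR >= 5 (inclusive) for "parent-child".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import MISSING, MarkerTable


@dataclass(frozen=True)
class DecisionPolicy:
    """Threshold on log10LR; ``inclusive`` means >= (the default rule)."""

    log10_threshold: float = 5.0
    inclusive: bool = True

    def decide(self, log10_lr: float) -> str:
        if self.inclusive:
            included = log10_lr >= self.log10_threshold
        else:
            included = log10_lr > self.log10_threshold
        return "parent-child" if included else "not-parent-child"


@dataclass
class LRResult:
    """Combined likelihood-ratio evidence for one tested pair."""

    pair: tuple[str, str]
    pi_values: np.ndarray
    log10_lr: float
    n_markers_used: int
    n_exclusions: int
    decision: str
    n_mismatch: int | None = None


def _transmit_prob(g_parent: int, allele: int) -> float:
    """Pr(parent transmits `allele` copies... probability of transmitting the
    minor allele) given parent dosage."""
    return (0.0, 0.5, 1.0)[g_parent] if allele == 1 else (1.0, 0.5, 0.0)[g_parent]


def duo_pi(g_af: int, g_child: int, p: float) -> float:
    """Paternity index for an alleged-parent/child duo at one bi-allelic
    marker with minor-allele frequency ``p``.

    Enumerates the allele transmitted by the alleged parent and the HWE
    allele contributed by an unknown mate. Opposite homozygotes give 0;
    at p = 0.5 the het/het configuration gives exactly 1.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("allele frequency must lie strictly in (0, 1)")
    if g_af not in (0, 1, 2) or g_child not in (0, 1, 2):
        raise ValueError("genotype codes must be 0, 1 or 2")
    q = 1.0 - p
    hwe = (q * q, 2 * p * q, p * p)
    # Pr(child | AF parent) = sum over transmitted allele a and mate allele b
    num = 0.0
    for a in (0, 1):  # transmitted allele: 1 = minor
        ta = _transmit_prob(g_af, a)
        if ta == 0.0:
            continue
        for b in (0, 1):
            tb = p if b == 1 else q
            if a + b == g_child:
                num += ta * tb
    return num / hwe[g_child]


def trio_pi(g_af: int, g_mother: int, g_child: int, p: float) -> float:
    """Paternity index when the mother's genotype is also available:
    Pr(child | mother, AF parent) / Pr(child | mother, random father).

    Raises on a mother/child Mendelian incompatibility (distinct from a
    paternal exclusion, which returns 0).
    """
    if not 0.0 < p < 1.0:
        raise ValueError("allele frequency must lie strictly in (0, 1)")
    q = 1.0 - p

    def child_prob(paternal_dist) -> float:
        total = 0.0
        for b in (0, 1):
            tb = _transmit_prob(g_mother, b)
            if tb == 0.0:
                continue
            for a in (0, 1):
                if a + b == g_child:
                    total += tb * paternal_dist[a]
        return total

    denom = child_prob((q, p))  # random father's allele at HWE
    if denom == 0.0:
        raise ValueError("mother and child genotypes are Mendelian-incompatible")
    num = child_prob((_transmit_prob(g_af, 0), _transmit_prob(g_af, 1)))
    return num / denom


def duo_pi_array(g_af: np.ndarray, g_child: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Vectorized :func:`duo_pi` over aligned arrays (broadcasting on ``p``);
    MISSING in either member yields NaN (caller skips those loci)."""
    g_af = np.asarray(g_af)
    g_child = np.asarray(g_child)
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    out = np.full(np.broadcast_shapes(g_af.shape, g_child.shape), np.nan)
    # transmitted-minor probability per AF genotype: dosage / 2
    t_minor = np.clip(g_af, 0, 2) * 0.5
    t_major = 1.0 - t_minor
    hwe = np.stack([q * q, 2 * p * q, p * p])
    num = np.zeros_like(out)
    num = np.where(g_child == 0, t_major * q, num)
    num = np.where(g_child == 1, t_major * p + t_minor * q, num)
    num = np.where(g_child == 2, t_minor * p, num)
    denom = np.choose(np.clip(g_child, 0, 2), hwe)
    pi = num / denom
    missing = (g_af == MISSING) | (g_child == MISSING)
    return np.where(missing, np.nan, pi)


def combine_lr(pis: np.ndarray, policy: DecisionPolicy,
               pair: tuple[str, str] = ("a", "b")) -> LRResult:
    """Combine per-marker PI values into a decision.

    log10LR is the sum of log10 PI over used markers (-inf on any zero);
    NaN entries (missing genotypes) are skipped and counted out of use.
    """
    pis = np.asarray(pis, dtype=float)
    used = ~np.isnan(pis)
    if not used.any():
        raise ValueError("no markers with called genotypes in both members")
    vals = pis[used]
    n_excl = int((vals == 0.0).sum())
    if n_excl > 0:
        log10_lr = float("-inf")
    else:
        log10_lr = float(np.log10(vals).sum())
    return LRResult(pair, pis, log10_lr, int(used.sum()), n_excl, policy.decide(log10_lr))


def pair_test(g_a: np.ndarray, g_b: np.ndarray, markers: MarkerTable,
              policy: DecisionPolicy | None = None,
              pair: tuple[str, str] = ("a", "b")) -> LRResult:
    """Sex-agnostic parent-child test of a pair of genotype vectors.

    The duo PI table is symmetric in which member is treated as the alleged
    parent, so either orientation gives the same log10LR. The opposite-
    homozygosity mismatch count is attached to the result.
    """
    from .popgen_stats import opposite_homozygosity

    policy = policy or DecisionPolicy()
    p = markers.freq_minor
    pis = duo_pi_array(np.asarray(g_a), np.asarray(g_b), p)
    res = combine_lr(pis, policy, pair)
    res.n_mismatch = opposite_homozygosity(g_a, g_b)
    return res


def batch_log10_lr(g_af: np.ndarray, g_child: np.ndarray, p: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """log10LR and exclusion counts for many pairs at once.

    ``g_af`` and ``g_child`` are (n_pairs, n_markers) dosage arrays with no
    missing codes; returns (log10_lr with -inf for excluded pairs,
    n_exclusions per pair).
    """
    pi = duo_pi_array(g_af, g_child, p[None, :])
    n_excl = (pi == 0.0).sum(axis=1)
    with np.errstate(divide="ignore"):
        log10 = np.where(pi > 0, np.log10(np.where(pi > 0, pi, 1.0)), -np.inf)
    return log10.sum(axis=1), n_excl
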