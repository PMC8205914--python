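"""Marker-count sweep and its summary metrics.

For each panel size n (default 70, 80, ..., 200) every family contributes
four alleged-father/child duos: the true father (AF1), the true father's
brother (AF2), the true father's other child (AF3) and a random man (AF4).
The false-negative rate is the percentage of AF1 pairs decided
"not-parent-child"; the false-positive rate is the percentage of
AF2/AF3/AF4 pairs decided "parent-child"; accuracy is the percentage of all
4 x n_families pairs decided correctly, so

    accuracy = 100 - (3 * FP + FN) / 4

holds exactly for every sweep row. An exact-binomial oracle for the
false-negative rate at minor-allele frequency 1/2 is provided: for a true
duo every non-contributing marker has PI 1 except the both-homozygous
(matching) configuration, whose probability is 1/4 and whose PI is 2, so
log10LR = K * log10(2) with K ~ Binomial(n, 1/4).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom

from .io_formats import MarkerTable
from .marker_selection import panel_subset
from .paternity_lr import DecisionPolicy, LRResult, batch_log10_lr
from .pedigree_sim import FamilyBatch

NON_FATHERS = ("af2", "af3", "af4")


@dataclass
class EvaluationSummary:
    """Per marker-count accuracy / false-positive / false-negative table
    (percentages), the machine-readable counterpart of the sweep."""

    rows: pd.DataFrame
    n_families: int
    pair_counts: dict[str, int] = field(default_factory=dict)

    def row(self, n_markers: int) -> pd.Series:
        hit = self.rows[self.rows["n_markers"] == n_markers]
        if hit.empty:
            raise KeyError(f"no sweep row for n_markers={n_markers}")
        return hit.iloc[0]


def evaluate_sweep(families: FamilyBatch, panel: MarkerTable,
                   counts: list[int] | None = None,
                   policy: DecisionPolicy | None = None) -> EvaluationSummary:
    """Run the marker-count sweep over a simulated family batch.

    ``panel`` must be the marker table the families were simulated on;
    subsets are the nested top-MAF prefixes from :func:`panel_subset`.
    """
    policy = policy or DecisionPolicy()
    counts = list(counts) if counts is not None else list(range(70, 201, 10))
    if families.n_families < 1:
        raise ValueError("empty family batch")
    full_ids = panel.marker_ids
    child = families.genotypes("child")
    af_geno = {"af1": families.genotypes("tf")}
    for m in NON_FATHERS:
        af_geno[m] = families.genotypes(m)
    rows = []
    n_fam = families.n_families
    for n in counts:
        sub = panel_subset(panel, n)
        idx = np.flatnonzero(np.isin(full_ids, sub.marker_ids))
        p = panel.freq_minor[idx]
        lr_tf, _ = batch_log10_lr(af_geno["af1"][:, idx], child[:, idx], p)
        thr = policy.log10_threshold
        fn = (lr_tf < thr).mean() if policy.inclusive else (lr_tf <= thr).mean()
        fp_hits = 0
        for m in NON_FATHERS:
            lr, _ = batch_log10_lr(af_geno[m][:, idx], child[:, idx], p)
            fp_hits += int((lr >= thr).sum() if policy.inclusive else (lr > thr).sum())
        fp = fp_hits / (3 * n_fam)
        accuracy = 100.0 - (3 * fp * 100.0 + fn * 100.0) / 4.0
        rows.append({"n_markers": n, "accuracy_pct": accuracy,
                     "fp_rate_pct": fp * 100.0, "fn_rate_pct": fn * 100.0})
    summary = EvaluationSummary(pd.DataFrame(rows), n_fam,
                                {"af1": n_fam, "af2": n_fam, "af3": n_fam, "af4": n_fam})
    return summary


def analytic_fn_rate(n_markers: int, p: float = 0.5, threshold: float = 5.0) -> float:
    """Exact false-negative rate for a true duo at minor-allele frequency 1/2.

    FN = Pr(K < k*) with K ~ Binomial(n_markers, 1/4) counting both-
    homozygous matching loci and k* the smallest integer with
    k* * log10(2) >= threshold. Returned as a percentage. Only valid at
    p = 0.5 (elsewhere the per-locus log10 PI is not two-valued).
    """
    if p != 0.5:
        raise ValueError("exact form is valid only at p = 0.5; use simulation")
    if threshold <= 0:
        return 0.0
    k_star = math.ceil(threshold / math.log10(2.0))
    return float(100.0 * binom.cdf(k_star - 1, n_markers, 0.25))


def lr_distribution(results: list[LRResult] | np.ndarray) -> dict[str, float]:
    """Mean/min/max of the finite log10LR values plus the count of excluded
    (log10LR = -inf) results."""
    if isinstance(results, np.ndarray):
        vals = results.astype(float)
    else:
        vals = np.array([r.log10_lr for r in results], dtype=float)
    finite = vals[np.isfinite(vals)]
    n_excluded = int(np.isneginf(vals).sum())
    if finite.size == 0:
        return {"mean": float("nan"), "min": float("nan"), "max": float("nan"),
                "n_finite": 0, "n_excluded": n_excluded}
    return {"mean": float(finite.mean()), "min": float(finite.min()),
            "max": float(finite.max()), "n_finite": int(finite.size),
            "n_excluded": n_excluded}
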