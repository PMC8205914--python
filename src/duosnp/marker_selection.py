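"""Staged candidate-marker selection: from a raw cohort genotype matrix to a
spaced, high-MAF, mutually independent candidate panel.

Stage order: gene-region exclusion -> QC (sample missingness, marker
missingness, HWE) -> relatedness pruning of samples -> F_ST screen ->
windowed LD pruning -> greedy MAF ranking under a same-chromosome spacing
constraint. Every stage appends to a :class:`SelectionAudit`. The pipeline
is deterministic: no stage uses random numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import GenotypeMatrix, IntervalSet, MarkerTable
from .popgen_stats import (allele_stats, fst_two_pop, hwe_exact_matrix,
                           king_kinship_matrix, ld_r2_window)


@dataclass(frozen=True)
class SelectionParams:
    """Thresholds of the selection pipeline.

    Defaults are the study's operating point: per-sample missingness 0.05,
    per-marker missingness 0.01, HWE exact-test alpha 1e-5, kinship cutoff
    0.0884 (second/third-degree boundary), F_ST screen 0.01, LD pruning
    window 500 markers / step 50 / r^2 0.01, same-chromosome spacing
    10 Mbp, 200 candidates.
    """

    max_sample_missing: float = 0.05
    max_marker_missing: float = 0.01
    hwe_alpha: float = 1e-5
    kinship_max: float = 0.0884
    fst_max: float = 0.01
    ld_window: int = 500
    ld_step: int = 50
    ld_r2_max: float = 0.01
    min_spacing_bp: int = 10_000_000
    n_candidates: int = 200

    def __post_init__(self) -> None:
        for name in ("max_sample_missing", "max_marker_missing", "hwe_alpha",
                     "fst_max", "ld_r2_max"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_candidates < 1:
            raise ValueError("n_candidates must be >= 1")
        if self.ld_window < 1 or self.ld_step < 1:
            raise ValueError("LD window/step must be >= 1")


@dataclass
class SelectionAudit:
    """Ordered per-stage bookkeeping: (stage, axis, removed, remaining)."""

    stages: list[tuple[str, str, int, int]] = field(default_factory=list)

    def record(self, stage: str, axis: str, removed: int, remaining: int) -> None:
        self.stages.append((stage, axis, int(removed), int(remaining)))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.stages, columns=["stage", "axis", "removed", "remaining"])


class SelectionError(RuntimeError):
    """Raised when a selection stage empties the data or supply runs short."""


def exclude_gene_regions(markers: MarkerTable, genes: IntervalSet,
                         g: GenotypeMatrix | None = None,
                         audit: SelectionAudit | None = None):
    """Drop markers whose position lies inside any gene interval."""
    keep = np.ones(len(markers), dtype=bool)
    for chrom in np.unique(markers.chrom):
        sel = markers.chrom == chrom
        keep[sel] = ~genes.contains(int(chrom), markers.bp[sel])
    idx = np.flatnonzero(keep)
    if audit is not None:
        audit.record("gene_regions", "markers", len(markers) - len(idx), len(idx))
    out_markers = markers.take(idx)
    if g is None:
        return out_markers
    return g.subset_markers(idx), out_markers


def qc_filter(g: GenotypeMatrix, markers: MarkerTable, params: SelectionParams,
              audit: SelectionAudit | None = None
              ) -> tuple[GenotypeMatrix, MarkerTable, SelectionAudit]:
    """Missingness and HWE quality control, in order:

    1. drop samples with missing rate > ``max_sample_missing``;
    2. drop markers with missing rate > ``max_marker_missing`` among the
       retained samples;
    3. drop markers failing the HWE exact test at ``hwe_alpha`` on the
       retained samples.
    """
    if g.n_samples == 0 or g.n_markers == 0:
        raise SelectionError("empty genotype matrix")
    audit = audit if audit is not None else SelectionAudit()

    _, _, sample_missing = allele_stats(g)
    keep_s = np.flatnonzero(sample_missing <= params.max_sample_missing)
    if keep_s.size == 0:
        raise SelectionError("all samples removed by missingness filter")
    g = g.subset_samples(keep_s)
    audit.record("sample_missingness", "samples", len(sample_missing) - keep_s.size, keep_s.size)

    _, call_rate, _ = allele_stats(g)
    keep_m = np.flatnonzero(1.0 - call_rate <= params.max_marker_missing)
    if keep_m.size == 0:
        raise SelectionError("all markers removed by missingness filter")
    g = g.subset_markers(keep_m)
    markers = markers.take(keep_m)
    audit.record("marker_missingness", "markers", len(call_rate) - keep_m.size, keep_m.size)

    pvals = hwe_exact_matrix(g)
    keep_h = np.flatnonzero(~(pvals < params.hwe_alpha))
    if keep_h.size == 0:
        raise SelectionError("all markers removed by HWE filter")
    g = g.subset_markers(keep_h)
    markers = markers.take(keep_h)
    audit.record("hwe", "markers", len(pvals) - keep_h.size, keep_h.size)

    return g, markers, audit


def prune_related_samples(g: GenotypeMatrix, params: SelectionParams,
                          audit: SelectionAudit | None = None) -> tuple[np.ndarray, SelectionAudit]:
    """Greedy removal of samples until all pairwise KING kinship < cutoff.

    Repeatedly removes the sample with the most over-threshold partners;
    ties resolve to the smaller sample index. Returns the retained sample
    indices (in original order).
    """
    audit = audit if audit is not None else SelectionAudit()
    if g.n_samples < 2:
        audit.record("kinship", "samples", 0, g.n_samples)
        return np.arange(g.n_samples), audit
    phi = king_kinship_matrix(g)
    over = np.nan_to_num(phi, nan=-1.0) >= params.kinship_max
    active = np.ones(g.n_samples, dtype=bool)
    while True:
        degree = (over & active[None, :] & active[:, None]).sum(axis=1)
        degree[~active] = 0
        worst = int(degree.argmax())
        if degree[worst] == 0:
            break
        active[worst] = False
    keep = np.flatnonzero(active)
    audit.record("kinship", "samples", g.n_samples - keep.size, keep.size)
    return keep, audit


def fst_screen(g: GenotypeMatrix, markers: MarkerTable, pop_labels: np.ndarray,
               params: SelectionParams, audit: SelectionAudit | None = None
               ) -> tuple[GenotypeMatrix, MarkerTable]:
    """Remove markers whose two-population F_ST is >= ``fst_max``."""
    audit = audit if audit is not None else SelectionAudit()
    fst = fst_two_pop(g, pop_labels)
    keep = np.flatnonzero(~(fst >= params.fst_max))
    audit.record("fst", "markers", len(fst) - keep.size, keep.size)
    return g.subset_markers(keep), markers.take(keep)


def ld_prune(g: GenotypeMatrix, markers: MarkerTable, params: SelectionParams,
             audit: SelectionAudit | None = None) -> tuple[GenotypeMatrix, MarkerTable]:
    """Sliding-window greedy LD pruning.

    Within each ``ld_window``-marker window (slid by ``ld_step``), while any
    retained pair exceeds ``ld_r2_max``, the member of the worst pair with
    the lower MAF is removed (tie: the larger bp). Guarantees no retained
    within-window pair with r^2 > threshold.
    """
    audit = audit if audit is not None else SelectionAudit()
    n_m = g.n_markers
    freq, _, _ = allele_stats(g)
    d = g.dosages
    keep = np.ones(n_m, dtype=bool)
    bp = markers.bp
    chrom = markers.chrom
    start = 0
    while start < n_m:
        end = min(start + params.ld_window, n_m)
        idx = np.flatnonzero(keep[start:end]) + start
        if idx.size >= 2:
            r2 = ld_r2_window(d[:, idx])
            np.fill_diagonal(r2, 0.0)
            r2 = np.nan_to_num(r2, nan=0.0)
            # windows never span chromosomes in spirit; zero out cross-chrom pairs
            same = chrom[idx][:, None] == chrom[idx][None, :]
            r2 = np.where(same, r2, 0.0)
            local_keep = np.ones(idx.size, dtype=bool)
            while True:
                masked = np.where(local_keep[:, None] & local_keep[None, :], r2, 0.0)
                worst = masked.max()
                if worst <= params.ld_r2_max:
                    break
                a, b = np.unravel_index(masked.argmax(), masked.shape)
                ia, ib = idx[a], idx[b]
                if freq[ia] < freq[ib]:
                    drop = a
                elif freq[ib] < freq[ia]:
                    drop = b
                else:
                    drop = a if bp[ia] > bp[ib] else b
                local_keep[drop] = False
            keep[idx[~local_keep]] = False
        if end == n_m:
            break
        start += params.ld_step
    idx = np.flatnonzero(keep)
    audit.record("ld_prune", "markers", n_m - idx.size, idx.size)
    return g.subset_markers(idx), markers.take(idx)


def select_candidates(markers: MarkerTable, params: SelectionParams,
                      audit: SelectionAudit | None = None) -> MarkerTable:
    """Greedy top-MAF candidate selection under a same-chromosome spacing rule.

    Markers are visited by descending MAF (ties: smaller chrom, then smaller
    bp) and accepted iff strictly farther than ``min_spacing_bp`` from every
    already-accepted marker on the same chromosome, until ``n_candidates``
    are found. Raises :class:`SelectionError` on shortfall.
    """
    audit = audit if audit is not None else SelectionAudit()
    freq = markers.freq_minor
    order = sorted(range(len(markers)),
                   key=lambda j: (-freq[j], markers.chrom[j], markers.bp[j]))
    accepted: list[int] = []
    by_chrom: dict[int, list[int]] = {}
    for j in order:
        c = int(markers.chrom[j])
        pos = int(markers.bp[j])
        if all(abs(pos - int(markers.bp[k])) > params.min_spacing_bp for k in by_chrom.get(c, [])):
            accepted.append(j)
            by_chrom.setdefault(c, []).append(j)
            if len(accepted) == params.n_candidates:
                break
    if len(accepted) < params.n_candidates:
        raise SelectionError(
            f"only {len(accepted)} of {params.n_candidates} candidates satisfy the "
            f"spacing constraint")
    audit.record("candidates", "markers", len(markers) - len(accepted), len(accepted))
    return markers.take(accepted)


def panel_subset(candidates: MarkerTable, n: int) -> MarkerTable:
    """Deterministic top-``n`` candidates by descending MAF (ties: smaller
    chrom then bp); subsets are nested across ``n``."""
    if not 1 <= n <= len(candidates):
        raise ValueError(f"n must lie in [1, {len(candidates)}]")
    freq = candidates.freq_minor
    order = sorted(range(len(candidates)),
                   key=lambda j: (-freq[j], candidates.chrom[j], candidates.bp[j]))
    return candidates.take(order[:n])


def run_selection(g: GenotypeMatrix, markers: MarkerTable, genes: IntervalSet,
                  pop_labels: np.ndarray | None, params: SelectionParams
                  ) -> tuple[MarkerTable, SelectionAudit]:
    """Full pipeline; returns the candidate panel (with frequencies
    re-estimated on the final unrelated sample set) and the audit."""
    audit = SelectionAudit()
    id_to_label = (dict(zip(g.sample_ids, np.asarray(pop_labels)))
                   if pop_labels is not None else None)
    g, markers = exclude_gene_regions(markers, genes, g, audit)
    g, markers, audit = qc_filter(g, markers, params, audit)
    keep_s, audit = prune_related_samples(g, params, audit)
    g = g.subset_samples(keep_s)
    if id_to_label is not None:
        labels = np.array([id_to_label[s] for s in g.sample_ids])
        if len(np.unique(labels)) == 2:
            g, markers = fst_screen(g, markers, labels, params, audit)
    g, markers = ld_prune(g, markers, params, audit)
    freq, _, _ = allele_stats(g)
    df = markers.df.copy()
    df["freq_minor"] = np.nan_to_num(freq, nan=0.0)
    markers = MarkerTable(df)
    panel = select_candidates(markers, params, audit)
    return panel, audit
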