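"""Synthetic cohorts with the statistical structure the pipeline assumes.

Two generators:

* :func:`generate_cohort` builds a population-cohort stand-in — a genotype
  matrix of nominally unrelated samples drawn under HWE from a realistic
  minor-allele-frequency spectrum, with configurable missingness, a
  fraction of markers planted inside gene intervals, markers planted out of
  HWE via an excess-homozygosity (inbreeding-style) coefficient, cryptic
  related pairs produced by gene dropping, and two subpopulation labels
  with optional frequency divergence.
* :func:`generate_family_cohort` builds a family-cohort stand-in from the
  pedigree simulator, emitting labeled parent-child, second-degree and
  unrelated pairs for validating the likelihood-ratio classifier.

Every planted anomaly is reported in a truth record so tests can check the
corresponding detector. Both generators are seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import MISSING, GenotypeMatrix, IntervalSet, MarkerTable
from .pedigree_sim import MEMBERS, SimParams, simulate_families

CHROM_LENGTHS_BP = {
    1: 249_250_621, 2: 243_199_373, 3: 198_022_430, 4: 191_154_276,
    5: 180_915_260, 6: 171_115_067, 7: 159_138_663, 8: 146_364_022,
    9: 141_213_431, 10: 135_534_747, 11: 135_006_516, 12: 133_851_895,
    13: 115_169_878, 14: 107_349_540, 15: 102_531_392, 16: 90_354_753,
    17: 81_195_210, 18: 78_077_248, 19: 59_128_983, 20: 63_025_520,
    21: 48_129_895, 22: 51_304_566,
}
"""hg19 autosome lengths used to place synthetic markers."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic population cohort.

    Defaults emulate a genotyping-array cohort at desk scale: a
    Uniform(0.01, 0.5) MAF spectrum, low missingness, a minority of markers
    inside gene regions, a few HWE-violating markers with strong excess
    homozygosity, a handful of cryptic first-degree relative pairs, and two
    equally sized subpopulation labels with no real divergence.
    """

    n_samples: int = 500
    n_markers: int = 2000
    freq_low: float = 0.01
    freq_high: float = 0.5
    sample_missing_rate: float = 0.002
    marker_missing_rate: float = 0.002
    gene_fraction: float = 0.3
    n_hwe_violators: int = 5
    hwe_inbreeding_f: float = 0.5
    n_related_pairs: int = 3
    related_degree: str = "parent-child"
    subpop_divergence: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_markers < 1:
            raise ValueError("n_samples and n_markers must be >= 1")
        for name in ("sample_missing_rate", "marker_missing_rate", "gene_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if 2 * self.n_related_pairs > self.n_samples:
            raise ValueError("more planted relatives than samples")
        if self.n_hwe_violators > self.n_markers:
            raise ValueError("more HWE violators than markers")


@dataclass
class CohortTruth:
    """Ground truth of the planted structure."""

    related_pairs: list[tuple[int, int, str]] = field(default_factory=list)
    hwe_violators: list[str] = field(default_factory=list)
    gene_markers: list[str] = field(default_factory=list)
    subpop_labels: np.ndarray | None = None


def _place_markers(n_markers: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    chroms = np.array(sorted(CHROM_LENGTHS_BP))
    lengths = np.array([CHROM_LENGTHS_BP[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    chrom = rng.choice(chroms, size=n_markers, p=probs)
    bp = np.empty(n_markers, dtype=np.int64)
    for c in chroms:
        sel = chrom == c
        bp[sel] = np.sort(rng.choice(CHROM_LENGTHS_BP[c] - 1, size=sel.sum(), replace=False)) + 1
    order = np.lexsort((bp, chrom))
    return chrom[order], bp[order]


def _marker_table(chrom, bp, freq, rng) -> MarkerTable:
    bases = np.array(list("ACGT"))
    a1 = rng.integers(0, 4, size=len(bp))
    a2 = (a1 + rng.integers(1, 4, size=len(bp))) % 4
    return MarkerTable.from_records([
        {"marker_id": f"snp{j:06d}", "chrom": int(chrom[j]), "bp": int(bp[j]),
         "allele_minor": bases[a1[j]], "allele_major": bases[a2[j]],
         "cm": np.nan, "freq_minor": float(freq[j])}
        for j in range(len(bp))
    ])


def generate_cohort(spec: CohortSpec) -> tuple[GenotypeMatrix, MarkerTable, IntervalSet, CohortTruth]:
    """Generate the synthetic population cohort described by ``spec``."""
    rng = np.random.default_rng(spec.seed)
    chrom, bp = _place_markers(spec.n_markers, rng)
    freq = rng.uniform(spec.freq_low, spec.freq_high, size=spec.n_markers)

    # subpopulation labels and (optionally diverged) per-group frequencies
    labels = np.zeros(spec.n_samples, dtype=int)
    labels[spec.n_samples // 2:] = 1
    if spec.subpop_divergence > 0:
        delta = rng.normal(0.0, spec.subpop_divergence, size=spec.n_markers)
        freq_by_group = np.clip(np.stack([freq - delta / 2, freq + delta / 2]), 0.005, 0.995)
    else:
        freq_by_group = np.stack([freq, freq])

    # unrelated genotypes under HWE within each subpopulation
    u = rng.random((spec.n_samples, 2, spec.n_markers))
    p_per_sample = freq_by_group[labels]  # (n_samples, n_markers)
    dos = (u[:, 0, :] < p_per_sample).astype(np.int8) + (u[:, 1, :] < p_per_sample).astype(np.int8)

    truth = CohortTruth(subpop_labels=labels)

    # plant HWE violators: excess homozygosity with inbreeding coefficient F,
    # placed at common markers (freq >= 0.2) where the exact test has power
    common = np.flatnonzero(freq >= min(0.2, freq.max()))
    viol = rng.choice(common, size=spec.n_hwe_violators, replace=False)
    f = spec.hwe_inbreeding_f
    for j in viol:
        p = freq[j]
        q = 1 - p
        probs = [q * q + f * p * q, 2 * p * q * (1 - f), p * p + f * p * q]
        dos[:, j] = rng.choice([0, 1, 2], size=spec.n_samples, p=probs)

    # plant related pairs by overwriting the second member with a gene-dropped
    # relative of the first (no recombination model needed at cohort scale:
    # independent fair-coin transmission per locus)
    for k in range(spec.n_related_pairs):
        i, j = 2 * k, 2 * k + 1
        parent = dos[i]
        p_row = p_per_sample[j]
        transmitted = np.where(parent == 1, rng.integers(0, 2, spec.n_markers), parent // 2)
        other = (rng.random(spec.n_markers) < p_row).astype(np.int8)
        if spec.related_degree == "parent-child":
            dos[j] = (transmitted + other).astype(np.int8)
        elif spec.related_degree == "second-degree":
            # transmit the parent's gamete through one more meiosis with an
            # unrelated mate, i.e. a grandchild of sample i
            mid = (transmitted + other).astype(np.int8)
            trans2 = np.where(mid == 1, rng.integers(0, 2, spec.n_markers), mid // 2)
            other2 = (rng.random(spec.n_markers) < p_row).astype(np.int8)
            dos[j] = (trans2 + other2).astype(np.int8)
        else:
            raise ValueError(f"unknown related_degree {spec.related_degree!r}")
        truth.related_pairs.append((i, j, spec.related_degree))

    # missingness: per-sample and per-marker Bernoulli, independent
    miss = (rng.random(dos.shape) < spec.sample_missing_rate) | \
           (rng.random(dos.shape) < spec.marker_missing_rate)
    dos = np.where(miss, MISSING, dos).astype(np.int8)

    markers = _marker_table(chrom, bp, freq, rng)
    truth.hwe_violators = [markers.marker_ids[j] for j in sorted(viol)]

    # gene intervals covering ~gene_fraction of markers: put an interval
    # around each designated marker
    n_gene = int(round(spec.gene_fraction * spec.n_markers))
    gene_idx = rng.choice(spec.n_markers, size=n_gene, replace=False)
    per_chrom: dict[int, list[tuple[int, int]]] = {}
    for j in sorted(gene_idx):
        c = int(markers.chrom[j])
        pos0 = int(markers.bp[j]) - 1
        half = int(rng.integers(500, 20_000))
        per_chrom.setdefault(c, []).append((max(0, pos0 - half), pos0 + half + 1))
    genes = IntervalSet({c: np.array(v, dtype=np.int64) for c, v in per_chrom.items()})
    truth.gene_markers = sorted(
        markers.marker_ids[j]
        for j in range(spec.n_markers)
        if genes.contains(int(markers.chrom[j]), [int(markers.bp[j])])[0]
    )

    g = GenotypeMatrix([f"S{i:05d}" for i in range(spec.n_samples)], dos)
    return g, markers, genes, truth


def synthetic_genetic_map(rate_cm_per_mb: float = 1.2, anchor_step_bp: int = 1_000_000,
                          seed: int | None = None):
    """A genome-wide genetic map with anchors every ``anchor_step_bp``.

    The local recombination rate is constant at ``rate_cm_per_mb`` unless a
    seed is given, in which case anchor-to-anchor rates are jittered with a
    lognormal factor to mimic rate heterogeneity.
    """
    from .io_formats import GeneticMapTrack

    rng = np.random.default_rng(seed) if seed is not None else None
    anchors = {}
    for c, length in CHROM_LENGTHS_BP.items():
        bp = np.arange(0, length + anchor_step_bp, anchor_step_bp, dtype=np.int64)
        rates = np.full(len(bp) - 1, rate_cm_per_mb)
        if rng is not None:
            rates = rates * rng.lognormal(0.0, 0.3, size=len(rates))
        cm = np.concatenate([[0.0], np.cumsum(rates * anchor_step_bp / 1e6)])
        anchors[c] = (bp, cm)
    return GeneticMapTrack(anchors)


def synthetic_panel(n_markers: int = 200, freq_low: float = 0.49,
                    freq_high: float = 0.5, min_spacing_bp: int = 10_000_000,
                    seed: int = 0) -> MarkerTable:
    """A spaced high-MAF candidate panel like the selection pipeline's output.

    Markers are laid out round-robin across the autosomes at strictly more
    than ``min_spacing_bp`` apart on a chromosome, with minor-allele
    frequencies drawn uniformly from [freq_low, freq_high] and cM positions
    from the default synthetic genetic map.
    """
    rng = np.random.default_rng(seed)
    slots: list[tuple[int, int]] = []
    offsets = {c: int(rng.integers(1, 5_000_000)) for c in CHROM_LENGTHS_BP}
    chroms = sorted(CHROM_LENGTHS_BP)
    while len(slots) < n_markers:
        progressed = False
        for c in chroms:
            pos = offsets[c]
            if pos <= CHROM_LENGTHS_BP[c]:
                slots.append((c, pos))
                offsets[c] = pos + min_spacing_bp + int(rng.integers(1, 4_000_000))
                progressed = True
                if len(slots) == n_markers:
                    break
        if not progressed:
            raise ValueError("genome exhausted before placing all markers")
    slots.sort()
    chrom = np.array([c for c, _ in slots])
    bp = np.array([b for _, b in slots], dtype=np.int64)
    freq = rng.uniform(freq_low, freq_high, size=n_markers)
    table = _marker_table(chrom, bp, freq, rng)
    from .io_formats import assign_cm

    return assign_cm(table, synthetic_genetic_map())


def generate_family_cohort(panel: MarkerTable, n_families: int, seed: int = 0,
                           linkage_enabled: bool = False,
                           ) -> tuple[GenotypeMatrix, list[tuple[str, str, str]]]:
    """Family-cohort stand-in: genotypes for all members of ``n_families``
    simulated families plus labeled pairs.

    Pair labels: ``parent-child`` (TF-child, mother-child), ``second-degree``
    (AF2-child uncle, AF3-child half sibling) and ``unrelated`` (AF4-child
    plus one cross-family child pair per adjacent family).
    """
    params = SimParams(n_families=n_families, seed=seed,
                       linkage_enabled=linkage_enabled)
    batch = simulate_families(panel, params)
    sample_ids = []
    rows = []
    for member in MEMBERS:
        geno = batch.genotypes(member)
        for i in range(n_families):
            sample_ids.append(f"fam{i:05d}_{member}")
            rows.append(geno[i])
    g = GenotypeMatrix(sample_ids, np.array(rows, dtype=np.int8))
    pairs: list[tuple[str, str, str]] = []
    for i in range(n_families):
        fam = f"fam{i:05d}"
        pairs.append((f"{fam}_tf", f"{fam}_child", "parent-child"))
        pairs.append((f"{fam}_mother", f"{fam}_child", "parent-child"))
        pairs.append((f"{fam}_af2", f"{fam}_child", "second-degree"))
        pairs.append((f"{fam}_af3", f"{fam}_child", "second-degree"))
        pairs.append((f"{fam}_af4", f"{fam}_child", "unrelated"))
        if i + 1 < n_families:
            pairs.append((f"{fam}_child", f"fam{i + 1:05d}_child", "unrelated"))
    return g, pairs
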