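"""Gene-dropping simulation of the evaluation pedigree.

Each simulated family contains the true father (TF), the mother, their
child, and three alternative alleged fathers: AF2 (full brother of TF,
a second-degree relative of the child), AF3 (child of TF by a second,
unrelated woman — the child's paternal half sibling, also second degree),
and AF4 (a random unrelated man).

Founder haplotypes are drawn at linkage equilibrium from the panel's
minor-allele frequencies. Transmission groups markers into clusters of
consecutive loci closer than a cM threshold: within a cluster alleles are
passed en bloc (no recombination); between consecutive clusters a
recombination occurs with the Haldane probability
r = (1 - exp(-2 d / 100)) / 2 for inter-cluster distance d cM. With
linkage disabled every locus segregates with an independent fair coin.

All members of all families are simulated in vectorized batches; the
per-family view objects index into the batch arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .io_formats import MarkerTable

MEMBERS = ("tf", "mother", "child", "af2", "af3", "af4")


@dataclass(frozen=True)
class SimParams:
    """Simulation settings: number of families, locus-clustering threshold in
    cM, RNG seed, and whether linkage (recombination model) is on."""

    n_families: int = 10_000
    cluster_cm: float = 25.0
    seed: int = 0
    linkage_enabled: bool = True

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if self.cluster_cm < 0:
            raise ValueError("cluster_cm must be >= 0")


@dataclass
class SimulatedFamily:
    """Genotypes (dosage vectors over the panel) for one family's six named
    members, plus the latent haplotypes they were built from."""

    index: int
    genotypes: dict[str, np.ndarray]
    haplotypes: dict[str, np.ndarray]  # member -> (2, n_markers) 0/1 alleles

    def __getattr__(self, name: str) -> np.ndarray:
        try:
            return self.genotypes[name]
        except KeyError:
            raise AttributeError(name) from None


@dataclass
class FamilyBatch:
    """Vectorized container of ``n_families`` simulated families.

    ``haplotypes[member]`` has shape (n_families, 2, n_markers);
    ``genotypes(member)`` returns the (n_families, n_markers) dosage array.
    """

    markers: MarkerTable
    haplotypes: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_families(self) -> int:
        return next(iter(self.haplotypes.values())).shape[0]

    def genotypes(self, member: str) -> np.ndarray:
        return self.haplotypes[member].sum(axis=1, dtype=np.int8)

    def __iter__(self) -> Iterator[SimulatedFamily]:
        geno = {m: self.genotypes(m) for m in MEMBERS}
        for i in range(self.n_families):
            yield SimulatedFamily(
                index=i,
                genotypes={m: geno[m][i] for m in MEMBERS},
                haplotypes={m: self.haplotypes[m][i] for m in MEMBERS},
            )


def founder_haplotypes(markers: MarkerTable, rng: np.random.Generator,
                       n: int = 1) -> np.ndarray:
    """Draw ``n`` founders' haplotype pairs, shape (n, 2, n_markers).

    Each haplotype allele is an independent Bernoulli(freq_minor) draw, i.e.
    founders are at Hardy-Weinberg and linkage equilibrium.
    """
    p = markers.freq_minor
    if np.isnan(p).any():
        raise ValueError("freq_minor unset for some markers")
    return (rng.random((n, 2, len(markers))) < p[None, None, :]).astype(np.int8)


def cluster_loci(markers: MarkerTable, cluster_cm: float) -> list[np.ndarray]:
    """Chain-cluster the panel: consecutive same-chromosome markers closer
    than ``cluster_cm`` join one cluster. Clusters are contiguous index
    ranges partitioning the panel."""
    cm = markers.cm
    if np.isnan(cm).any():
        raise ValueError("cM positions unset; assign a genetic map first")
    chrom = markers.chrom
    clusters: list[np.ndarray] = []
    current = [0]
    for j in range(1, len(markers)):
        same = chrom[j] == chrom[j - 1]
        if same and (cm[j] - cm[j - 1]) < cluster_cm:
            current.append(j)
        else:
            clusters.append(np.array(current, dtype=np.intp))
            current = [j]
    if current:
        clusters.append(np.array(current, dtype=np.intp))
    return clusters


def haldane_r(d_cm: np.ndarray) -> np.ndarray:
    """Haldane map function: recombination fraction for distance d in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def transmit(parent_haps: np.ndarray, markers: MarkerTable,
             clusters: list[np.ndarray] | None, rng: np.random.Generator,
             linkage_enabled: bool = True) -> np.ndarray:
    """Simulate one gamete per parent from (n, 2, n_markers) haplotype pairs.

    Returns an (n, n_markers) array of transmitted alleles. With linkage on,
    the grand-parental origin switches between consecutive clusters with the
    Haldane probability for the inter-cluster cM gap (gap measured between
    the adjacent boundary markers); each chromosome starts with a fair coin.
    With linkage off, each locus gets an independent fair coin.
    """
    n, _, n_m = parent_haps.shape
    if not linkage_enabled:
        pick = rng.integers(0, 2, size=(n, n_m))
    else:
        if clusters is None:
            clusters = cluster_loci(markers, 0.0)
        cm = markers.cm
        chrom = markers.chrom
        pick = np.empty((n, n_m), dtype=np.int64)
        state = None
        prev_chrom = None
        prev_last = None
        for cl in clusters:
            first, last = cl[0], cl[-1]
            if prev_chrom is None or chrom[first] != prev_chrom:
                state = rng.integers(0, 2, size=n)
            else:
                r = haldane_r(cm[first] - cm[prev_last])
                flip = rng.random(n) < r
                state = np.where(flip, 1 - state, state)
            pick[:, cl] = state[:, None]
            prev_chrom, prev_last = chrom[first], last
    return np.take_along_axis(parent_haps, pick[:, None, :], axis=1)[:, 0, :]


def _mate(father: np.ndarray, mother: np.ndarray, markers: MarkerTable,
          clusters, rng, linkage: bool) -> np.ndarray:
    pat = transmit(father, markers, clusters, rng, linkage)
    mat = transmit(mother, markers, clusters, rng, linkage)
    return np.stack([pat, mat], axis=1)


def simulate_families(markers: MarkerTable, params: SimParams) -> FamilyBatch:
    """Gene-drop ``params.n_families`` families over the marker panel.

    Founders are TF's two parents, the mother, AF3's mother, and AF4;
    TF and AF2 are full siblings; the child is TF x mother; AF3 is
    TF x AF3's mother. Reproducible bit-for-bit under a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    clusters = cluster_loci(markers, params.cluster_cm) if params.linkage_enabled else None
    n = params.n_families
    gf = founder_haplotypes(markers, rng, n)       # TF's father
    gm = founder_haplotypes(markers, rng, n)       # TF's mother
    mother = founder_haplotypes(markers, rng, n)
    w2 = founder_haplotypes(markers, rng, n)       # AF3's mother
    af4 = founder_haplotypes(markers, rng, n)
    link = params.linkage_enabled
    tf = _mate(gf, gm, markers, clusters, rng, link)
    af2 = _mate(gf, gm, markers, clusters, rng, link)
    child = _mate(tf, mother, markers, clusters, rng, link)
    af3 = _mate(tf, w2, markers, clusters, rng, link)
    return FamilyBatch(markers, {
        "tf": tf, "mother": mother, "child": child,
        "af2": af2, "af3": af3, "af4": af4,
    })
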