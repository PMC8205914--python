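# Methods

## Scope and data model

`duosnp` implements a complete panel-design-and-validation workflow for duo
paternity testing on bi-allelic autosomal SNPs. Genotypes are minor-allele
dosage codes 0/1/2 with a `-1` missing sentinel in a samples × markers
matrix; marker metadata (autosome 1–22, 1-based bp, alleles, cumulative cM,
folded minor-allele frequency ≤ 0.5) lives in a `MarkerTable`. Readers
exist for PLINK-style PED/MAP text, VCF (GT field, via pysam) and a
transposed dosage TSV; gene regions are BED intervals (0-based half-open —
a 1-based marker at bp *b* is inside [s, e) iff s ≤ b−1 < e), and genetic
maps are 1000G-style (position, rate, cumulative cM) tables. Dosages are
re-oriented on read so codes always count the empirically minor allele; at
an exact 0.5 frequency the orientation is a documented tie-break, so
round-trip identity is only guaranteed off the tie.

## Statistics

* **Hardy–Weinberg exact test**: conditional on the observed allele counts,
  the probability of every compatible heterozygote count is enumerated (log
  factorials for numerical range) and the two-sided p-value sums
  configurations no more probable than the observed one. No mid-p
  correction; monomorphic markers give p = 1. The implementation is checked
  against an exact-rational enumeration for all configurations with ≤ 20
  genotypes and against null super-uniformity by simulation.
* **Kinship**: the KING-robust between-family estimator
  φ = (N_het,het − 2·N_opp-hom) / (N_het(i) + N_het(j)), computed per pair
  on loci called in both samples (all-pairs form uses masked matrix
  products). The pruning cutoff 0.0884 is the conventional second/
  third-degree boundary: parent–child pairs sit near 0.25, second-degree
  near 0.125.
* **F_ST**: the Weir–Cockerham (1984) two-population estimator per marker
  (a/(a+b+c) with the r = 2 sample-size correction); slightly negative
  values are expected at null differentiation.
* **LD r²**: composite genotypic r² — squared Pearson correlation of
  dosages on pairwise-complete samples. Unphased composite r² is the
  standard choice when haplotypes are not estimated; the windowed form used
  by the pruner computes the identical quantity with masked matrix algebra.
* **Opposite homozygosity**: the count of loci where the pair carries
  different homozygous genotypes. Its per-locus expectation is
  2p²q² · IBD0, which at p = ½ gives 20/160 loci for unrelated pairs,
  10 for second-degree and 5 for full siblings — all verified by
  simulation within Monte-Carlo error.

## Selection pipeline

Stages run in a fixed order (gene-region exclusion → sample missingness
> 0.05 → marker missingness > 0.01 → HWE p < 10⁻⁵ → kinship pruning →
F_ST screen → LD pruning → MAF/spacing selection), each appending
(removed, remaining) counts to an audit; the pipeline uses no randomness.
Where the procedure is under-determined, the tie-breaks are fixed choices:

* kinship pruning greedily removes the sample with the most over-threshold
  partners (ties → smaller index) until no pair reaches the cutoff;
* LD pruning slides a 500-marker window by 50; within a window the worse
  member (lower MAF, ties → larger bp) of the worst-r² pair is removed
  until no within-window pair exceeds r² = 0.01. The guarantee is
  window-local: arbitrary cross-window pairs can still show sampling-noise
  r² above 0.01, and at a few hundred samples the 0.01 threshold sits near
  the noise floor (E[r²] ≈ 1/n under independence), so desk-scale runs
  prune a large fraction of genuinely independent markers — consistent
  with how aggressive an r² < 0.01 screen is in practice;
* candidate selection visits markers by descending MAF (ties → smaller
  chromosome, then bp) and accepts a marker iff it is **strictly** more
  than 10 Mbp from every accepted marker on its chromosome; spacing is
  enforced during selection, not after. Sweep subsets (`panel_subset`) are
  nested MAF-ranked prefixes, so the 70-marker panel is contained in the
  80-marker panel, and so on.
* the F_ST screen is a real filter (≥ 0.01 removed) even though a
  homogeneous cohort rarely triggers it, so the stage stays testable.

## Pedigree simulation

Each simulated family contains the true father (TF), the mother, their
child, the TF's full brother (AF2), the TF's child by a second unrelated
woman (AF3) and an unrelated man (AF4). AF2 and AF3 are both second-degree
relatives of the child (uncle and paternal half-sibling); this structure is
what makes their expected mismatch count 160·(½)·(⅛) = 10 at p = ½, and a
full-sibling alternative (expectation 5) is inconsistent with that target,
which is why AF3's mother is modelled as unrelated to the child's mother.

Founders draw each haplotype allele independently as Bernoulli(freq_minor):
Hardy–Weinberg **and linkage equilibrium**. Transmission clusters
consecutive same-chromosome loci closer than 25 cM; within a cluster a
gamete copies one grand-parental haplotype en bloc, and between consecutive
clusters the copied haplotype switches with the Haldane probability
r = ½(1 − e^(−2d/100)) for the boundary-to-boundary distance d in cM (no
interference; each chromosome starts with a fair coin). With
`linkage_enabled=False` every locus segregates with an independent fair
coin. Haplotype frequencies within clusters are products of allele
frequencies — defensible for a panel pruned to r² < 0.01. There is no
mutation or genotyping-error model, so a true parent–child pair can never
show an opposite-homozygote locus.

Because founders are at linkage equilibrium, the per-locus *marginal*
distributions — and therefore the false-negative rate of a true duo —
are identical with linkage on or off (the true father's transmission
indicator is irrelevant wherever he is homozygous). What linkage does
change is the *joint* IBD pattern of relative pairs: clustered loci share
transmission indicators, which correlates exclusion events for AF2/AF3 and
inflates their false-inclusion rate under an independence-scoring LR
(measured: ≈ 8× at 160 markers). The matching correction belongs to a
linked-marker pedigree likelihood (Lander–Green/Elston–Stewart), which is
deliberately out of scope; the evaluation that pairs the independent-
product LR with independent transmission is the internally consistent
configuration and is what the acceptance surface and the sweep defaults in
the examples use. The `linkage_enabled` switch exists precisely so users
can measure this discrepancy.

## Likelihood ratios and the sweep

`duo_pi` is computed from first principles (enumerate the transmitted
allele × the HWE mate allele) and satisfies, exactly, the unit-expectation
identity Σ_child Pr(child|HWE)·PI = 1 for every father genotype and
p ∈ (0, 1). The combined log₁₀LR is the sum over markers; a single PI = 0
forces log₁₀LR = −∞ (LR exactly 0) — exclusion is absolute. The decision
threshold log₁₀LR ≥ 5 is inclusive. `pair_test` is sex-agnostic: the duo
PI table is symmetric in which member is treated as the alleged parent, so
maternity testing is the same computation.

The sweep tests, for each panel size n ∈ {70, …, 200}, the four
alleged-father duos of every family. Denominators are fixed by the
arithmetic identity accuracy = 100 − (3·FP + FN)/4: FN over the n_families
true-father pairs, FP over the 3·n_families non-father pairs, accuracy over
all pairs; the identity holds exactly for every sweep row. At MAF ½ the
false-negative rate has the closed form P(K ≤ k*−1), K ~ Binomial(n, ¼),
k* = ⌈5/log₁₀2⌉ = 17 (`analytic_fn_rate`), which the simulated column
must match within three Monte-Carlo standard errors. The expected number
of false inclusions at 160 markers is 30 000·(15/16)^160 ≈ 1, so a single
sweep realisation shows 0–3 false inclusions; "perfect separation" at
160 markers is a statement about this Poisson scale, not a deterministic
guarantee under independence scoring.

## Synthetic data

`generate_cohort` emulates a genotyping-array cohort: default 500 samples ×
2,000 markers, MAF ~ Uniform(0.01, 0.5) (so a high-MAF candidate band
arises from selection rather than construction), markers placed uniformly
over hg19 autosome lengths, 0.2% missingness per axis, 30% of markers
inside generated gene intervals, 5 excess-homozygosity markers
(inbreeding-style F = 0.5, planted at MAF ≥ 0.2 where the exact test has
power at the 10⁻⁵ level), 3 cryptic parent–child pairs, and two equal
subpopulation labels with zero true divergence (divergence is
configurable to exercise the F_ST screen). `generate_family_cohort` wraps
the pedigree simulator and emits labeled parent-child / second-degree /
unrelated pairs. The synthetic genetic map uses a constant 1.2 cM/Mb
baseline (≈ 3,460 cM autosomal total) with optional lognormal rate jitter.

What the generators do **not** emulate: array batch effects, probe-level
error, population admixture and cryptic structure beyond two labels,
realistic LD (markers are generated independent, so the LD pruner's power
is exercised only by planted duplicates and sampling noise), and mutation.
Passing tests therefore demonstrate correctness of the statistical
machinery under its stated assumptions, not robustness to real-array
artifacts.

## Problem sizes and numerics

Simulation studies run at 10,000 families × 200 markers (vectorized over
families; a full sweep takes seconds), cohort tests at a few hundred
samples × a few thousand markers. The HWE test normalises log-probabilities
by their maximum before exponentiating; p-value comparison uses a 1+10⁻¹²
relative guard so exactly-tied configurations are included. LR products are
accumulated in log space. All generators and simulations take explicit
integer seeds (numpy `default_rng`); fixed seeds give bit-identical output.

## Known limitations

* Duo/trio hypotheses only (parent–child vs unrelated); no other kinship
  LRs, silent alleles, drop-out or mutation-aware PI.
* No linked-marker likelihood; see the linkage discussion above.
* No binary PLINK BED input, no multi-allelic sites, no build liftover.
* The gene list, genetic map and cohort are synthetic stand-ins; results
  on real panels require supplying the corresponding real files.
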