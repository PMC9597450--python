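# Methods

## Scope and data model

The package analyses three kinds of input: binary band matrices from
dominant marker assays (ISSR and SCoT primers) and SDS-PAGE protein
profiles; per-chromosome arm-length tables; and an optional population
map assigning individual columns to populations. Cells of a band matrix
are strictly 0/1 — only clear, reproducible bands are scored in this kind
of work, so no missing-data state is modelled. Band identity is
(assay id, band id), with the fragment size carried per record; the
writer sorts by assay then descending size so output is deterministic.

## Band classes and accounting

A band present in every genotype is monomorphic (MB); present in exactly
one genotype it is a positive unique band, absent from exactly one a
negative unique band (UB counts both); every other segregating pattern is
plain polymorphic. Unique bands are a subset of the polymorphic bands,
so MB + PB = TAB and UB ≤ PB for every assay — these identities are
enforced by the `PrimerSummary` constructor and property-tested against
an exhaustive truth table for all presence patterns up to 8 genotypes.
With two genotypes the single-presence pattern is classed positive
unique (precedence over negative unique). Bands present in no genotype
are legal in synthetic data but are never "scored": they are excluded
from TAB and all indices.

Two unique-band accountings exist in this literature: per-assay UB
columns and a per-genotype specific-marker catalogue. Both are emitted
(`summarize_assay` and `unique_band_catalogue`); in the source study the
published figure-level totals (84/104 specific markers) cannot be
reconciled with the published table UB totals (62/76), so the package
reports the table-consistent accounting and leaves the discrepancy to
the user. Likewise the SCoT narrative ("214 polymorphic and 76
monomorphic of 275") conflicts with the printed table (MB total 61); the
tables, whose rows satisfy MB + PB = TAB, are treated as authoritative.

## Informativeness indices

P% = 100·PB/TAB; EMR = PB·(PB/TAB); MI = PIC·EMR (with unrounded PIC);
Rp = Σ_b (1 − 2|0.5 − f_b|), where f_b is the fraction of genotypes
carrying band b (genotype fraction, not a per-lane replicate fraction).

PIC has no unique dominant-marker definition. The per-band form
2f(1−f) is capped at 0.5, yet published assay-level PICs for multi-band
dominant systems reach 0.92 — consistent only with a banding-*phenotype*
formula. The default mode therefore treats each genotype's multilocus
pattern for an assay as one phenotype class and returns 1 − Σⱼ pⱼ²
(maximum 1 − 1/n for n genotypes); `per_band_mean` mode is available by
configuration, and MI always uses the active mode.

Report tables carry both polymorphism conventions: the Average row is
the arithmetic mean of per-assay P% and the Total row the pooled
100·ΣPB/ΣTAB. Rounding (2 dp) is display-only; all downstream
computation uses full precision.

## Population genetics for dominant data

Dominant bands cannot separate heterozygotes from dominant homozygotes,
so allele frequencies are back-calculated assuming Hardy–Weinberg
proportions: q = √(1−f), p = 1 − q. Per locus: Na = number of alleles
with frequency > 0 (1 or 2), Ne = 1/(p²+q²) ∈ [1,2], Shannon
I = −(p ln p + q ln q) with 0·ln 0 ≡ 0 (natural log; maximum ln 2 at
p = q = 0.5, i.e. f = 0.75), He = 2pq ∈ [0, 0.5], and
uHe = [2N/(2N−1)]·He with N the number of individuals in the population,
per the standard small-sample correction. Population summaries are
plain means over *all* loci — fixed loci contribute Na = 1, Ne = 1,
He = 0 rather than being dropped, matching the GenAlEx binary-data
convention. P% per population counts loci with 0 < f < 1.

A population must contain several individuals for these statistics to be
non-degenerate; the source study reports per-genotype diversity without
stating how many individuals were scored per genotype, so its Table-6
values can be reproduced structurally but not numerically. The
synthetic study data therefore expands each genotype into 10 replicate
individuals with a 10% per-cell band-flip rate — chosen once as giving
within-genotype heterozygosity of the magnitude reported for small
landrace panels (He ≈ 0.2) — and the population map groups replicates by
genotype.

## Karyotype indices

Per chromosome (arms normalised so l ≥ s on input): CL = s + l, arm
ratio r = l/s (∞ for telocentrics), centromeric index ci = s/CL, M value
(l−s)/CL. Centromere classes use Levan-style arm-ratio bands — nm for
r < 1.7, nsm(−) for 1.7 ≤ r < 3, nst for 3 ≤ r < 7, nt for r ≥ 7 — the
source nomenclature names the "nearly" classes without printing cut
points, so the classical bands are the default and the thresholds are
configurable. The karyotype formula doubles the haploid class tallies
(classes in the fixed order nsm(−), nst, nm, nt); the "(−)" token is
reproduced as part of the class label with no further semantics.

Per karyotype: HCL = ΣCL; TF% = 100·Σs/ΣCL and AsK% = 100·Σl/ΣCL
(complementary by construction); S% = 100·min CL/max CL (Arano's
symmetry — the study never defines its S% column, and a length-ratio
index is the only reading consistent with its 28–51 range); CI = mean
ci (a pooled Σs/ΣCL would duplicate TF%/100); A = mean M and MCA = 100A;
CVcl and CVci as 100·sd/mean with the sample (n−1) sd by default
(switchable, since the measurement software's convention is unstated);
A1 = 1 − mean(s/l) (telocentrics contribute 0 to the mean); A2 =
CVcl/100; AI = CVcl·CVci/100. The published AI column (139–345) is
inconsistent with that product given the published CVs, so AI is
computed and reported but not treated as reproducible. Stebbins
categories: column A/B/C for largest/smallest CL ratio < 2 / < 4 / ≥ 4;
row 1–4 for the proportion of chromosomes with arm ratio > 2 equal to
0 / ≤ 0.5 / < 1 / = 1, telocentrics counting as ratio > 2.

Identities TF% + AsK% = 100, MCA = 100·A and A2 = CVcl/100 hold exactly
before rounding and are asserted over 1,000 random karyotypes; scale and
permutation invariance of all summary indices are property-tested.
Ideogram tables place 0 at the short-arm telomere, the centromere at s
and the end at CL, default order descending CL; a minimal deterministic
SVG renderer is included.

## Synthetic data generators

`generate_band_matrix` realises per-assay counts (MB, positive/negative
UB, other-polymorphic) exactly: monomorphic bands are all-ones rows,
unique bands place their single presence/absence in a seeded random
genotype, and other-polymorphic bands draw a presence count uniformly
from 2..n−2 so they can never collide with the monomorphic, unique or
absent classes. Fragment sizes are drawn without replacement from the
assay's size range (they carry no statistical role). Negative uniques
need ≥ 3 genotypes, other-polymorphic bands ≥ 4; infeasible
specifications raise before any generation. `summarize(generate(spec))
= spec` is property-tested over random feasible specifications.

`generate_karyotype` offers three constructive targets: (a) TF% mode
gives every chromosome the target short-arm fraction, so the pooled TF%
is exact; (b) M mode gives every chromosome the target (l−s)/(l+s), so
A and MCA are exact; (c) CV mode builds a two-point length distribution
— ⌊n/2⌋ chromosomes above the mean and the rest below, offsets solved in
closed form against the sample-sd convention — so CVcl matches to solver
precision (~1e−12). CV mode combines with (a) or (b); on its own it
uses a fixed default arm split (M = 0.15). TF and M modes exclude each
other (both fix the arm split). Lengths without a CV target are
lognormal draws rescaled to the exact total.

What the generators do *not* emulate: within-karyotype variation in
centromere position (modes (a)/(b) make every ci equal, so CVci, AI and
the mixed-class karyotype formulas of real data do not arise), linkage
between bands, size-dependent band intensities, or genotyping error
structure beyond independent Bernoulli flips. Passing tests therefore
demonstrate correctness of the statistics on data matching the published
marginal structure, not biological realism of the joint distribution.

## Clustering

Dice similarity 2a/(2a+b+c) (undefined for two all-zero profiles —
raised as an error); distances are 1 − similarity. UPGMA is the
classical unweighted pair-group method: the merge height is half the
minimal average distance, averages are leaf-pair means maintained by
size-weighted updates, and ties are broken toward the pair whose
lexicographically smallest member label sorts first, making trees
deterministic. Equivalence with an independent average-linkage
implementation is asserted via cophenetic matrices on hundreds of random
distance matrices, and UPGMA provably reconstructs ultrametric inputs.

PCoA double-centres −D²/2 and eigendecomposes; axes are eigenvectors
scaled by √eigenvalue, negative eigenvalues are clamped to zero and
excluded from the explained-variance denominator. Planar point
configurations are recovered to Procrustes residual < 1e−8. The
published ordination of the source study ("PCA" on a Dice similarity
matrix) is implemented as PCoA on the Dice distance, which is the
coherent reading of that input; its printed variance percentages depend
on the unreleased raw matrices and are not reproduction targets, and the
same holds for published cluster memberships.

The combined cyto-molecular feature matrix concatenates the binary band
columns of all marker systems with z-scored karyotype indices
(zero-variance columns dropped with a warning) and is exported together
with UPGMA leaf orders for external heatmap rendering; heatmap drawing
itself is out of scope.

## Problem sizes and numerical choices

The analysis scripts run the full published scale — 233 ISSR and 275
SCoT bands over 6 genotypes, 60 synthetic individuals (10 per genotype),
six 13-chromosome karyotypes — in a few seconds. Property suites use
200 random 6-leaf matrices (UPGMA), 1,000 random karyotypes and 500
random assay specifications. All randomness flows through
`numpy.random.default_rng` seeds recorded in the simulation manifests;
reports round to 2 decimals for display while computations keep full
precision; the pipeline writes nothing until every stage has succeeded,
and its manifest contains no timestamps so reruns are byte-identical.
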