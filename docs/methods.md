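# Methods

This note documents the models, conventions and design choices behind
`hrrscan`, in the order data flows through the pipeline.

## Genotype representation and I/O

Genotypes are 4-state codes per individual and SNP: 0 (homozygous
allele1), 1 (heterozygous), 2 (homozygous allele2), −1 (missing).
Every heterozygosity statistic depends only on whether the two allele
calls differ, so the allele1/allele2 orientation is irrelevant
downstream of input; it matters only when merging datasets whose files
store alleles in opposite order, which `merge_datasets` reconciles by
flipping codes 0↔2 (SNPs whose allele sets cannot be reconciled are
dropped and counted). On PED input, allele1 is the first allele
observed in file order; when both alleles first appear in one
heterozygous field they are assigned lexicographically. This makes
read→write→read a fixed point (bit-identical codes), though a single
write→read of an in-memory matrix may flip orientation at SNPs whose
first-listed sample is homozygous for allele2 — zygosity, the only
thing the analyses consume, is unaffected.

Coordinates are 1-based inclusive bp throughout; interval length is
`end_bp − start_bp`, matching the run-detection convention below.

## Quality control

Filter order is fixed and documented because MAF shifts with sample
removal: (1) drop unmapped and non-autosomal SNPs, (2) drop
individuals with missing fraction > `max_ind_missing` (default 0.20),
(3) drop SNPs with missing fraction > `max_snp_missing` (default
0.05), (4) drop SNPs with MAF < `min_maf` (default 0.05) computed on
the remaining individuals. Breed subsampling (uniform without
replacement, at most 30 per breed by default, seed recorded in the
provenance log) happens *before* QC; with randomized subsampling the
exact post-QC dimensions depend on the seed, which is why count-level
comparisons against published runs of the same data carry a
seed-induced spread. `apply_qc` is idempotent and its report counts
sum exactly to the input−output differences.

## Diversity indices

All frequencies are computed within breed (a pooled variant is behind
the `pooled` flag of `inbreeding`; pooling changes F because the
reference expectation changes). Per SNP, h_obs = n_het/n_called and
h_exp = 2p(1−p); breed H_O/H_E are unweighted means over SNPs with at
least one call. The plain 2pq estimator is used for H_E, while the
finite-sample factor 2n/(2n−1) enters only the expected-homozygosity
term of the inbreeding coefficient,

    F = (O_hom − E_hom) / (L − E_hom),
    E_hom = Σ_snp [1 − 2p(1−p)·2n/(2n−1)],

so F is a relative excess-homozygosity measure while H_E stays
directly comparable across tools. Individuals with L − E_hom ≤ 0 are
excluded from the breed mean. Group averages are unweighted over
breeds.

## Relationships

IBS similarity between two individuals is (2·n_IBS2 + n_IBS1) /
(2·n_pair) over co-called SNPs, with het-vs-het counted as IBS2; with
0/1/2 codes this reduces to 1 − mean(|g_i − g_j|)/2. Classical MDS
double-centers the squared distances and eigendecomposes; explained
variance is each eigenvalue's share of the positive spectrum, and the
theoretically arbitrary axis signs are fixed by making each
component's largest-magnitude loading positive, for reproducible
plots. Reynolds' distance defaults to the sample-size-uncorrected
least-squares coancestry form θ = Σ(p_A−p_B)² / Σ(p_A+p_B−2p_Ap_B)
restricted per pair to loci informative in both breeds; a corrected
variant that subtracts the binomial sampling terms p(1−p)/(2n−1) per
breed is available behind `corrected=True` since distance-software
implementations differ on this point. PHYLIP (10-character sanitized
labels with collision suffixes) and NEXUS distance exports feed
external split-network tools.

## Run detection

Default parameters: minimum 10 SNPs per run, zero missing and zero
opposite genotypes allowed, maximum inter-SNP gap 1 Mb, minimum run
length 250 kb; SW additionally uses 10-SNP windows with zero
missing/opposite allowed, a minimum density of one SNP per 100 kb, and
an in-run score threshold of 0.05 (strictly greater than, not ≥).
`zygosity_mode="homozygous"` turns both scanners into classic ROH
detectors.

CR is a greedy left-to-right scan; with the zero allowances it is
exactly a maximal-substring search (verified against an independent
enumeration oracle in the tests). The `maxMiss`/`maxOpp` counters
exist so the parameter sweep can reproduce published screening ranges;
note that raising `maxOpp` is *not* guaranteed to increase the run
count — an absorbed opposite genotype can merge two qualifying runs
into one — although it does on sparse backgrounds.

SW windows are fully contained 10-SNP blocks: SNPs near chromosome
ends belong to fewer windows, which biases their scores at the
termini. With the default zero allowances and threshold 0.05, the
in-run SNP set is exactly the union of all-heterozygous windows, so CR
and SW coincide except for the SW-only density filter; this is why the
two methods agree exactly on clean inputs and differ by a handful of
sparse runs on real-scale data. Candidate SW runs are split at gaps
> 1 Mb (a flag discards them instead, since run-detection tools are
not explicit about this case); gap splitting is applied before the
count/length filters in both methods.

## Breed statistics

L_HRR is the mean over individuals of each individual's mean run
length (not the pooled-run mean): this weights individuals equally,
consistent with how N and S are defined; zero-run individuals are kept
in N, S and D (contributing 0) and excluded from L only. D_HRR divides
per-individual covered length by the array-spanned autosomal genome,
by default Σ over chromosomes of (last−first SNP bp) from the map —
for a 50k goat panel this is ≈ 2.4–2.5 Gb, and a fixed override (e.g.
2.4e9) is available for comparability with published tables.
Cross-method agreement is the Pearson r of CR vs SW breed means per
parameter, NaN with a warning when a parameter has zero variance.

## Island calling

Incidence uses the full breed size as denominator (individuals without
runs count toward it). z-scores standardize incidence over all SNPs of
a breed/method using the population sd (ddof = 0 — the subsequent
selection is rank-based, so the ddof choice cannot change which SNPs
are selected); p is the upper-tail normal probability (one-sided:
high incidence means island; a two-sided rule would also flag
heterozygosity deserts, which this analysis does not target). The
selection threshold is the k-th smallest empirical p-value with
k = ⌈0.001·M⌉, and *all* SNPs at or below it are kept, so tie groups
can push the selection well past k — with discrete incidence values
(multiples of 1/n per breed) ties are the norm, which is how a "top
0.1%" cut of ~50 SNPs can legitimately return >150 SNPs on real
panels. A consequence worth knowing: if one island's member SNPs sit
at a strictly higher incidence than another's within the same breed,
only the higher tie group survives the cut; recovery guarantees
therefore apply per breed with one dominant island, or islands of
equal incidence.

Candidate regions are maximal stretches of selected SNPs consecutive
on the post-QC map; region frequency is the mean CR incidence of
member SNPs (CR is the reference method; a max-incidence variant is
behind a flag). Regions with ≥ 4 SNPs and frequency ≥ 0.20 survive,
and survivors closer than 1 Mb merge — which is how many passing
fragments can reduce to a few islands. A diagnostic additionally
counts individual-level runs containing at least one selected SNP,
covering the alternative published reading of "in-breed HRR" counts.
Cross-breed merging is transitive on ≥ 1 bp overlap; codes are
assigned per chromosome by descending breed count, ties by start
position.

## Synthetic data

The generator draws SNP positions uniformly per chromosome at a target
spacing (default 50 kb ≈ a 50k array over 2.5 Gb), per-breed per-SNP
allele frequencies from Beta(a, b) (default Beta(0.5, 0.5), the
U-shaped spectrum of ascertained arrays; a fixed p is available for
calibration tests), and genotypes from the inbreeding-adjusted
Hardy–Weinberg law P(het) = 2p(1−p)(1−F) with the +F excess
apportioned to the homozygotes. Missing calls are masked at a flat
rate. Planted islands force carrier individuals (a random
`carrier_fraction` of the breed) to be heterozygous at every member
SNP, unmasked: the analysis needs only the observable signature of
locally elevated heterozygote incidence, not a balancing-selection
dynamic. What the generator deliberately does **not** emulate:
linkage disequilibrium, realistic site-frequency spectra from
demography, chip ascertainment bias, or genotype-calling error
structure — so passing tests demonstrate algorithmic correctness and
calibration under the stated model, not robustness to those real-data
features.

The canned paper-scale fixture (6 breeds × 20 individuals, two 50 Mb
chromosomes, ~2,000 SNPs, F ladder {0, 0.1, 0.4}, three planted
1.5 Mb islands, frozen seed) keeps the default U-shaped prior: its
background heterozygote rate (~0.25 per SNP) makes a 10-SNP chance
run astronomically rare, so planted islands stand on a clean
background and member SNPs tie at exactly the carrier fraction —
the regime in which the ±1-SNP recovery guarantee holds (see the
tie-group caveat above). Island windows are 1.5 Mb (~30 SNPs at 50 kb
spacing) so that a window essentially always contains the ≥ 10 SNPs a
run needs under uniform position placement. Direction checks that
need a *nonzero* background run rate (more inbreeding ⇒ fewer
background runs) use dedicated higher-heterozygosity configurations
(Beta(8, 8)) instead of the fixture.

## Problem sizes and numerical choices

The test suite and the acceptance script run entirely on synthetic
data at the fixture scale (≤ 120 individuals × ~2,000 SNPs, 20
replicate seeds for recovery checks, 100/50 random chromosomes for the
detector-vs-oracle equivalences); these sizes give exact or
tight-tolerance checks in seconds while exercising every code path.
Degenerate inputs are defined rather than left to chance: all-missing
SNPs propagate NaN frequencies; a breed with constant incidence
selects no SNPs (warning); zero-variance parameters yield NaN
correlations (warning); pairs with no co-called SNPs, jointly
monomorphic breed pairs, all-zero distance matrices, and maps with
non-increasing positions raise errors naming the offender. Eigenvalues
below 1e-12 are treated as zero in MDS. The corrected Reynolds
numerator is floored at 0.

## Known limitations

* PED/MAP text only; binary BED is out of scope.
* No LD-aware or phased-haplotype run detection; no F_ROH inbreeding.
* Gene annotation and enrichment are external by design — islands are
  exported as BED for downstream tools.
* The top-0.1%+ties selection is sensitive to incidence tie structure
  (see above): on data with near-continuous incidence values the
  selected set size approaches k, on coarse incidence grids it can be
  several times k.
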