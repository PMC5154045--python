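# Methods

This note documents the models, conventions and numerical choices behind
`ssrchar`, and what the synthetic-data tests do and do not demonstrate.

## Dominant band data and its two kinds of "zero"

All statistics operate on genotypes × per-locus bands with three states:
present (1), absent (0) and failed (NA). Failure is a property of the
whole (genotype, locus) pair — a PCR that produced nothing scorable — and
is enforced to blank every band of that locus for that genotype. The
distinction matters because transferability counts *amplification* while
band statistics count *bands*: a genotype can genuinely lack every scored
band yet amplify, and conflating the two states corrupts both numbers.
Failed genotypes leave the denominator of band frequencies and banding
patterns, and cannot veto a band's privacy.

The missing-data filter drops loci whose failure fraction exceeds a
threshold (default 0.25, configurable; the threshold is a convention, not
an estimate). Filtering is monotone in the threshold.

## SSR detection

A perfect SSR is a maximal periodic interval: positions `i` with
`s[i] == s[i+L]` for a motif length `L` in 1–6, with `N` never matching
(not even `N == N`). The reported locus is the unit-aligned prefix of the
maximal interval, anchored at its leftmost base, with a primitive unit
(a unit that is itself a repetition of a shorter unit belongs to the
shorter length class). Mononucleotide runs are not searched by default;
default minimum repeat counts are di ≥ 6, tri ≥ 4 and tetra/penta/hexa
≥ 3, all configurable — chosen so that every motif class in the packaged
panel's marker table is detectable. Coordinates are 0-based half-open
internally; motif strings (`(GT)8CA(GT)7`) are the human rendering.

Compound merging joins runs separated by at most `max_gap` bases
(default 4, configurable), recording each run and the interruption text.
The defaults are conventions: enrichment-library studies report compound
motifs without stating a join rule.

Motif canonicalization uses the lexicographically minimal rotation only;
reverse-complement folding is opt-in, because repeat-finding tools
conventionally report motifs as observed on the given strand.

An exhaustive brute-force enumerator (`brute_force_ssrs`, quadratic) is
kept in the package as an independent reference; the scanner is tested
against it on hundreds of random sequences, including N-containing ones.

## Primer screening

Screening measures primer length, GC fraction, Tm and product size
against ordered windows; the pair passes iff every criterion passes, so
widening any window is monotone. Tm methods: the Wallace rule
`2(A+T) + 4(G+C)` and the nearest-neighbor thermodynamic model
(Biopython's `Tm_NN` with its default Allawi & SantaLucia table). The
nearest-neighbor default reflects what thermodynamic design software
reports, but exact parity with any particular tool is not promised —
the criteria windows, not the third decimal of Tm, are the contract.

## PIC and DP

`PIC = 1 − Σ pᵢ² − Σᵢ Σ_{j>i} 2 pᵢ² pⱼ²` is evaluated exactly as written
over band frequencies. Two frequency modes exist: `normalized` (presence
counts rescaled to sum to 1; the default, which keeps PIC in [0, 1) and
makes PIC = 0 iff the locus is monomorphic) and `presence` (raw carrier
fractions, which can co-occur and need not sum to 1, letting PIC leave
its usual bounds). The choice is exposed because dominant-marker studies
rarely state it.

`DP = 1 − Σₖ qₖ (N qₖ − 1)/(N − 1)` over the distinct banding patterns of
the N scored genotypes: the probability that two genotypes drawn without
replacement differ. It is 1 iff all patterns are distinct, 0 iff all are
identical, and invariant to pattern relabeling.

A band is private to species *s* iff it is present in at least one
genotype of *s* and zero genotypes of every other species. Private-band
percentages use the full panel locus count as denominator, while panel
means (bands/locus, PIC, DP) are computed over the quality-retained loci
— both denominators are explicit arguments because published summaries
use both conventions. Transferability is likewise reported over all loci
and over the retained subset.

Report rendering rounds to 2 decimals, half-up, at render time only;
all internal math is full precision.

## Structure utilities

**Evanno ΔK.** From a (K, replicate, lnP) table with a contiguous K
range (length ≥ 3) and ≥ 2 replicates per K:
`L′(K) = mean(K) − mean(K−1)`, `L″(K) = L′(K+1) − L′(K)`,
`ΔK = |L″(K)| / sd(K)` with the sample (ddof = 1) standard deviation.
ΔK is defined only for interior K with sd > 0; zero-sd Ks are flagged
undefined and excluded from the argmax, and a flat curve yields no best
K rather than an arbitrary one. The statistic is invariant to adding a
constant to every lnP and to replicate order. The Bayesian MCMC that
produces the lnP values is external; only its numeric output is consumed.

**PCA and K-means + BIC.** The band matrix is 1/0-encoded with failed
cells imputed by the band's panel mean (dropping failing genotypes is
available by flag); principal components come from a full SVD.
`BIC(k) = n ln(W_k/n) + k ln n` with W_k the best-of-restarts within-
cluster sum of squares (k-means++, 20 restarts default, deterministic
given the seed; ties broken toward smaller k). The BIC form is a
standard K-means convention chosen to preserve the "reaches a minimum"
selection behavior, not a likelihood derivation. Because typical
software restricts k ≥ 2, both the unconstrained argmin and the argmin
over k ≥ 2 are reported, and the BIC curve is returned so a user can
override k deliberately (e.g. to compare against a Bayesian clustering
that supported a different number).

A practical point the tests encode: cluster-number selection is run on
the **full** principal-component space. In a low-dimensional truncation
the unmodelled noise variance is concentrated into few axes and splitting
it keeps lowering W_k faster than the `ln n` penalty, biasing the argmin
upward; in the full space the same noise is spread thin and the minimum
lands at the planted k. The single-blob control (BIC(1) ≤ BIC(2))
likewise holds at panel-scale dimensionality, not in toy 2–5-dimensional
data. The discriminant projection, by contrast, needs an invertible
within-scatter and therefore *fewer* components (at most n − k − 1; the
CLI caps at 90 % cumulative variance), mirroring common DAPC usage.

**Discriminant projection.** Fisher axes solve `S_b v = λ S_w v` for the
between- and within-cluster scatter matrices (scipy generalized
symmetric eigensolver), keeping the top k − 1 axes, with each axis' sign
canonicalized so its first nonzero loading is positive. Every cluster
needs ≥ 2 members; a singular S_w raises with the advice to retain fewer
components. The axes agree with scikit-learn's eigen-solver LDA up to
scale and sign (checked in the tests, where sklearn serves as the
independent cross-check, not the implementation).

## Synthetic data

The generator emulates a multi-species germplasm panel scored with
dominant SSR markers. Defaults mirror the packaged study panel: 8
species with genotype counts (26, 3, 4, 6, 3, 1, 3, 2), 25 loci, 2–17
bands per locus. Per locus, a shared presence-frequency vector (uniform
on [0.1, 0.9]) is mixed with species-specific Beta(α, α) draws by a
differentiation scalar d — d = 0 is panmixia, d = 1 fully
species-specific frequencies, and small α pushes frequencies toward
fixed 0/1 differences. Default d = 0.6 and α = 0.5 give a moderately
structured panel; cluster-recovery tests use d = 1, α = 0.2 ("strong
differentiation"). Amplification failure (default 5 %, optionally
species-dependent) is drawn per (genotype, locus) before band draws.
Bands are independent within a locus — no dosage model — with an
optional tetraploid mode mapping a latent allele frequency q to presence
probability 1 − (1 − q)⁴.

Private-band injection appends, with a per-locus rate, one extra band
carried only by one species (within-species frequency 0.8 by default).
If the binomial draw leaves the target species without a carrier, one
genotype is promoted to carrier, so injected bands are always observable
under lossless conditions and recall-1.0 ground truth is exact; the
small upward bias in that band's empirical frequency is accepted.

SSR sequence fixtures are flank + runs/interruptions + flank, with
flanks rejection-sampled until no detected run leaks outside the core.
Truth coordinates are canonicalized to the leftmost-anchored convention,
because an interruption character can legitimately extend a run's
periodic interval one base left and phase-shift its unit.

What the generator does **not** emulate: linkage between bands, allele
dosage and its size ladder structure, scoring error on real gels,
geographic or pedigree structure within species, and inter-species
admixture. Passing the recovery tests therefore shows the algorithms are
correct under the stated model, not that real Plicatula-group panels are
this easy; the published panel itself shows three genetic clusters that
do not coincide with the eight species.

## Packaged fixtures

The raw 48 × 25 band matrix behind the published panel was never
deposited, so per-locus PIC/DP values cannot be recomputed from
genotypes; they are validated at formula level instead (worked examples
and property suites), while the packaged transcriptions of the summary
tables support exact recomputation of the panel-level numbers:
transferability percentages under both locus conventions, private-band
counts/percentages, and the per-locus column means. In the private-band
table the attribution of a few individual cells to species columns is a
consistent reconstruction (the published layout is ambiguous there); all
row multisets and every column summary match the source exactly, and
the acceptance checks consume only those summaries. No raw band matrix
is fabricated.

## Problem sizes

The test suite and the acceptance script use 200 random sequences
(≤ 500 bp) for the finder-vs-oracle comparison, panels of 36–150
genotypes for statistics properties, n = 2000 per species for frequency
convergence (empirical PIC within 0.01 of the truth), and 20 planted
3-species panels of 48 genotypes × 25 loci for cluster recovery — sizes
at which the checked properties are already tight while the whole suite
runs in seconds.
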