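# Methods

This note records the statistical conventions, generator design and numerical
choices behind `allelemap`, at the level of detail a maintainer or reviewer
needs to interpret its output.

## Study design assumed

A panel of a few hundred selfed lines (homozygous, one allele code per locus)
scored at ~100–150 multi-allelic loci with a genetic map, phenotyped for
several correlated quantitative traits in a small number of environments with
replicated plots, and annotated with era-group metadata in which a small
founder (CK) group anchors the transmission analysis.  All analyses treat
lines as haplotypes; heterozygotes are not representable and are rejected at
input.

## Diversity conventions

Frequencies are computed over typed lines only.  Gene diversity is the
uncorrected He = 1 − Σp²; the n/(n−1) bias correction is deliberately not
applied (the convention of the common SSR summary tools), and at panel sizes
of hundreds the difference is below the second decimal.  PIC uses the
Botstein (1980) formula.  "Rare" means frequency strictly below 0.05;
"unique" means carrier count exactly 1, independent of frequency.

## Structure

The number of subpopulations is chosen by the Evanno Δk statistic computed
from replicate log-likelihoods: means enter the second difference, the
replicate standard deviation at k the denominator, and ties break toward
smaller k.  Replicate sd of exactly zero is an error rather than a silent
infinity.  The canonical Q matrix is an imported clustering result; the
built-in `estimate_Q_em` is a multiplicative EM on the haploid admixture
likelihood Σᵢ Σₗ log(Σ_c q_ic f_cl(a_il)) with k-means-seeded initialization,
a 1e−6 frequency pseudocount, and a monotone-likelihood assertion each
iteration.  It is a convenience surrogate, not an MCMC replacement: its
maximized likelihoods are nearly deterministic, so Δk magnitudes computed
from EM replicates have an arbitrary scale (the replicate sd is tiny).  The
Δk *peak position* is still informative, and the synthetic-data tests
therefore also check the k = 1→2 share of the likelihood gain, which is the
curvature Δk keys on without the noise-scale dependence.

For the mixed model, Q enters with k − 1 columns to avoid collinearity with
the intercept.  Structure runs use a map-thinned subset (default one marker
per 20 cM) mirroring the practice of selecting unlinked or weakly linked
markers.

## Kinship

The Loiselle et al. (1995) estimator with panel allele frequencies as
reference, pairwise-complete over loci, negatives truncated to zero.  The
small-sample correction term p(1−p)/(n−1) is off by default (flag to
enable).  Truncation generally destroys positive semidefiniteness, so
`KinshipMatrix.to_psd()` clips negative eigenvalues before REML; the
low-level fit refuses an indefinite K beyond a −1e−8 tolerance rather than
repairing it silently.

## LD

For a locus pair, every allele pair (i, j) is collapsed to a 2×2 table and
r²ᵢⱼ = D²ᵢⱼ / (pᵢ(1−pᵢ)qⱼ(1−qⱼ)); the pair statistic is Σᵢⱼ pᵢqⱼ r²ᵢⱼ (the
weights sum to one).  Rare alleles (<0.05) are masked to missing *before*
frequencies are recomputed, in a single pass.  Significance is a two-sided
Fisher exact test when both loci are biallelic after masking; otherwise a
Monte-Carlo permutation test implemented by sampling contingency tables with
the observed margins (Patefield's algorithm via `scipy.stats.random_table`),
which is exactly the permutation null of shuffling one locus, with p =
(1 + #{r²* ≥ r²}) / (1 + n_perm).  Background LD is the nearest-rank (no
interpolation) 99th percentile of unlinked r².  The decay curve is an
ordinary least-squares fit of r² on ln(d) over linked pairs significant at
P ≤ 0.01; crossing distances d* = exp((t − a)/b) are reported only when the
slope is negative and d* falls within [min observed d, 10 × max observed d],
otherwise NOT_REACHED.

## Phenotypic analysis

Line means are replicate averages per environment; across-environment means
are unweighted means of the available environment means (unbalanced data
tolerated with a warning).  The ANOVA is the balanced two-factor layout with
replicates nested in environments; components come from equating mean
squares to expectations (error; GE = (MS_GE − MS_e)/r; G = (MS_G − MS_GE)/er;
blocks analogous), with negative estimates truncated to zero and flagged, and
near-balanced data analyzed via unweighted cell means with the mean replicate
number.  Genotype is tested against G×E, G×E against error.  Heritability is
the entry-mean form h²_B = σ²_G/(σ²_G + σ²_GE/e + σ²_e/(er)), clipped to
[0, 1].  Trait correlations are pairwise-complete Pearson r with t-test
stars.

## Association model

Per trait × environment the null model y = μ + Qv + u + e, Var(u) = σ²_g K,
is fitted by REML: after one eigendecomposition of K, the profiled REML
log-likelihood is a function of δ = σ²_e/σ²_g alone, scanned on a log₁₀ grid
over [−6, 6] and polished by bounded scalar minimization — deterministic by
construction.  On a flat likelihood (e.g. K = I, where only σ²_g + σ²_e is
identified) the largest δ is taken, attributing the variance to the
residual; marker tests are invariant to this choice because V is then
proportional to the identity.

Markers are tested under P3D: the null variance components are reused for
every marker (exact per-marker REML behind a flag).  A marker enters as a
categorical fixed effect over its allele classes; alleles below frequency
0.05 among complete cases are pooled into an "other" class (`pool`, default)
or their carriers dropped (`drop`).  Lines untyped at a marker leave that
marker's test only, via a Cholesky-whitened GLS on the subset with the same
variance components.  The F statistic compares RSS of the null and marker
models on the whitened scale; marker R² = (RSS₀ − RSS₁)/TSS with TSS taken
about the whitened intercept fit, a convention documented here because
software R² definitions differ.  The Bonferroni line is −log₁₀(α/m), held
unrounded internally.

Stability counts, for each marker × trait, the environments in which a
chosen significance flag holds; "stable" means at least two.  The flag
column is a parameter because published multi-environment tables typically
list associations that pass the family-wise line in *some* environment and
then count per-environment detections at a looser per-test level (0.01);
both readings are supported.

## Allele mining

aᵢ is the carrier mean minus the mean over *all* phenotyped accessions
(missing genotypes leave the carrier set but stay in the panel mean), on
across-environment line means; per-environment effects are available behind
a flag.  Carrier-weighted effects at a locus then sum to zero identically on
complete data, which tests assert.  Favorable means sign(aᵢ) matches the
trait objective — maximize everything except seed index (SI), configurable.
Representative accessions are the top-3 carriers in the objective direction,
ties broken lexicographically by id.  Transmission: class 3 iff founder (CK)
frequency is zero; class 1 iff founder-present and at or above a
high-frequency threshold (default 0.8, chosen to reproduce the canonical
worked trajectories) in every modern group; class 2 otherwise.  No minimum
carrier count is imposed by default (`min_carriers` available).

## Synthetic-data generator

What it emulates: per-subpopulation allele frequencies drawn around a common
ancestral frequency vector with Balding–Nichols concentration
(1 − Fst)/Fst; per-line admixture from a symmetric Dirichlet(α); chromosomes
as mosaics over a small founder-haplotype pool, with segment breaks between
adjacent markers at probability 1 − (1 − r)^g, r from the Haldane map
function, g the generations of mating; alleles lost in the founder
bottleneck re-entering as low-copy variants (1–5 carriers), which produces
the rare- and unique-allele classes of real panels.  Phenotypes are grand
mean + fixed environment offsets + QTL allele effects + a marker-derived
polygenic line effect (hence correlated with kinship) + G×E deviations +
replicate error.

Defaults are sized to the assumed study design: 356 lines, 145 loci on 26
chromosomes, 2–9 alleles per locus skewed so ~80% of loci carry 2–3, two
subpopulations at Fst 0.10 with strong ancestry assortment (α = 0.2), a
6-haplotype founder pool per subpopulation (the few-founder breeding history
that gives germplasm panels their strong short-range LD), 10 generations of
mating, 2% missing calls, and seven yield traits whose grand means, CVs and
entry-mean heritabilities (0.47–0.78 realized) match a multi-location
lint-yield trial; the default QTL architecture places one QTL per trait
(two shared between correlated traits) sized to ~8–12% of line-mean
variance, the upper range of detectable yield QTLs.  With these defaults the
realized panel shows ~3.0 alleles/locus, mean He ≈ 0.32 and PIC ≈ 0.28,
~125 rare and ~70 unique alleles, a single dominant Δk peak at k = 2, linked
mean r² about twice the unlinked mean, a background-LD 99th percentile near
0.07 and decay to background within a few cM.

What it does not emulate: allotetraploid duplicated-locus banding (one locus
is one column), genotyping error, selection during breeding history, real
pedigree structure, and environment-specific G×E covariance.  Two realized
quantities deliberately trade off against each other: a founder pool small
enough to give paper-like short-range LD leaves ~65–70% of kinship pairs
below 0.05 rather than the ~87% a weakly structured real panel can show;
tests of the weak-kinship property therefore use an information-rich,
near-unstructured configuration where the property genuinely holds.  Passing
tests on these panels shows the estimators and the scan behave correctly
under the assumed generative model, not that any particular real panel
satisfies that model.

## Numerical choices and degenerate inputs

Missing calls are 0 internally; allele codes are locus-local labels.
Monomorphic loci carry no kinship or LD information and are skipped with
log entries.  Markers monomorphic among a scan's complete cases are skipped,
not scored.  The EM asserts monotone likelihood to 1e−6 relative tolerance
and stops on a likelihood gain below tol.  REML uses eigenvalue clipping at
zero for K within the −1e−8 PSD tolerance.  Percentiles are nearest-rank.
All simulation randomness flows from a single seed through named
sub-streams, so partial re-runs are reproducible; pipeline configs must name
a seed explicitly.

## Problem sizes in tests and the acceptance script

Simulation-backed checks run at reduced sizes chosen to keep the full suite
in the low minutes while leaving each assertion comfortably powered: the
structure-correction study uses 50 structured-null panels of 150 lines × 100
markers (≈5000 null marker tests), recovery studies use n = 300 with 50
effective replicates, and the shared session panel is 200 lines × 60 loci.
The package-level defaults above remain the full-size study conditions.
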