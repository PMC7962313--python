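# Methods

This note documents the models and procedures implemented in `kmersig`,
the conventions and defaults that matter, what the synthetic generator
does and does not emulate, and the design choices made where the design
was genuinely open.

## k-mer and codon profiles

A genome's k-mer profile is the vector of all 4^k overlapping window
counts (step 1) on the given strand, divided by the total count, so each
profile sums to 1. Windows containing `N` are skipped — no composition is
fabricated for ambiguous positions, and GC content likewise excludes `N`
from numerator and denominator. Features are indexed lexicographically
(A < C < G < T) everywhere, so column identity is stable across matrices,
files and modules.

Counting is single-strand by default; canonical counting (each window
pooled with its reverse complement under the lexicographically smaller
key) is available as a flag. Both behaviours are offered because
composition tools differ on this point and the choice changes the profile
of any non-palindromic word; the default reproduces plain single-strand
counting.

Codon profiles are the 64 non-overlapping in-frame triplet frequencies of
the concatenated coding regions — by construction identical to the
phase-0 3-mer profile of the CDS, which the tests use as a cross-check.

## Coding-region extraction

CDS intervals are 1-based inclusive with strand (GFF3 convention;
internal coordinates are 0-based half-open, converted only at the I/O
boundary). Minus-strand intervals are reverse-complemented before
concatenation; each interval's contribution is trimmed to a whole number
of codons (trailing partial codons dropped with a warning), so the
concatenation is frame-consistent and phases are well defined across gene
boundaries. How joined/partial CDS should be treated is not standardized;
the trim rule is this package's decision. Genomes without CDS annotation
are excluded from coding-region analyses with a logged count.

## Phased Markov model and word exceptionality

The background model for coding DNA is a Markov chain of order *m*
(default 2) whose transition row depends on the codon position ("phase"
0/1/2) of the emitted base: π_φ(a | c) for each phase φ and context c of
length *m*. Fitting is maximum likelihood on phased transition counts of
the concatenated CDS; rows never observed are flagged rather than
imputed. A warning is emitted below ~10·4^(m+1) positions, where rows
become noisy.

A word occurrence takes the phase of its start position. With start
positions p ∈ [0, L−k], the expected count of word w conditions on the
observed phased prefix counts N_φ:

    E(w) = Σ_φ N_φ(w[0:m]) · Π_{j=m..k−1} π̂_{(φ+j) mod 3}(w[j] | w[j−m:j])

The exceptionality score is (O − E)/√V with the Poisson plug-in variance
V = E. This plug-in is unambiguous, cheap, and slightly conservative for
comparative use; the exact conditional Gaussian variance that also
accounts for model estimation is a *reserved* mode
(`variance_mode="conditional"` raises `NotImplementedError`) because its
3-phase formula is not stated in the sources this package draws on and
should not be reinvented ad hoc. Scoring is single-strand.

Degenerate cases are explicit: words whose expectation is 0, or which
require an unobserved transition row from an occurring prefix, get a
*missing* (NaN) score — never a silent 0. Missing scores are imputed as 0
only when assembling the score matrix, with per-genome logging, and a
genome with more than 5% missing words is excluded instead.

Two properties anchor the implementation: on a sequence scored under its
own fitted model, Σ_w E(w) equals the number of start positions exactly
(the chain rule telescopes), so scores are centered near 0; and on a
deterministic periodic sequence every expectation collapses to the
observed count, making all scores exactly 0.

## Multivariate analyses

Distances are plain Euclidean distances between profile rows. Clustering
is Ward.D2 agglomeration (scipy's `ward` linkage on the unsquared
Euclidean distance matrix, which reproduces R `hclust(method="Ward.D2")`
heights); dendrograms export to newick with branch lengths equal to
height differences. PCA runs on centered, scaled data via SVD;
zero-variance columns are dropped with a log entry and component signs are
fixed (largest-magnitude loading positive) so loadings are reproducible.

PLS-DA one-hot encodes the class membership and fits PLS (NIPALS, via
scikit-learn's `PLSRegression`) on centered, scaled data; a sample is
assigned to the argmax of the predicted responses. The number of
components (grid 1–10 by default) is chosen by 10-times-repeated 10-fold
*stratified* cross-validation on accuracy, smallest n on ties;
stratification matters because the niche partitions are imbalanced, and
folds are reduced with a warning when the smallest class is smaller than
the fold count. Features are ranked by VIP (mean of squared VIPs = 1 by
construction), with ties broken lexicographically; loading-based
inspection is available through the returned loadings. Each selected
feature is annotated with the class in which its mean frequency is
higher, producing the "high frequency in X" direction split. Confirmation
tests use the two-sided Mann–Whitney U statistic: exact enumeration of
all group assignments when both groups have ≤8 members (ties handled by
the ½ convention), normal approximation with tie correction otherwise. A
Welch t-test is offered alongside; no multiple-testing correction is
applied by default, matching the raw-p usage of the workflow this
implements (a Benjamini–Hochberg step can be applied downstream by the
user).

## PERMANOVA and commonality

The distance matrix is Gower-centered (G = −½ J A J, A = d², J the
centering projector), so tr(G) is the total sum of squares. Terms enter
sequentially (Type-I): categorical factors as one-hot blocks,
quantitative covariates (GC) as single centered columns; each term's SS
is the increase in tr(H G) as the orthonormal basis of the design
expands, with the rank increase as its df. A term adding no rank (fully
confounded with earlier terms) is dropped with a warning. Pseudo-F is
(SS/df)/(SS_res/df_res); p = (1 + #{F* ≥ F})/(1 + n_perm) under
unrestricted permutation of observations (no strata), 9999 permutations
by default, seeded. Model strings like `"D ~ order*gc"` mean sequential
main-effect entry, not interaction expansion — that is how conditional
percentages are read off such models.

The commonality partition of factors A and B reports unique(A) = R²(A
after B), unique(B) = R²(B after A), and shared = R²(A alone) −
unique(A); the identity shared = R²(B alone) − unique(B) holds to
machine precision and is asserted. Shared variance may be negative
(suppression) and is reported as-is.

On 1-D embeddings the single-factor decomposition reduces to classical
one-way ANOVA; the tests verify R² and F against direct sums of squares
to 1e-9 and against scikit-bio's PERMANOVA as an independent oracle.

## Outlier detection

Within each family of ≥2 elements, the Euclidean distance of each
element's frequency profile to the family's arithmetic-mean profile
(barycenter) is computed; singleton families are excluded (their distance
is 0 by construction). One gamma distribution is fitted by maximum
likelihood (location 0) to the *pooled* distances across families — a
single pooled fit rather than per-family fits, which would starve small
families. Elements strictly above the gamma quantile at the confidence
level (default 0.95) are flagged; flags use strict inequality, documented
for reproducibility. The two-stage practice of systematic flagging
followed by visual curation is represented by manual add/remove override
lists, with every flag's provenance (`systematic`, `manual_add`,
`manual_remove`) recorded in the report. Distances are computed on
frequency profiles (consistent with the dendrogram inputs), not on
standardized ones.

## Gene-sharing network

Edges come from an externally produced pairwise shared-gene-count table
(the upstream all-vs-all protein search is never run here; its parameters
can be attached as provenance metadata). Weights divide the raw count by
the smaller genome of the pair, by default its length in **kilobases**: a
literal bases denominator would make the conventional 0.1 weight filter
unreachable for realistic gene counts, while kb makes it meaningful;
bases and gene-count denominators are provided and the mode is stamped
into every output. Filtering keeps edges with weight ≥ threshold
(strictly lower removed) and keeps isolated nodes. Category statistics
divide the edge count between categories X ≠ Y by |X| + |Y| and within X
by |X| (a `per_pair` variant dividing by |X|·|Y| is also emitted); the
pooled convention is this package's choice of a size normalization.

## Synthetic data generator

The generator's purpose is to produce datasets with the *structure* the
analyses assume, at desk scale:

* **Groups (orders)** get models derived from a common base by
  log-multiplicative jitter of the transition rows (the order-level
  signature) followed by exponential tilting toward G/C, with the tilt
  parameter solved by bisection against the model's exact stationary GC
  (computed from the phase×context chain), so targets are hit to
  ±0.001 rather than ±0.02.
* **Genomes** are emitted as gene blocks (lengths multiples of 3, mean
  900 b) separated by short spacers (24 b), tiling ≈97% of the sequence;
  an option places a fraction of genes on the minus strand to exercise
  strand handling.
* **Mobile elements** are emitted from the normalized geometric blend
  host^w · family^(1−w) of their host-order model and a family model (the
  host model re-perturbed at the family signature magnitude), emulating
  composition shaped jointly by host coevolution and family identity.
* **Planted host transfers** swap the *source* order's model into the
  blend while keeping the target host label, reproducing the signature of
  a recently transferred element. **Planted outliers** are emitted from an
  independently perturbed model at 3× the group magnitude, guaranteeing
  detectability without hand-tuned distances.
* A **synthetic homolog table** gives same-order cell/large-plasmid pairs
  high normalized sharing and small-plasmid/virus pairs low sharing, so
  network category statistics have a known ordering.

Default study conditions (`demo_spec`): four orders with GC 0.62 / 0.36 /
0.45 / 0.29 and niches halophile / extreme thermophile / hyperthermophile
/ mesophile (niche nested in order, as in real archaeal datasets), 8
cells each of 60–80 kb; seven MGE families including megaplasmid
(150–200 kb) and large-plasmid (100–150 kb) classes; one
Thermococcales→Methanococcales plasmid transfer; three 3× outliers.
Genome sizes are two orders of magnitude below real archaeal chromosomes —
a deliberate desk-scale choice; the signature magnitude (0.35) was set so
that between-order profile separation exceeds the within-order sampling
noise (~√(2/L) in Euclidean profile distance) at these lengths.
Reproducibility is exact: all randomness derives from the spec seed
through an ordered seed-sequence spawn, and identical spec+seed yields
byte-identical FASTA/GFF3 output.

**What passing tests do and do not show.** The generator emulates
compositional structure only: there is no real gene content, tRNAs,
amino-acid-level selection, replication biology, horizontal transfer of
genome fragments, or assembly noise. Tests passing on synthetic data
demonstrate that the statistical machinery recovers structure *of the
kind assumed*, with effect sizes in the planted regime — not that real
archaeal datasets have that structure, nor that the effect sizes there
are detectable.

## Numerical choices and degenerate inputs

* Transition rows must sum to 1 within 1e-9; unobserved rows are masked,
  never renormalized from zero.
* Frequency profiles sum to 1 within 1e-9; empty profiles (no valid
  window) are an error at the single-genome level and a logged drop at
  the matrix level (fewer than 2 usable rows is an error).
* PERMANOVA design rank uses an SVD threshold scaled by matrix size;
  permutation p-values use a 1e-12 tie tolerance on F.
* Gamma fitting rejects fewer than 10 positive distances and
  (near-)constant samples; zeros are dropped with a warning.
* PCA on an all-constant matrix, PLS-DA with one class, clustering with
  fewer than 2 observations, words shorter than m+1: all explicit errors.

## Problem sizes in tests and acceptance

Markov recovery and exceptionality null checks run on 500 kb sequences:
at 500 kb the ±0.02 recovery band sits at ≈4.7σ of the estimator's
sampling error (at 200 kb it would sit near 3σ, i.e. at the edge of the
band for the maximum over ~10² entries). Null calibration of the
PERMANOVA permutation test uses 200 runs × 999 permutations at n = 20;
PLS-DA recovery uses 10 replicates of a 40×1024 two-class scenario with
ten planted features. The full synthetic study (71 genomes, ~4 Mb) builds
in under 10 s and is shared across tests as a session fixture.

## Known limitations

* The exceptionality variance is the Poisson plug-in; scores are mildly
  conservative and not exactly unit-variance under the null (the model is
  estimated from the scored sequence itself).
* PERMANOVA provides no interaction terms, strata, or dispersion
  (PERMDISP) diagnostics; significance with heterogeneous dispersion
  should be interpreted with the usual caution.
* Word length is limited to k ≤ 8, and counting is not streamed — inputs
  are whole genomes in memory, not metagenome-scale read sets.
* Newick export encodes topology and heights only (no support values).
* The gene-sharing network consumes an externally computed homolog table;
  nothing validates how that table was produced beyond schema checks.
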