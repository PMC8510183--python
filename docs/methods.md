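# Methods

## The problem being modelled

A biospecimen's inferred microbiome depends on how the specimen was stored
before DNA isolation.  The package models a factorial storage experiment on
fecal/sewage-like communities: storage temperature (−80, −20, 5, 22 °C) ×
storage time (0, 16, 64 h) × technical triplicates, for four sample matrices
(P1, P2, S1, S2), each analyzed unspiked and spiked with a defined 8-member
mock community, plus a freeze-thaw-cycle subexperiment (2–4 cycles at the
two frozen temperatures, matrices P1 and S1 only).  All analyses treat
spiked and unspiked sets separately.

## Synthetic generator

**Baselines.**  Genus log-abundances are the sum of a community core shared
by all matrices (SD 2.0), a sample-type component (pig vs sewage, SD 1.0)
and a matrix component (SD 0.8), exponentiated and closed.  This makes the
four matrices mutually distinct while the two pig samples resemble each
other more than they resemble sewage, which is what drives the
"samples cluster by origin" outcome downstream.  Eukaryotic genera are
down-weighted by 3 log2 units (they are a minor fraction of such
communities).  The six bacterial mock genera plus the two eukaryotic ones
exist natively in every baseline, so spike correction has a real background
to remove.

**Storage effects.**  For a sample stored at temperature T for t hours,

log2 a(taxon) = log2 a₀ + effect(T, phylum)·(t/64) + ft_slope(phylum)·cycles
+ δ(taxon),

then re-closed.  Hours map linearly onto [0, 1] over the 0–64 h span (the
functional form of the drift is not identified by triplicate endpoints; a
linear gradient is the simplest shape consistent with time-ordered drift).
Default effects over the full span: at 22 °C Firmicutes +1.2, Actinobacteria
+1.0, Bacteroidetes −1.2, Proteobacteria −1.0; at 5 °C half of that; both
frozen temperatures share one sign-flipped vector (−0.7/−0.6/+0.7/+0.6) —
frozen samples behave alike, warm storage moves farthest.  These magnitudes
are calibrated only to the qualitative ordering (largest drift at 22 °C /
64 h, frozen conditions mutually similar, 5 °C / 16 h closest to baseline);
no quantitative fold-change estimates exist to pin them down.  Freeze-thaw
slopes (+0.5 per cycle for eukaryotes, +0.3 for Firmicutes/Actinobacteria,
−0.3 for Bacteroidetes/Proteobacteria) encode preferential lysis of
rigid-walled cells.  Taxon-level deviations δ ~ N(0, 0.2²) are drawn once
per matrix × temperature class, so replicates share expected profiles.

**Noise.**  Counts are gamma-Poisson: K ~ Poisson(Gamma(1/α, μα)) with
α = 0.05 per taxon, matching the downstream differential-abundance model;
dispersion 0 degenerates to Poisson.  Library sizes are lognormal around
2 × 10⁵ fragments (SD 0.3 on the log scale) — a desk-scale stand-in for
millions of reads; noise is applied exactly once, to the combined
native + spike mean.

**Mock community.**  Eight members spanning five bacterial phyla and two
eukaryotes.  Cell loads: 10⁹ cells/mg Gram-positive (5 × 10⁸ for P1),
10⁸ Gram-negative, 2 × 10⁷ yeast, 2 × 10⁶ Cryptosporidium.  Expected read
contribution ∝ cells × genome size × extraction efficiency (Gram-negative
1.0, Gram-positive 0.3, eukaryote 0.1 — mimicking higher DNA recovery from
Gram-negative cells), scaled to a spike fraction of 5 % of the native
library.  The planted contribution per member per sample is recorded in the
ground truth.

**Resistome.**  Each AMR gene is assigned a host genus
(abundance-weighted among bacterial taxa), a drug class drawn from a
host-phylum-specific preference table, a length (0.5–3 kb) and a lognormal
copy factor; gene mean = host count × copy factor × length(kb), with the
same gamma-Poisson noise.  The resistome therefore co-varies with taxonomy
by construction, which is what the Procrustes stage is expected to detect.

**What the generator does not emulate.**  Read-level artifacts (mapping
bias, contig-hit inflation), DNA-extraction chemistry, library-preparation
batch effects, blank-control contamination, and physiological differences
between cultured mock cells and native cells.  A green downstream test
establishes that the statistics recover planted compositional effects of
realistic size under NB replicate noise — not that they are robust to those
unmodelled artifacts.

## Analysis choices

- **Alpha diversity** uses raw integer counts (richness estimation is
  meaningless after normalization).  Chao1 is the bias-corrected form
  S + F₁(F₁−1)/(2(F₂+1)), finite when no doubletons exist.  Shannon uses the
  natural log; Pielou J = H/ln S is flagged NaN below two taxa.  Rarefaction
  subsamples without replacement (multivariate hypergeometric), seeded.
- **PCoA** applies no Cailliez/Lingoes correction; negative eigenvalues are
  reported and excluded from coordinates, and variance explained is relative
  to the positive-eigenvalue sum.
- **betadisper** uses group centroids (not spatial medians); squared
  distances subtract negative-axis components and are clamped at zero before
  the square root; the permutation test shuffles group labels.
- **CCA** follows the weighted-projection formulation; sample coordinates
  are linear-combination scores u·s/√r and feature scores v/√c.  Zero-sum
  rows/columns are dropped with a warning; a saturated factor reproduces the
  total inertia exactly (verified against R/vegan).
- **Procrustes/protest** is symmetric (both configurations centered and
  scaled to unit sum of squares); each ordination contributes its first
  min(n−1, axes) principal coordinates; p-values use "≤" counting with
  add-one smoothing.  Permuting rows of the centered configuration preserves
  centering, so the null statistics are exact.
- **NB Wald test**: β̂ is the log2 ratio of size-factor-normalized group
  means; zero group means are floored at half a fragment so the SE stays
  finite (the taxon is then effectively censored, not dropped).  Dispersions
  are per-taxon method-of-moments, floored at 1e-8, and shrunk
  (geometric mean, weight 0.5) toward an a₀ + a₁/μ trend fitted by
  nonnegative least squares across taxa — the stabilizer that keeps the
  3-vs-3 null false-positive rate at p<0.01 below 0.03 (measured ≈ 0.01–0.02).
  This is a transparent approximation of DESeq2-style analysis: no Cox-Reid
  adjustment, no LFC priors, and p-values will not match DESeq2's.
- **Dunn post-hoc** z-tests use pooled ranks with tie correction and Holm
  adjustment, and run only when Kruskal-Wallis p < 0.05.
- **Table-1 analog**: for each matrix and stored condition, the mean and SE
  over all condition-replicate × 0 h-replicate dissimilarity pairs (9 at the
  default design); the 0 h row is the mean of the 3 within-replicate pairs.
- **Spike correction** operates on TSS relative abundances by default
  (configurable to raw counts); f is computed from replicate means, the
  subtraction applied per spiked replicate; negative corrected values are
  clamped to zero and flagged.  Clamping truncates the noise distribution
  and therefore biases low-spike members upward — unbiasedness holds for the
  unclamped subtraction, which is how the recovery acceptance check
  evaluates it.
- **Permutation defaults**: 999 permutations, add-one p-value estimator,
  seeded generators throughout; identical seeds give byte-identical output
  tables end to end.

## Numerical conventions

Distance matrices must be symmetric to 1e-12 with an exactly zero diagonal;
undefined dissimilarities (two all-zero samples) are stored as NaN and
rejected by the embedding stages.  Eigenvalue/singular-value cutoffs are
relative (1e-9–1e-10 of the leading value).  Linkage input features are
sorted lexicographically so tie-breaking is deterministic.  All-zero samples
are retained (zeros) with warnings rather than dropped.  TSV round-trips
preserve 12 significant digits.

## Known limitations

The generator's storage effects act at the phylum level with modest
taxon-level scatter; real storage responses are partly genus-specific and
not generalizable across sample types.  The NB test is an approximation of
DESeq2, adequate for planted-effect recovery but not a drop-in replacement.
PERMANOVA is single-factor (no strata/blocked permutations).  FPKM depends
on a bacterial-fragment denominator that, in the synthetic setting, is the
sum over bacterial taxa — real pipelines define "bacterial reads" by mapping
database, which can shift absolute FPKM levels.
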