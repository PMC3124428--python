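# Methods

## The informativeness model

The package predicts, per site, how much phylogenetic signal a locus will
contribute to resolving divergences at a given historical depth. Time runs
from the present (*t* = 0, at the tips of the ultrametric tree) toward the
root (*t* = depth); this direction is a convention the package fixes
explicitly, since Newick files carry none. For a site with substitution
rate λ, the informativeness density is

    ρ(t; λ) = 16 λ² t e^(−4λt)

with antiderivative −(1 + 4λt)e^(−4λt), so the epoch integral over
[t₁, t₂] is available in closed form and ∫₀^∞ ρ dt = 1 for every λ > 0:
each rated site carries exactly one unit of predicted signal, apportioned
over history. The density peaks at *t* = 1/(4λ) (height 4λ/e): a site is
most useful for divergences old enough that it has likely substituted once,
but not so old that later substitutions have overwritten the record. The
four-state form is applied to amino-acid loci as well, on their estimated
rates; the functional form is an extension point if a state-space-specific
variant is adopted later.

The model predicts signal only. It does not subtract phylogenetic noise —
homoplasy from convergent or parallel substitutions — so integrals over
epochs substantially deeper than a profile's peak overstate resolving
power and should be read cautiously.

## Per-site rate estimation

Rates are estimated per column by maximum likelihood on the fixed tree:
the column likelihood is computed by Felsenstein pruning with transition
matrices exp(Q·λ·b) on each branch of length b, and λ is optimized over
[0, λ_max]. Details:

- **Models.** JC69 (DNA default), K80, HKY85, GTR, and POISSON20, the
  20-state equal-rates model (protein default). Generators satisfy
  detailed balance and are normalized so −Σ πᵢQᵢᵢ = 1; λ is therefore in
  expected substitutions per site per unit of tree time, and estimates
  scale as 1/c when all branch lengths are multiplied by c. The defaults
  are deliberately assumption-light; HKY85/GTR shape parameters can be
  fitted once, globally, on the variable columns at a shared rate of 1
  (`fit_model`), with base frequencies taken from empirical counts.
- **Transition matrices** come from the symmetric eigendecomposition of
  D^½QD^(−½) (stable for reversible Q); λ·b = 0 uses the exact identity.
- **Optimizer.** Deterministic golden-section search, 72 iterations,
  which shrinks the bracket far below the 1e-6 relative tolerance of
  interest. The search is vectorized across the columns of a locus (each
  column follows its own bracket; all arithmetic is elementwise per
  column), and identical columns are recognized by hashing and estimated
  once. Because every per-column operation is elementwise with a fixed
  summation order, results are bitwise identical whether columns are
  batched, deduplicated, or estimated singly.
- **Statuses.** Columns with fewer than two non-missing observations are
  FAULTY (no rate; excluded from profiles and counted in the per-locus
  report). Columns whose non-missing symbols are a single unambiguous
  state return λ = 0 (INVARIANT_ZERO) without optimization. A maximum
  attained at λ_max — including likelihood plateaus that reach the bound,
  as with a two-taxon mismatch whose likelihood increases monotonically —
  is clamped and flagged CLAMPED_MAX. λ_max defaults to 20/depth (twenty
  expected substitutions over the tree height), beyond which the profile
  contribution is numerically nil.
- **Missing data and ambiguity.** "?", "-", and N/X are fully missing
  (tip partial of ones); IUPAC codes are state sets; U maps to T; under
  reversibility the likelihood is root-invariant and the supplied rooting
  is used as-is. Zero-length branches are permitted.

Per-site independent ML was chosen over empirical-Bayes gamma-category
estimation: it needs no hyperparameter, is embarrassingly parallel across
columns, and its statuses are directly reportable. A gamma-posterior-mean
estimator is a documented extension point.

## Profiles, integrals, rankings

Net profiles sum ρ over non-faulty sites; per-site profiles divide by the
number of rated sites (not raw length — faulty sites carry no estimate and
would deflate loci with more missingness; a `per_site_denominator="length"`
option restores length normalization). Epoch integrals are computed from
the closed form per site, never from the gridded curve; the default
1,000-point grid on [0, depth] exists only for tables and plots. Rankings
default to the per-site basis (comparing cost-effectiveness across loci of
different lengths and being less exposed to noise than net signal); ties
use competition ranking ("1, 1, 3"), are flagged, and tied loci keep
alphabetical order. NEXUS charsets are profiled as pseudo-loci named
`locus:partition`, inheriting the parent locus's per-site estimates.

Tree depth is not normalized by default; for trees in unspecified
molecular-evolutionary units `--normalize-depth` rescales depth to 1 so
epochs can be given as fractions of tree height. Rankings are invariant
either way by rescaling equivariance.

## Input handling

All site coordinates on file interfaces are 1-based (NEXUS convention).
Ultrametricity is enforced to a relative tip-depth deviation of 1e-4
(configurable; chronograms from rate-smoothing tools carry rounding
noise). Tree tips absent from an alignment are pruned from a working copy
with a warning; alignment taxa absent from the tree are a hard error —
pruning the tree loses nothing, while inventing a placement would. Basal
trifurcations are accepted and treated as rooted. The alphabet is detected
as DNA when ≥ 80% of non-gap symbols are in {A,C,G,T,U,N}. The rate TSV
(`locus  site  rate  model`, `NA` = faulty) is this package's own format;
it round-trips exactly because rates are written with full `repr`
precision.

## The simulator and what passing tests show

`simulate` draws pure-birth (Yule) topologies — unit birth rate, node
heights rescaled so the depth is exact — and evolves sites independently
down the tree from stationary root states, with per-site rates constant,
gamma(α, mean), or explicit. All randomness flows through numpy's PCG64
generator with explicit seeds, so fixtures are bit-reproducible. Default
benchmark conditions are 16 taxa, depth 1, gamma shape α = 0.5 (strong
among-site heterogeneity, typical of protein-coding loci), mean rate 1.

The simulator deliberately omits indels, among-branch rate variation,
selection, alignment error, and empirical protein exchangeabilities.
Passing recovery tests therefore demonstrate that the estimator inverts
the generative model it assumes — not that real loci meet those
assumptions. On the benchmark conditions the Spearman rank correlation
between true and estimated rates on 2,000 gamma-rate sites exceeds 0.8,
and the median estimate on a 1,000-site constant-rate locus (λ = 0.5) is
within 15% of truth; per-site ML medians fluctuate by seed at roughly the
±10–15% level on trees of this size, which bounds what per-site estimates
can promise.

## Numerical choices

- Pruning partials are rescaled per internal node (log-scale accumulator),
  keeping likelihoods finite up to λ_max on deep trees.
- Likelihood agreement with exhaustive enumeration over internal-node
  states is verified to < 1e-10 relative on random trees of ≤ 5 tips.
- Closed-form epoch integrals agree with adaptive quadrature to 1e-8
  absolute; epoch additivity holds to 1e-12.
- Column likelihood at λ = 0 is the invariant-explanation limit: π(state)
  for constant columns, −∞ (probability zero) for variable ones.
- SVG output formats all coordinates to fixed precision and orders nodes
  deterministically (ladderized by clade size, ties by label), so output
  is byte-stable; tree and profile panels share one linear time transform.

## Problem sizes

The default test suite and the acceptance script use scaled benchmark
sizes chosen to exercise every code path at meaningful statistical power:
2,000 sites for rank-correlation recovery, 1,000 for median recovery, 200
random small trees for the enumeration cross-check, and a 100-locus ×
1,000-bp × 16-taxon batch through the CLI (the vectorized estimator
handles that batch in well under two minutes on one core).

## Known limitations

- Per-site ML rates from a single column are noisy by nature; profiles of
  short loci inherit that noise. The rank ordering of loci is far more
  stable than individual site rates.
- No codon models and no among-branch rate variation; a clock-like tree
  is assumed correct and fixed.
- Amino-acid informativeness reuses the four-state ρ form.
- The estimator replaces external rate programs; their output files are
  not parsed (convert to the rate TSV instead).
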