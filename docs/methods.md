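# Methods

## The branching-process model of PCR

PCR is treated as a discrete-generation Galton–Watson process on whole
molecules: in each cycle a molecule either replicates (offspring 2) or
does not (offspring 1). No strand bookkeeping is attempted — a successful
replication copies one parent into one child — which matches the
branching abstraction the family-size statistics rest on. The expected
copy number of a lineage after `c` cycles at constant efficiency `e` is
`(1+e)^c`; the distribution around it is multimodal, because a lineage
that misses cycle 1 lands near `(1+e)^{c−1}`, half the principal mode,
with probability `1−e`.

Six replication-probability rules are implemented:

| model | per-cycle replication probability |
|---|---|
| 1 | constant `e` |
| 2 | constant `e`; a molecule that fails degrades w.p. `d` |
| 3 | `min(1, R / M_t)` with fixed resource `R`, population `M_t` |
| 4 | as 3, with `R` decremented by `δ` per successful replication |
| 5 | fresh draw per molecule per cycle from Normal(μ, σ) truncated to [0, 1] |
| 6 | one truncated-normal draw per initial molecule, inherited by all descendants |

Notes on the open points these definitions settle:

- **Model 3.** The resource rule is implemented as
  `p_t = min(1, R/M_t)`: full efficiency until the population outgrows the
  resource, then declining as `R/M_t`. (The inverse ratio `M_t/R` is not a
  probability once `M_t > R`, so the capacity reading is the coherent
  one.) `R` is configured as a multiple of the initial molecule count and
  converted to an absolute capacity when amplification starts.
- **Model 2 ordering.** Degradation is only attempted on that cycle's
  replication failures, so the expected per-cycle growth factor is
  `1 + e − (1−e)d` and the population can shrink to zero.
- **Model 4 accounting.** Resource decreases by `δ` per successful
  replication with a floor at zero; with `δ = 1` and `R = k·M_0` the
  lifetime number of replications is bounded by `k·M_0` exactly.
- **Models 5/6 efficiency distribution.** Truncation to [0, 1] is by the
  true truncated distribution (scipy `truncnorm`), not clipping, so no
  probability atoms sit at the boundaries. Model 5 draws independently
  per molecule *and* per cycle; those draws marginalise out, making model
  5 statistically identical to model 1 at the truncated-normal mean —
  this is a documented property of the model (and a test), not an
  accident. Heritability (model 6) is what breaks the equivalence and
  generates lineage-to-lineage dispersion.

### Execution paths

With no replication error the simulator advances one binomial draw per
lineage per cycle (`copies += Binomial(copies, p)`), so 10^4 lineages
through 25 cycles cost ~10^5 draws regardless of population size. With a
per-base error rate, every molecule is materialised as a string and each
successful replication copies the parent and then mutates the copy
(substitution only; an erroneous position takes one of the other three
bases uniformly), so errors propagate along the lineage tree exactly as
in PCR. The two paths agree in distribution at zero error rate (tested by
two-sample KS). A configurable population cap (default 10^9 molecules)
aborts runaway configurations with an explicit error; heavy-tailed
settings such as model 6 with (μ, σ) = (0.3, 0.3) over 25 cycles
genuinely need ~5×10^9 molecules and must raise the cap deliberately.

## Barcode pools, labelling and clash

Barcodes are integer ids in `[0, 4^L)`; nucleotide strings are
materialised lazily by base-4 expansion only when sequences are needed,
so a 4^12-barcode pool never exists as strings in memory. Labelling is
sampling with replacement from the pool's weight distribution — clash is
an outcome, never prevented. Uniform pools store no weight vector;
non-uniform pools draw one weight per barcode (normal variates
rejection-sampled to be positive, or log-normal) and normalise.

Exact clash analytics assume a uniform pool: the no-clash probability is
the birthday product `∏_{i<n} (1 − i/N)` (computed in log space; zero by
pigeonhole for `n > N`), with `exp(−n(n−1)/2N)` exposed separately as the
labelled approximation; the expected uniquely-barcoded fraction is
`((N−1)/N)^{n−1}`.

### Inferring pool structure from labelling events

The histogram of barcode-labelling events (how many molecules each
observed barcode labelled) is fitted by a zero-truncated K-component
Poisson mixture,

    P(k) = Σ_j w_j Pois(k; λ_j) / (1 − Σ_j w_j e^{−λ_j}),  k ≥ 1,

by maximum likelihood over an unconstrained reparameterisation (log
rates, softmax weights; Nelder–Mead, tolerance 1e-8, 10 random restarts —
the surface is multimodal for K ≥ 2). In this parameterisation `w_j` is
the fraction of the *whole* pool in class j and `λ_j` its per-barcode
event rate, so the fit maps directly to a pool description: class
fractions `w_j`, relative labelling propensities ∝ `λ_j`. That
description round-trips into the simulator as an `empirical-mixture` pool
spec, and a fresh labelling from the rebuilt pool reproduces the fitted
event law (chi-squared, tested). K is selectable by AIC over 1..K_max
(default K_max 3); the criterion choice is a package convention, since
model selection for these histograms has no canonical rule. Fits where no
restart converged are returned flagged, never raised.

## Subsampling and the zero-truncated Poisson

Sequencer loading draws molecules uniformly **without replacement** —
physical molecules are loaded once — as one multivariate hypergeometric
draw over lineage copy numbers. (numpy refuses totals ≥ 10^9; beyond
that the implementation draws distinct molecule indices directly, which
is still an exact without-replacement sample and is only used when the
sample is far smaller than the pool.) When the sample is small relative
to the amplified pool, per-lineage observed counts are approximately
independent Poisson; conditioning on observability (size-0 families are
invisible) gives the zero-truncated Poisson with rate equal to the sample
ratio `r` for a uniformly amplified pool. The ZTP is an approximation to
the exact hypergeometric law, and the chi-squared acceptance checks use
regimes (amplification depth 2^10 per lineage) where it holds; at very
shallow amplification the without-replacement correction would be
detectable.

The ZTP maximum-likelihood fit is a bounded 1-D likelihood maximisation
(tolerance 1e-10); it coincides with inverting the moment equation
`λ/(1−e^{−λ}) = mean`, which is kept as an independent routine and
cross-checked to 1e-6. All-singleton data pushes λ to the lower boundary
(the ZTP degenerates to a point mass at 1); such fits are flagged and
excluded from goodness-of-fit testing. The chi-squared test bins family
sizes 1, 2, …, pools rightward until every expected count is ≥ 5 (the
final bin absorbs the infinite tail), and uses bins − 2 degrees of
freedom (total + one fitted parameter); the binning rule is stated
because only the test itself, not its binning, is canonical.

The coefficient of variation uses the population standard deviation
(denominator n) by default, switchable to the sample form. Run-to-run
comparison ranks per-barcode family sizes ascending with dense ties (no
rank gaps, so small families rank equal to their size) and reports the
R² of the rank-rank least-squares line.

## Reads and errors

Each sampled molecule yields one read; sequencing substitutions use the
same uniform-substitution model as replication error, applied to the full
molecule including the barcode positions, so barcode-position errors can
split observed families exactly as they do experimentally. Family-size
reporting defaults to ground-truth lineage identity, with an
observed-barcode mode in which clash merges and errors split families.
Quality strings are constant Phred 40 placeholders — quality-score
modelling is out of scope. FASTQ is written via Biopython, with lineage
and barcode ids in the header comment.

## Reproducibility and problem sizes

Every stochastic operation takes an explicit seed (numpy `default_rng`);
one seed per pipeline stage (pool, labelling, amplification, sampling,
sequencing), offset by the repeat index, so stages vary independently and
identical configurations produce byte-identical outputs. Default study
conditions follow the standard desk-scale settings of this problem area:
10^4–10^5 initial molecules, 25 cycles, sample ratios 0.5–2.5, 10
repeats for mean ± sd summaries, per-base error 10^−4, 12-nucleotide
barcodes (4^12 ≈ 1.7×10^7). Sequence-path runs (with error) are kept to
10^2–10^3 lineages and single-digit cycle counts in the test suite, which
is ample for distribution-level checks while keeping runs in seconds.

## What the synthetic data does and does not show

The generator reproduces the *mechanisms* — clash, branching
stochasticity, resource competition, heritable efficiency, subsampling,
substitution error — under idealised conditions: no primer or GC-content
effects, no chimeras or non-specific products, no quality-score
structure, no strand asymmetry, and an exactly known ground truth per
read. Passing tests therefore demonstrate internal consistency of the
models and estimators, and that heritable efficiency (and only the
mechanisms that include it) produces decisively non-Poisson family-size
distributions; they do not certify that any particular real protocol is
described by one of the six models, nor calibrate (μ, σ) for a real
polymerase.

## Known limitations

- Model 5's per-molecule-per-cycle reading makes it marginally
  indistinguishable from model 1; a shared-per-cycle draw (a plausible
  alternative reading of "variable efficiency") would behave differently
  and is not implemented.
- The mixed-Poisson fit can be slow and multimodal for K > 3; AIC
  selection is a convention, not an optimality claim.
- The without-replacement sampler's large-pool fallback requires the
  sample to be at most half the pool (always true in the intended
  regimes).
- Sequence-path memory grows with total molecules × molecule length; use
  the count path unless per-base errors are required.
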