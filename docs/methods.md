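# Methods

## Steady-state yield model

A transcript initiates when a free ribosomal subunit (level *R*) engages
its start codon, which succeeds only if the first *L* codons — one
footprint — are clear. The steady-state clearance probability is
`p = 1 − L/(ke/(ki·R) + L − 1)`, giving the production rate
`Q = m·R·ki·p` and, by Little's law, the expected per-copy ribosome load
`(Q/m)·n/ke` for a coding length of *n* codons. Time, ribosome level and
mRNA level carry arbitrary units; every statement the package makes is
about ratios or the dimensionless occupancy variable `x = ki·R/ke`.

The formula is valid for `x ≤ 1`. At `x = 1` the start region never
clears (`Q = 0` exactly, treated as part of the domain); beyond it the
package raises `JammedRegimeError` rather than clamping, so upstream
solver misuse surfaces immediately. The load `n·x·p(x)` is unimodal with
its maximum at `x* = 1/(√L+1)` (≈ 0.24 for the default L = 10): below
`x*` a transcript is initiation-limited, above it elongation-limited.
This point matters throughout — total bound ribosomes are monotone in
`R_free` only while all genes stay below `x*`, so the conservation solver
uses a bracketing root finder (`scipy.optimize.brentq` on
`[1e-12·R_total, min(R_total, min_g ke/ki)]`) that needs no monotonicity,
and re-checks the residual at 1e-8 relative after convergence.

## Two-phase elongation and the knockdown scenario

Each codon advance decomposes into two sequential exponential stages:
recruitment of eEF2 (rate `k_bind·E`, with `E` the factor's availability
fraction — sequence independent) and translocation (rate
`k_trans0·exp(−β·q)`, where `q` counts lysines/arginines among the `W`
residues most recently synthesized — the stretch inside the negatively
charged exit tunnel). Scarcity of the factor lengthens only the waiting
stage, so the *relative* cost of charge-slowed translocation shrinks as
`E` falls.

The pool module maps this to a per-gene effective elongation rate

    ke_g(E) = 2·ke / (1/E + A_g),      A_g = mean_i exp(β·q_i) ≥ 1,

calibrated so an uncharged transcript at `E = 1` keeps its nominal `ke`.
A knockdown scenario with residual fraction `f` solves the pool twice —
baseline at `E = 1`, knockdown at `E = f` — and reports per-gene relative
yield changes `log2[(Q′_g/ΣQ′)/(Q_g/ΣQ)]` (relative, because absolute
synthesis falls genome-wide). A scenario built with `elongation=None`
instead applies the plain uniform scaling `ke′ = f·ke`.

The distinction is not cosmetic. Under uniform scaling, conservation
forces every gene's `x` to move by a common factor, and a short
calculation (the elasticity of `p` is strictly decreasing in `x`) shows
high-initiation genes can then only *lose* relative yield share — uniform
slowdown alone cannot produce preferential TOP translation. The observed
direction emerges from the two paper-motivated asymmetries the default
scenario encodes: TOP transcripts are charge-rich (their elongation slows
*less* than the bulk's under depletion) and they sit beyond `x*` at
baseline (elongation-limited, as ribosomal-protein transcripts are), so
the relative relaxation of their elongation constraint converts directly
into yield and footprint gains.

Polysome profiles distribute each gene's bound-ribosome signal over a
Poisson law with mean equal to the model load, truncated at the steric
capacity `floor(n/L)`; an mRNA carrying *j* ribosomes contributes *j*
units of signal. Classes follow gradient convention: monosome = exactly
1, light = 2–4, heavy = >4 ribosomes; free subunits are excluded from the
monosome/polysome ratio. The Poisson choice is the maximum-entropy law
consistent with a mean; the lattice simulator's empirical load histogram
validates it at low density (total variation < 0.05) and quantifies its
failure under congestion, where exclusion makes occupancy underdispersed.

## Stochastic lattice simulator

`tasep.simulate_transcript` runs the Gillespie direct method over
ribosomes of footprint *L* on an *n*-codon lattice: initiation at rate
`alpha = ki·R_free` when the first *L* sites are vacant, the two-stage
dwell per advance, termination at the last codon. No tau-leaping is
needed at these sizes (n ≤ a few thousand). Occupancy statistics come
from snapshots at `n_samples` regular times after a burn-in, so the
density/histogram bookkeeping identities hold exactly; the production
rate carries a batch-means standard error (10 batches) that absorbs
autocorrelation. Trajectories are bit-reproducible given a seed. A debug
flag asserts footprint exclusion after every event. In the
initiation-limited regime the simulator reproduces the closed form with
the harmonic per-codon rate `1/(1/(k_bind·E) + 1/k_trans0)`; this is the
package's central cross-validation and is exercised at `x ≤ 0.1`, where
mean-field theory is trustworthy, with tolerance `max(10%, 3 SE)`.

`charge_penalty` measures `P(E) = production(uncharged)/production(charged)`
for sequence pairs differing only in charge; `charge_penalty_limit` gives
the zero-simulation renewal approximation
`(1 + α·T_charged)/(1 + α·T_uncharged)` from expected start-region
transit times, which tends to 1 as `E → 0`.

Defaults: `W = 10` residues (approximate ribosomal exit-tunnel span near
the peptidyl-transferase centre), `β = 0.15` per charge in the lattice
config, `β = 0.3` in the pool-level scenario. No quantitative measurement
pins these; both are single-parameter knobs documented here and
configurable everywhere. The larger pool-level default reflects that
`A_g` averages the penalty over whole coding regions, diluting local
charge clusters.

## Synthetic data

The generator emulates a paired liver experiment: three control and three
knockdown animals, one mRNA-seq and one Ribo-seq library each. Defaults
(chosen once, as the study conditions):

- 200 genes, 10% TOP-like. `ki`: log-normal, median 1.0 (σ_log 0.10) for
  TOP vs median 0.03 (σ_log 0.5) for the bulk — the order-of-magnitude
  initiation advantage attributed to TOP motifs.
- K/R frequency per gene: Beta(40,113) for TOP (mean 26%, matching the
  strongly basic composition of ribosomal proteins) vs Beta(2,18) for the
  bulk (mean 10%); coding lengths 80–250 vs 150–600 codons; `ke = 10`,
  `L = 10`.
- mRNA abundance log-normal (σ_log 0.8) in arbitrary units; its scale
  fixes the baseline free-subunit fraction at ~3–4% of all ribosomes.
- `R_total` is calibrated so the median TOP gene sits at `x = 0.45` at
  baseline — inside the elongation-limited regime, with headroom below
  jamming for the parameter spread.
- Counts: expected mRNA ∝ `m`, expected footprints ∝ `m·load` at the
  condition's solved pool (footprints sample ribosome occupancy, so
  stalled ribosomes *raise* footprint signal — the mechanism by which
  impaired elongation inflates apparent TE). Library sizes 2×10⁷ ± 20%.
  A per-gene-per-sample log-normal factor (sd 0.2) multiplies both
  assays of a sample — animal-level biology that cancels in the paired
  TE ratio — while negative-binomial dispersion (log-normal, median
  0.001) models assay-level technical noise that does not cancel.
- The truth table stores the exact expected log2 TE change (ratio of
  composition-normalized expected count ratios) and the model's relative
  yield change per gene.

What the generator does **not** emulate: UTR/metagene structure, reads or
alignment, codon-level dwell variation beyond charge, isoforms, batch
effects, time-course dynamics, or ribosome biogenesis (R_total is fixed
per scenario). Passing tests therefore certify the inference machinery
against this generative model, not against the full complexity of real
Ribo-seq.

## TE analysis

Size factors are median-of-ratios against per-gene geometric means over
genes with all-positive counts. TE is
`(fp/sf + pc)/(mrna/sf + pc)` with pseudocount 0.5; genes under 10
summed counts in either assay are excluded from testing. The per-gene
statistic is the difference of condition means of per-sample log2 TE;
the null permutes condition labels jointly across both assays,
enumerated exhaustively whenever the label space has ≤ 10,000
assignments (20 for 3v3, including the observed labelling, so p-values
sit on a grid and are never zero; sampled permutations use the add-one
convention). BH correction uses statsmodels. Class enrichment
standardizes the TOP rank-sum by its exact null moments and takes its
p-value from label permutations, one-sided (TOP up) by default.

A consequence of the exact 3v3 null: the smallest attainable p is 2/20,
so rejection at α = 0.05 is impossible and the test is conservative
there by construction; calibration is checked at the attainable 0.1
level and validity (no anti-conservatism) at 0.05.

## Numerical conventions

Codon indices are 0-based internally, 1-based in outputs; intervals are
half-open. Floats serialize at %.17g and are parsed with round-trip
precision, so TSV/JSON round-trips are exact. Stage seeds derive from a
master seed by fixed offsets, overridable per stage. Degenerate inputs
are contracts, not surprises: empty transcriptomes keep the pool free,
`m = 0` genes contribute nothing, an all-monosome profile reports an
infinite monosome/polysome ratio with an explicit capped flag.

## Known limitations

- The mean-field formula is an extrapolation between `x*` and 1; the
  lattice simulator, not the formula, is authoritative in that regime,
  and the package uses the formula there only as the spec'd closure.
- Conservation roots are unique only below `x*`; the default operating
  point keeps the aggregate bound mass dominated by sub-maximal genes,
  and the solver verifies its residual regardless.
- The charge window `W` and penalty `β` are effective parameters, not
  measurements; conclusions that depend on their precise values should
  be swept.
- The truncated-Poisson polysome law ignores exclusion correlations;
  expect it to overstate heavy-fraction tails for congested genes.
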