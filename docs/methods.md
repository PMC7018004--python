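# Methods

## The morphologies

The unit of analysis is a *floret*: the bouton-dense, self-similar
terminal arborization that a thalamocortical axon forms in its cortical
target layer, separated from the long-range axonal trunk.  A floret is
represented as a rooted, strictly binary tree of *segments* — neurite
stretches between consecutive branch points, or between a branch point
and a tip — each carrying only a scalar length in micrometres.  All
statistics in this package are functions of segment lengths and tree
topology; 3D coordinates, radii and bouton positions are not modelled
(the spatial embedding attaches polylines as metadata but never feeds
them into statistics).  A floret with one segment is *trivial*; with
`n` segments there are `(n+1)/2` terminals, `(n-1)/2` internal
segments, and `n` is odd.  Reconstructed data carry a 1 um measurement
floor; `Floret.finalize()` enforces it, while zero-length segments are
legal mid-simulation.

SWC files are read by collapsing chains of unary sample points into
single segments (summed 3D point-to-point distance, including the step
from the parent branch point).  A sample with more than two children is
an error rather than being silently split, because the model space is
strictly binary.  Florets without geometry are written as abstract
polylines along +z, declared in a header comment; lengths round-trip to
1e-6 um either way.

## Morphometric indicators

Per floret: segment count, mean/SD of lengths and natural-log lengths
(sample SD, n-1 denominator; SD defined 0 for a single segment), mean
and maximal depth (root depth 1, +1 per bifurcation; "mean depth" is
the mean over *segments*, and reported separately from max depth), and
two asymmetry indices.

At a branch point whose sub-trees hold `t_l`, `t_r` terminals with mean
segment lengths `w_l`, `w_r`:

* partition (Van Pelt / Colless) asymmetry
  `A_p = |t_r - t_l| / (t_r + t_l - 2)`,
* length-weighted asymmetry
  `A_pw = 2 |w_r t_r - w_l t_l| / [(t_r + t_l - 2)(w_r + w_l)]`,

both defined as 0 for a cherry (`t_l + t_r <= 2`), and averaged over
all `(n-1)/2` internal segments to give the floret-level index
(trivial florets score 0).  Conventions worth stating:

* The cherry convention is forced by self-consistency: it makes the
  weighted index reduce *exactly* to the partition index on equal-length
  trees (property-tested over random topologies), and it reproduces the
  worked examples (the 5-segment fixture scores `A_w = 0.4` vs
  `A_p = 0.5`).  A consequence sometimes overlooked: a finite
  caterpillar with `k` terminals scores `(k-2)/(k-1)`, approaching 1
  only asymptotically.
* `A_pw` as written can exceed 1 at cherty partitions with extreme
  weight ratios (supremum 4 at `t = (2, 1)`).  It is clamped at 1, and
  clamps are counted, to preserve the unit-interval codomain; no
  alternative normalizer is invented.
* If both sub-trees have zero mean length (possible for the unit-step
  baseline mid-simulation), the equal-weight limit applies and
  `A_pw = A_p`.

Dataset summaries report length rows as segment-pooled means (all /
non-trivial / trivial florets) and depth/SD/asymmetry rows as means of
per-floret values, with trivial florets contributing depth 1, SD 0 and
asymmetry 0.  This bookkeeping gives exact dilution identities
(overall mean = NT mean x NT fraction) that the test suite checks
structurally.

## The growth model

Growth is enacted by independent growth cones sharing one rule set —
no global coordination.  Each floret draws an initial resource budget
`r ~ Gamma(rs_shape, rs_scale)` (an abstract tubulin-supply proxy).  A
branch first grows a mandatory offset `os` (interpretable as the
minimal microtubule building block; it also depletes mass below ~1 um)
and pays one resource unit.  While `r >= 1`:

1. with probability `p_growth`: elongate by `Gamma(g_shape, g_scale)`
   um and pay 1 resource;
2. otherwise with probability `p_retract`: shorten by
   `Gamma(r_shape, r_scale)` um at no resource cost; below 1 um the
   segment is removed and its cone dies;
3. otherwise bifurcate: draw `z ~ U[bias, 1]`, allocate
   `r_f = 1 + (1-z)(r-2)` and `r_s = 1 + z(r-2)` (summing to `r`
   exactly) to the daughters, and recurse for both if both shares
   exceed 1, else the segment closes as a terminal.

With `bias >= 0.5` the split is almost always uneven; which daughter
receives the larger share is a fair coin in the abstract model (the
spatial embedding replaces this with the gradient rule — all reported
statistics are invariant to the choice).  Resource is real-valued and
never rounded.  When a pruned segment leaves its parent with one child,
the surviving child is merged into the parent (lengths summed): since a
segment is *defined* as the stretch between branch points, leaving a
unary node and collapsing chains afterwards would yield the identical
segment multiset, so only the merge semantics is implemented.  Florets
whose root retracts away are resampled (datasets contain only florets
with at least one segment); attempts are recorded in `meta`.  A hard
cap of 1e6 events per floret converts non-terminating parameter sets
(e.g. free infinitesimal retraction) into an error.  One independent
random stream per floret, derived from the master seed, makes datasets
reproducible and florets exchangeable.

Conditioned on the resource, the model is an age-dependent
(Bellman-Harris-type) branching process: segment lifetimes (lengths)
come from an arbitrary distribution rather than the constant step of
the Galton-Watson baseline.

### Default parameters and a calibration caveat

The packaged defaults (`OPTIMIZED_PARAMS`) are the reference
genetic-algorithm calibration for the cat LGN -> area 17 floret dataset:
gamma(1.26, 21.18) elongation, gamma(1.69, 17.82) retraction,
gamma(14.99, 11.29) resource, `p_growth = 0.11`, `p_retract = 0.58`,
`bias = 0.63`, `offset = 1.76`.  Users should know what these defaults
actually produce here: ~500-floret datasets have pooled mean segment
length ~8.6 um, mean depth ~1.50, mean partition asymmetry ~0.11
(non-trivial ~0.29) and ~60% trivial florets.  The summary statistics
reported for this parameter set (mean length ~52.6 um,
mean depth ~1.77, asymmetry ~0.24/0.35, ~1/3 trivial) are *not*
reproduced by these values under the growth rules as stated above; an
extensive search over alternative readings of the update rule and over
the full parameter box showed no configuration that reproduces that
summary jointly, so the discrepancy appears to lie in the reported
parameter values rather than in this implementation.  The package
reports what it computes; `scripts/acceptance.py` recomputes these
numbers from scratch on every run.

### Galton-Watson baseline

Per step a cone grows by a fixed `step_length` (default 1 um), branches
or halts with constant probabilities; segment lengths are therefore
geometric (exponential-like), the structural failure mode against
log-normal data.  Sampling is segment-wise via the exact geometric
equivalence of the per-step scheme (run length ~ Geometric(1 -
p_growth), then branch with probability `p_branch / (p_branch +
p_halt)`), which is identical in law and orders of magnitude faster
inside calibration loops.  Subcriticality `2 p_branch + p_growth < 1`
is enforced at construction.  Zero-length segments (immediate branch or
halt) are returned as-is and flagged only by the finalizer.  Defaults
are the reference calibration (0.98, 0.0031).

## Distribution analysis

The pooled segment-length distribution is fitted with a three-parameter
(shifted) log-normal `X = gamma + exp(mu + sigma Z)`.  Its likelihood
is unbounded as `gamma -> min(x)`, so the fit profiles `gamma` on a
log-spaced grid bounded `1e-3` below the sample minimum (closed-form
`mu`, `sigma` at each point) with bounded local refinement —
deterministic, stable, and by construction at least as good as the
unshifted fit.  Parameter recovery at n = 2000 is verified to
(+-0.5, +-0.1, +-0.05); note that `gamma` is identified by the left
tail, so truncated samples (e.g. a 1 um floor) bias it upward.

Jensen-Shannon divergences are computed in nats on probability
histograms with *shared* edges built from the pooled two-sample data
(Freedman-Diaconis by default; the binning behind previously reported
divergence values is irrecoverable, so divergences are comparable only
within a stated binning policy).  Skewness is the plain Fisher-Pearson
g1; normality via Shapiro-Wilk (3 <= n <= 5000); distribution equality
via the two-sample Kolmogorov-Smirnov test; candidate families
(shifted log-normal, gamma, exponential, normal) are ranked by BIC.
All hypothesis tests use the 5% level.

## Calibration

The objective is
`alpha * JS(lengths) + (1 - alpha) * JS(weighted asymmetries)` with
`alpha = 0.9` by default, evaluated on `n_sim = 500` freshly simulated
florets per candidate.  The GA is real-coded: 10% elitism with cached
elite fitness (the best-of-generation trace is provably
non-increasing), tournament selection (k = 2), uniform crossover
(fraction 0.8), bounded Gaussian mutation (rate 0.25, sigma 10% of
range); per-evaluation seeds derive deterministically from
(master seed, generation, individual).  Halting: 10 x n_params
generations or mean best-objective improvement < 1e-6 over 50
generations.  Parameter boxes follow the stated optimization ranges;
the Galton-Watson search repairs subcriticality violations by shrinking
`p_branch`.

A design note on the Galton-Watson self-recovery experiment used in the
acceptance suite: `p_branch` does not affect the segment-length
distribution at all (lengths are geometric in `p_growth` alone), so it
is identified only through the asymmetry histogram.  The recovery run
therefore weights the two terms equally (`alpha = 0.5`), uses fixed
40-bin histograms for stable support, and simulates 8000 florets per
evaluation (Galton-Watson florets are cheap); these choices follow from
a signal-vs-sampling-noise analysis of the objective, not from the
recovered values.

## Spatial embedding

The bias parameter is reinterpreted as the norm of an extracellular
concentration gradient `v = (0, 0, slope)`, constant in x, y and linear
in z.  At bifurcations the cone reads the gradient noisily —
`z = ||v|| + U(0,1)(1 - ||v||)`, i.e. exactly `U[bias, 1]` — and the
daughter closer in angle to the gradient receives the larger resource
share.  Daughters leave the parent direction at +-30 degrees about a
random orthogonal axis (60 degrees between them, exact).  Elongation is
straight between bifurcations (no tortuosity model) and retraction
shortens the polyline from the distal end, so per-segment arc length
equals the abstract length to 1e-6 um.  The field is purely linear and
unbounded — no reaction-diffusion solver, since only the gradient's
norm and direction enter the rules.  Because the split fraction has the
same law and the share assignment merely relabels two exchangeable
daughters, every length/topology statistic matches the abstract
generator; the suite checks this by KS tests on pooled lengths and
indicator distributions.

## What the synthetic data do and do not show

The built-in reference sample (`fixtures.reference_length_sample`)
draws from the shifted log-normal fitted to the biological pooled
lengths (gamma = -2.9157, mu = 3.52, sigma = 1.03), redrawing below the
1 um floor (~2% of mass); it emulates the *global* length distribution
only.  It carries no per-floret structure, no depth/asymmetry
correlations, no reconstruction artifacts.  Tests passing against it
show the pipeline's statistics and contrasts behave correctly, not that
the growth model matches real axons; conversely the Galton-Watson
rejection contrast is robust because it is structural (geometric vs
log-normal shape).

## Problem sizes

Default test and acceptance runs use 500-floret datasets (3 master
seeds), 2000-point fit-recovery samples, and GA budgets of 24 x 20
generations; these match the scale of the reference analyses while
keeping a full run on one CPU within minutes.

## Known limitations

* No bouton positions, radii, branch angles against data, Sholl or
  tortuosity metrics; no trunk-axon growth.
* The reference calibrated parameter set does not reproduce the
  summary statistics reported for it under the stated update rule (see
  above); defaults are shipped as printed rather than re-tuned.
* Mean asymmetry is *not* monotone in the bias parameter: near
  `bias = 1` the smaller daughter share approaches 1 and bifurcations
  fail their viability check, so extreme bias raises the trivial
  fraction instead of the asymmetry.
* XLSX ingestion requires the optional `openpyxl` extra.
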