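# Methods

## The time-ordered linear model

A differentiation time course is an `n × t` log-scale matrix `X`
(`n` probes, `t` ordered stages, `n > t`). Its segment vectors
`a_i = X_{i+1} − X_i` join consecutive stages head-to-tail in gene space.
The developing line is the co-bisector `v = Σ_j λ_j a_j` of these
segments, defined by the equal-angle condition
`⟨a_i, v⟩ / |a_i| = c` for all `i`.

Substituting the linear combination gives, with the Gram matrix
`G_ij = ⟨a_i, a_j⟩`,

    Σ_j G_ij λ_j − |a_i| c = 0 ,   i = 1 … t−1 ,

`t−1` equations in the unknowns `λ_2 … λ_{t−1}` and `c` once `λ_1` is
pinned to 1. Pinning `λ_1` (rather than any other coefficient) is an
arbitrary normalisation: changing it rescales `v` and leaves every
projection-derived quantity unchanged, because the projection
`P(s) = ⟨s, v⟩ / |v|` is invariant under positive rescaling of `v`.

**Why this line.** Because all segments make the same angle with `v`,
the projected stages satisfy `P(X_{i+1}) − P(X_i) = c |a_i| / |v|`: the
gaps all carry the same sign (so time order is preserved after
orientation) and are proportional to the segment lengths (so distance
ratios are preserved). Restricting to span{a_i} maximises the common
cosine: adding any out-of-span component `w` with mixing angle θ
multiplies every cosine by cos θ < 1 while keeping them equal, so the
in-span co-bisector is the longest bisector. Both facts are verified
directly in the test suite (property tests and an SLSQP oracle that
maximises the common cosine subject to the equal-angle constraints,
independent of the linear solve).

**Numerical choices.**

* The system is solved with minimal-norm least squares (`lstsq`). For a
  generic course it is square and nonsingular; for degenerate courses
  (collinear or repeated segment directions) it is rank-deficient, but
  the *normalised* direction of `v` is still unique and the minimal-norm
  solution recovers it. A collinear course (`X_i = i·u`) yields `v ∥ u`
  with zero residual.
* After solving, the per-segment cosines are checked against `c`; the
  maximal deviation, relative to `|c|` (floored by `|v|·1e-3` to avoid a
  vacuous check when `c ≈ 0`), is the fit residual. The default
  tolerance is 1e-8 (relative); a genuinely inconsistent system raises
  rather than returning a bad line.
* Identical consecutive stages (zero segment) are an error with advice
  to average replicates upstream — silent averaging would hide a data
  problem.
* Orientation: if the course's last stage projects below its first, `v`
  and `c` are negated, so projections increase from the undifferentiated
  to the differentiated end and positive weights mean up-regulation
  along differentiation. `λ` is reported as fitted (the sign flip is a
  property of the stored `v`, not of the solve).

## Normalisation and probe alignment

Raw intensities are log-transformed (base 2 by default; a pseudocount is
available but defaults to 0 so that silently shifted data cannot pass
unnoticed) and each sample column is centred on its own median,
dataset by dataset. Per-sample median centring is used because the
projections must be comparable across laboratories; a per-dataset global
median is exposed as a non-default option for data already centred
sample-wise. Normalisation is idempotent on log-scale data. Probes are
treated as independent transcripts; datasets are aligned by probe-id
intersection in lexicographic order (no imputation), with a warning when
the intersection drops below 90% of any input.

## The differentiation-index coordinate and distance index

Two developing lines fitted to *different* differentiation processes are
restricted to their common probes (weights subset, never re-fitted) and
used as x and y axes; each sample is placed by its two projections.
Cell-type regions are summarised by per-axis mean and sample standard
deviation (ddof = 1; a single-sample region gets sd 0 with a warning),
drawn as axis-aligned 1-sd ellipses in plots — deliberately not
covariance ellipses or Mahalanobis distances.

The distance index of a sample at point `p` is

    Di = d_ES / (d_ES + d_Fib) ,

with `d_ES`, `d_Fib` the Euclidean distances from `p` to the ESC-region
and fibroblast-region centres (the anchors, computed from *all* samples
carrying those labels). This normalised form is 0 at the ESC anchor, 1 at
the fibroblast anchor, bounded in [0, 1], and strictly increasing along
the anchor segment; the unnormalised ratio `d_ES / d_Fib` is available
via `form="ratio"` for sensitivity analyses. The pass/fail threshold is
the arithmetic mean of the ESC samples' Di; a sample exactly at the
threshold passes (boundary convention, documented as arbitrary).

## Weight significance

Weights on an oriented line are standardised against their own empirical
mean and standard deviation, tested two-sided against N(0, 1), and
adjusted by Benjamini–Hochberg FDR (via statsmodels; an independent
brute-force step-up implementation exists only in the tests as an
oracle). The parametric normal null is the simplest model consistent
with treating the weight distribution itself as the reference; a
permutation null (re-fitting on courses whose values are shuffled within
each probe across time) is provided for data where the normal null is
suspect. Selection uses p < 0.01 and FDR < 0.1 by default, with
p < 0.001/FDR < 0.1 as a second named preset; the two presets reflect
the two cutoffs in circulation for this kind of analysis, and the default
is the looser one that produces usable list sizes. Probe→gene collapse
keeps the probe with maximal |z| per symbol.

## Robustness harness

`perturb_timecourse` replaces a chosen fraction of probes' values; the
default scheme draws each replaced value from the same time point's full
empirical distribution, which destroys per-gene temporal signal while
preserving every column's marginal — the most conservative reading of
"random replacement". Within-probe permutation across time is the
alternative scheme. `robustness_curve` re-fits the line and re-projects a
test cohort for each fraction × replicate and summarises the Spearman
correlation of projections against the unperturbed baseline plus the
across-replicate projection variance. `tolerated_fraction` reports the
largest fraction whose median Spearman stays ≥ 0.95 (configurable): the
"endurance" criterion is not uniquely defined, so the figure is
meaningful in trend, not as a universal constant.

## Seesaw modules

On an undirected protein-interaction graph (two-column or BioGRID-tab2
edge lists; symbols upper-cased, self-loops dropped, duplicate edges
collapsed), every gene marked `unchanged` with at least one `up` and one
`down` direct neighbour is a linker. Linkers sharing any partner are
merged into one module (union-find), reproducing multi-linker motifs such
as one down-regulated gene bridged to one up-regulated gene through
several co-complex members; `merge=False` emits raw triplets. "Unchanged"
means present in the state map but in neither significance list — no
expression floor is imposed. Only distance-1 interactions qualify.

## Synthetic study conditions

The generators produce the minimal structure under which the model is
well specified, and their defaults are the conditions used throughout
the acceptance checks:

* `gen_timecourse`: 2000 genes, 5 stages, 100 signal genes with per-step
  drift of magnitude 1.0 (random sign) on a N(0, 1) baseline, N(0, 0.2)
  measurement noise. Drift 1.0 corresponds to a twofold change per stage
  on a log2 scale — a moderate, realistic differentiation effect —
  and noise sd 0.2 is typical residual array noise after normalisation.
  With zero noise the course is exactly collinear and the fit residual
  is 0.
* `gen_cohort`: samples interpolated as `(1−α)·X_1 + α·X_t` plus noise;
  α ≈ 0 labelled ESC, α ≈ 1 fibroblast, intermediate iPSC. Projection is
  linear, so Di is strictly increasing in α at zero noise — the
  monotonicity the coordinate is meant to expose.
* `gen_network`: disjoint planted down–linker–up paths plus uniform
  background edges, rejecting (where possible) edges that would complete
  a motif around an unplanted linker; ground truth is returned alongside.

What the generators deliberately do **not** emulate: probe-level
chemistry, batch effects, platform differences, nonmonotone or
saturating expression trajectories, and correlated gene modules. Passing
tests therefore demonstrate the model's mathematical guarantees and its
statistical behaviour under well-specified conditions, not performance
on any particular published dataset.

## Problem sizes

The test suite and acceptance script run at desk scale: 50 random
courses of 200 × {3–5} for the geometry properties, 20 generator seeds
at the default 2000 × 5 conditions for recall/FDR, and a 20-fraction ×
20-replicate robustness grid on a 2000-gene course with a 15-sample test
cohort. These sizes give stable Monte-Carlo summaries while keeping a
full run in seconds.

## Known limitations

* The model is deliberately linear: one direction per differentiation
  process. Curved trajectories are out of scope.
* Distance-index values depend on which cohorts define the anchors;
  thresholds are not transferable across anchor choices or platforms.
* The normal null for weights is a modelling choice, not a derived
  distribution; the permutation null is the fallback when it is in
  doubt.
* Replicates within a time point must be averaged before fitting.
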