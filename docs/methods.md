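# Methods

## Synthetic cohort model

Each subject's regional signal is a stationary multivariate Gaussian
process: white innovations with population covariance C are coloured by a
zero-phase Butterworth band-pass (order 4, 0.01–0.1 Hz at the configured
TR). Because the same linear filter is applied to every region, the
zero-lag correlation structure of the innovations is preserved exactly in
expectation, so C is directly the quantity the downstream pipeline
estimates. Observation noise (`noise_sd`, default 0.25) is folded into the
covariance diagonal *before* colouring rather than added as white noise
afterwards; adding broadband noise post hoc would break the band-limited
spectral contract (≥ 80% of variance in 0.01–0.1 Hz) that the analysis
assumes of conditioned BOLD data. Its effect is a uniform attenuation of
all correlations by 1/(1 + noise_sd²) ≈ 0.94.

**Base covariance.** A block-equicorrelation correlation matrix: contiguous
blocks of `block_size` = 11 regions at r = 0.30 within block and r = 0.05
across blocks, positive definite by construction. This emulates the modular
community structure of cortical networks at the coarsest useful level. The
designated behaviour edge is floored at r = 0.35 so that its |Fisher z|
weight is a monotone function of the signed correlation; without the floor
a weak edge's absolute weight would fold the sign and make a planted
negative coupling unidentifiable.

**Hub effect.** In group A, every correlation touching a hub region
(default: the six NOIs for 110 regions) is incremented additively by
`hub_effect` (default 0.25), capped at 0.95, then projected to the nearest
positive-definite correlation matrix (eigenvalue flooring at 1e−6 plus
diagonal renormalisation, two passes). Additive injection on correlations
gives direct control of the quantity the pipeline measures. An effect that
cannot be projected to a positive-definite matrix is rejected with a
message naming the offending effect size.

**Behaviour coupling.** After the signals are realised, each subject's
behaviour-edge Fisher z is computed from the clean (pre-contamination)
signal, standardised within group to z_w, and the score generated as
5 + 1.2·(ρ·z_w + √(1−ρ²)·ε) with ε ~ N(0,1) and ρ = `behavior_coupling`
(default −0.6), clipped to the 0–10 visual-analogue scale. Conditioning on
the realised weights makes the within-group sample correlation target ρ in
expectation without assuming any causal direction. Both groups are coupled
with the same ρ; setting ρ = 0 yields pure-noise scores.

**Motion and nuisance.** Motion traces are zero-start Gaussian random walks
with per-step σ = 0.03 mm/deg. At 200 volumes this puts the walk's terminal
SD at 0.42 mm, ~4.7σ below the 2 mm screen limit, so unplanted subjects
pass the screen (crossing probability ~1e−5) while `plant_motion_outlier`
can place a violation at any volume. Ventricle- and white-matter-like
signals are independent band-limited noise; both they and the motion trace
are mixed into the emitted series with random per-region loadings scaled by
`nuisance_strength` (default 0.2), so nuisance regression removes real
structure rather than being a no-op.

**What the generator does not emulate.** No haemodynamic response function,
no spatial (voxel-level) structure, no non-stationarity, no physiological
(cardiac/respiratory) noise beyond the two nuisance channels, no
inter-subject variability in the population covariance beyond sampling
noise, and no spatial autocorrelation between parcels beyond the block
structure. Passing recovery tests therefore demonstrates the pipeline's
statistical behaviour under its own assumptions, not robustness to the many
ways real BOLD data violate them.

## Signal conditioning

Order is fixed: drop initial volumes → nuisance regression → band-pass.

* **Motion screen**: fail iff any volume exceeds 2 mm translation or 2°
  rotation on any single axis, strict inequality (a volume at exactly
  2.0 passes). Per-axis absolute position is the screened quantity; a
  `framewise=True` option screens frame-to-frame differences instead, since
  field practice varies and the choice is rarely reported.
* **Nuisance regression**: ordinary least squares of each regional series
  on [intercept, 6 motion parameters, ventricle mean, white-matter mean].
  The intercept is required for well-posed residualisation. Rank-deficient
  designs are rejected with the collinear columns named. Global-signal
  regression is deliberately not offered.
* **Band-pass**: zero-phase forward–backward Butterworth, order 2 per pass
  (configurable), 0.01–0.1 Hz. Measured contract at TR 2 s: gain 0.994 at
  0.05 Hz, 0.002 at 0.2 Hz, exact DC removal, no passband phase lag.
  The filter family is the de facto standard for resting-state work and has
  a directly testable gain contract.

## Network construction

* Pearson correlations (zero-variance regions rejected by name) are clipped
  at ±(1 − 1e−6) before atanh so numerically perfect correlations yield
  finite weights; the edge weight is the absolute z.
* The backbone is the **maximum-weight spanning tree** (Kruskal over edges
  sorted by weight descending, ties broken lexicographically on the region
  index pair, so results are bit-reproducible across platforms). A
  per-node-strongest-edge variant is available behind
  `backbone_variant="per_node_strongest"` for comparison; it does not
  guarantee connectedness and is not used by default.
* The global stage retains E* = round(d·n(n−1)/2) edges (round half away
  from zero — the rounding convention is a documented package choice), the
  backbone plus the strongest non-backbone edges in order. When E* < n−1
  (e.g. 1% density on 110 regions needs 60 edges but the backbone has 109)
  the backbone is returned unchanged and flagged `sub_minimum_density`;
  preserving connectedness is the method's core guarantee and disconnecting
  to hit the count would defeat it.
* Sweeps share one backbone and one sorted edge order, so networks are
  nested across densities by construction.

## Statistics

* Degree centrality: edge count (binary) or summed retained |z| weight
  (weighted). The handshake identity Σ DC = 2|E| is asserted in tests for
  every generated network.
* Group comparison: pooled-variance Student's t, one-tailed A > B for the
  confirmatory NOI analysis; the opposite tail is always reported alongside
  for the exploratory all-region analysis. Welch's t is available by flag.
  No multiple-comparison correction by default (α = 0.05 uncorrected across
  nodes and densities); Benjamini–Hochberg columns can be requested.
  Degenerate cells (zero pooled variance with equal means) report t = 0,
  p = 0.5 rather than NaN.
* Group connectivity: exact rational fractions count/n per group, plus a
  pooled "all" panel — the within-group and pooled readings are both
  defensible, so both are emitted. Display filtering at > 10% is a view,
  not a data change.
* Edge–behaviour regression: Pearson r on pre-threshold |z| weights,
  two-sided p, the sign of r carrying direction (a one-sided convention
  would hide sign reversals).

## Test and acceptance problem sizes

Replicate-based checks run at sizes chosen to make their Monte-Carlo error
small relative to the tested margins: null calibration uses 500 cohorts of
12 + 12 subjects × 40 regions at 10% density (3% lies below the 40-region
backbone minimum of 5%, where degrees are tree degrees); hub recovery and
the binary/weighted concordance use 70 regions, the smallest round size
where 3% density exceeds the backbone minimum (n − 1 < 0.03·n(n−1)/2
requires n ≥ 67), at the full 23 + 23 sample size; behaviour recovery uses
200 replicates at 20 regions. The full-scale structural checks (edge-count
exactness, nesting, connectedness, handshake) run at 46 subjects × 110
regions × 40 densities.

## Known limitations and observed behaviour

* **Fixed-density degree compensation.** At a fixed edge budget, elevating
  hub correlations in group A necessarily removes edges elsewhere, so
  non-hub regions show *depressed* A-side degrees and the one-tailed A > B
  false-flag rate on non-planted regions sits below the nominal α (~0.001
  at hub_effect 0.25) rather than at it. Exact α-level calibration holds
  under a true null (all effects zero), where the measured per-cell
  rejection rate is statistically indistinguishable from 0.05.
* Sub-minimum densities (1–2% at 110 regions) return flagged backbones;
  how such densities could be realised without either disconnecting the
  graph or exceeding the target is left open, and the flag documents rather
  than resolves it.
* The behaviour score is one scalar per subject; aggregating multi-trial
  ratings into that scalar is the caller's responsibility.
* Atlas volumes are not bundled; `extract_regional_timeseries` accepts any
  integer-label volume, with maximum-probability label assignment assumed
  to have been done upstream.
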