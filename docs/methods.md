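# Methods

## Model

Each alternative-splicing event is observed, per sample, as junction read
counts (#inc, #exc). Conditional on a true inclusion fraction ψ, #inc is
modelled as Binomial(#inc + #exc, ψ); with a uniform prior on ψ the posterior
is Beta(#inc + 1, #exc + 1). The package treats the posterior's Monte-Carlo
draws ("emissions") as pseudo-replicates of the sample's PSI: wide when
coverage is thin, tight when coverage is deep. The +1 pseudo-counts keep both
shape parameters positive, so zero-coverage samples emit from Beta(1, 1)
(uniform — maximal uncertainty) rather than failing.

Per event, with two conditions and `n_emit` emissions per sample:

* condition PSI = median of the pooled per-condition emissions (the median of
  a pooled mixture, not the mean of per-sample summaries; with an even pooled
  length, the midpoint of the two central order statistics);
* ΔPSI = PSI_test − PSI_reference;
* p = fraction of elementwise differences of the two independently shuffled
  pooled vectors (test − reference) that are strictly > 0, an estimator of
  P(PSI_test > PSI_reference) under the two posterior mixtures. For
  single-replicate conditions this converges to the exact
  P(X > Y), X ~ Beta(inc_t+1, exc_t+1), Y ~ Beta(inc_r+1, exc_r+1), which the
  test suite verifies against a finite-sum oracle;
* call: significant iff max(p, 1−p) > `prob_threshold` and
  |ΔPSI| > `dpsi_threshold`, both strict.

The calling is deliberately direction-symmetric. The one-sided fraction p
only exceeds the threshold for positive shifts; using max(p, 1−p) applies the
same evidence standard to negative shifts, which a knockdown experiment
produces in abundance (e.g. skipped exons). The cost is a doubled
false-positive rate relative to a one-sided rule; see "Calibration" below.

### Direction statistics

Among *called* events of one type, the number with ΔPSI > 0 out of the total
is tested against a fair 0.5 with the one-sample Pearson chi-squared
proportion test with continuity correction,

    chi2 = (|k − n/2| − c)² / (n/4),   c = min(0.5, |k − n/2|),

p from chi-squared with 1 df. Capping c at the absolute deviation makes the
exact-null observation give chi2 = 0, p = 1 instead of a spurious positive
statistic. The 95% interval is the Wilson score interval computed after
shifting the point estimate by c/n toward each limit — the exact behaviour of
R's `prop.test(..., correct = TRUE)`, which the tests pin to 6 significant
digits on frozen reference output. Because c is capped by the deviation from
the *null*, the interval coincides with the plain Wilson interval when k = n/2.

The corrected test is conservative in small samples: its exact size under a
fair coin at α = 0.05 is 0.0352 at n = 100 and 0.0400 at n = 200 (computed by
binomial enumeration in the test suite, which checks the empirical rejection
rate against the exact size rather than against nominal).

## Tunable parameters

| parameter | default | units | role |
|---|---|---|---|
| `n_emit` | 500 | draws/sample | Monte-Carlo resolution of p; 500 gives SE(p) ≈ 0.013 at 3 replicates. Tests use 20000 where tight oracle agreement is asserted. |
| `prob_threshold` | 0.8 | probability | evidence cut on max(p, 1−p), strict |
| `dpsi_threshold` | 0.05 | PSI fraction | effect-size cut ("5%"), strict; the CLI flag `--min-dpsi` takes percent |
| `min_coverage` | VLOW | ordinal score | per-sample floor; an event failing it in *any* sample is dropped before emission |
| `conf_level` | 0.95 | — | Wilson interval level |

PSI is a fraction in [0, 1] everywhere internally; only table writers render
percentages (rounded half-up to 2 decimals, matching how proportions such as
805/849 → 94.82% are reported).

## Synthetic data

`simulate_dataset(SimConfig)` emulates a two-condition knockdown experiment
at the inclusion-table level:

* per event and sample, total junction depth ~ NegBin(mean `depth_mean`,
  size `depth_dispersion`), truncated at ≥ 1 by redrawing zeros; default mean
  50 and size 10 (depth CV ≈ 0.35, a moderate library-to-library spread);
* #inc ~ Binomial(depth, true ψ of that sample's condition), #exc the rest —
  exactly the sampling model whose posterior the analysis uses, so
  parameter-recovery tests are meaningful;
* control ψ uniform on [0.05, 0.95]; a fraction `effect_fraction` (default
  0.10) of events receives a signed ΔPSI drawn from `effect_sizes`
  (±0.10/0.20/0.30 by default), its sign optionally biased per event type
  (`direction_bias`, to emulate the retention skew of intron-retention events
  under spliceosome knockdown); knockdown ψ is clipped to [0.01, 0.99] and
  truth records store the post-clip delta;
* coverage scores follow fixed depth cutpoints (N < 10 ≤ VLOW < 20 ≤ LOW <
  40 ≤ OK < 100 ≤ SOK) — a package-defined dialect chosen for deterministic
  testability;
* defaults of 500 events per type and 3 + 3 replicates keep a full run in
  seconds.

What the generator does **not** emulate: overdispersion of inclusion reads
beyond binomial (no within-condition biological variance of ψ), correlated
events within a gene, mapability artefacts, library-size effects, or event
discovery itself. Passing tests therefore demonstrate correctness of the
statistical machinery under its own assumptions, not robustness to the messier
structure of real RNA-seq.

## Calibration and recovery (what the checks compute)

With 2000 null events at depth 50 and 3 + 3 replicates, the pipeline calls
≈ 5–6% of events (the acceptance run at its fixed seed measures the exact
number). This is intrinsic to the direction-symmetric rule at these depths:
the ΔPSI-of-medians noise scale and the pooled-emission spread shrink
together with depth, leaving a roughly depth-independent false-call rate that
a one-sided rule would halve. Deeper coverage does not reduce it; a stricter
`prob_threshold` or `dpsi_threshold` does. With planted |ΔPSI| = 0.30 at
depth 100, sensitivity and sign accuracy are essentially 1.

## Numerical choices

* Ties in the difference count (exactly zero) count as not positive; with
  continuous emissions they have probability ~0.
* Unequal replicate counts: both pooled vectors are shuffled, the longer is
  truncated to the shorter (subsampling without replacement), keeping the
  elementwise-difference scheme.
* Per-event RNG substreams are seeded from (master seed, sha256(event_id)),
  so results are independent of event order and stable when events are added
  or removed. All CLI randomness flows from `--seed`; an omitted seed is
  drawn from entropy and printed.
* Fractional junction counts (mapability-corrected dialects) are rejected by
  default and rounded half-to-even with a warning in lenient mode.
* Zero-coverage PSIs are an explicit NA/None marker, never 0 or 0.5.

## Limitations

* No multiplicity correction across events: calling uses fixed
  probability/effect thresholds, so the called set is threshold-calibrated,
  not FDR-controlled.
* No shrinkage across events or replicates; each event is analysed in
  isolation.
* Two conditions only; no covariates or paired designs.
* The direction test conditions on the called set; with few called events the
  corrected test is conservative (exact sizes above).
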