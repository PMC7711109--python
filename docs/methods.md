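# Methods

## Model and procedure

The pipeline treats one subject's masked fMRI series as a matrix of TR
rows by voxel columns and asks, TR by TR, which internal attention state
the pattern expresses. Three stages:

1. **State learning.** An L2-penalized multinomial logistic classifier is
   fit on TRs labeled by the Internal Attention task (five states: Breath,
   Feet, MW, Self, Sounds). The objective is
   `Σ_t CE_t + penalty · ‖W‖_F²` with `penalty = 0.01`; this maps onto
   scikit-learn's `LogisticRegression(C = 1/(2·penalty))` (lbfgs,
   tol 1e-8), and the convention is fixed here so results are reproducible
   across implementations. Validation is leave-one-block-out with
   k = n_blocks (6): blocks are the exchangeable unit, and holding out
   whole blocks prevents temporal leakage between neighbouring TRs of one
   trial. Accuracy per condition is tested against 1/K chance (20%) with a
   1-df χ² goodness-of-fit test, without continuity correction (immaterial
   at n = 432 per condition). Eligibility for meditation decoding requires
   ≥ 2 of {Breath, MW, Self} above chance with p < 0.001; both the count
   and α are configurable, since the coupling of the two thresholds is a
   convention of this implementation.
2. **Meditation decoding.** The five-class probabilities are restricted to
   {Breath, MW, Self} and renormalized rather than refitting a 3-class
   model: decoding should reuse the very signatures validated in Step 1.
   Argmax ties are broken by the fixed state order (Breath < MW < Self)
   and logged; they are measure-zero on real-valued data. Mental events
   are maximal runs of ≥ 3 identical decisions (`min_event_len`
   configurable); shorter runs are left unassigned.
3. **Attention metrics.** `percent_time` uses *all* decoded TRs (the
   decoder decides every TR), so the three values sum to 100; an
   `events_only` variant restricts the numerator to event TRs for the
   stricter reading of "time spent engaged". Event-duration SD is the
   sample SD (ddof = 1), undefined below two events. Group tests are
   two-sided one-sample / paired t-tests with Cohen's d; correlations are
   pooled via Fisher r-to-Z, excluding undefined (NaN) correlations with a
   logged count.

## Label extraction conventions

TR indices are 0-based; a TR at time `t` belongs to a trial when
`onset ≤ t − lag·TR < onset + duration` (half-open, so boundaries are
never double-counted). The default hemodynamic lag is 0 TRs because the
generator applies no hemodynamic convolution, keeping synthetic ground
truth exact; for real data a positive `lag_trs` shifts labels later.
Instruction periods (2 s audio cues) are excluded from training: they are
cues, not attention states. In preprocessing, constant voxels are zeroed
and logged rather than dropped, preserving voxel indexing for importance
maps; standardization uses the sample SD, making it idempotent.

## Importance maps

Per condition, importance = classifier weight × z-scored mean condition
activation, z-scored **across voxels** of the condition-mean vector (the
alternative, z-scoring each voxel over the condition's TRs first, sits
behind `zscore_over="time"`). The ±2 SD threshold is read as
|importance − map mean| > k·SD with the population SD of the within-map
distribution; mean-centering is the conventional reading and the center is
configurable (`center="zero"`). Group frequency maps require a shared
voxel grid — given by construction for synthetic cohorts, and requiring
prior spatial normalization (out of scope here) for real data.

## Synthetic generator: what it emulates, what it does not

The generator reproduces the *structure* of the study data: six task
blocks with exactly 72 s per condition per block, stimulus trials of
16–50 s (integer partitions of the 72 s budget into 2–3 trials, drawn
uniformly from the feasible set), 2 s instructions, TR = 1 s, four fixed
condition order sets (stand-ins, since the originals are unpublished), and
a 600-TR meditation period whose hidden state follows a first-order Markov
chain over (Breath, MW, Self). Ratings (1–4) attach to the later half of
non-MW trials, optionally coupled to trial signal quality to test the
rating–accuracy association under null and positive coupling.

Signal model: each state has a sparse Gaussian voxel pattern
(`sparsity = 0.1`, `amplitude = 1`, ~200 of 2000 voxels nonzero; pairwise
overlap controlled by mixing a shared component). A stimulus TR carries
its state's pattern as a boxcar plus i.i.d. `N(0, noise_sd²)` noise
(`noise_sd = 1` default) and an optional per-voxel linear drift. No real
SNR figures exist to calibrate against, so these defaults are calibration
choices, recorded in every generation manifest; they give a clearly
separable but non-trivial problem (null sessions decode at chance,
noise ladders degrade accuracy monotonically). The generator does **not**
model hemodynamic convolution (by default), autocorrelated or
physiological noise (respiration, cardiac), motion, or spatial smoothness
— so passing tests demonstrate the pipeline's correctness given patterns,
not its robustness to real scanner artifacts.

The meditation chain defaults to the sticky family
`P = s·I + (1−s)·1πᵀ`, which has stationary law π *exactly* (left
eigenvector check included in the tests) and mean dwell
`1/((1−s)(1−π_i))`; with π = (0.5, 0.3, 0.2) and s = 0.8 the Breath dwell
is 10 TRs. This makes percent-time recovery targets exact rather than
asymptotic.

## Demographics reporting

Each identity axis is recorded twice: free-text self-identification and a
standardized category from a fixed vocabulary (including an explicit "No
response"). Percentages are always of the full sample, one decimal;
missing answers never shrink the denominator. Composites: racial minority
= any standardized race other than White alone; sexual minority =
Lesbian/Gay/Homosexual, Bisexual/Pansexual, or Asexual. The bundled
15-record cohort is a synthetic reconstruction matching published per-axis
marginal counts exactly; the cross-axis pairing within records is
arbitrary, so axis summaries and composites are exact while cross-axis
summaries are not meaningful.

## Numerical choices and problem sizes

All randomness flows from one root seed through `SeedSequence` spawning
(per subject, per stage), giving byte-identical reruns. The test suite and
acceptance script run the property suites at the study's feature scale
(2000 voxels, 2160 training TRs, 600 meditation TRs); the chance
calibration uses 1000 simulated chance-level subjects, segmentation is
cross-checked against an independent run-length-encoding oracle on 10,000
random sequences, and parameter recovery uses 20 simulated subjects.
End-to-end orchestration tests use a reduced configuration (2 subjects,
150 voxels, 2 blocks) chosen as the smallest size exercising every stage.

## Known limitations

- Real-data preprocessing (motion correction, slice timing, registration)
  is upstream and out of scope; `load_session` expects preprocessed,
  mask-aligned NIfTI volumes.
- Group-level (cross-subject) classifier training is not implemented.
- Importance quantification beyond weight × activation (voxel-removal
  bootstraps, univariate effect sizes) is an extension point only.
- The rating simulation is a coarse ordinal mapping of a Gaussian latent;
  it supports association tests, not psychometric realism.
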