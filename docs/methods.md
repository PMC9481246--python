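# Methods

## The problem and the models

Population recordings from awake mice show that responses to repeats of
the same stimulus decorrelate over time.  `driftlab` treats this
"representational drift" as a joint function of stimulus coding and
behavioural state.  The central quantity is representational
similarity (RS): the Pearson correlation between concatenated
population vectors (N units × M one-second movie frames) for two
repeats of the same natural movie.  Within- and between-block mean RS
(CC_ws, CC_bs) summarize to the drift index
RDI = (CC_ws − CC_bs)/(CC_ws + CC_bs), and for a single repeat pair
rdi = (1 − ρ)/(1 + ρ) since the within-pair similarity of a repeat with
itself is 1.

Two families of generative models formalize how behaviour could enter.

**Gain models.**  A frozen signal vector S (one value per unit, uniform
on [0, 1]) is combined with per-repeat noise N (same distribution) and
a per-repeat gain g drawn uniformly from [0.5, 2]:
u = gS + gN, u = S + gN, or u = gS + N.  In the large-population limit
the expected repeat-pair correlation is

- unscaled / both-scaled: ρ = σ_S²/(σ_S² + σ_N²) (gain cancels),
- noise-scaled: ρ = σ_S²/√((σ_S² + g_i²σ_N²)(σ_S² + g_j²σ_N²)),
- signal-scaled: ρ = g_i g_j σ_S²/√((g_i²σ_S² + σ_N²)(g_j²σ_S² + σ_N²)),
  which → 1 as both gains grow.

σ here denotes the SD of the zero-mean part of each component; Pearson
correlation removes means, so uniform-[0, 1] draws enter with variance
1/12.  An extended gain model gives each unit a tuning T_k over an
Ns-dimensional stimulus (u_k = g·T_k s + N, defaults Ns = 10,
Np = 1000, Nr = 200); its signature is a strong coupling between a
unit's stimulus reliability and its behavioural modulation.

**Independent mixing.**  u = S_S + N + βT_B: behaviour contributes an
additive signal, the tuning vector T_B scaled by a per-repeat amplitude
β ∈ [0.5, 2].  Because T_B is orthogonal to the stimulus tuning, the
model predicts *no* relation between reliability and behavioural
modulation — the discriminating prediction against the gain family.

The marginal closed form
ρ = σ_S²/√((σ_S² + β_i²σ_T² + σ_N²)(σ_S² + β_j²σ_T² + σ_N²)) treats the
behavioural signal purely as noise; it is exact when the behavioural
pattern decorrelates between the two repeats (implemented by the
`refresh_tuning` simulator mode).  When T_B is frozen across repeats
the shared pattern also enters the covariance, giving
ρ = (σ_S² + β_iβ_jσ_T²)/√(…), exposed as
`rs_independent_frozen_tuning`.  Both forms are kept because the
package's Monte-Carlo oracle tests pair each simulator mode with its
exact expectation; the marginal form is the one that describes what a
stimulus-space analysis *sees* when behaviour varies.

A related limit connects population RS to single-unit reliability: for
responses r = r_b + r_m with fixed baselines and per-repeat random
modulation, every unit has reliability 0, yet the raw population RS is
Var(r_b)/(Var(r_b) + Var(r_m)) → 1 when baselines dominate.  Raw
(non-z-scored) population vectors therefore carry baseline-driven
similarity that z-scoring removes; both vector types are supported.

## Synthetic sessions

The generator produces sessions shaped like the Neuropixels datasets
the analyses target: two blocks of a 30-frame movie at 10 repeats per
block (a "dataset-1-like" layout; 30 repeats per block for the
"dataset-2-like" variant), separated by a gap, with 1-s bins throughout
and optional drifting-grating blocks inside the gap.

- **Latent state.**  β(t) is a stationary Ornstein–Uhlenbeck process,
  timescale 60 s and SD 0.5, plus a deterministic offset per block
  (default 0 → 1.5).  The state is thus stable within a block relative
  to the between-block step, matching the abrupt arousal transitions
  seen between presentation blocks separated by an hour.  Pupil width
  is β plus Gaussian observation noise (SD 0.1); running speed is
  max(0, 10·β + noise) cm/s, capturing the pupil–running coupling
  without locomotion dynamics.
- **Units.**  Baselines r_b are lognormal (log-mean 1.0, log-SD 0.7
  counts/bin).  Frame tuning is a rectified-Gaussian PSTH-like curve,
  standardized and scaled by r_b times a modulation index
  (exponential, mean 0.5, capped at 1.2), giving the long-tailed
  reliability distribution typical of cortex.  Behavioural tuning is
  T_B = 0.8·r_b·γ·s with γ ~ Gamma(4, ¼) (mean 1, SD ½) and sign s
  positive for 90% of units; arousal-suppressed units are attenuated
  (×0.3).  Tying |T_B| to the baseline makes arousal act on overall
  excitability, so the session reproduces the observed phenomenology:
  the leading PC tracks pupil, PC loadings track mean activity but not
  reliability, and setpoints rise with the block transition.
- **Regimes.**  `independent` (default):
  rate = r_b + tuning + T_B β.  `gain_signal`: the tuning term is
  multiplied by g(β) = exp(0.35 β) (g spans ≈ [0.5, 2] for β ∈ ±2).
  `gain_both` scales baseline and tuning together.  `gain_noise` scales
  the untuned baseline component under Poisson noise — a Poisson
  count's noise cannot be scaled independently of its mean — and
  scales the additive noise SD directly under the Gaussian noise
  model.
- **Noise.**  Counts are Poisson draws from the per-bin rate (Gaussian
  optional); rates are clipped at 0 before sampling.  In strongly
  modulated regimes ~10–20% of unit-bins rectify at low arousal; this
  is logged and is a known small bias toward positive setpoints at
  extreme parameters.

What the generator does **not** emulate: spike-timing structure within
bins, receptive-field geometry and pupil-position effects, adaptation,
non-stationary tuning (the stimulus code is frozen by construction),
and realistic pupil/running noise spectra.  Passing tests therefore
show that the *analysis* behaves as intended under the stated
statistical structure, not that real cortex satisfies that structure.

## Analysis conventions

- All correlations are Pearson; z-scoring uses the population SD
  (divisor n) over the whole session unless a window is given.
- Missing bins propagate as NaN; windowed statistics use
  pairwise-complete data and refuse to return a value when fewer than
  50% of points are present.
- Bins are aligned to stimulus onset per block; a 2-s variant
  aggregates adjacent frames without overlap.
- Pupil change between repeats is |Δ| of session-z-scored per-repeat
  means; the running-change percentile filter (default 80th) and a
  within/between-block-averages mode mirror the session-level
  regression variants.
- CC_ws pools the within-block pairs of both blocks with equal pair
  weighting; all non-identical pairs are included.
- The bootstrap shuffle is a full random permutation of time bins (100
  shuffles).  Permutation destroys all autocorrelation, which is
  conservative for slowly varying behaviour; the null false-positive
  rate at |Z| > 1.96 calibrates to ≈5%.
- SCI counts zero correlations as positive (deterministic tie-break).
- PCA runs on per-unit mean-centred (not variance-normalized) activity
  so that loadings retain their dependence on activity level; a
  z-scored option exists.  Component signs are fixed by making the
  largest-magnitude loading positive; loadings are reported normalized
  to their maximum.  The passage-of-time control refits the
  |ΔPC1|-vs-|Δpupil| regression on bin pairs closer than 10% of the
  series span.
- The frame decoder is a closed-form ridge regression (λ = 1 on
  per-unit z-scored inputs) onto 1-vs-0 frame labels.  The readout D
  is kept continuous: the discriminability
  d′ = (μ_s − μ_n)/√(σ_s² + σ_n²) needs a graded score, and a
  thresholded decision would make its statistics degenerate.
  Non-target statistics are computed per test frame (a pooled option
  exists).  Reliable units are those with ρ_k > 0.5, and reliable-unit
  comparisons require more than 10 such units.
- The behaviour decoder ridge-regresses pupil and running on per-bin
  population activity with a seeded random half-split of repeats; the
  sensory-bias check projects each repeat's N × M response onto the
  behaviour-decoder weights and averages the cross-repeat correlations
  of the resulting frame traces.

## Reproducibility and problem sizes

Every stage seed derives from one master seed through stable
string-keyed streams (`derive_seed(master, "stage-purpose")`), so
adding a stage never reshuffles earlier draws and two runs with the
same configuration produce byte-identical `report.json` (numbers are
serialized at 12 significant digits).

Monte-Carlo checks use 1000-unit populations with ≥ 200 repeat pairs,
where the sampling error of a mean repeat-pair correlation is well
below the 0.02 tolerance applied against the closed forms; the
frozen-tuning independent model is additionally averaged over five
simulations because its frozen cross-terms do not average out within a
single draw.  Session-level property checks average 3–5 independent
200-unit sessions.  Bootstrap calibration uses 2000 null units at 100
shuffles.  These sizes keep the whole suite fast while holding the
directional properties comfortably away from their thresholds.

## Known limitations

- The closed forms are large-population limits; at Np = 1000 the
  residual O(1/√Np) fluctuation is visible only in the frozen-tuning
  independent model (hence the averaging above).
- Rectification of negative rates biases low-arousal setpoints
  upward at strong behavioural tuning.
- The gain regimes at session level are one reasonable mapping of the
  abstract gain models onto count data, not a unique one; the
  repeat-level module implements the abstract forms exactly.
- Real sessions contain invalid intervals, eye-tracking dropouts and
  unit-quality churn that the generator only represents as optional
  NaN bins.
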