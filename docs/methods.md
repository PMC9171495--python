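# Methods

This note documents the models, estimators, and design choices behind
`tvconn`, and what the synthetic-data validation does and does not show.

## Time-varying MVAR model and Kalman estimator

Each trial is modelled as a time-varying multivariate autoregressive
process

    x(t) = Σ_{k=1}^{p} A_k(t) x(t−k) + e(t),

with `x(t)` the n-channel sample at time t and `e(t)` multivariate white
innovations. The coefficient matrices are tracked by the classic adaptive
Kalman formulation: the state is the stacked coefficient matrix Θ under a
random-walk transition, all channels share the regressor
`c(t) = [x(t−1); …; x(t−p)]` and one state covariance P, and a single
scalar **update coefficient** (UC) sets the state-noise level:

    e(t) = x(t) − Θ c(t)
    g(t) = P c / (cᵀ P c + v)
    Θ   += e gᵀ,   P ← P − g (cᵀP) + UC·I
    V   ← (1−UC) V + UC e eᵀ

with `v = tr(V)/n` a scalar measurement-noise proxy and V the recursive
innovation-covariance estimate.

* **UC = 1e−3 by default** (dimensionless). Larger values track faster
  changes at the price of noisier coefficients; 1e−3 localises a step
  change at 100 Hz within a few hundred milliseconds (measured by the
  validation experiments) while keeping stationary estimates within ±0.1
  of the least-squares solution.
* **Initialisation**: Θ = 0, P = I, V = sample covariance of the first
  max(10p, 50) samples. Coefficients for t < p stay at 0.
* **Forward-only filtering**: the estimate at time t uses samples ≤ t
  only (no smoothing), so estimation is causal — a property the test
  suite checks by perturbing future samples.
* The filter runs vectorised over all trials of a subject at once; with a
  21-channel, order-20 model the per-trial coefficient tensor is large,
  so batches are chunked to bound memory.

### Order selection

`AIC(p) = ln det(ε̂) + 2β²p/α` with β the channel count and α the number
of samples in the full trial window. The scan covers p = 2…20 (quick
profile: 2…4), the score is averaged over trials, one order is selected
per subject, and ties break toward the smaller order. ε̂ comes from an
ordinary least-squares VAR(p) fit — deterministic and much faster than a
Kalman refit per candidate, and equivalent for the purpose of ranking
orders. Exactly singular covariances (e.g. after common-average
referencing, which removes one signal dimension) are handled by flooring
eigenvalues at 1e−10·λmax; the floor shifts ln det by a near-constant
across candidate orders, so the argmin is unaffected.

## ADTF

The frequency-domain coefficient matrix is
`Ā(f,t) = I − Σ_{k≥1} A_k(t) e^{−j2πfkΔt}` (the zero-lag term −I folded
into the identity — the standard sign convention, which makes an empty
model give H = I), and `H(f,t) = Ā⁻¹`. The normalised squared ADTF is

    r²_ij(f,t) = |H_ij(f,t)|² / Σ_m |H_im(f,t)|²,

so every row sums to 1 by construction. The band summary
`Θ²_ij(t)` is the **arithmetic mean** of r² over the grid bins inside the
analysis band (8–30 Hz, 1 Hz spacing, 23 bins by default); the mean
rather than a (f2−f1) denominator keeps Θ² in [0, 1] and preserves the
row normalisation. Diagonals are computed and kept in Θ² but excluded
from thresholding and graph metrics.

ADTF measures *total* directed flow, direct plus cascaded: coupling
1→2→3 produces nonzero Θ²₃₁. This matters for interpretation and for
generator design (below).

### Onset latency

`adtf.onset_crossing_time` localises a coupling switch as the first time
the (0.2 s-smoothed) Θ² trace stays above half its post-onset plateau for
0.25 s, excluding the first second of the trial where the zero-initialised
filter produces transient estimates. With default UC at 100 Hz, a step
onset is localised within ±0.5 s in ≥80% of seeded replicates.

## Networks and global efficiency

Trial-averaged Θ²(t) is binarised at a fixed connectivity cost: the
`round(cost·n(n−1))` strongest off-diagonal weights become edges
(deterministic tie-break by weight, then source, then target index). At
the full-scale montage (n = 21) the default 5% cost keeps exactly 21
directed edges. Directed global efficiency is

    GE = (1/(n(n−1))) Σ_{i≠j} 1/d_ij,

with hop-count shortest paths on the binary graph and unreachable pairs
contributing 0; GE(complete) = 1, GE(empty) = 0. The implementation uses
`scipy.sparse.csgraph`; tests verify exact agreement with an independent
brute-force BFS on random digraphs. Network snapshots for topology
inspection are taken every 1.5 s (nearest grid sample); the GE *series*
used for statistics is computed on a dense 0.1 s grid over the task
window, skipping the first 0.5 s after onset where the adaptive filter is
still reacting to the rest→task switch.

## Statistics

* **Edgewise contrasts**: two-sided Wilcoxon rank-sum per off-diagonal
  edge; exact null distribution when both groups have ≤10 subjects and no
  ties, tie-corrected normal approximation otherwise; two identical
  constant samples give p = 1. Uncorrected p-values by default with an
  optional Benjamini–Hochberg flag (both behaviours serialised).
* **Group GE**: rank-sum on per-subject task-window mean GE (conditions
  of the same subject are averaged first), with the direction of the
  median difference.
* **Severity classes**: half-open FMA intervals severe [0,20),
  moderate [20,40), mild [40,60], so every score maps to one class.
* **GE–FMA**: Pearson r over patients between FMA and the subject mean GE
  (task window, both conditions), with its two-sided p.

## Synthetic data: what it emulates and what it does not

The generator emulates the study conditions of a KMI experiment:
21-channel 10–20 montage, 1000 Hz recordings, trials of 4 s rest + 6 s
task, 30 trials per class, groups LS/RS/HC (7/5/9), FMA scores on
[0, 60], and amplitudes of a few tens of μV (innovation SD 5 μV).

* **Channel dynamics** are damped AR(2) oscillators resonant at 15 Hz
  (mid analysis band) with a 50 s⁻¹ amplitude decay rate — beta-band-like
  bursts whose power lies where the analysis looks.
* **Dynamics are defined at the 100 Hz analysis rate** (so a lag-1
  coupling is a 10 ms cortico-cortical delay) and band-limit upsampled to
  the recording rate. A near-unit-pole MVAR with meaningful coupling
  defined directly at 1000 Hz per-sample lags would be numerically
  unstable and physiologically wrong.
* **Task coupling** is a directed ring over all channels with edge
  strengths graded linearly from 1.0 down to 0.7 of the subject's
  coupling gain, switching on at stimulus onset (step by default, linear
  ramp optional). The grading is what links coupling *magnitude* to
  network *topology*: as the gain rises, successively weaker ring edges
  emerge from the estimation noise floor, the fixed-cost binarised
  network completes more of the ring, and global efficiency rises.
  Validation measured this response to be monotone for gains in
  ≈[0.10, 0.35] and non-monotone above (strong cascaded ADTF flows start
  displacing weak direct edges from the edge budget), so the planted
  gains live on the monotone branch:
* **Planted FMA link**: patient gain = 0.12 + 0.2·(FMA/60) ∈ [0.12, 0.32];
  healthy controls sit at 0.32. Slope 0 generates null cohorts. The
  stability gate (companion spectral radius < 1 per schedule segment,
  margin ≈0.95 at the largest gains) rejects any unstable configuration.
* **Every simulation** discards a 10·order-sample burn-in, and all
  randomness derives from explicit seeds (identical seed ⇒ identical
  bytes).

Not emulated: volume conduction, lead fields and reference-electrode
physics, eye/muscle artifacts, inter-subject montage variability,
non-stationary background rhythms. Consequently, passing tests show that
the *estimation and statistics chain* recovers planted directed structure
under its own model class — not that the pipeline is robust to the mixing
and artifact structure of real scalp EEG.

Two preprocessing stages are therefore configured off in the synthetic
profiles: re-referencing (the synthetic channels share no physical
reference to remove; subtracting a 3-channel mean would inject strong
instantaneous mixing) and narrow-band filtering (the generator is already
band-limited, and filtering before MVAR estimation is a documented source
of spurious directed structure). Both stages remain active for real
recordings and are unit-tested on their own contracts.

## Profiles and problem sizes

The default configuration reproduces the full study conditions (21
channels, 1000 Hz, 30 trials/class, order scan 2–20, cost 5%). The
**quick profile** used by the test suite and validation experiments is a
scaled-down cohort in the same generative family: 3 channels at 100 Hz, 6
trials per class, order scan 2–4, cost 0.5 (3 of 6 possible edges — the
5% rule would keep zero edges on 3 nodes), Θ² evaluated on a 10 Hz grid.
The effect-recovery experiments run 50 planted and 50 null cohorts of 12
patients each at this profile.

## Numerical choices and degenerate inputs

* Zero-phase 4th-order Butterworth band-pass (per direction); band edges
  validated against Nyquist.
* Resampling via polyphase FIR (`resample_poly`), rational-ratio
  approximation for non-integer factors.
* Artifact rule: absolute amplitude |x| > 70 μV on any retained channel
  rejects the trial (an amplitude gate, not peak-to-peak); rejecting every
  trial is an explicit error.
* Θ² normalisation refuses all-zero rows; Ā singular at some (f, t)
  raises with the offending frequency and time.
* A cost that rounds to zero edges warns and returns the empty network;
  disconnected node pairs contribute 0 to GE rather than erroring.
* Epochs are closed-left/open-right ([−4, 6) s at fs ⇒ exactly 10·fs
  samples); snapshot times map to the nearest grid sample.
* The manifest checksums `.npz` outputs over their logical content
  (member names, dtypes, shapes, bytes), making manifests byte-identical
  across reruns regardless of archive metadata.

## Known limitations

* EDF export requires an mne EDF backend; absent one, the documented
  `.npz` + JSON-sidecar container is the write format (EDF/BrainVision
  reading is unaffected).
* The Kalman filter estimates one model per trial; multi-trial joint
  estimation and smoothed (non-causal) variants are out of scope.
* Group contrasts are computed per snapshot time point; no
  cluster-based or time-pooled inference is provided.
* The GE–FMA link in the generator is monotone but not exactly linear;
  Pearson r against a planted "true" correlation is therefore a design
  target, not a calibrated equality.
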