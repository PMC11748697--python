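# Methods

## The problem being modelled

A gesture decoder for myoelectric control is trained on surface EMG recorded
while a participant holds grasps, and is then expected to work while the arm
moves through space. Arm translation changes the recorded signal — muscles
shift under the electrode ring and different static postural activity is
required to hold the arm up — so a decoder trained at one position loses
accuracy at another. The package reproduces the structure of that study
design: a two-day protocol over a 3×3 grid of forearm orientations, flat
per-position decoders, cross-position transfer, and a hierarchical
(position, grasp) classifier.

## Acquisition protocol emulated by the simulator

One *trial* is a 5 s grasp hold sampled at 2 kHz on 16 EMG channels and 18
glove sensors. Five consecutive trials of one (position, grasp) pair form a
*block*; a *session* records every pair of one day's position set (five
positions × six grasps, so 30 blocks / 150 trials) in a seeded
pseudorandomised block order; each day holds two sessions. Day 1 uses the
plus-shaped position subset {2,4,5,6,8}, day 2 the cross-shaped {1,3,5,7,9};
only the neutral position 5 repeats across days. Grasp labels 1–6 are power,
lateral, pointer, tripod, open and rest; rest is simulated as a genuine
low-amplitude class, not as absence of signal, because it is one of the six
decoded classes.

## Signal model

Per channel c, with position p and grasp g:

    emg_c(t) = (1 + δ·u[p,c]) · A[g,c] · n_c(t)          (grasp activity)
             + δ · τ · v[p,c] · m_c(t)                   (postural tone)
             + a_pl · sin(2π f_pl t + φ_c)               (mains interference)
             + dc_c                                      (electrode offset)

* `n_c`, `m_c` — independent unit-variance Gaussian carriers band-limited to
  20–450 Hz with the same Butterworth design the preprocessing uses (one
  filter implementation, fewer code paths).
* `A` (6×16, `amp_profile`) — grasp amplitude profiles: smooth bumps of
  distinct centre, width and height over the electrode ring on a 0.15
  baseline; rest is 0.08 uniform. Per participant the profile is jittered
  multiplicatively (5% Gaussian, seeded) so simulated participants differ.
* `u[p]` (`shift_pattern`) — a smooth bump over the 16-channel ring,
  circularly shifted by an offset derived from the position's grid row and
  column (the neutral centre position gets the unshifted bump). This mimics
  apparent muscle displacement under arm rotation without claiming
  physiological fidelity.
* `v[p]` (`tone_pattern`) — fixed non-negative random per-position channel
  patterns (constant internal seed; they are part of the model definition).
  The postural-tone term represents the static muscle activity needed to
  hold each arm position and is deliberately *grasp-independent*. It is also
  what makes the position linearly decodable: the multiplicative term alone
  only ever exposes position information multiplied into grasp amplitudes,
  and because the grasp profiles, the ring bump and their products are all
  smooth patterns on the ring, a linear 9-class position encoder cannot
  disentangle them (it saturates near 25% accuracy at any δ). Random tone
  patterns put position energy outside that smooth subspace, so the
  documented recovery property (below) holds by design.
* δ (`shift_magnitude`, default 0.3) scales *both* position-dependent terms;
  δ = 0 makes every position share one signal distribution per grasp. The
  real effect size is not quantified anywhere, so the default is an
  arbitrary moderate value; experiments that study the shift set δ
  explicitly. τ (`postural_tone`, default 0.5) sets the tone-to-activity
  ratio.
* Mains: 50 Hz at amplitude 0.1 with random per-channel phase, so the
  un-notched spectrum shows a dominant 50 Hz line. DC offsets default to a
  small per-channel ramp so offset correction is exercised.

Glove channels relax exponentially (τ = 0.3 s) from a rest posture toward a
grasp-specific 18-sensor target; sensor noise is generated at ~100 Hz and
step-upsampled to 2 kHz, matching how a real data glove is upsampled to the
EMG rate.

Determinism: every trial's draw is seeded from
(seed, participant, day, session, block, trial) via `SeedSequence`, so a
session is bit-reproducible and independent of which trials are actually
synthesised (position-filtered simulation yields identical records).

## Preprocessing and features

4th-order Butterworth band-pass 20–450 Hz, then a 50 Hz notch (Q = 30 — a
European mains frequency; the recording-site frequency is configurable),
then per-channel mean subtraction. Filtering is causal by default, matching
signals processed while being recorded; zero-phase filtering is an option.
Trials are cut into 128 ms windows with 50 ms stride (floor((T−w)/s)+1
windows; the trailing remainder is dropped — 98 windows per 5 s trial at
2 kHz). The parameters file written with each session carries the 150 ms
window size of the published metadata; the analysis default of 128 ms
follows the validation settings and both are configurable.

Each window yields the Hudgins set per channel — MAV, zero crossings, slope
sign changes, waveform length — concatenated channel-major into 64
dimensions, so all four features of a sensor form a contiguous block.
Deadbands for ZC/SSC default to 0 (published pipelines rarely state them)
and are exposed. All window samples share the trial's grasp label; the
majority-vote labeller is retained for generality and tested on mixed
inputs.

Normalisation is a per-feature-dimension z-score fit on training windows
only and reused on held-out windows (constant dimensions map to 0 with a
warning). "Per sensor" could alternatively mean sharing statistics across a
channel's four features, but those features live on very different scales,
so per-dimension is the default.

## Decoding experiments

The engine is pooled-covariance LDA with ridge default 1e-6·trace(Σ)/dim
(64-dimensional features from a few thousand windows can be near-singular
per class; ridge 0 raises with a remediation hint). Ties in the argmax
resolve to the lowest class label.

Splitting is always by trial — windows of one trial never straddle the
train/test boundary — with stratified 5-fold CV, so each fold holds out 20%
of trials. Sessions are processed separately; per-participant numbers are
fold means averaged over the participant's sessions, and scenario-level
mean/σ aggregate across participants.

* *Within-position*: one 6-grasp LDA per position.
* *Transfer*: cell (s,t) trains on the source position's 80% training
  portion of a fold (not 100%, so diagonal and off-diagonal cells are
  comparable) and tests on the target position's held-out fold. The
  diagonal therefore reproduces the within-position protocol on identical
  folds. The OVR column pools every off-diagonal test window of its row
  (micro average over counts).
* *Position-per-grasp*: a 5-class position LDA per grasp within one day's
  configuration.

## Hierarchical multi-label classifier

Both day configurations are merged into one 9-position dataset per
participant (day-1 and day-2 recordings of the same session index are
paired; position 5 is taken from the plus configuration by default, the
source is a flag). The split is the same trial-wise 5-fold CV, stratified on
the joint (grasp, position) label. E_p is fit on (x, z); each grasp encoder
E_g:n is fit on the ground-truth z = n samples augmented with norm(n), where
norm(z) = (z−1)/8 maps the position label to [0,1] (a one-hot context is
available by flag). At test time z′ = E_p(x) routes the sample to E_g:z′,
which sees x ⊕ norm(z′) — the hierarchy constraint holds by construction and
is still audited by recording the routing encoder of every prediction.

Strict accuracy counts pairs with y′ = y and z′ = z; the soft metric keeps
the same predictions and routing but freezes the position condition,
counting y′ = y only. Logically strict ≤ min(soft, E_p accuracy) on any
prediction set. An oracle-routing mode (route by true z) exists as a
diagnostic, not as the default. σ aggregates across participants of
fold-pooled values.

## Problem sizes used by the shipped checks

The test suite exercises protocol-scale signals (2 kHz, 5 s, 150-trial
sessions) where the property under test needs them — e.g. within-position
accuracy across 8 simulated participants and 5 generator seeds, transfer
gaps at δ = 0 and δ = 1, and the hierarchy run at δ = 1 with two
participants — and reduced trials (1 kHz, 1 s) for unit-level checks where
only the arithmetic matters. `scripts/acceptance.py` uses 4 participants
for the within-position block and 2 participants for the transfer,
position-per-grasp and hierarchy blocks, one session each; these sizes are
the package's chosen defaults for a quick, deterministic end-to-end
reproduction.

## What the simulator does and does not show

The generator reproduces the *statistical* structure the decoding
experiments rely on: grasp-specific amplitude patterns, a controllable
position-dependent distribution shift with both multiplicative and additive
components, mains interference, DC offsets, participant-to-participant
variation, and the exact trial/block/session bookkeeping. It does not model
motor-unit physiology, fatigue, perspiration, electrode drift, day-to-day
electrode repositioning, or transitional movement segments, and its default
class separation is easier than real recordings — within-position
accuracies near 1.0 and the near-ceiling hierarchy numbers say that the
pipeline is correct, not that real data behaves this way. On real
recordings the same code paths apply unchanged via the session-folder
reader; expect lower numbers and a position encoder far from ceiling.

## Degenerate inputs and numerical choices

Empty grasp/position sets, invalid days, unknown labels, inconsistent
record identities, single-class strata, missing positions in the hierarchy
merge, and windows shorter than the descriptor support all raise
`ValueError` with the offending trial or stratum named. Filter attenuation
is characterised on the steady-state portion of a tone (causal-filter
startup transients are excluded). Trial matrices are stored as 64-bit
floats; the HDF5 trial keys are zero-padded decimals so lexicographic order
is numeric order, and the reader falls back to plain-decimal and
numerically sorted keys for third-party files.
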