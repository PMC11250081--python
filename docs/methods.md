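# Methods

`dystonia-screen` implements a video-kinematics screening method for
musician's dystonia (MD) in pianists, together with the two companion
measurements used to characterize the disorder outside the instrument: the
left–right asymmetry of finger biomechanics, and the tactile temporal-order
judgment threshold (TOJT). This note documents the models, the parameters
that matter, the numerical choices, and what the synthetic data does and
does not establish.

## One-class detection of dystonic playing

### Model

The unit of data is one performance trial, reduced to a fixed-shape tensor:

1. **Trial window.** The playing span is delimited from the key-displacement
   record: from the first time any key's displacement rises through a press
   threshold to the last time any key falls through a release threshold.
   Defaults are 0.5 mm (press) and 0.3 mm (release). The hysteresis pair is
   far above the 0.01 mm sensor quantization and far below the ~10 mm key
   travel, so the window is insensitive to sensor noise yet within ~2 ms of
   the true excursion boundaries for realistic key-attack speeds.
2. **Time normalization.** Each of the 63 landmark-coordinate channels
   (21 MediaPipe-style hand landmarks × x, y, z) is resampled independently
   by a natural cubic spline onto 128 uniformly spaced times spanning the
   window, giving a 21 × 3 × 128 tensor. Spline interpolation is exact at
   the input frames, so an already-uniform 128-frame segment is reproduced
   sample-for-sample, and endpoint values are always preserved. The
   normalization is identical for every trial regardless of tempo condition;
   tempo information is therefore deliberately absent from the tensor, and
   the detector sees movement *shape*, not speed.
3. **Handedness.** Left-hand trajectories are mirrored (x → 1 − x) before
   tensorization so one model serves both hands; this matches the
   mirror-image fingering of bimanual performance. A flag disables it.

The detector is a **convolutional autoencoder trained only on healthy
pianists' tensors**. An autoencoder trained to reproduce its input through a
bottleneck reconstructs data like its training distribution well and
anything else poorly; the mean-squared reconstruction error is therefore an
anomaly score, with no patient data needed for training. Convolutions are
used (rather than dense layers) because dystonic playing disrupts
spatiotemporal coordination of *adjacent* fingers and joints, and the
landmark index order approximates anatomical adjacency — a convolution over
the (landmark × time) grid preserves that neighbourhood structure.

The network is a 7-layer convolutional encoder and a 7-layer convolutional
decoder over the 21 × 128 grid with the three coordinates as input
channels. All kernels are 3 × 3 with same padding; the encoder channel
schedule is 8-8-16-16-32-32-4 with time-stride 2 on layers 1, 3, 5, 7 and a
landmark-stride 3 on layer 3, giving a 4-channel 7 × 8 bottleneck (a
224-dimensional latent code for the 8 064-element input, a ~36× 
compression). The decoder mirrors the encoder with nearest-neighbour
resize-convolutions; the final layer is linear. This is a deliberately
CPU-scale architecture: it trains to convergence on a cohort of ~10³
augmented tensors in minutes on one core while keeping the 7+7 structure
and the coordinate-as-channel convolutional reading of the data.

Training minimizes mean-squared reconstruction error with Adam
(lr 10⁻³, batch 16, float32), stopping when the patience-window (20-epoch)
moving average of the epoch loss stops improving by more than 10⁻⁶, or at
300 epochs. The implementation is plain numpy (convolutions as nine
shifted-slice matrix products, hand-derived backward pass, checked against
finite differences in the test suite) and is exactly reproducible for a
given seed.

### Calibration and decision rule

Healthy participants are split 80/20 **at the participant level** — no
subject contributes to both sides — because trials of one subject are
correlated through their personal movement template; a trial-level split
would leak subject identity into validation and overstate specificity.
Training includes augmentation by default (two copies per tensor: in-plane
rotation ±10°, anisotropic scaling 0.9–1.1 about the image center,
emulating camera-mounting deviations). Besides mounting robustness,
augmentation acts as a strong regularizer here: it roughly halves the
reconstruction error on *unseen* participants and shrinks the
between-subject error spread, which matters because the threshold is built
from validation errors of only ~4 held-out subjects — without it, a single
hard-to-reconstruct validation subject can inflate the SD and starve the
detector of sensitivity. Augmented copies are generated from training-set
participants only, and validation errors are computed on unaugmented
tensors.

The anomaly threshold is the **mean + 2 sample standard deviations**
(n − 1 denominator) of the validation reconstruction errors; a trial is
abnormal iff its error *strictly exceeds* the threshold. Under a Gaussian
error distribution this rule fixes expected specificity at Φ(2) ≈ 97.7%
independent of the error scale — the test suite verifies 97.0–98.2% on
10 000 simulated errors. Sensitivity is the fraction of patient trials
flagged abnormal, specificity the fraction of healthy trials passed as
normal; both are computed per pianistic task, since different tasks expose
dystonic symptoms to different degrees, and a task whose sensitivity does
not exceed the 50% chance level is flagged as uninformative. One model and
threshold are calibrated per task (a pooled mode exists behind a flag).

Calibration records (error mean, SD, threshold, split/init/augmentation
seeds, config echo) are serialized as diffable JSON next to the weights.

## Hand-asymmetry statistic

Six per-finger functions are scored per hand:

| function | definition | units |
|---|---|---|
| strength | maximum voluntary press force per finger | N |
| reduction ratio | force per finger during all-finger simultaneous press ÷ that finger's maximum | – |
| independence | 1 − (sum of non-instructed fingers' force ÷ designated finger force), floored at 0, from a 20%-MVC 5 s hold | – |
| agility | taps in a 5 s fastest-tapping trial ÷ 5 s | taps/s |
| ROM flex/ext, abd/add | finger range of motion from external angle sensors | deg |

The sustained-hold summary force is the mean over the central 3 s of the
5 s hold (1 s transients trimmed at each end). The independence formula is
the individuation-consistent reading — enslaved force relative to the
instructed finger's force — so 1 is perfect individuation and 0 means the
other fingers produced at least as much force as the instructed one.

Because patients differ in which hand is affected, the group-level statistic
is the **left–right asymmetry** of each function: scores are z-scored per
function per finger against the healthy cohort pooled over hands (pooling
keeps both hands on one scale, which the difference requires), and

    Assym = ‖ z_L − z_R ‖

is the Euclidean norm over the five-finger difference vector. Assym is
invariant to hand swap and to any common permutation of fingers, and zero
iff the two hands have identical z-profiles.

Groups are compared per function with the **Mann–Whitney U test** (midranks
for ties; exact permutation null enumerated for pooled n ≤ 12, normal
approximation with tie correction above — without continuity correction,
which at n = 20 vs 16 makes the two-sided rejection region coincide with
the exact test's) and **Benjamini–Hochberg** step-up correction across the
family of functions tested in one invocation, at α = 0.05.

## Temporal-order judgment threshold

Two tactile stimuli are delivered to the index and middle fingertips with a
stimulus-onset asynchrony (SOA); the observer reports the order. The
psychometric model is a cumulative Gaussian in log₁₀-SOA with guess rate
0.5 (two-alternative judgment) and lapse rate 0.02:

    P(correct | soa) = 0.5 + (0.5 − λ) Φ(β (log₁₀ soa − log₁₀ θ))

ZEST maintains a discrete posterior over candidate thresholds θ on a
61-point log-spaced grid over 1–500 ms, starting uniform, places each trial
at the log-domain posterior mean snapped to the grid (so the SOA shortens
after correct and lengthens after incorrect responses), and performs a
Bayes update with the trial outcome. Sessions run a fixed 40 trials. The
reported TOJT is the SOA at which the final posterior-mean psychometric
curve crosses 75% correct, which has the closed form
θ̂ = 10^(μ + Φ⁻¹((0.25)/(0.5 − λ))/β). Default slope β = 3 per log₁₀-ms.

Hardware stimulation is replaced by a simulated-observer abstraction plus a
session-log replay interface for real data.

## Synthetic data: what it emulates, and what it does not

No recordings are distributed with the method, so the generators emit the
study's data structures at its recording specifications (60 Hz landmarks in
normalized image coordinates with C4 centred; 1 kHz / 0.01 mm key traces;
11 tasks — single-note sequences at 100 bpm, chord sequences at 80 bpm,
with representative note sequences per category since exact task notes are
not published).

The healthy kinematic template is a *schematic articulated hand*: a wrist
anchor translating along the keyboard with the note sequence, five finger
chains, and a keystroke dip of the assigned fingertip synchronized to each
key excursion, with per-subject amplitude/hand-size/timing offsets
(template, keyed by subject id) and Gaussian landmark noise (SD 0.003
normalized units ≈ 4 px at 1280-pixel width — visible but not
class-dominating). The dystonic perturbation scales continuously with a
severity parameter in [0, 1]: sustained flexion bias of affected
fingertip/DIP/PIP landmarks toward the key plane (0.03 normalized y units
at severity 1 ≈ 2–3 cm of fingertip curl at the study's 1.3 mm/px scale),
loss of half the keystroke lift, timing jitter (SD 20 ms at severity 1),
and co-movement coupling of adjacent fingers (0.4 of the affected dip).
Severity 0 reproduces the healthy trial bit-for-bit. Affected-finger
patterns are drawn from a vocabulary mirroring the clinical variety
(index+middle flexion, single-finger flexion, etc.).

Biomechanical cohorts draw healthy scores Normal(reference mean, SD) per
function/finger/hand; the dystonic cohort's affected hand (right with
clinical frequency 14/16) is shifted on the two multi-finger-control
functions by default (−1.0 SD reduction ratio, −1.5 SD independence),
mirroring the finding structure that strength, agility and ROM are intact.

**What passing tests show:** the pipeline is internally correct (windowing
matches ground truth, resampling is exact where exactness is provable, the
threshold rule has its designed specificity, the statistics match exact
oracles) and the *method* can separate keystroke-locked healthy structure
from flexion-type perturbations at realistic noise levels.
**What they do not show:** performance on real video. The schematic hand
has no pose-estimation failure modes (occlusion, identity swaps, depth
error), its inter-subject variation is low-dimensional by construction, and
the dystonic perturbation is the generator's own definition of the symptom —
real sensitivities/specificities cannot be inferred from the synthetic
ones.

## Experiment scales and numerical choices

- End-to-end screening experiment: 20 healthy subjects × 8 trials of the
  arpeggio-with-black-keys task analog (≈380 tensors after augmentation);
  16 dystonic subjects × 8 trials at severity 0.8; one ~200-epoch training
  on one CPU core (several minutes). Expected outcome: sensitivity above
  the 50% chance criterion and validation specificity ≥ 80%.
- Severity sweep: 50 trial seeds × severities {0, 0.25, 0.5, 0.75, 1},
  scored under the already-trained model; mean error must be nondecreasing.
- Asymmetry calibration: 1 000 null cohorts (family-wise false-positive
  rate ≈ 5% at α = 0.05, the Simes identity for the BH step-up under the
  global null) and 200 shifted cohorts (power > 80% for the −1.5 SD
  independence shift at n = 20 vs 16).
- ZEST recovery: 100 sessions × 40 trials; session-mean estimate within
  ±15 ms of a 60 ms observer; one-grid-step recovery for a step-function
  observer with a matched sharp model (with a mismatched moderate-slope
  model the fixed criterion offset of ~4% plus placement hover can exceed
  one grid step — the matched model is the meaningful sharp limit).
- Ties in the exact Mann–Whitney null are handled by enumerating midrank
  assignments; two-sidedness is by distance from the null mean n₁n₂/2,
  which is exact for the symmetric null and well-defined under ties.
- Windowing intervals are closed; timestamps are seconds; frames and key
  indices 0-based (C4 = key 39 of the 88-key range A0..C8).
- Degenerate inputs raise typed errors rather than warnings: fewer than 4
  frames in a window (spline underdetermined), all-zero key traces, single
  participants at split time, fewer than 2 validation errors at calibration
  time, zero reference SDs, out-of-grid SOAs, all-zero priors.

## Known limitations

- The numpy autoencoder is single-core and unsuitable for cohorts beyond
  ~10⁴ tensors; the architecture is fixed-shape (21 × 3 × 128).
- The generator's hand is kinematic, not dynamic: no key-force coupling, no
  occlusion, no pose-estimation artifacts.
- Only whole-trial normalization is implemented (no per-keystroke
  sub-segmentation), matching the method's design.
- Severity grading, saliency explanations (e.g. Grad-CAM-style maps) and
  alternative one-class models are out of scope.
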