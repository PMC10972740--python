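# Methods

`twocap` analyzes sessions of the two-way cued access protocol (2CAP), a
shuttle-box task in which a 4 s visual CS+ on one side of the chamber
predicts that, after a 1 s delay, an alcohol sipper descends for 8 s. The
CS− illuminates both sides and predicts no access. Each session interleaves
48 CS+ and 48 CS− trials. On *congruent* sessions alcohol is on the CS+
side; on *incongruent* sessions it is opposite. The analytic goal is to
distinguish two control strategies: *proactive* control, in which the
side/goal representation is carried in advance of movement (cue-locked
population activity, pre-approach left/right separation), and *reactive*
control, in which it is generated at stimulus time (sipper-locked activity,
post-approach separation).

## Behavioral pipeline

Pose tables carry four body points (snout, head cap, back, tail) and six
static landmarks (four corners, two sipper ports) at 30 frames/s, with a
per-frame tracker likelihood. Frames below the likelihood floor (default
0.90) are replaced by linear interpolation between the nearest flanking
confident frames; edge frames take the nearest confident value, replaced
frames get likelihood set to the floor and are flagged imputed. The floor
is interpreted as the tracker's [0, 1] confidence score.

An **approach** is the first frame the snout comes within 9 px (Euclidean,
uncalibrated pixels) of a sipper-port landmark during the access window
`[sipper_in, sipper_out]`. A CS+ trial is *correct* when the alcohol port
is visited first, *incorrect* when the other port is visited first (the
later correct-port entry is still recorded, since animals typically correct
and drink), and an *omission* when neither port is entered. Latencies run
from sipper descent; port visits during the cue but before the sipper
descends are ignored for latency. CS− trials are scored approached /
not-approached over the equivalent virtual access window, which feeds the
CS discrimination ratio CS+ approaches / (CS+ + CS− approaches), counting
both correct and incorrect approaches as CS+ approaches (0.5 = chance).
Approach probabilities are 3-trial centered moving averages with shrinking
edge windows (edge handling is our choice; no convention is standard).
Epoch speeds are |net change of snout-to-sipper distance| divided by epoch
duration for PreCue `[cue_on−4, cue_on)`, CueOn `[cue_on, sipper_in)` and
SipIn `[sipper_in, sipper_out)`, with 5-trial block means over CS+ trials
1–15.

## Firing rates

Sorted units are kept when their ISI-violation fraction (ISIs < 2 ms) is
strictly below 5%. Rates are binned at 100 ms and smoothed per neuron with
a Gaussian kernel of width sigma = sqrt(mean ISI) × (1/CV) seconds, where
CV is the sample (n−1) coefficient of variation of the ISIs. The formula
is evaluated with the mean ISI in seconds despite its odd dimensional form;
a configurable switch is unnecessary because the cap dominates the regime
where the two readings diverge. Sigma is capped at 2 s, and a CV of 0
(perfectly regular unit) falls back to the cap. The kernel is truncated at
±3 sigma with renormalized mass, so smoothing is linear and conserves spike
count away from the window edges — both properties are tested.

Bin centers sit on the 100 ms grid and include both window endpoints, so
the cue-centered window [−4, 18] s yields exactly 221 bins (the half-open
convention would give 220; the inclusive convention is the one consistent
with the printed bin count). Cue-centered tensors use the first 15 CS+
trials of the session — CS+ rather than all trials, because the analyzed
window is built around the CS+ trial structure and CS− trials have no
sipper events. Approach-centered tensors use [−2, 2] s around the correct
approach.

The modulation index is our construction (the comparison it supports is
stated elsewhere only at the level of proportions): index =
(r_post − r_pre)/(r_post + r_pre) from mean rates in 1 s windows around the
event, significance by a Wilcoxon signed-rank test across trials at
alpha = 0.05. Units silent in both windows are flagged untested.

## Population geometry

Both PCA strategies treat units as variables and timepoints as samples;
each unit's mean over timepoints is removed before decomposition, and every
component's sign is fixed by forcing its largest-magnitude loading positive
(sign indeterminacy would otherwise scramble left-minus-right difference
signs). With unit-norm loadings, duplicating every unit row leaves the
explained-variance spectrum unchanged and rescales scores by sqrt(2); this
is the invariance the tests assert.

*Cue-centered*: per session, trial-average the first 15 CS+ trials into a
units × 221 matrix; stack one strain's congruent and incongruent sessions
vertically; decompose. *Side-concatenated*: per session, trial-average up
to 15 correct left and 15 correct right approaches over [−2, 2] s;
concatenate left|right in time (units × 2M); stack both strains' sessions
within a session type; decompose; split scores back into halves. The
approach falls at the midpoint bin (index M//2). Because units are pooled
across sessions by stacking, the decomposition yields a single shared score
set per session type; single trials are projected by subtracting the
per-unit column means and multiplying by the coefficient rows of that
trial's units (the standard score map, exact when one session per condition
is analyzed).

Components are retained by the broken-stick rule b_k = (1/p) Σ_{i=k..p} 1/i
(keep the leading run with explained fraction > b_k; stop at the first
failure). For p = 7, b_1 ≈ 37%.

Left/right separation is measured in every C(n, 3) 3-component subspace of
the retained set. When the broken-stick point falls below 3 the top three
components are used (a single subspace) — retention is always derived from
the data at hand, never hard-coded to the counts any particular dataset
produced. Per subspace, 1,000 bootstrap (left, right) single-trial pairs
are drawn with replacement, their Euclidean distance taken at each time
sample — restricted to pre-approach bins for the headline statistic — and
averaged over samples and pairs. Sampling pairs rather than the full cross
product is a cost choice; the reported number is a mean either way, and the
pair count is configurable.

The loading split partitions units by their coefficient on a chosen
component: positive ≥ +0.01, negative ≤ −0.01, middle band excluded. The
component of interest is the one whose sign-group mean rates show a
significant time-by-side repeated-measures interaction in every session
type (all candidates are returned; no silent tie-break). For each sign
group the left-minus-right group-mean rate trace is averaged over the bins
before and after the approach bin (the approach bin itself belongs to
neither half); positive values mean the group skews toward encoding left.

## Group statistics

Standard tests are delegated: Kruskal–Wallis omnibus over the per-condition
subspace-distance distributions with Tukey–Kramer pairwise follow-ups
(statsmodels' Tukey HSD, which applies the Kramer correction under unequal
n); per-trial 2×3 chi-square on outcome proportions with Benjamini–Hochberg
correction across the first 15 trials, falling back to a seeded Monte-Carlo
permutation test on the chi-square statistic when an expected cell is below
1 (scipy has no exact r×c test); OLS for Latency ~ Distance × Session with
per-session-type Pearson correlations; two-way ANOVA per behavioral metric
plus a per-strain MANOVA across the metric vector (outcome counts are
collinear — they partition the CS+ trials — so one of them is dropped from
the multivariate test); and pingouin's repeated-measures ANOVA for the
side × time screen, with time averaged down to 8 levels to keep the
within-subject design well conditioned (no sphericity correction is applied
to the reported uncorrected p; Greenhouse–Geisser values are available in
the returned table).

## Synthetic sessions

The generator is first-class, tested code; it defines the study conditions
under which the pipeline's claims are checked.

*Schedule*: 96 trials (48 CS+ / 48 CS−) in random order, CS+ side uniform
per trial, cue style counterbalanced, 30 s inter-trial interval, and the
4 s cue / 1 s delay / 8 s access timing.

*Behavior*: the agent rests at the chamber center (which anchors the
pre-cue distance baseline), leaves after `cue_on + latency` (proactive) or
`sipper_in + latency` (reactive) with latency ~ N(2.0, 0.5²) s truncated at
0, and travels at 200 px/s in a 640 × 480 px arena with sippers at mid-left
and mid-right. Omissions occur with probability 0.05; on congruent sessions
the first approach is correct with probability 0.90; on incongruent
sessions the agent follows the cue to the wrong port with probability 0.90
(the rule-following error). Incorrect trials dwell at the empty port until
the sipper descends plus a 1 s check, then correct — so both the incorrect
latency and the eventual drink are realized. Proactive agents move at 0.7×
speed on incongruent sessions (deliberation under a contingency conflict;
this is what makes the congruent-faster-at-cue-onset contrast hold in the
generator, as it does in recorded animals). Gaussian position jitter
(2 px) is added to all points and 2% of frames are corrupted and assigned
likelihood 0.5 to exercise interpolation. Ground-truth outcomes come from
the sampled decisions, and truth timing from the noiseless kinematics
scanned with the same ≤ 9 px rule the detector applies — so on noise-free
sessions event detection recovers truth on 100% of trials, which is tested
as a closed loop. An optional linear engagement decay over trials exists
and defaults off (no quantitative within-session disengagement model is
available to calibrate it).

*Spikes*: each unit is an inhomogeneous Poisson process realized by
thinning with a hard 2 ms refractory period (ISI violations are zero by
construction; the realized rate of a homogeneous unit is
lambda/(1 + lambda·tau), which the rate-realization test accounts for).
Baselines are Gamma(shape 2, scale 2.5) Hz (mean 5 Hz). Of 40 units, 20%
are cue-modulated (gain 3 during the cue), 20% sipper-modulated (gain 3 for
1 s after sipper descent and before ascent), 40% side-preferring (gain 3 on
preferred-side trials, split evenly left/right), the rest untuned. Side
coding is active for 2 s *ending at* the approach in the proactive regime
and *starting at* it in the reactive regime — the minimal pair the
pre/post-approach statistics must separate.

What the generator does **not** emulate: correlated noise across neurons,
slow drift and non-Poisson spiking statistics, body-posture variation
(trailing points are rigid offsets), heterogeneous per-unit gains, and
learning within a session. Passing tests therefore show that the pipeline
recovers the encoding regime under idealized, label-known conditions — not
that recorded cortical data satisfy these assumptions.

## Problem sizes and numerical choices

Tests run full 96-trial sessions; the parameter-recovery suite uses 10
seeded runs per regime at 40 units and up to 15 correct trials per side
with 1,000 bootstrap pairs per subspace, the same conditions the recovery
claim states. All randomness flows through `numpy.random.default_rng`
seeds; identical (parameters, seed) reproduce byte-identical outputs.
Degenerate inputs are handled explicitly: zero-variance matrices are
rejected rather than decomposed, a CV of 0 falls back to the sigma cap,
silent units are flagged untested by the modulation index, empty loading
groups map to None, and an undefined CS ratio (no approaches of either CS
type) is flagged rather than silently zero.

## Known limitations

The pipeline consumes sorted spikes and pose tables; spike sorting, pose
network inference and video handling are out of scope. Single-trial
projections through a pooled-unit PCA are exact only when trials carry all
pooled units (one session per condition); with multiple sessions the
partial-unit projection is an approximation. The Monte-Carlo chi-square
fallback and the bootstrap distance are seeded but stochastic; their
resolution is set by the permutation/pair counts.
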