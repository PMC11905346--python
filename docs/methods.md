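# Methods

## Scope

`perturbmap` measures the trial-normalized influence of single
photostimulated excitatory neurons on the surrounding imaged population
and its spatial, population-geometric, behavioral-state, correlational and
tuning structure. All statistics operate on any (neurons × frames)
activity matrix plus a stimulation table; the bundled synthetic-session
generator supplies inputs with known ground truth.

## Preprocessing

Raw fluorescence is neuropil-corrected as `f_raw − 0.7·f_neu`. ΔF/F uses a
slow rolling baseline: per frame, the 8th percentile of the corrected
trace over ±450 frames (±15 s at 30 Hz), with windows truncated (not
reflected) at trace edges and percentiles computed by linear interpolation
between order statistics; these conventions are fixed in `RunConfig` for
bit-reproducibility. A non-positive baseline anywhere flags the neuron and
removes it from analysis. The interior of the rolling percentile is
evaluated by a JIT-compiled sorted-window update (a chunked numpy path is
the fallback); both paths are exact, not approximations.

Deconvolved "events" come from direct AR1 inversion,
`s[t] = dff[t] − g·dff[t−1]` with `g = exp(−1/(rate·tau))` and a global
indicator constant `tau` (default 0.35 s), thresholded at 0.05 a.u. This
is exact on noiseless transients; unlike per-cell kernel optimization it
fixes one kernel for the field of view, which is adequate here because all
headline analyses default to ΔF/F and events are a secondary path.

## Influence and its null

Windows are 10 frames (333 ms) pre and post; the onset frame — which
contains the stimulation artifact — belongs to neither. (A 1 s post
window is available via `post_len=30`.) Influence is `mean(d)/sd(d)` over
trials with the sample SD; a zero-SD pair with nonzero mean is flagged and
excluded rather than divided. Note the statistic carries no √n factor, so
on null data its across-pair spread is ≈ 1/√n_trials (≈0.1 at 100
trials), not 1.

The per-pair null replaces the target's onsets with 1000 equal-size
pseudo-onset sets drawn from the pooled onsets of all targets and
recomputes the statistic. Three details make the nominal 99% rule
actually run at ~99% on null data:

1. *The pool includes the target's own onsets.* Restricting it to other
   targets' onsets (the obvious alternative) makes the observed statistic
   an outsider to the null family and inflates the false-call rate.
2. *Draws are stratified by repeat block* — one pseudo-onset per block,
   exactly the design that produced the real onset set, so under no
   effect the observed statistic is exchangeable with the shuffled ones.
   (Stimulation tables without usable block structure fall back to plain
   subsets without replacement.)
3. *Thresholds are order statistics*, implementing the rank rule
   literally: positive means the observed influence strictly exceeds at
   least 99% of the 1000 shuffled values (the k-th smallest with
   k = ⌈0.99·M⌉), negative the mirror image; ties are uncalled. An
   interpolated percentile estimate adds noise that inflates both tails.

One further refinement: when the *measured* neuron is itself a target,
its own onsets are removed from that pair's pool — otherwise its direct
responses contaminate the null and inflate its thresholds (on null
sessions this raised the apparent negative-call rate for target neurons
to ~17%). A residual caveat: a target stimulated 1 s before another
target's trial leaves a small calcium tail in that trial's pre-window;
this is a property of the 1 s ISI protocol, not of the analysis.

A target is "successfully stimulated" when its own influence is classified
positive against its own shuffle null — the criterion is not specified in
the source protocol, so this documented rule stands in; control (non-opsin)
targets are evaluated the same way and succeed at roughly the false-positive
rate. Only successful, non-control targets contribute influence records,
and neurons within 25 µm of the target are excluded throughout.

## Spatial analyses

Distance is 2-D Euclidean between ROI centroids within the imaging plane.
Distance bins are 50 µm wide (25 µm in the recovery analysis) with edges
starting at the 25 µm exclusion radius. Centered maps accumulate
(neuron − target) offsets of significantly influenced neurons on a 20 µm
grid, summed over targets and divided by the target count; the map total
therefore equals influenced-neurons-per-target whenever the map extent
covers the field of view.

`fit_center_surround` fits `A_c·exp(−d²/2σ_c²) − A_s·exp(−d²/2σ_s²)` to
the binned mean-influence profile, weighting bins by pair count, with
amplitudes bounded nonnegative. Because the influence statistic divides by
a trial SD that grows with response rate, strong centers are compressed
and the fitted σ_c runs systematically ~10–20% above the generative width;
recovery within 25% is the realistic expectation at one-session scale.

## Population stimulus axis

Per target, the axis is the unit-norm vector from the population's
trial-averaged prestimulus window mean to its trial-averaged post window
mean, over all SOM and Non-SOM neurons at least 25 µm away (the source
analyses state neither the averaging window nor the normalization; unit
norm makes weights comparable across targets). Projections subtract the
prestimulus mean before the dot product. Signed weights binned by distance
summarize the center/surround structure at population level.

## Running state

Prestimulus speed is the mean over the 20 frames (660 ms) before onset;
within-session quartiles (25/50/75 percentile cuts, boundary ties to the
lower quartile) label each trial. Q1 is not separately thresholded as
"stationary" — with the generator's two-state running model, zero-speed
trials naturally fill Q1. Quartile-restricted influence reuses the same
mean/SD statistic on the trial subset (no re-assessed significance),
restricted to pairs significantly positive over all trials; quartiles with
fewer than two trials for a target are skipped and logged.

## Noise correlations

Per stimulation event, the response is the 10-frame post-window mean; the
trial-averaged response to that event's target is subtracted, and the
Pearson correlation between a target's and a neuron's residuals is taken
over all events in which that target was *not* stimulated (raw r, no
Fisher transform). The mean subtraction makes r invariant to any
deterministic target-locked component. Pairs split at 125 µm into
near/far classes when related to influence.

## Tuning

Tone responses are measured on z-scored activity (deconvolved events by
default): mean over the 1 s tone window minus a 10-frame prestimulus
baseline, averaged per frequency. Responsiveness is a sign-flip
permutation test of that difference across trials at α = 0.05 (the source
threshold is unstated; this is the package's documented choice). Best
frequency is the center of a Gaussian fit in log2 frequency with center
bounded to the tested range [2, 5] log2 kHz and width to [0.1, 4] octaves.
The like-to-like test correlates influence with |ΔBF| over all retained
tuned pairs and compares against 500 within-session permutations of the
BF labels; p = max(#{r_shuffle ≤ r_observed}, 1)/500.

## Permutation tests

Two-sided tests for differences in means: label permutation (unpaired) or
sign flips (paired), 10,000 iterations, `p = max(count, 1)/n_iterations`
(so the floor at the default is 0.0001). Effect size is Cohen's d with a
pooled SD — the source's effect-size formula is undefined, and the pooled-SD
convention reproduces its difference/effect-size ratio structure.
Bonferroni significance is `p < 0.05/m`.

## The synthetic-session generator

What it emulates, per field of view: uniformly placed neurons in a 500 µm
square; a SOM fraction of 0.07; Poisson spiking at 1 event/s modulated by
(a) a two-state Markov running process (mean dwell 8 s, log-normal bout
speeds, gain `run_gain_som`/`run_gain_nonsom` while running) and (b) a
slow shared latent per cell type (AR1, SD 0.3, 1 s timescale) with
per-neuron loadings; stimulation as an added rate for 3 frames (~100 ms)
after each onset — a strong direct drive (30 events/s) within the 12.5 µm
direct-activation radius and a difference-of-Gaussians network kernel
elsewhere; AR1 calcium (τ = 0.35 s, 0.2 ΔF/F per event), Gaussian
fluorescence noise (0.05 ΔF/F), and a shared neuropil trace mixed at 0.7
into the raw signal. Control targets are spirals on non-opsin cells and do
nothing. The protocol is 100 pseudorandom repeats of all targets at 1 s
ISI — every target once per repeat block — plus, in AC-like sessions, a
tone block (6 frequencies × 20 trials, 1 s tones).

Regime presets encode the two cortical areas' qualitative patterns:
`ac_like_params` has a narrow center (σ_c = 45 µm), a wide strong surround
(1.2 reduced to 0.7 events/s amplitude at σ_s = 180 µm), state-independent
influence, and like-to-like coupling (the positive center scaled by tuning
similarity, σ = 1 octave); `ppc_like_params` has a wide center (80 µm), a
weak narrow surround (0.35, 120 µm), strong positive running gains
(SOM 2.0, Non-SOM 1.3), and influence scaled to 0.3 on running trials.
Both presets couple near-pair (<125 µm) center amplitude to the product of
the two neurons' latent loadings, which is what links influence to noise
correlation for near pairs. Kernel amplitudes (center 8, surround
0.35–0.7 events/s) were set so a single synthetic field of view lands in
the experimentally reported range of outcomes — a few percent of pairs
significantly positive, near-complete target success, controls at chance —
and effect couplings were set strong enough to be detectable at
one-session scale (a real multi-session dataset pools 10–50× more pairs).

What the generator does not emulate — and what passing tests therefore do
not establish about real data: optics and point-spread functions, motion
artifacts, ROI segmentation errors, spatially clustered somata, layered or
recurrent network dynamics (influence is imposed as a feedforward rate
change, not generated by a network), plasticity across trials, pupil-linked
arousal beyond locomotion, and realistic heavy-tailed firing statistics.

## Numerical choices and degenerate inputs

Percentiles everywhere use numpy's linear interpolation. Window means are
accumulated in float64 via cumulative sums. Zero-SD influence pairs are
flagged, never divided; zero-variance correlation series give NaN records;
an all-equal speed distribution throws every trial into Q1 and flags the
assignment; flat tuning curves are non-selective (no BF); DoG and Gaussian
fits report non-convergence instead of raising mid-pipeline. All
randomness derives from explicit seeds — the generator's seed lives in its
parameters, and `RunConfig` spawns named substreams (shuffles, tuning,
permutation tests) from one root seed, so every stage is independently
reproducible.

## Problem sizes

Tests exercise the pipeline at the study's per-session scale (215 neurons,
30 targets + 5 controls, 100 repeats, 1000 shuffles) for acceptance
checks, and at reduced scale (≤100 neurons, ≤20 targets, 15–80 repeats)
for module tests; the statistical-calibration checks use 2000 null
permutation runs and 200 shuffle-test replicates. One full-scale session
generates, preprocesses and maps in well under a minute.
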