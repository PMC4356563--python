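# Methods

`emegscan` implements a presurgical-epilepsy source-analysis chain — interictal
spike detection, bootstrap subaveraging with SNR gating, combined EEG/MEG
single-dipole deviation scanning, skull-conductivity calibration, and
stereo-EEG-referenced validation statistics — exercised end to end on a
synthetic digital phantom. This note records the models, the parameters that
matter, and the design choices that were genuinely open.

## Head model and forward solutions

The head is a four-shell concentric sphere (brain, CSF, skull, scalp) with
default outer radii 79 / 82 / 87 / 92 mm and conductivities 0.33 / 1.79 /
0.0024 / 0.43 S/m. The skull value is the compacta conductivity that also
serves as the ground truth in calibration experiments. The spherical model is
a deliberate desk-scale substitute for patient-specific finite-element
modeling: it preserves the properties the analysis depends on (skull
attenuation and smearing of EEG, conductivity independence and radial-source
silence of MEG, depth-dependent sensitivity loss) while remaining analytic
and fast.

EEG scalp potentials use the exact multishell Legendre series. For each
harmonic order `n` the radial interface conditions (continuity of potential
and radial current density at the three interfaces, insulating outer surface)
are solved as a 7-unknown linear system in radii normalized by the scalp
radius, yielding a geometry coefficient `c_n` that multiplies the standard
interior dipole expansion; with equal shell conductivities `c_n` reduces to
`(2n+1)/n` and the series sums to the homogeneous-sphere closed form, which
the tests verify to 1e-6 relative. The series is truncated when the next term
falls below 1e-10 of the accumulated maximum (cap 200 terms) — far below
every tolerance used elsewhere. Potentials are average-referenced; gains are
µV/nAm.

MEG uses the closed-form field of a current dipole in a spherically symmetric
conductor, evaluated at point magnetometers with radial orientations; gains
are fT/nAm. The formula contains no conductivity, so MEG leadfields are
bit-identical across conductivity profiles, and radial dipoles are exactly
silent. The real instrument's synthetic gradiometers are not modeled; the
noise level absorbs the difference. Tests cross-check the implementation
against a symbolic re-derivation (gradient taken by computer algebra) and
against the volume-current-free radial field component.

## The digital phantom

Coordinates are head-centered RAS in millimetres, origin at the sphere
center, left hemisphere at x < 0.

- **Source space** — a regular grid restricted to a "cortical band" of radii
  55–74 mm. The default spacing is 8 mm (~1 900 sources), a desk-scale
  stand-in for clinical 2 mm grids; the generator honours any requested
  spacing and the tests exercise a 2 mm band. Source normals are radial
  directions tilted by a fixed angle about a random tangent: 40° generically,
  35° in the deep patch and 15° in the lateral patch. The orientation profile
  encodes two physical facts: purely radial sources would be invisible to
  MEG, and deeper mesial sources are more quasi-radial than superficial
  temporal-pole cortex, which is what ultimately makes the fused EMEG scan
  outperform either modality alone at spike onset.
- **Sensors** — 80 EEG electrodes on the scalp sphere and 275 MEG
  magnetometers 20 mm outside it, both laid out as deterministic Fibonacci
  caps.
- **sEEG contacts** — seven depth electrodes (five targeting the left
  temporal region, two distant) with 5 mm contact spacing. Activity labels
  are assigned by proximity quotas: the 8 contacts nearest the deep patch on
  the two deep-most electrodes are ictal, the interictal-measuring set
  extends by proximity to 24 contacts, the rest are inactive. Ictal contacts
  are by construction a subset of the interictal set. Contacts are geometric
  validation points only; no intracranial signal is synthesized.
- **Irritative zone** — a deep patch (seizure-onset analogue, centroid radius
  ≈ 58 mm) and a lateral patch (temporal-pole analogue, ≈ 67 mm), each the
  nearest grid sources within a 14 mm patch radius of its seed.

## Spike simulation

Each of the (default 200) spikes draws an origin within 10 mm of the deep
patch seed and an independent lateral source near the lateral seed — the
stochastic origin models the observation that epileptic activations wander
within the irritative zone, which is what subaveraging is designed to
exploit. Amplitudes are log-normal (median 200 nAm, σ_log 0.4); the lateral
source fires with twice the deep amplitude after a 30 ms propagation delay.
The deep waveform rises over 35 ms and falls over 30 ms; the lateral one
rises over 20 ms. With the epoch clock set by the lateral (EEG-dominant)
peak, the analysis instants −33/−23/−13/−3 ms then span genuine low-SNR
onset (deep source at ~half amplitude), deep-dominant rising flank, early
propagation, and lateral-dominant peak — reproducing the reported SNR
pattern in which EEG and MEG are nearly identical and low at onset while EEG
grows much faster toward the peak. These generator values were fixed once,
against that qualitative pattern, and define the study conditions for every
stochastic test.

Sensor noise mixes two components at a per-channel SD of 5 µV (EEG) and
300 fT (MEG): a spatially structured part (random deep brain dipoles
projected through the leadfield, temporally low-passed at 40 Hz) and white
sensor noise, mixed so the structured part carries 60 % of the variance.
Structured background of this kind is what produces the depth bias of
low-SNR localizations that the subaveraging study measures; per-channel SDs
are normalized exactly in expectation.

What the phantom does *not* emulate: realistic cortical folding, extended
patch waveform heterogeneity, ocular/cardiac artifacts, head movement, and
gradiometer reference geometry. Passing tests therefore demonstrate the
correctness and the qualitative behavior of the analysis chain, not clinical
performance.

## Detection, epochs, SNR, subaverages

Continuous data are band-passed 1–100 Hz (zero-phase 4th-order Butterworth).
A template is averaged from ten marked spikes, the search is restricted to
the 20 channels carrying the largest template amplitude (the synthetic
analogue of selecting the involved temporal channels), and events are local
maxima of the channel-joint normalized cross-correlation above 0.5 with a
200 ms lockout. Detected events are re-aligned to the EEG global-field-power
maximum, defining time 0 of the 400 ms epochs (−200…+200 ms).

The SNR of an epoch at an instant is the channel-mean instantaneous squared
amplitude divided by the channel-mean per-channel baseline variance over
−200…−70 ms. Both estimator choices (single sample; pooled noise across the
modality's channels) are the simplest consistent readings and are fixed
package-wide. Subaverage groups Av5…Av50 draw 200 realizations each of k
distinct epochs (repeats allowed across realizations); Av1 is the identity
list of single epochs. Realization r of group k derives its RNG stream from
(seed, k, r), making every draw reproducible and order-independent. The
SNR>3 gate is strict and applied per modality and time point.

## Deviation scan, fusion, calibration

The scan solves, at every source independently, the least-squares fit of the
local 3-column gain to the data vector and reports GOF = 1 − residual/total
variance; the highest-GOF position wins, ties break to the lowest index. MEG
scans add Tikhonov regularization with λ = 1e-3 × trace of the local normal
matrix — enough to stabilize the near-silent radial direction without moving
the argmax of well-posed fits (tested) — and only the left-hemisphere
(x < 0) MEG channels are used. The winning moment is always re-solved
without regularization through a tolerance (1e-10) pseudo-inverse, so the
reported moment never contains an arbitrary radial component. Local normal
matrices that are rank-deficient at that tolerance are flagged.

EMEG fusion divides every channel — data row and leadfield row alike — by
that channel's baseline noise SD and stacks EEG then left-MEG. Amplitude
(not power) normalization is required for the fused quantity to remain
linear in the data, which least-squares scanning assumes. Channels with zero
baseline SD are dropped with a warning.

Skull calibration runs a conductivity-independent MEG scan on the averaged
somatosensory (N20-analogue) response to fix the source location, then
scores each candidate skull conductivity by the EEG goodness of fit of the
local gain rebuilt at that conductivity. Scoring uses all samples of the N20
lobe (spatial rms ≥ half the peak) rather than a single instant: the
component shape carries the conductivity information and the extra samples
suppress noise. The default candidate grid is logarithmic over the
physiologically contested range {0.0004, 0.001, 0.0024, 0.0058, 0.014} S/m.
In a 4-shell sphere the GOF contrast between conductivities ±40 % apart is
only ~0.3 %, below the noise floor of a moderately averaged response, so a
fine grid is not identifiable at realistic SNR; the wide grid is, and with
1 200 stimulation trials (≈ 7 minutes at ~3/s) the true compacta value
0.0024 is recovered exactly.

## Validation statistics

- **Centroid dipole**: arithmetic mean of member locations; orientation =
  renormalized mean of unit orientations after sign-aligning every member to
  the first (a dipole and its negation are the same generator; with this
  rule the aligned sum always retains a positive component along the first
  member, so the mean cannot vanish).
- **Outlier pruning**: one pass — distances to the centroid, members beyond
  mean + 2×SD removed (population SD; the rule is a filter, not an
  estimator). No re-iteration, matching the single-pass reading of the
  protocol; a flag enables iterating for sensitivity analyses.
- **SDI**: for contact i and the N gated dipoles,
  `SDI_i = (100/N) · Σ_j 1/(d_ij² + 1)` with distances in mm. The +1 makes a
  perfect colocalization score exactly 100 and keeps the index finite;
  values decay with the inverse square distance. Summaries are the mean and
  population SD over contacts — high mean and low SD together indicate that
  the dipole cloud covers the whole irritative zone rather than one corner
  of it. SDI is computed on SNR-gated, pre-pruning sets by default; a flag
  switches to post-pruning, and the statistics tables are emitted under both
  flags.
- **Coverage**: per contact, the count and fraction of dipoles within 10 mm
  (closed ball by default; a strict flag exists, and the two differ only on
  exact boundaries).

## Problem sizes and numerical choices

Tests and the acceptance script run on the 8 mm (and for micro-tests 12 mm)
source grids with 30–200 simulated spikes, 10–50 bootstrap realizations per
group and 6–20 random seeds per stochastic property — sizes chosen so the
whole suite completes in minutes on one core while leaving every qualitative
contrast (EMEG onset advantage, single-spike depth bias, SNR growth with
averaging, calibration recovery) statistically comfortable. Degenerate
inputs fail loudly: zero data vectors, empty channel sets, non-increasing
shell radii, out-of-shell sources and empty conductivity grids all raise
typed errors rather than propagating NaNs.

Two behavioral checks are deliberately phase-specific. The depth-bias
comparison (Av1 centroid deeper than Av50) and the gated-SNR monotonicity
are evaluated at −3 ms, the lateral-dominant phase: at −23 ms the phantom's
activity is still purely deep, and the SNR>3 gate passes so few single
spikes that their survivor median is an upper-tail statistic rather than a
property of averaging.

## Known limitations

The spherical forward model understates the skull-conductivity sensitivity
of realistic geometries, which is why calibration needs a wide candidate
grid. The two-patch ramp propagation model is the simplest structure
consistent with a deep-onset/lateral-peak spike; real propagation is
continuous. Validation statistics treat contacts as points and dipole
scatter as the extent estimate, inheriting the corresponding clinical
caveats. The deposited clinical dipole tables can be analyzed through
`reproduce-s1`, but are not shipped with the package.
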