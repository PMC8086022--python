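# Methods

This note documents the statistical procedures, the synthetic cohort
model, the numerical conventions, and the design decisions behind
`sleeptopo`. It describes what the code computes and why the defaults
are what they are; every empirical number quoted in the README is
produced by the test suite or `scripts/acceptance.py` at run time.

## Macrostructure scoring

A hypnogram is a per-epoch stage sequence (default 30-s epochs) with a
lights-off/lights-on window. Operational definitions vary between
laboratories, so the package's conventions are explicit:

* **Sleep onset** is the first epoch of any sleep stage; a single N1
  epoch counts. No "three consecutive epochs" rule is applied.
* **WASO** counts W epochs strictly between sleep onset and the last
  sleep epoch. Terminal wake is excluded and appears only in the exact
  identity TBT = SOL + TST + WASO + terminal wake, which the property
  tests enforce.
* **ISA** is the number of maximal W runs inside the same interval.
* Stage percentages are of TST. Metrics that are undefined for a record
  (SOL of an all-wake night) are NaN, never silently 0, so downstream
  group statistics exclude them listwise rather than absorbing zeros.

## Spectral estimation

Welch's method with a Hann window, 4-s segments (0.25 Hz resolution)
and 50 % overlap — standard sleep-EEG practice. Band powers are
trapezoidal integrals of the one-sided density over half-open bands
delta [0.5, 5), theta [5, 8), alpha [8, 12), sigma [12, 16), beta
[16, 25) Hz. The scheme is configurable; bands must be ordered,
non-overlapping and below Nyquist. Three identities anchor the
implementation and are asserted in tests: a sinusoid of amplitude A
carries A²/2 in its band (within 2 %), the integrated density matches
the signal variance (Parseval, within 5 % for long noise signals), and
band powers are additive over a partition and scale as c² under
amplitude scaling by c.

Artifact handling is a declared, testable rule rather than a
reconstruction of any laboratory's pipeline: fixed-length segments with
any |sample| > 300 µV, or flat channels, are dropped, and the PSD is
the window-count-weighted average over the remaining clean runs. The
threshold is configurable.

Group statistics operate on log₁₀ absolute power, which symmetrizes the
right-skewed power distribution; linear power is retained because the
slowing index is a ratio of powers.

## Channel-wise inference and FDR

Per channel: classical fixed-effects one-way ANOVA (identical, to
1e-10 relative, whether computed from raw data or from per-group
mean/SD/n summaries) and pooled-variance Student *t* tests
(df = n₁+n₂−2), matching the convention of reporting F₂,₁₄₇ and t₉₈ at
50 subjects per group. Welch's t is deliberately not used. Post-hoc
pairwise tests are gated on omnibus FDR significance and reported
uncorrected at α = 0.05, mirroring standard practice in this
literature.

The multiple-comparisons family is all channels × bands within one
behavioral state (95 tests), corrected by the Benjamini–Hochberg
step-up. The reported threshold is the data-dependent largest p(k)
satisfying p(k) ≤ k·q/m — this is why published maps carry cutoffs like
"p ≤ 0.0102" that vary between figures; such numbers are outputs, never
hard-coded inputs.

The Group × Time-of-day interaction for the two wake sessions is
computed as a one-way ANOVA on per-subject AM − PM difference scores.
With a two-level within factor this equals the mixed-design interaction
F exactly; the test suite verifies agreement with an independent
mixed-ANOVA implementation to 1e-8. Subjects missing a session are
excluded listwise with a logged manifest, reflecting that per-analysis
Ns legitimately differ.

A deliberate caveat, verified by simulation during development: BH
controls the *expected false-discovery proportion*, not the familywise
error. When a large fraction of a family carries true effects (7 of 19
channels in the interaction map), the step-up threshold rises and the
significant set occasionally includes a channel outside the true
support. The acceptance tests therefore assert full sensitivity plus an
empirical FDP at the nominal q, and assert exact support recovery only
where the planted fraction is small (the NREM sigma map, 7 of 95
family members).

## Slowing index and overnight delta change

slowing = (P_delta + P_theta) / (P_alpha + P_sigma + P_beta) on linear
power: dimensionless, strictly positive, invariant to overall scaling,
monotone in each constituent. It equals 2/3 on a flat spectrum. The
ratio is computed on state-pooled band powers (not per epoch and then
averaged); group maps are ANOVA-tested on log₁₀ of the index so the
statistics see a symmetric quantity. The overnight change is AM − PM
log₁₀ delta power per channel; negative means delta fell across the
night. Representative channels for seeding correlation maps default to
F4 (overnight change) and O1 (REM slowing) and are configurable.

Correlations are two-sided Pearson (t transform, n−2 df), Spearman for
ordinal macrostructure variables, pairwise-complete deletion, n ≥ 3
enforced. The across-severity trend of wake–REM slowing correlations is
an OLS fit of z = atanh(r) on the ordinal HC = 0, MCI = 1, AD = 2,
reported descriptively as β and R² without p-values (three points
cannot support inference; the fit summarizes a monotone trend). A
constant triple yields β = 0 and R² = 0 by the 0/0 convention.

## Synthetic cohort model

The generator's defaults are the study conditions the package is
validated under: 50 subjects per group, 128 Hz, 30-s epochs, 300 s of
EEG per state, and 0.3 log₁₀-unit mean AD − HC contrasts with MCI
halfway (a per-subject severity latent has group means 0/1/2 and
within-group SD 0.35).

Every band-power cell is log-normal: a state × band baseline typical of
elderly scalp EEG, plus a posterior-alpha regional offset, plus planted
topographic effects scaled by severity, plus latent couplings, plus a
subject × state × band offset (SD 0.18) and per-cell noise (SD 0.08) —
total between-subject SD ≈ 0.2 log₁₀ units, so the planted contrast is
d ≈ 1.5. The planted topography: NREM left-temporal alpha and posterior
sigma deficits; REM frontotemporal delta excess and temporo-occipital
fast-band deficits; evening-wake prefrontal/right-frontotemporal delta
excess and right-occipital alpha deficit. A weak (±0.07–0.12 per band)
scalp-wide severity tilt in wake and REM makes the five-band slowing
ratio differ between groups at all sites while single-band maps stay
regionally specific — the aggregation gain of a composite index.

Morning delta is generated as the subject's evening value plus an
overnight change: −0.25 (HC), −0.12 (MCI), 0.00 (AD) at the
frontal-central cluster and −0.10 for every group elsewhere, plus
N(0, 0.12) noise, making the interaction effect exact by construction.
In AD the change is additionally coupled (slope 0.18) to a sleep
high-frequency latent that loads (0.15) on NREM/REM alpha/sigma/beta —
this produces the negative change-vs-sleep-power correlations that the
correlation maps recover. Wake and REM spectral-tilt latents share a
group-dependent correlation (0.55/0.80/0.95 for HC/MCI/AD), which
drives the increasing wake–REM slowing correlation across severity.
MMSE = round(clip(29.5 − 3·severity − 0.8·REM tilt + N(0, 1.3), 0, 30)),
giving group means near 29/26/23 and the negative slowing–cognition
coupling, strongest for REM sleep.

Hypnograms are Markov chains: the latency phase leaves wake with
probability epoch/SOL_target per epoch (per-subject SOL targets are
gamma-distributed with the group's published mean and SD, so expected
SOL matches by construction); after onset, sleep epochs are drawn
i.i.d. from the group's stage distribution (stationary shares equal the
targets exactly, with per-subject jitter on the N3 share), awakenings
occur at 0.035 per epoch and intra-sleep wake persists at 0.885 —
chosen to land WASO near 80 min and ~19 awakenings over a ~390-min
night, matching the emulated cohorts. Run lengths are sampled
geometrically, which is algebraically the same process as the
epoch-by-epoch chain.

Signal mode synthesizes each state as a sum of independent band-limited
Gaussian components (frequency-domain brick-wall filtering), each
rescaled so its variance equals the subject's drawn band power; Welch
estimation then recovers the table-mode draws with a median log₁₀ error
below 0.05 (worst cells: low-power bands adjacent to strong delta,
where window leakage bites). Table-only mode skips synthesis and emits
the draws directly; both modes share the same random draws per seed.

What the generator does **not** emulate: discrete spindles/K-complexes,
artifacts, non-stationarity within a state, circadian structure,
volume-conduction correlation between neighboring channels, or
realistic 1/f spectral shape within bands. Passing tests therefore
demonstrate that the analysis machinery is correct and calibrated under
the planted statistical structure — not that real recordings would show
these effect sizes.

## Problem sizes and numerical conventions

The test suite and acceptance script use: 1000 null cohorts at
20/group for FDR calibration (300 in the acceptance script), 20
replicates at 50/group for pattern recovery (10 in the script), 10,000
hypnograms for the SOL Monte-Carlo, and 300-s signals for spectral
checks — sizes at which the Monte-Carlo error of each assertion is
well below its tolerance. Degenerate cases are defined, not left to
chance: F = 0 when both SSB and SSW vanish, an infinite-F/t sentinel
with a warning when only SSW does, p-values clipped away from exact 0,
BH threshold 0 with an empty mask when no k qualifies, and validation
errors that name the offending field. All simulation randomness flows
through a single `numpy` Generator per cohort, so identical (spec,
seed) gives byte-identical output.

## Known limitations

EDF export is not implemented (reading is available through `mne`);
signals travel as in-memory arrays or band-power TSVs. The slowing
index is the only spectral composite offered. No covariate adjustment,
cluster-based permutation statistics, or effect-size confidence
intervals — the inference surface is deliberately the classical
ANOVA/t/FDR stack this analysis tradition uses.
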