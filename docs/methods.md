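# Methods

`dotprobe_eeg` re-implements, end to end, the analysis chain of a two-group
dot-probe EEG study of attentional bias in adolescents with high vs low
social-anxiety traits (HSA / LSA): behavioral bias indices, the P2
event-related potential, phase-locking-value (PLV) functional connectivity,
nodal graph metrics, and the group-level inferential statistics. Because no
public recording of such a study is consumed here, the pipeline is driven by
a synthetic-data generator that reproduces the study's *statistical
structure*; every downstream stage is validated against that known ground
truth.

## Study design emulated by the generator

Two groups (27 HSA, 18 LSA by default), 100 dot-probe trials per subject in
3 blocks — 40 congruent (probe replaces the emotional face), 40 incongruent
(probe replaces the other face), 20 neutral — with probe side balanced
within condition. EEG epochs span −100…+500 ms around stimulus onset at
500 Hz (300 samples) over a 32-channel 10/20 scalp montage (mastoids
excluded; hemisphere tags derived from the odd/even/z label convention).

Per trial and channel the generator sums four components:

1. **White noise**, Gaussian, `noise_sd` (default 1 µV).
2. **1/f noise**: white noise spectrally shaped to power ∝ 1/f^β
   (β = `one_over_f_exponent`, default 1), analytically normalised to a
   stationary SD of `pink_sd` (default 1 µV), no DC component. Together
   these give realistic band-limited spectra for filtering tests.
3. **A P2-like deflection at Pz**: a Gaussian bump
   `a · exp(−(t−µ)²/2σ²)` with latency µ = 170 ms and σ = 20 ms
   (`p2_width_ms` = 40 ≈ 2σ), confined to the post-stimulus window.
   The amplitude is `p2_mean[group][condition] + offset_subject`, where
   the per-(group, condition) means default to the group means reported
   for this paradigm (HSA 0.330 / 0.197 µV, LSA 1.625 / 1.625 µV for
   congruent / incongruent; neutral, which the ERP analysis does not use,
   sits at the per-group average). `offset_subject ~ N(0, p2_between_sd)`
   is drawn once per subject and shared across conditions, producing both
   the between-subject spread (default 2.1 µV, the pooled SD implied by
   the reported group summary statistics) and the within-subject
   correlation a mixed design assumes.
4. **Theta-band phase coupling** between designated channel pairs
   (defaults O1–O2 and P7–P8, posterior pairs standing in for the
   occipitotemporal connectivity effect): each pair shares a 6 Hz
   sinusoid (2 µV) with a fresh uniform phase per trial; each channel
   adds its own slowly varying phase-jitter process — independent
   von-Mises(0, κ) draws at knots every 100 ms, circularly interpolated
   between knots. κ is the coupling-strength dial: at the knots the
   expected pair PLV is (I₁(κ)/I₀(κ))², monotone in κ, 0 jitter as
   κ → ∞ and uniform (incoherent) offsets at κ = 0. The groups differ
   only in κ (defaults HSA 1.0 < LSA 3.0), making HSA connectivity
   weaker by construction — the direction reported for this population.
   The jitter varies *within* the trial so that both PLV estimators (see
   below) are sensitive to κ; a per-trial constant offset would leave
   the within-trial estimator blind to coupling strength.

Reaction times are truncated-normal (lower bound 100 ms) with
per-(group, condition) means and SDs. Defaults give the HSA group a
vigilance pattern (congruent 540, incongruent 585, neutral 560 ms) and the
LSA group a near-flat profile (555/560/557 ms), SD 90 ms, 5% error rate;
no published RT table constrains these, so they are chosen as typical
adolescent dot-probe values. Amplitude outliers for artifact-rejection
tests (rectangular 40 ms, ±150 µV pulses on a random channel) are off by
default (`artifact_fraction = 0`).

Everything derives from one master seed through `numpy.random.SeedSequence`
spawning, so identical configurations give bit-identical datasets and each
subject is independently reproducible.

**What the generator does not emulate:** volume conduction and field
spread (each component is injected into named channels directly), ocular
and muscle artifacts (hence no ICA stage), latency jitter of the P2,
cross-frequency structure, and any relationship between RT behavior and
the EEG signals. Passing tests therefore demonstrate that the pipeline
recovers known effects embedded in realistic noise — not that it would be
robust to every pathology of real recordings.

## Behavioral indices

Incorrect trials are removed first; then, in a single pass, trials whose RT
deviates from the subject's mean by more than 2.5 SD (mean and SD over the
remaining correct trials; a zero SD excludes nothing). One pass, one
per-subject criterion: iterating the rule or computing it per condition are
defensible alternatives, but a single application of a single criterion is
the common convention and avoids convergence ambiguity. From condition-mean
RTs: OI = neutral − congruent, DI = incongruent − neutral, BI = OI + DI
(= incongruent − congruent); BI is computed as the sum so the additivity
identity is exact in floating point.

## ERP branch

Fixed order: common-average re-reference → zero-phase band-pass →
baseline correction (−100…0 ms) → artifact rejection (any |sample| >
100 µV drops the trial) → per-condition averaging. The filter is a
4th-order Butterworth run forward and backward (`sosfiltfilt`); zero phase
matters because the same filtering front-end serves the phase-based
connectivity. The default band is 1–40 Hz and is configurable: a 0.1 Hz
high-pass edge is equally defensible for ERP work (the source material is
ambiguous between the two), and on the synthetic P2 the choice shifts the
window mean by only a few percent. The P2 is quantified as the mean
voltage at Pz over 140–200 ms (inclusive sample window), averaged over
the valid trials of each of the congruent and incongruent conditions.
Peak-based scoring is deliberately not implemented: the group comparison
is defined on mean amplitude.

Note that common-average referencing attenuates a source present in one of
n channels by (n−1)/n; with the 32-channel montage this ~3% bias on the
injected amplitudes is well inside the between-subject Monte-Carlo error
the recovery tests allow, and it cancels from scale-free statistics
(t, d, F).

## Connectivity branch

For each band (delta 1–3, theta 4–7, alpha 8–13, beta 14–30, gamma
31–50 Hz) the *raw* epochs are re-filtered — the gamma band would
otherwise be truncated by the 1–40 Hz ERP filter, and a warning is
collected whenever a requested band exceeds a previously applied passband.
Instantaneous phase is the argument of the analytic signal (FFT Hilbert
transform). No reflection padding is applied: measured against
long-signal ground truth, mirror padding of either parity *increases*
phase error across the epoch (a reflected oscillation rotates backwards,
so the pads inject negative-frequency content); the bare transform
confines distortion to a few samples at the epoch edges for the bands of
interest.

PLV_ij = |mean over N of exp(i(φ_i − φ_j))|. Because "N" is ambiguous
between time points and trials, both estimators are provided:
`within_trial` (default) computes PLV over post-stimulus time points
(0–500 ms) within each trial and averages across trials — matching the
use of a single connectivity number per subject, condition and band —
while `across_trial` computes PLV across trials at each time point and
averages over time. Matrices are symmetrised, unit-diagonal, clipped to
[0, 1], written as labelled TSV with a JSON sidecar, and averaged
entrywise for group matrices. The within-trial null level for narrowband
signals over short epochs is high (the effective number of independent
phase samples is far below N), so uncoupled-pair baselines are assessed by
Monte-Carlo, not by the iid-phase formula √π/(2√N), which applies only to
independent phases (and is used as such for the across-trial estimator).

## Graph metrics

Connectivity matrices become weighted graphs (diagonal dropped). Nodal
metrics:

* **Degree Dc** — row sums of a binarised adjacency. Binarisation uses a
  proportional (sparsity) threshold keeping the strongest
  ⌊s·n(n−1)/2⌋ off-diagonal weights (default s = 0.2, configurable);
  zero-weight pairs are never promoted to edges, and exact ties are
  resolved in stable upper-triangle index order (documented,
  deterministic).
* **Strength Ne** — row sums of the full weight matrix.
* **Betweenness Bc** — Σ_{j≠i≠k} σ_jk(i)/σ_jk, unnormalised by default
  (a flag enables 2/((n−1)(n−2)) normalisation). Default on the weighted
  graph with edge length 1/w (strong links are short), which preserves
  weight information; a binary hop-count mode on the thresholded graph is
  available. Computed via networkx; validated against an exhaustive
  all-simple-paths oracle on small graphs.
* **Lateralization Nlp** — (S_iL − S_iR)/(S_iL + S_iR) with S_iL/S_iR the
  summed weights to left/right-hemisphere nodes; midline nodes are
  excluded from the sums but still receive a value; an isolated node
  (S_iL + S_iR = 0) is flagged undefined (NaN) rather than inventing a 0.

## Group statistics

* Independent-samples t-tests from raw vectors or summary statistics
  (mean, SD, n per group). The pooled rule is the default — it is the
  rule that exactly reproduces the published worked example (t = −2.237,
  df = 43, d = −0.681, CI (−2.715, −0.141) from the incongruent-P2
  summary rows) — with Welch available by flag. Cohen's d always uses
  the pooled SD; the 95% CI is on the mean difference. Zero-variance
  degenerate inputs yield signed-infinite t with p = 0 as an explicit
  signal.
* The 2×2 mixed ANOVA exploits the two-level within factor: the group
  effect is the pooled t² on subject means, the condition effect the t²
  of the *unweighted* mean of the two groups' difference-score means
  (the Type III convention, robust to unequal group sizes), the
  interaction the pooled t² comparing difference scores. All effects are
  F(1, N−2); partial η² = F/(F + df₂); Greenhouse–Geisser ε ≡ 1 for two
  within levels (reported for interface completeness). The decomposition
  reproduces R `car::Anova` type III (sum contrasts) exactly on all
  three effects.
* Pearson correlations via the t transform; Bonferroni adjustment
  p_adj = min(1, m·p). For the nodal contrasts the correction family is
  each band × condition × metric set of node-wise tests, and both raw
  and adjusted p are reported.
* Repeated-measures ANOVA power: for k groups and m measurements with
  repeated-measures correlation ρ and nonsphericity ε, the
  within/interaction effect of size f (Cohen) has noncentrality
  λ = f²·N·m·ε/(1−ρ) with df (m−1)ε and (N−k)(m−1)ε; power is the
  noncentral-F tail beyond the central-F critical value, and the sample
  size routine returns the smallest total N reaching the target power
  (for k = 2, m = 2 the within and interaction effects coincide under
  these conventions). With f = 0.25, α = 0.05, power 0.80, ρ = 0.5,
  ε = 1 this yields N = 34 (power 0.807 at 34, 0.795 at 33), matching
  the planning computation the design is based on.

## Pipeline, provenance, CLI

A single YAML config drives `simulate` → `analyze` → `report`
(`dotprobe-eeg` CLI or the `run_simulate`/`run_analyze`/`make_report`
functions). Datasets are one directory per subject (trial CSV, epoch
`.npy`, JSON sidecar) plus a config echo; results are tidy CSVs (indices,
ERP summary, ANOVA, contrasts, correlations, nodal metrics),
group-average connectivity TSVs, condition-average waveform CSVs, and a
manifest with the config echo, seeds, per-stage record counts (inputs
reconcile with used + excluded at every stage) and SHA-256 checksums of
every output, so a rerun under the same seed is verifiable
byte-for-byte. Stage failures abort with the stage name and offending
subject; analysis requires ≥2 subjects per group (the inferential layer
needs within-group variance).

## Validation scale and known limitations

The heavy closed-loop checks run at reduced, stated sizes chosen to keep
the suite quick while leaving conclusions unchanged: the ERP
power-recovery experiment (200 simulate-measure-test replicates at the
default group sizes, trial counts and amplitudes) and the PLV–κ
monotonicity grid use a 9-channel montage containing Pz and both coupled
pairs — the tested quantities (a rejection rate of a scale-free t-test;
the ordering of PLV means) are montage-size invariant. The type-I
calibration of the group t-test uses 5,000 summary-level null replicates.

Known limitations: no source-space analysis or anatomical labelling
(nodes are electrodes; region-level claims are outside scope); no WPLI or
other leakage-robust connectivity (PLV is sensitive to common reference
and volume conduction in real data — harmless here because the generator
injects no shared sources into uncoupled channels, but a caveat for any
real-data use); no global network metrics (path length, efficiency,
small-worldness); the ANOVA layer is specialised to the 2×2 mixed design
rather than general factorial models.
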