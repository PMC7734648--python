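# Methods

This note documents the models and algorithms implemented in
`necroptodyn`, the parameter and calibration choices behind them, the
numerical conventions, and what the synthetic-data validation does and does
not demonstrate.

## Conceptual IFFL models (`necroptodyn.conceptual`)

Two minimal variants contrast a *pre-existing* with an *inducible* survival
mechanism. Shared deterministic death arm (time in hours, concentrations in
arbitrary units):

    dR/dt = k_rip_act · TNF(t) · (1 − R) − k_rip_deact · R
    dP/dt = k_mlkl_on · R / (1 + X / K_X) − k_mlkl_off · P

R is the active RIP (RIPK1/3) fraction, P is pMLKL, and the survival factor
X inhibits the RIP→pMLKL flux with inhibition constant `K_X`. A cell dies
at the first grid time with P ≥ θ (θ = 1, no interpolation — mirroring
frame-based experimental death calls; deaths are latched for reporting).

X is the only stochastic quantity: bursts of fixed size arrive as a Poisson
process and X decays exponentially (rate `k_x_deg`) in between. Burst times
are sampled exactly (thinning for the time-varying case); between events
the system is integrated with classical RK4 on the 1.5-min output grid,
with X evaluated analytically at the RK midpoints. This is a
piecewise-deterministic Markov process: in the limit burst_size → 0 at
fixed burst_freq × burst_size it converges to the deterministic ODE, which
the test suite checks as a monotone shrinkage of death-time variance.

* **Constitutive variant** — constant burst propensity `burst_freq` =
  0.6/h, burst_size 40, `k_x_deg` = 0.15/h. X starts from its stationary
  distribution (realised by a 24-h burn-in of the burst process). The
  stationary X pool (mean 160, shape ≈ 4) spreads death times smoothly:
  unimodal distributions across the full ×0.5–×2 one-at-a-time parameter
  scan.
* **Inducible variant** — no basal bursts; burst propensity
  `k_x_induced` · N(t), where NFκB activity N follows an IκB-feedback motif:

      dN/dt = k_nfkb_act · TNF · (1 − N) − k_nfkb_deact · I · N
      dI/dt = k_ikb_syn · N − k_ikb_deg · I

  with k_ikb_deg = 0.02/h (IκB effectively stable over 24 h), giving a
  pulse of N that peaks within the first hour and adapts to a low residual.
  Induced bursts are large and shorter-lived (burst_size 400, k_x_deg
  0.25/h): a cell that receives no burst during the NFκB window dies early
  (~2–4 h); protected cells die late (~10–20 h) once X has decayed, and
  some survive 24 h. The death-time distribution is therefore bimodal.

Exact death times in these models are parameter-dependent by construction;
the modality dichotomy (constitutive ⇒ unimodal, inducible ⇒ bimodal) is
the robust feature, and the defaults were chosen so that both the dip-test
classification and its robustness to two-fold parameter changes hold at
population size 300.

## Full network model (`necroptodyn.network`)

The wild-type network has exactly 41 species and 98 reactions in three
modules:

* **TNFR–IKK** (24 reactions): TNF–receptor binding, complex-I (C1)
  assembly/activation, receptor internalisation and recycling, an
  IKKK→IKK kinase cascade with an inactive-IKK refractory state, and A20
  binding to active C1 and IKK that promotes their inactivation.
* **IκB–NFκB** (46 reactions): NFκB shuttling, IκBα/ε synthesis
  (NFκB-inducible + constitutive), nuclear import/export of free and bound
  IκB, IKK-mediated degradation of free and complexed IκB, a slow
  IκBδ-like compensatory inhibitor, and the A20 target gene (inducible +
  constitutive transcription, translation, turnover). NFκB-dependent
  transcription uses a Hill function of nuclear NFκB (Km 0.3, n = 2); the
  total NFκB moiety is conserved (no synthesis or degradation), which the
  test suite verifies to < 1e-6 relative drift over 24 h.
* **Necroptosis** (28 reactions): constitutive RIPK1/RIPK3/MLKL expression
  (mRNA + protein), C1a-catalysed RIPK1 activation, necrosome assembly
  from active RIPK1 and RIPK3, slow basal plus autocatalytic necrosome
  activation (the hours-long switch), A20 binding and disassembly of the
  active necrosome (the anti-necroptotic arm of the IFFL), and saturating
  MLKL phosphorylation (Km 3) with dephosphorylation and membrane
  translocation of pMLKL.

Rate-law kinds are mass-action, zeroth-order (constitutive synthesis),
transcriptional-synthesis (Hill in nuclear NFκB), and saturating
(Michaelis–Menten in the substrate). The full reaction table round-trips
bit-exactly through CSV (`ReactionNetwork.write_table` / `read_table`).

**Inputs.** TNF is an external clamp: amplitude 1.0 ≡ 10 ng/ml, held
constant for the schedule's duration and zero afterwards (washout);
integration is segmented at input discontinuities. The
`ikb_ko_extrinsic_nfkb` genotype zeroes every reaction of the IκB–NFκB
control subcircuit and clamps nuclear NFκB to a step function that drives
the NFκB target genes directly.

**Genotypes** are value edits, never structural edits (species/reaction
counts are invariant): RelA KO zeroes all NFκB-inducible synthesis;
A20 KO zeroes A20 synthesis; constitutive ×2/×4 A20 zeroes inducible A20
transcription and scales the constitutive term; inducible-reconstituted
A20 keeps only the inducible term.

**Heterogeneity** is extrinsic: each cell is a deterministic ODE system
with its own multipliers. A cell is an A20 "responder" with probability
0.76 (the measured smFISH responder fraction); non-responders have zero
inducible A20 transcription. Responders carry a lognormal multiplier
(σ = 0.4, unit mean) on inducible A20 transcription, and every cell a
lognormal multiplier (σ = 0.3, unit mean) on the RIPK1 activation rate.
The RIPK1 multiplier acts on the rate constant (not the initial amount).

**Death threshold.** pMLKL ≥ θ with θ = 1.5, calibrated once on the
wild-type sustained-TNF protocol so that 24-h survival is non-degenerate
and the late/early death-rate structure is biphasic, then frozen across
all genotypes and protocols — re-tuning per condition would be circular.

**Calibration.** The published structure fixes which interactions exist;
the rate constants here were parameterised from timescale targets and then
calibrated against the wild-type phenotype, in this order:
(1) NFκB activity and A20 mRNA transient under sustained TNF (peaks before
4 h, decay towards baseline), necrosome activity developing over hours;
(2) RelA-KO populations dying early and unimodally (median ≈ 4.5 h);
(3) wild-type populations bimodal with a late(≥12 h)/early(<12 h) mean
death-rate ratio ≈ 2 and low sustained-TNF survival;
(4) pulse discrimination (wild type better protected than RelA KO for
3–12-h TNF pulses; near-equal at sustained 24 h).
The extrinsic NFκB step amplitude (0.06 a.u.) was then calibrated so the
longest (16-h) step reproduces the predicted ~56% fractional survival;
below ~0.1 a.u. the protection during the step is partial and survival
responds sharply to amplitude, so the step series behaves almost
all-or-none between the 8-h and 16-h steps. All constants live in
`necroptodyn.network.PARAMS`.

**Numerics.** The whole population (41 × n_cells states) is integrated as
one batched system with explicit RK45 (rtol 1e-6, atol 1e-9, max step
0.25 h), dense output on a 1.5-min grid (961 frames for 24 h, inclusive
endpoint). The rate constants are deliberately on a gentle scale
(≤ ~30/h), which keeps the system non-stiff and makes the batched explicit
integration ~20× faster than per-cell implicit solves; the conservation
and non-negativity checks in the test suite guard the accuracy of this
choice. States are clipped at zero inside the right-hand side to keep
rates well-defined under solver trial steps.

## Death-kinetics conventions (`necroptodyn.kinetics`)

* **Death call**: first frame of the first run of ≥ 6 consecutive frames
  with intensity strictly greater than the threshold; latched thereafter.
* **Death rate**: forward-anchored window — at frame time t, deaths in
  (t, t + 5 h] divided by cells alive at t; per-hour rate = window
  fraction / window length. No partial windows at the end of the movie; the
  series stops when the alive population drops below 1/3 of the *starting*
  population (or reaches zero). No smoothing is applied.
* **Histogram**: 12 bins of 2 h from 0.5 to 24.5 h, density normalised to
  integrate to 1 over observed deaths; censored cells never enter the
  histogram but always count in at-risk denominators. Out-of-range deaths
  are counted and logged.
* **Dip test**: Hartigan & Hartigan's dip statistic via the greatest-convex
  minorant / least-concave-majorant algorithm (implemented in
  `necroptodyn._dip`, numba-accelerated, and verified in the tests against
  an LP brute-force minimisation over piecewise-linear unimodal CDFs). The
  probability of unimodality is the Monte-Carlo fraction of uniform(0,1)
  samples of the same n with dip ≥ observed (null draws cached per sample
  size; seeded). Per-condition probabilities are compared with a standard
  pooled-variance two-sample t-test.
* **Proliferative index**: divisions per non-overlapping 4-h window
  divided by alive cells at the window start.

## Imaging (`necroptodyn.imaging`)

Nuclear-stain-only segmentation: median-background subtraction, Gaussian
smoothing (σ 2 px), Otsu threshold (overridable), watershed seeded at
smoothed local maxima, minimum-area filter. Tracking is greedy
nearest-centroid linking (closest pair first) under a hard displacement
gate; unmatched detections start new tracks and there is no gap bridging.
Traces are mean death-marker intensity over each track's nuclear mask;
`run_nectrack` composes segment → track → measure → call_deaths →
death_rate, scoring only tracks that span at least half the movie (short
fragments carry no death-time information) and padding trace edges.
The default death-marker threshold is Otsu on the channel histogram;
real-data thresholds should be supplied explicitly.

## smFISH (`necroptodyn.smfish`)

DoG band-pass = blur(σ 0.8) − blur(σ 2.5) (in px); spot candidates are
strict 8-neighbourhood local maxima of the clipped response, scored by
their 3×3-neighbourhood mean (plateau ties are not reported). The high
hysteresis threshold sits at the elbow of the spot-count-vs-intensity
curve — the point of the normalised log-count curve farthest below its
end-to-end chord, separating the steep noise regime from the spot
plateau; the low threshold is 0.5 × high. Candidates above high are kept
outright; candidates above low are rescued only when 8-connected, within
a compact (≤ 64 px) support component of the low-thresholded response, to
a kept spot — sprawling low-level components are noise percolation, not
spot halos. Nuclei: watershed on the negative smoothed (σ 5 px) DAPI
intensity seeded at its local maxima; cytoplasm: watershed of the negative
smoothed autofluorescence seeded by the nucleus labels, restricted to the
autofluorescent foreground. Spots are assigned by mask containment;
per-cell counts are volume-normalised (raw / area × mean area),
log2-transformed with pseudo-count 1, and a cell is a responder when its
*normalised* A20 count exceeds 1 (the normalisation-then-threshold order
is a deliberate convention).

## Synthetic data (`necroptodyn.synthetic`)

The generators emulate the study conditions: 1.5-min frame interval over
24 h (961 frames, inclusive endpoint), nuclear + death-marker channels,
death-marker intensity stepping up at death (jump to 60% of the step at
the death frame, full amplitude over the rise window — so a half-amplitude
threshold is crossed at the death frame itself), nuclei as isotropic
Gaussians (half-maximum at the nominal radius) on a constant background
with additive Gaussian noise, bounded random-walk motion, optional
divisions (off by default for kinetics fixtures), and a 0.76 responder
fraction with per-class transcript-count laws for smFISH scenes. Trace
fixtures additionally cap pre-death noise excursions at runs of ≤ 5
above-threshold frames, so the 6-frame persistence rule is exercised
non-trivially but never fires early.

Not emulated: DIC/transmitted-light channels, photobleaching and
illumination-field artifacts, 3-D stacks, segmentation-confounding debris,
apoptotic morphologies, and transcriptional dynamics beyond static
per-cell counts. Passing the recovery contracts therefore demonstrates
correctness of the algorithms under the stated image-formation model, not
performance on real microscopy data; on real data, thresholds (PI
intensity, displacement gates) must be set by the user.

## Problem sizes in the test suite

Population simulations run at the study scale of 300 cells. The
end-to-end movie recovery tests render 512×512 movies at a 6-min frame
interval (241 frames) — the recovery contract (±2 frames) is evaluated on
the movie's own grid, and the coarser cadence keeps the rendered data at a
tractable size. smFISH recovery runs one 1536×1536 field with 500 cells
for the responder contract and a sparser 768×768 field (≤ 0.02 spots/px²,
SNR 10) for the spot-F1 contract, matching that contract's stated
operating regime; at the default dense-scene counts (~10 transcripts per
responder cell) sub-PSF spot spacings make merged maxima physically
unavoidable and recall tops out lower, which is a property of the imaging
model, not of the detector.

## Known limitations

* The network parameterisation is calibrated to reproduce the wild-type
  and perturbation phenotypes described above, not fitted to molecular
  time-course data; absolute concentrations and rates are in arbitrary
  units.
* The dip-test p-value uses the uniform null (the standard calibration);
  p-values for small samples (n < ~30) are conservative.
* The greedy tracker assumes motion small relative to nucleus spacing; it
  does not handle merges, splits, or gap closing.
* Constitutive ×4 A20 fully protects the simulated population within 24 h
  (an empty death-time histogram), consistent with strong protection but
  without a quantitative survival claim.
* The extrinsic-NFκB step series transitions sharply between the 8-h and
  16-h steps (see Calibration); intermediate-duration behaviour is not
  graded.
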