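# necroptodyn

Models and analytics for TNF-induced necroptosis fate decisions in single
cells.

TNF signals through NFκB to coordinate inflammatory gene expression, but it
can also kill the same cell by necroptosis: RIPK1 and RIPK3 assemble the
necrosome, which phosphorylates MLKL (pMLKL) and ruptures the plasma
membrane. Whether a cell dies, and *when*, is shaped by an incoherent
feedforward loop (IFFL): TNF drives both the death arm and — via
NFκB/RelA-inducible expression of A20 — an inhibitor of the death arm. Because
induced A20 is transient, the circuit protects a fraction of cells from
short TNF exposures while leaving them sensitive to sustained exposure, and
it splits the population's death times into two phases.

`necroptodyn` implements, in one package:

* **Conceptual IFFL models** (`necroptodyn.conceptual`) — a minimal hybrid
  model in which a survival factor X, expressed in stochastic bursts
  (constitutively, or driven by IκB-controlled NFκB activity), inhibits the
  RIP→pMLKL flux; a cell dies when pMLKL crosses a threshold θ. The
  constitutive variant yields unimodal death-time distributions, the
  inducible variant bimodal ones.
* **A full reaction network** (`necroptodyn.network`) — 41 species, 98
  reactions across TNFR–IKK, IκB–NFκB and necroptosis modules, with
  genotype edits (RelA KO, A20 KO, constitutive/inducible A20 transgenes,
  extrinsic NFκB step functions) and extrinsic cell-to-cell heterogeneity
  (a 76% A20 "responder" fraction, lognormal variability of inducible A20
  transcription and of RIPK1 activation). Populations of virtual cells are
  integrated as one batched ODE system.
* **Death-kinetics analytics** (`necroptodyn.kinetics`) — death calling from
  nuclear death-marker (PI) traces with a six-consecutive-frame persistence
  rule, latched alive/dead matrices, forward 5-h sliding-window death rates
  normalised to the at-risk population with a 1/3-alive stop rule,
  pdf-normalised 2-h death-time histograms, Hartigan's dip statistic with a
  Monte-Carlo probability of unimodality, and per-replicate unimodality
  comparisons by two-sample t-test.
* **Live-cell image analysis** (`necroptodyn.imaging`) — nuclear
  segmentation, greedy nearest-centroid tracking, mean nuclear intensity
  traces, and the composed movie→death-kinetics pipeline.
* **smFISH quantification** (`necroptodyn.smfish`) — difference-of-Gaussians
  band-pass (σ 0.8/2.5 px), strict local-maxima spot calling scored by 3×3
  means, hysteresis thresholding from the spot-count-vs-intensity elbow,
  DAPI watershed nuclei, autofluorescence-valley cytoplasm segmentation,
  mask-containment spot assignment, area-based volume normalisation, and
  responder fractions (normalised A20 count > 1).
* **Synthetic data with ground truth** (`necroptodyn.synthetic`) — rendered
  two-channel time-lapse movies with planted deaths and divisions, intensity
  trace fixtures, four-channel smFISH image sets with planted
  diffraction-limited spots, and Gaussian-mixture death-time samples. Every
  analysis stage is validated against these generators; no external data is
  required.

## Worked example

Simulate TNF-treated wild-type and RelA-knockout populations of 300
heterogeneous virtual cells and test the modality of their death times:

```bash
necroptodyn sim-network --genotype wt -n 300 --seed 0 --out out/wt
necroptodyn sim-network --genotype relA_ko -n 300 --seed 0 --out out/ko
```

prints (wild type, then RelA KO):

```json
{"genotype": "wt",      "n_cells": 300, "deaths": 295,
 "fractional_survival_24h": 0.017, "dip": 0.0857, "p_unimodal": 0.0}
{"genotype": "relA_ko", "n_cells": 300, "deaths": 300,
 "fractional_survival_24h": 0.0,   "dip": 0.0211, "p_unimodal": 0.494}
```

The wild-type population is significantly non-unimodal (`p_unimodal` = 0.0:
an early death phase of A20 non-responders and a late phase once induced
A20 has decayed), while the RelA knockout — which cannot induce A20 — dies
in a single early unimodal wave (`p_unimodal` ≈ 0.49, unimodality not
rejected). Per-cell death times land in `out/*/death_times.csv` and
population summaries of NFκB activity, A20 mRNA/protein, necrosome activity
and pMLKL in `out/*/summary_*.csv`.

The same analysis runs on rendered synthetic movies:

```bash
necroptodyn synth movie --out movie/ --seed 1
necroptodyn nectrack --nuclear movie/nuclear.tif --pi movie/death_marker.tif --out nt/
```

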