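# smdol — single-molecule degree-of-labeling estimation

How completely does a fluorescent substrate actually label a protein
tag (SNAP-tag, HaloTag, ...)? Quantitative single-molecule microscopy
needs that number — the **degree of labeling (DOL)** — to convert
counted fluorophores into protein copy numbers, yet it varies with
substrate, concentration, incubation time, fixation and cell type.
`smdol` estimates the DOL per cell from dual-channel diffraction-limited
TIRF images of a membrane-anchored probe that carries a reference
fluorophore (eGFP-like, present on every probe copy) alongside the tag:
the fraction of reference molecules with a colocalized target-channel
signal, corrected for density-dependent detection losses, is the DOL.
The package is aimed at labs calibrating labeling protocols and at
anyone converting single-molecule counts into stoichiometries.

## Method in brief

For localization sets of the two channels (after cell segmentation,
sub-pixel Gaussian fitting, PSF-width filtering and chromatic affine
registration), the specific and random colocalization fractions over a
distance tolerance t are

    F_c(t) = ( # one-to-one pairs with Δd ≤ t ) / N_ref
    F_r(t) = same, after rotating the target channel 90° about the frame centre

and the cutoff T maximises z(t) = F_c(t) − F_r(t) (smallest such t;
per-image pair counts are pooled across the cells of an experiment).
The per-cell degree of colocalization DOC = F_c(T) is then converted to
a DOL with a simulation-derived, fitter-specific recall line:

    DOL = ( DOC − F_r(T) ) / ( CF_slope · ρ_measured + CF_offset )

where ρ_measured is the reference localization density per µm² of cell
mask. Unspecific label density (target signals not attributable to the
tag, per µm² of cell) is reported alongside. For bulk (antibody)
conjugates the ensemble DOL follows from absorbances,
DOL = A_label·ε_target / (ε_label·(A_280 − c_280·A_label)), with helpers
for label-number distributions, the unlabeled fraction and
copy-number extrapolation. A full synthetic image generator
(`smdol.sim`) reproduces the measurement — blinking/bleaching
photophysics, camera noise, chromatic offsets — so the whole chain is
testable against ground truth. See `docs/methods.md` for the complete
model description.

## Worked example

Simulate a small experiment at true DOL 0.5 and 0.3 probes/µm²,
calibrate the recall line, and analyse:

```sh
smdol simulate --n-cells 3 --seed 4 --density 0.3 --out demo/
smdol calibrate --out demo/cal.csv --n-replicates 2 --seed 5
smdol analyze --in demo/ --calibration demo/cal.csv --out demo/results.csv
smdol report --in demo/results.csv --condition demo
```

prints

```
wrote 3 simulated cells to demo
cf_slope -0.1305 /(um^-2), cf_offset 1.0010, R^2 0.541
3 cells, T = 140 nm, DOL median 0.477 +/- 0.047 (s.d.)
demo: n=3 cells, DOL 47.7 +/- 4.7% (median +/- s.d.), unspecific 0.0199/um^2
```

Reading this: the recall calibration says the pipeline recovers
essentially all colocalization events at zero density (offset ≈ 1.00)
and loses ~13% per emitter/µm² (slope −0.13); the data-driven
colocalization cutoff settled at 140 nm; and the three cells, simulated
at a true DOL of 0.5, come back at 47.7 ± 4.7% with an unspecific
label density of 0.02/µm². Per-cell numbers (counts, densities, DOC,
random-colocalization fraction, QC flags) are in `demo/results.csv`.

The same flow in Python:

```python
from smdol import AnalysisConfig, SimConfig, analyze_experiment, calibrate_recall, simulate_experiment

config = AnalysisConfig()
calib = calibrate_recall(SimConfig(), config, n_replicates=6, seed=0)
cells = simulate_experiment(SimConfig(true_dol=0.5, probe_density_um2=0.3), 10, seed=1)
results, ctx = analyze_experiment([(c.reference, c.target) for c in cells], config, calibration=calib)
```

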