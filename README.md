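# memdomain

Quantification of cholesterol/sphingomyelin membrane nanodomains ("lipid
rafts") from three kinds of live/fixed-cell fluorescence data:

* **qSMLM** — blinking single-molecule localization tables are turned into
  per-ROI surface densities, cluster radii, molecules per cluster and
  clusters per μm², with fiducial-based drift correction and blinking
  correction through the mean number of localizations per probe (α);
* **FCS** — photon-count traces from a confocal spot are autocorrelated
  (`G(τ) = ⟨I(t)I(t+τ)⟩/⟨I(t)⟩²`) and fitted with a triplet-corrected
  one-component 3D model (calibration dye) or a two-component 3D + 2D model
  (probe free in the medium + bound to the membrane), yielding the membrane
  diffusion coefficient `D = ω²xy/(4 τ_D2)`, the apparent membrane density
  `ρ = F₂ N/ω²xy` and the molecular brightness `CPM = I/N`;
* **ratiometric imaging** — the Fura Red calcium ratio
  `FRr(t) = I_bound/I_unbound` (baseline over the pre-stimulus frames,
  amplitude at the first post-stimulus maximum) and the generalized
  polarization `GP = (I₅₆₀₋₅₈₀ − I₆₄₀₋₆₆₀)/(I₅₆₀₋₅₈₀ + I₆₄₀₋₆₆₀)` of a
  solvatochromic membrane dye, read at the membrane position of line
  profiles.

A bespoke split-sampling sufficiency test (randomize, split in two, Welch
t-test, 15 repetitions, mean p ≥ 0.1 ⇒ sufficient sampling) and thin
wrappers for Welch t / Mann–Whitney / ANOVA+Tukey group comparisons cover
the reporting statistics. Because this class of microscopy data is rarely
deposited, the package ships first-class synthetic-data generators with
known ground truth for every input, and the whole chain is validated as a
set of recovery problems.

Intended users: quantitative microscopists and method developers who need a
tested, scriptable reference implementation of this analysis stack.

## Worked example

Simulate the default clustered membrane field (5 clusters/μm² with on
average 10 molecules per cluster, Gaussian spread σ = 30 nm, 20 background
molecules/μm², α = 3.3, 15 nm localization precision, 60,000 frames) and
quantify one 3 × 3 μm ROI:

```python
import numpy as np
from memdomain import smlm
from memdomain.synthetic_data import SmlmGroundTruth, simulate_smlm

table, truth = simulate_smlm(SmlmGroundTruth(), seed=0)
table = smlm.correct_drift(table)
phys = smlm.PhotophysicsModel(alpha=3.3, max_dark_time=20.0, max_dark_frames=2000)
report, pc = smlm.analyze_roi(table, smlm.Roi((1000, 1000), 3000), phys)
print(pc.summary())
print({k: round(v, 2) for k, v in report.as_dict().items()})
```

prints

```
Pair-correlation analysis
  points: 1762   density: 195.778 /um^2
  converged: True
  cluster radius xi: 29.7 nm   amplitude A_c: 24.025
  blinking sigma: 15.0 nm   amplitude A_psf: 0.000
{'detected_density': 59.33, 'cluster_radius': 29.72, 'molecules_per_cluster': 8.33, 'clusters_per_area': 3.33, 'clustered_fraction': 0.47}
```

The localization density in the ROI (195.8/μm²) divided by α gives the
blinking-corrected 59.3 molecules/μm² against a true 70 (cluster-edge and
single-ROI sampling account for the gap; the 5-seed mean lands within 10%).
The pair-correlation cluster radius ξ ≈ 30 nm sits at the analytic target
for this truth (≈ 31 nm once localization noise is folded in), and
3.3 clusters/μm² of the 4.85 expected above the more-than-four-molecule
rule are found in this single ROI.

The same chain is scriptable from the shell:

```sh
memdomain simulate-smlm --out field.csv --seed 0
memdomain analyze-smlm --loc field.csv --alpha 3.3
memdomain run --config run.yaml     # cohort simulate → analyze → report
```

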