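# pipbind

Quantitative analysis of PCNA–PIP-Box interactions: exact competitive-
binding equilibria and curve fits for fluorescence-polarization (FP)
assays, Cheng–Prusoff inhibition constants, assay quality control,
forward/reverse PIP-Box motif scanning, and trajectory-ensemble analytics
(RMSD/RMSF/PCA/ΔSASA anchor classification).

PCNA (proliferating cell nuclear antigen) is a homotrimeric sliding clamp
that recruits replication and repair proteins through the eight-residue
PIP-Box motif, QXXφXXΩΩ (φ hydrophobic, Ω aromatic).  Peptide mimics of
these motifs compete with a fluorescent probe for the PIP-Box site, and
their affinities are read out by fluorescence polarization.  `pipbind`
implements the full analysis chain for such experiments, for assay
scientists and modelers who need the exact (ligand-depletion-aware)
binding models rather than the dose–response shortcuts.

## The models at the core

Observed anisotropy r converts to probe occupancy with the quantum-yield
ratio Q = q_b/q_f:

    f_b = (r − r_f) / [(r − r_f) + Q (r_b − r)]

Direct titrations are fitted with the Hill isotherm
f_b = Pⁿ/(K_dⁿ + Pⁿ) mapped through this conversion.  Competition data
are described by exact mass-balance models:

* **complete displacement** — R + L* ⇌ RL\* (K_d1), R + I ⇌ RI (K_d2);
  the free receptor is the physical root of a cubic and the probe
  occupancy is [R]/([R] + K_d1);
* **incomplete displacement** — the four-state model adding
  RI + L* ⇌ RIL\* (K_d3), which plateaus above zero at saturating
  competitor (the signature used to select between the two models).

IC50s from a four-parameter logistic are converted to inhibition
constants with the classic Cheng–Prusoff equation
K_i = IC50/(1 + L/K_d) or its FP-corrected form
K_i = IC50/([L]₅₀/K_d + [P]₀/K_d + 1).

Assay QC uses Z′ = 1 − 3(σ₊+σ₋)/|μ₊−μ₋| and two-sided Grubbs outlier
screening of replicates.  See `docs/methods.md` for assumptions,
defaults and numerical details.

## Worked example

Simulate a p21-like competition experiment (a partial displacer:
K_d2 = 477 nM with a residual ternary state, K_d3 = 2.9 µM) at the
standard conditions — 50 nM probe, 1 µM PCNA monomer, probe
K_d1 = 760 nM, anisotropy noise 0.003 on 4 replicates — and analyze it:

```python
import numpy as np
from pipbind import *
from pipbind.synthetic import AssayGroundTruth, simulate_competition

grid = np.sort(np.array([1e-4 / 2.0**k for k in range(15)] + [0.0]))
truth = AssayGroundTruth(K_d2=477e-9, K_d3=2.9e-6, noise_sd=0.003, seed=11)
series = simulate_competition(truth, grid)

ic50 = fit_ic50(series)
model = select_competition_model(ic50)
print(f"IC50 = {ic50.IC50*1e6:.2f} uM   Hill slope = {ic50.hill_n:.2f}   "
      f"fb at max = {ic50.fb_at_max:.2f}   model: {model}")

fit = fit_competition_incomplete(series, K_d1=760e-9, seed=11)
print(f"Kd2 = {fit.K_d2*1e9:.0f} nM   Kd3 = {fit.K_d3*1e6:.2f} uM")

fb0 = hill_fraction_bound(1e-6, 760e-9)
ki = ki_modified(ic50.IC50, fb0, 50e-9, 1e-6, 760e-9)
print(f"Ki (modified Cheng-Prusoff) = {ki.K_i*1e6:.2f} uM")
```

Output:

```
IC50 = 1.33 uM   Hill slope = -1.19   fb at max = 0.26   model: incomplete
Kd2 = 423 nM   Kd3 = 2.81 uM
Ki (modified Cheng-Prusoff) = 0.57 uM
```

The residual occupancy at the highest competitor concentration (0.26)
flags incomplete displacement, so the four-state model is fitted; both
dissociation constants come back near their ground truth (477 nM,
2.9 µM), and the logistic IC50 converts to an apparent K_i of 0.57 µM —
as expected for a partial displacer, a blend of the two underlying
constants rather than either one.

A `pipbind` command-line tool wraps the same functionality
(`pipbind simulate|qc|zprime|fit-direct|fit-competition|ki|scan|traj`);
run `pipbind --help`.

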