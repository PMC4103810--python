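# Methods

`pipbind` analyzes fluorescence-polarization (FP) binding and competition
assays of the PCNA–PIP-Box interaction, scans protein sequences for
forward and reverse PIP-Box motifs, and post-processes structural
ensembles of PCNA–peptide complexes.  This note records the models, the
defaults and why they were chosen, and what the synthetic data do and do
not establish.

## Anisotropy and occupancy

A fluorescent peptide probe (FITC-PL) reports binding through its
anisotropy r, which rises from r_f (free) to r_b (bound).  Binding also
quenches the fluorophore, so occupancy is not a linear interpolation
between the endpoints; with the quantum-yield ratio Q = q_b/q_f,

    f_b = (r − r_f) / [(r − r_f) + Q (r_b − r)].

Defaults mirror the assay this package models: r_f = 0.0470,
r_b = 0.1587, Q = 0.70 (probe quenched ~30% on binding).  The inverse map
is exact and used by the simulators.  Converted f_b values are **not**
clamped to [0, 1] before fitting — clamping truncates the noise
distribution and biases least squares; clamp only for display.

A consequence of Q ≠ 1 worth spelling out: for 1:1 binding the raw
anisotropy curve is *exactly* hyperbolic with apparent midpoint K_d/Q.
Fitting a Hill isotherm directly to anisotropy therefore estimates
K_d/Q, not K_d (a 43% error at Q = 0.70).  `fit_direct` avoids this by
pushing the Hill occupancy through the Q-corrected conversion above, with
Q fixed from the calibration and r_f, r_b free parameters.

## Binding models

* **Direct binding** R + L* ⇌ RL* (K_d1): exact ligand-depletion solution
  from the quadratic mass balance, in the cancellation-free form.
  Titration *fits* use the phenomenological Hill isotherm
  f_b = Pⁿ/(K_dⁿ + Pⁿ), matching how such assays are conventionally
  reported; n absorbs apparent cooperativity of the trimeric receptor.
* **Complete competition** adds R + I ⇌ RI (K_d2).  The free receptor is
  the physical root of the competitive-binding cubic
  [R]³ + d[R]² + e[R] + f = 0 with
  d = K_d1 + K_d2 + L_ST + L_T − R_T,
  e = K_d1 K_d2 + K_d2(L_ST − R_T) + K_d1(L_T − R_T),
  f = −K_d1 K_d2 R_T,
  computed by the trigonometric solution (the largest real root is the
  physical one) and polished with a few Newton steps on the mass-balance
  residual; a log-space bisection fallback guards marginal discriminants.
  Probe occupancy is [R]/([R] + K_d1).
* **Incomplete competition** (four-state): RI + L* ⇌ RIL* (K_d3) lets
  the probe bind competitor-occupied receptor, so displacement plateaus
  at the occupancy of a receptor with affinity K_d3.  Given free [R],
  the two ligand balances reduce to a quadratic in free competitor —
  solved in closed form — and the outer [R] balance is monotone, solved
  by bracketed root-finding **in log space** (under a tight competitor
  the free receptor can sit many orders of magnitude below R_T, where
  absolute tolerances are meaningless).  The ternary complex is assumed
  spectroscopically identical to the binary probe complex.

All solvers conserve mass to 1e−9 relative (enforced; property-tested),
and an independent plain-bisection oracle exists purely for tests.

## Fits, IC50 and inhibition constants

Fits operate on replicate-level residuals (unweighted) after per-point
Grubbs screening; mechanistic parameters are optimized as log10 values so
positivity is structural, with standard errors delta-transformed back.
The four-state fit uses three seeded starts because K_d2/K_d3 couple in a
shallow valley when the plateau is barely sampled; an unsampled plateau
(observed f_b at the top concentration < 0.02) triggers an
identifiability warning — K_d3 then has only a lower bound.

IC50s come from a four-parameter logistic in log concentration with a
*signed* Hill slope (negative for displacement).  The logistic is not the
exact shape of a depletion-corrected competition curve; at the modeled
conditions (1 µM receptor, 50 nM probe) the noiseless mismatch in IC50 is
~0.8%, which bounds how literally the logistic IC50 should be read.

Model selection between complete and incomplete displacement follows the
residual occupancy at the highest tested competitor concentration:
incomplete iff f_b(max) > 0.05 (strict inequality; threshold
configurable).  The paper-level rule is "f_b ≠ 0", which is not decidable
on noisy data; 0.05 is roughly 2.5 standard errors of a 4-replicate mean
at the default noise.

Two IC50 → K_i conversions are provided:

* classic Cheng–Prusoff, K_i = IC50/(1 + L/K_d);
* the FP-corrected form K_i = IC50/([L]50/K_d + [P]0/K_d + 1) with
  [L]50 = L_ST(1 − f_b0/2) (free probe at 50% inhibition) and
  [P]0 = R_T − f_b0 L_ST (free receptor at zero inhibition), following
  the Nikolovska-Coleska definitions of the free species.

## Quality control

Z′ = 1 − 3(σ₊ + σ₋)/|μ₊ − μ₋| with sample standard deviations.  Grubbs'
test is two-sided, single-pass, per concentration point: with N = 4 the
statistic is bounded by (N−1)/√N = 1.5 against a critical value of 1.481
at α = 0.05, so only gross artifacts are detectable and iterative
deletion would be unstable.  Zero-variance points are never flagged.

## Motif scanning

The PIP Box is modeled as an 8-position residue-class pattern.  Presets:
`strict` = Q,x,x,φ,x,x,Ω,Ω and `relaxed` = Q,x,x,φ,x,x,x,Ω with
φ = {L,I,M,V,F} and Ω = {F,Y,W} by default.  Published screens disagree
about histidine as an aromatic and about A/C as hydrophobics, so the
classes are configuration, not constants.  Reverse-orientation partners
(e.g. the Akt kinase) are detected by matching the reversed window
against the forward pattern; all overlapping hits in both orientations
are reported.  Note the limits of any such pattern: one published
partner motif (PLCγ, QEHLADHE) carries no aromatic in its final
positions and cannot match any Q…aromatic pattern — screens that list it
used looser criteria than the canonical definition.

## Trajectory analytics

Superposition is the Kabsch least-squares rotation (SVD with reflection
guard); it requires ≥ 3 non-collinear atoms.  RMSD series are computed
against a reference frame after per-frame superposition; RMSF is the
root-mean-square deviation of each atom from its time-average position
after aligning all frames to frame 0 on the masked (typically Cα) atoms.
Snapshot PCA eigendecomposes the 3N×3N Cartesian covariance of the
aligned, flattened frames (the frame-space Gram matrix is used instead
when frames are fewer than coordinates — same nonzero spectrum); a
residue range can be dropped first to exclude mobile termini.

SASA is Shrake–Rupley with Bondi van-der-Waals radii, probe 1.4 Å, and a
deterministic golden-spiral point set, 960 points/atom by default (single
atom accurate to ~0.1%; doubling the point count moves per-residue values
by < 1%).  ΔSASA of a bound ligand residue is its isolated SASA minus its
in-complex SASA at identical coordinates, hence non-negative up to
sampling noise (±0.5 Å²).  Ligand residues are classified as **anchor**
when ΔSASA strictly exceeds 70 Å², else **tether** when at least one
polar contact (hydrogen bond or salt bridge) is recorded, else other.
Hydrogen bonds use the common geometric convention — donor–acceptor
heavy-atom distance ≤ 3.5 Å and, when a hydrogen is resolvable, a D–H–A
angle ≥ 120° (both inclusive, both configurable); an electrostatic
"salt-bridge" criterion (≤ 4.0 Å between charged groups) can be supplied
through the same evidence channel.

Multi-model PDB files are the trajectory interchange format; atom
identity and order must be identical across MODEL blocks (validated on
read).

## Synthetic data: what it emulates and what it does not

Generators are pure functions of (truth, seed) through a single
`numpy.random.default_rng` stream.  Defaults reproduce the modeled assay:
probe 50 nM, receptor 1 µM monomer, K_d1 = 760 nM, the calibration above,
Gaussian anisotropy noise σ = 0.003 on N = 4 replicates, and optional
gross outliers of ±0.05 anisotropy (about half the assay window — the
magnitude an air bubble or dust produces, and the scale at which a
4-replicate Grubbs screen has useful power).  Canonical designs used in
the tests: a 12-point log titration grid from 10 nM to 32 µM, and a
16-point 2-fold competitor dilution from 100 µM plus a zero point.

The structural generators produce Cα-only chains with imposed per-residue
fluctuation profiles (per-axis σ = profile/√3 so the 3-D RMSF equals the
profile, plus removable rigid-body motion per frame) and single-atom
"residue" peptides whose designated residues are enclosed in receptor-atom
cages, making ΔSASA ground truth exact (buried ⇒ ΔSASA = isolated SASA;
exposed ⇒ 0).

What passing on these data shows: the estimators are unbiased and
appropriately precise when the model generating the data is the model
being fitted, and the geometric/surface kernels agree with independent
oracles.  What it does not show: robustness to real-assay pathologies the
generator omits — peptide aggregation at high concentrations, plate
drift, non-Gaussian photophysics beyond the single Q factor — nor any
force-field realism in the toy ensembles.

## Numerical conventions

Concentrations are molar internally (CSV I/O converts declared nM/µM/M);
negative round-off in solver outputs is clamped to zero but genuine tiny
species are kept so mass balances close; equilibrium solves are accurate
to better than 1e−9 relative (oracle cross-checks at 1e−12); optimizer
multi-start jitter is seeded; sphere sampling and all generators are
deterministic at fixed seed.  Degenerate inputs (flat series, equal
control means, collinear geometries, N < 3 replicates) raise typed errors
or return flagged fits rather than numbers.

## Known limitations

Estimated K_i values inherit the logistic-IC50 approximation; the
four-state K_d3 is identifiable only when the displacement plateau is
sampled; the trimeric receptor is treated phenomenologically through the
Hill slope (no explicit trimerization equilibrium or site-site coupling);
SASA uses a single radii set without explicit hydrogens; and the motif
scanner scores presence, not affinity.
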