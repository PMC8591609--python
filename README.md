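# dendricomplex

Analytics for the complexation of cationic dendrimers (PAMAM, PPI) with the
anionic photosensitizer rose bengal (RB): binding stoichiometry from
titration curves, dendrimer protonation/charge modelling, and structural
descriptors of conformational ensembles — size, shape, core-referenced
radial organisation, hydrogen bonding, and internal void volume.

It is written for people who study dendrimer nanocarriers: the titration
estimators analyse real spectrofluorimetric or zeta-potential data, and the
ensemble descriptors analyse multi-frame PDB/GRO/XYZ coordinate files from
any source. Because deposited trajectories and raw titrations are rarely
available, the package ships first-class synthetic-data generators that
produce every input with known ground truth, so the whole pipeline is
testable end to end.

## What it computes

**Charge model.** A dendrimer of generation *g* (G3 = 32, G4 = 64 terminal
primary amines) is a stack of amine layers halving toward a 2-amine core.
At neutral pH PAMAM protonates only its terminal layer; PPI protonates the
terminals plus alternating tertiary layers (2/3 of all amines). Net formal
charges: +32 (PAMAM G3), +64 (PAMAM G4), +42 (PPI G3), +84 (PPI G4).

**Stoichiometry (Job's method, titration form).** A titration response
y(x) — the fluorescence ratio F564/F575 or the zeta potential in mV versus
the RB:dendrimer molar ratio x — shows two regimes: a binding limb and a
saturation plateau. Lines are fitted by least squares to the two regimes
over a grid of candidate breakpoints; the stoichiometry *n* (RB per
dendrimer at saturation) is the x-coordinate where the SSE-optimal pair of
lines intersects.

**Shape.** Mass-weighted radius of gyration
RoG = √(Σᵢ mᵢ|rᵢ − r_cm|²/Σᵢ mᵢ); principal inertia moments Ix ≤ Iy ≤ Iz;
aspect ratios Ix/Iy, Ix/Iz; asphericity δ = 1 − 3⟨I₂⟩/⟨I₁²⟩ with
I₁ = Ix+Iy+Iz, I₂ = IxIy+IyIz+IxIz and ⟨·⟩ the time average (0 for a
sphere, →0.25 for a thin rod).

**Radial organisation.** Shell-volume-normalised density profiles and RDFs
of any labelled species (RB, water, ions, amines) about the dendrimer core,
plus the fraction of a species inside a given radius (e.g. ligand inside
the RoG).

**Hydrogen bonds.** Geometric detection over explicit donor/hydrogen and
acceptor lists (defaults: donor–acceptor ≤ 0.35 nm, deviation at the donor
≤ 30°), classified as dendrimer-internal, with water, or with RB.

**Void volume.** V_sasa(r_p), the volume enclosed by the solvent-accessible
surface at probe radius r_p, is computed on a grid with a boundary flood
fill so probe-inaccessible pockets count as enclosed. A line fitted to
V_sasa^⅓ over large probes (≥ 0.4 nm) is extrapolated to a small probe
(0.3 nm); the deviation from the measured volume there estimates internal
cavity volume. For complexes, RB atoms are removed before the sweep so the
complex/neat void ratio isolates the structural effect of binding.

## Worked example

```python
import numpy as np
import dendricomplex as dc
from dendricomplex.synthetic_data import TitrationModel, gen_titration

dc.charge_table()
# {'PAMAM G3': 32, 'PAMAM G4': 64, 'PPI G3': 42, 'PPI G4': 84}

series = gen_titration(TitrationModel(n=27.0, noise_sd=1.0, seed=5))
est = dc.job_stoichiometry(series)
print(est.ratio_string, round(est.n, 2), round(dc.zeta_saturation(series), 1))
# 1:27 27.23 -30.5
```

The curve fell from +40 mV to its plateau; the breakpoint estimator
recovers the generator's true stoichiometry of 27 RB per dendrimer to
within the noise, and the saturation estimator returns the plateau
(−30.5 mV here against a −30 mV truth).

The same estimators run from the shell:

```bash
dendricomplex charge --family PPI --generation 4   # PPI G4: net charge +84 e
dendricomplex simulate --seed 5 --out-dir out --titration-n 27
dendricomplex titrate out/titration.csv --kind zeta
```

## Analysis scripts

`analysis/01…06` are thin narrative drivers over the library, writing
tables under `results/`: dendrimer charges, stoichiometry recovery for the
four dendrimer:RB systems, shape descriptors of rigid (PPI-like) vs
flexible (PAMAM-like) bead ensembles, radial profiles with ligand
internalization fractions, per-class hydrogen-bond counts, and void-volume
ratios. Run them in order with `python analysis/01_dendrimer_charges.py`
etc.; each prints what it found.

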