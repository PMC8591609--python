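#!/usr/bin/env python
"""Size/shape descriptors of rigid (PPI-like) vs flexible (PAMAM-like) ensembles.

Generates bead ensembles for the four systems with the experimentally
reported mean radii of gyration as generator targets and a family-dependent
stiffness (PPI rigid, PAMAM flexible), then computes RoG, aspect ratios,
asphericity, and the RoG probability density over the trailing analysis
window.  Writes results/shape_summary.csv and results/rog_pdf.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from dendricomplex.dendrimer_model import DendrimerSpec, build_topology
from dendricomplex.shape_metrics import inertia_descriptors, rog_pdf
from dendricomplex.synthetic_data import BeadDendrimerModel, gen_dendrimer_ensemble

RESULTS = Path(__file__).resolve().parent.parent / "results"

# generator targets: mean RoG (nm) per system; stiffness encodes the
# rigid-PPI vs flexible-PAMAM contrast
SYSTEMS = {
    "PAMAM G3": {"family": "PAMAM", "generation": 3, "target_rog": 1.460,
                 "stiffness": 4.0},
    "PAMAM G4": {"family": "PAMAM", "generation": 4, "target_rog": 1.859,
                 "stiffness": 4.0},
    "PPI G3":   {"family": "PPI", "generation": 3, "target_rog": 1.284,
                 "stiffness": 50.0},
    "PPI G4":   {"family": "PPI", "generation": 4, "target_rog": 1.590,
                 "stiffness": 50.0},
}
N_FRAMES = 200          # frames per ensemble
LAST_FRACTION = 0.25    # trailing analysis window


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows, pdf_rows = [], []
    for i, (system, p) in enumerate(SYSTEMS.items()):
        topo = build_topology(DendrimerSpec(p["family"], p["generation"]))
        ens = gen_dendrimer_ensemble(BeadDendrimerModel(
            topology=topo, target_rog=p["target_rog"],
            stiffness=p["stiffness"], n_frames=N_FRAMES, seed=300 + i))
        s = inertia_descriptors(ens, last_fraction=LAST_FRACTION)
        rows.append({"system": system, "stiffness": p["stiffness"],
                     "target_rog_nm": p["target_rog"], **s.to_row()})
        centers, density, _ = rog_pdf(s.rog, bins=12)
        pdf_rows += [{"system": system, "rog_nm": c, "density": d}
                     for c, d in zip(centers, density)]
        print(f"{system}: RoG {s.rog_mean:.3f} ± {s.rog_sd:.3f} nm, "
              f"Ix/Iy {s.aspect_xy:.3f}, Ix/Iz {s.aspect_xz:.3f}, "
              f"δ {s.asphericity:.4f}")

    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "shape_summary.csv", index=False)
    pd.DataFrame(pdf_rows).to_csv(RESULTS / "rog_pdf.csv", index=False)

    ppi_sd = df[df.system.str.startswith("PPI")].rog_sd_nm.mean()
    pamam_sd = df[df.system.str.startswith("PAMAM")].rog_sd_nm.mean()
    print(f"\nmean RoG SD: PPI-like {ppi_sd:.4f} nm < PAMAM-like "
          f"{pamam_sd:.4f} nm — the rigid family shows the narrower "
          f"size distribution")
    print(f"wrote {RESULTS/'shape_summary.csv'} and {RESULTS/'rog_pdf.csv'}")


if __name__ == "__main__":
    main()
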