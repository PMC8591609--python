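#!/usr/bin/env python
"""Net formal charges of the four studied dendrimers at neutral pH.

PAMAM G3/G4 protonate only their terminal primary amines; PPI G3/G4
additionally protonate alternating tertiary layers (two thirds of all
amines).  Writes the charge panel and full layer tables to results/.
"""

import json
from pathlib import Path

from dendricomplex.dendrimer_model import (
    DendrimerSpec,
    assign_protonation,
    build_topology,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    panel = {}
    for family in ("PAMAM", "PPI"):
        for g in (3, 4):
            topo = assign_protonation(build_topology(DendrimerSpec(family, g)))
            panel[f"{family} G{g}"] = topo.to_json()
            frac = topo.net_charge / topo.total_amine_count
            print(f"{family} G{g}: {topo.terminal_count} terminal amines, "
                  f"net charge +{topo.net_charge} e "
                  f"({topo.net_charge}/{topo.total_amine_count} = "
                  f"{frac:.3f} of amines protonated)")
    out = RESULTS / "dendrimer_charges.json"
    out.write_text(json.dumps(panel, indent=2))
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
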