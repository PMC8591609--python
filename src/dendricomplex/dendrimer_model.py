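"""Layer-count model of PAMAM/PPI dendrimer amines and their neutral-pH protonation.

A dendrimer of generation ``g`` (labelled so that G3 carries 32 and G4 carries 64
terminal primary amines, for both families) is represented as an ordered stack of
amine layers from the terminal primaries inward to a two-amine core layer, with
counts halving at each step: 2^(g+2), 2^(g+1), ..., 4, 2.

Protonation at neutral pH follows the standard schemes for these polymers:

* PAMAM — only the terminal primary amines are protonated; interior tertiary
  amines stay neutral.  Net charge equals the terminal count (+32 for G3,
  +64 for G4).
* PPI — terminal primaries plus alternating tertiary layers are protonated
  (the even depths counted from the terminal layer), the occupancy pattern
  predicted by Ising-type models of PPI acid-base behaviour.  Two thirds of
  all amines end up charged: +42 of 62 amines for G3, +84 of 126 for G4.

This is a combinatorial charge model, not an atomistic structure; bead-level
3D realisations of the same topology are produced by :mod:`.synthetic_data`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterator


class Family(str, Enum):
    """Supported dendrimer chemistries."""

    PAMAM = "PAMAM"
    PPI = "PPI"


class DendrimerModelError(ValueError):
    """Invalid dendrimer specification or protonation request."""


@dataclass(frozen=True)
class DendrimerSpec:
    """Family + generation label of a dendrimer.

    Generations are labelled by terminal-amine count (G3 -> 32, G4 -> 64 for
    both families); half-generation (ester-terminated) species are not
    supported.
    """

    family: Family
    generation: int

    def __post_init__(self) -> None:
        try:
            object.__setattr__(self, "family", Family(self.family))
        except ValueError:
            raise DendrimerModelError(
                f"unsupported dendrimer family {self.family!r}; "
                f"expected one of {[f.value for f in Family]}"
            ) from None
        if not isinstance(self.generation, int) or self.generation < 1:
            raise DendrimerModelError(
                f"generation must be an integer >= 1, got {self.generation!r}"
            )


@dataclass(frozen=True)
class AmineLayer:
    """One concentric layer of chemically equivalent amines.

    ``depth_from_terminal`` counts inward: 0 is the terminal primary layer,
    the deepest layer is the 2-amine core.
    """

    depth_from_terminal: int
    amine_type: str  # "primary" | "tertiary"
    count: int
    protonated: bool = False

    def __post_init__(self) -> None:
        if self.depth_from_terminal < 0:
            raise DendrimerModelError("layer depth must be >= 0")
        if self.amine_type not in ("primary", "tertiary"):
            raise DendrimerModelError(f"unknown amine type {self.amine_type!r}")
        if (self.depth_from_terminal == 0) != (self.amine_type == "primary"):
            raise DendrimerModelError("depth 0 and only depth 0 is primary")
        if self.count < 1:
            raise DendrimerModelError("layer count must be >= 1")


@dataclass(frozen=True)
class DendrimerTopology:
    """Ordered amine layers (terminal -> core) with protonation flags."""

    spec: DendrimerSpec
    layers: tuple[AmineLayer, ...]
    protonation_assigned: bool = False

    def __iter__(self) -> Iterator[AmineLayer]:
        return iter(self.layers)

    @property
    def terminal_count(self) -> int:
        return self.layers[0].count

    @property
    def total_amine_count(self) -> int:
        return sum(layer.count for layer in self.layers)

    @property
    def net_charge(self) -> int:
        """Formal net charge in elementary charges (one +e per protonated amine)."""
        return sum(layer.count for layer in self.layers if layer.protonated)

    def to_json(self) -> dict:
        """JSON-serialisable summary of the topology."""
        return {
            "family": self.spec.family.value,
            "generation": self.spec.generation,
            "terminal_count": self.terminal_count,
            "total_amine_count": self.total_amine_count,
            "net_charge": self.net_charge,
            "protonation_assigned": self.protonation_assigned,
            "layers": [
                {
                    "depth_from_terminal": layer.depth_from_terminal,
                    "amine_type": layer.amine_type,
                    "count": layer.count,
                    "protonated": layer.protonated,
                }
                for layer in self.layers
            ],
        }


def build_topology(spec: DendrimerSpec) -> DendrimerTopology:
    """Construct the layer stack for a dendrimer, unprotonated.

    Generation ``g`` has 2^(g+2) terminal primaries at depth 0 and tertiary
    layers of 2^(g+1), ..., 4, 2 amines toward the core (for PPI the deepest
    2-amine layer is the diamine core; PAMAM's core layer likewise carries 2
    amines).  All protonation flags start unset.
    """
    spec = spec if isinstance(spec, DendrimerSpec) else DendrimerSpec(*spec)
    g = spec.generation
    layers = tuple(
        AmineLayer(
            depth_from_terminal=d,
            amine_type="primary" if d == 0 else "tertiary",
            count=2 ** (g + 2 - d),
        )
        for d in range(g + 2)
    )
    return DendrimerTopology(spec=spec, layers=layers)


def assign_protonation(topology: DendrimerTopology) -> DendrimerTopology:
    """Apply the neutral-pH protonation scheme for the topology's family.

    PAMAM: terminal primary layer only.  PPI: terminal layer plus every
    second tertiary layer going inward (even depths from the terminal layer),
    the unique alternation that yields the +42/+84 charges and the 2/3
    protonated fraction.  Idempotency violations are rejected: protonating an
    already-protonated topology raises.
    """
    if topology.protonation_assigned or any(l.protonated for l in topology.layers):
        raise DendrimerModelError(
            "protonation already assigned; assign_protonation is not idempotent "
            "on protonated input by contract"
        )
    if topology.spec.family is Family.PAMAM:
        protonated_depths = {0}
    else:  # PPI: alternating layers, starting from the terminal primaries
        protonated_depths = {d for d in range(len(topology.layers)) if d % 2 == 0}
    layers = tuple(
        replace(layer, protonated=layer.depth_from_terminal in protonated_depths)
        for layer in topology.layers
    )
    return DendrimerTopology(spec=topology.spec, layers=layers, protonation_assigned=True)


def net_charge(topology: DendrimerTopology) -> int:
    """Net formal charge (elementary charges) = number of protonated amines."""
    return topology.net_charge


def charge_table(generations: tuple[int, ...] = (3, 4)) -> dict[str, int]:
    """Net charges for a panel of dendrimers, keyed like ``"PPI G4"``."""
    return {
        f"{family.value} G{g}": net_charge(
            assign_protonation(build_topology(DendrimerSpec(family, g)))
        )
        for family in Family
        for g in generations
    }
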