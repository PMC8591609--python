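"""Geometric hydrogen-bond detection and per-class counting.

A hydrogen bond is a donor-hydrogen...acceptor triplet satisfying a distance
cutoff on the donor-acceptor separation and an angular cutoff on the deviation
at the donor (angle between the D->H and D->A vectors).  Donor/hydrogen and
acceptor atom lists are explicit inputs — no chemical perception is attempted.
Defaults (d(D,A) <= 0.35 nm, deviation <= 30 deg) are the common geometric
definition used in trajectory analysis.

Bonds are classified by the group labels of the participating atoms:
``internal`` (both sides on the dendrimer, core included), ``with_water``,
``with_RB``, or ``other``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .ensemble_io import ConformationEnsemble

#: maximum covalent D-H separation accepted when validating donor lists (nm)
MAX_DH_BOND = 0.15

_DENDRIMER_TAGS = {"core", "dendrimer"}


class HBondInputError(ValueError):
    """Inconsistent donor/hydrogen/acceptor lists."""


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric acceptance window for a hydrogen bond."""

    max_da_distance: float = 0.35       # nm, donor-acceptor
    max_angle_deg: float = 30.0         # deviation at the donor (H-D-A)
    angle_convention: str = "deviation_at_donor"

    def __post_init__(self) -> None:
        if self.max_da_distance <= 0:
            raise ValueError("distance cutoff must be > 0")
        if not 0 < self.max_angle_deg <= 90:
            raise ValueError("angle cutoff must be in (0, 90] degrees")


DEFAULT_CRITERIA = HBondCriteria()


@dataclass(frozen=True)
class HBondRecord:
    frame: int
    donor: int
    hydrogen: int
    acceptor: int
    distance: float   # nm
    angle: float      # deg, deviation at donor
    hb_class: str     # internal | with_water | with_RB | other


def _classify(donor_label: str, acceptor_label: str) -> str:
    pair = {donor_label, acceptor_label}
    if pair <= _DENDRIMER_TAGS:
        return "internal"
    if pair & _DENDRIMER_TAGS:
        if "water" in pair:
            return "with_water"
        if "RB" in pair:
            return "with_RB"
    return "other"


def find_hbonds(
    ensemble: ConformationEnsemble,
    donors: Sequence[int],
    hydrogens: Sequence[int],
    acceptors: Sequence[int],
    criteria: HBondCriteria = DEFAULT_CRITERIA,
) -> list[HBondRecord]:
    """All donor-H...acceptor triplets meeting the criteria, every frame.

    ``donors`` and ``hydrogens`` are parallel sequences (one hydrogen per
    entry; a donor with several hydrogens appears once per hydrogen).  Each
    hydrogen must sit within a covalent-bond distance of its donor in every
    frame, otherwise the lists are inconsistent and an error is raised.
    Self-pairs (donor atom == acceptor atom) are skipped.
    """
    donors = np.asarray(donors, dtype=int)
    hydrogens = np.asarray(hydrogens, dtype=int)
    acceptors = np.asarray(acceptors, dtype=int)
    if donors.shape != hydrogens.shape:
        raise HBondInputError("donors and hydrogens must be parallel lists")
    if donors.size == 0 or acceptors.size == 0:
        return []

    records: list[HBondRecord] = []
    cos_max = np.cos(np.deg2rad(criteria.max_angle_deg))
    labels = ensemble.labels
    for f in range(ensemble.n_frames):
        xyz = ensemble.coords[f]
        dh = np.linalg.norm(xyz[hydrogens] - xyz[donors], axis=1)
        bad = np.flatnonzero(dh > MAX_DH_BOND)
        if bad.size:
            raise HBondInputError(
                f"hydrogen {hydrogens[bad[0]]} is {dh[bad[0]]:.3f} nm from donor "
                f"{donors[bad[0]]} in frame {f} (> {MAX_DH_BOND} nm): not covalently bonded"
            )
        tree = cKDTree(xyz[acceptors])
        neighbours = tree.query_ball_point(xyz[donors], criteria.max_da_distance)
        for di, acc_positions in enumerate(neighbours):
            if not acc_positions:
                continue
            d_idx, h_idx = donors[di], hydrogens[di]
            v_h = xyz[h_idx] - xyz[d_idx]
            nv_h = np.linalg.norm(v_h)
            for ai in acc_positions:
                a_idx = acceptors[ai]
                if a_idx == d_idx:
                    continue
                v_a = xyz[a_idx] - xyz[d_idx]
                dist = np.linalg.norm(v_a)
                if dist == 0 or nv_h == 0:
                    continue
                cos_t = np.clip(v_h @ v_a / (nv_h * dist), -1.0, 1.0)
                if cos_t >= cos_max:
                    records.append(HBondRecord(
                        frame=f, donor=int(d_idx), hydrogen=int(h_idx),
                        acceptor=int(a_idx), distance=float(dist),
                        angle=float(np.rad2deg(np.arccos(cos_t))),
                        hb_class=_classify(labels[d_idx], labels[a_idx]),
                    ))
    return records


@dataclass
class HBondSummary:
    """Per-class mean +/- SD of per-frame hydrogen-bond counts."""

    per_class: dict[str, tuple[float, float]]
    n_frames: int
    sd_convention: str
    criteria: HBondCriteria = field(default_factory=HBondCriteria)

    def __getitem__(self, hb_class: str) -> tuple[float, float]:
        return self.per_class.get(hb_class, (0.0, 0.0))


def hbond_count_summary(
    records: Sequence[HBondRecord],
    n_frames: int,
    sd: str = "sample",
    criteria: HBondCriteria = DEFAULT_CRITERIA,
) -> HBondSummary:
    """Mean and SD of per-frame counts for each bond class.

    Frames with no bonds of a class contribute zero counts.  ``sd`` selects
    the convention: "sample" (ddof=1, the default, matching how replicate
    trajectory statistics are usually reported) or "population" (ddof=0); the
    choice is recorded on the summary.
    """
    if n_frames <= 0:
        raise ValueError("n_frames must be >= 1")
    if sd not in ("sample", "population"):
        raise ValueError("sd must be 'sample' or 'population'")
    ddof = 1 if sd == "sample" else 0
    classes = sorted({r.hb_class for r in records}) or []
    per_class: dict[str, tuple[float, float]] = {}
    for c in ("internal", "with_water", "with_RB", *classes):
        if c in per_class:
            continue
        counts = np.zeros(n_frames)
        for r in records:
            if r.hb_class == c:
                counts[r.frame] += 1
        sd_val = 0.0 if n_frames <= ddof else float(np.std(counts, ddof=ddof))
        per_class[c] = (float(counts.mean()), sd_val)
    return HBondSummary(per_class=per_class, n_frames=n_frames,
                        sd_convention=sd, criteria=criteria)
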