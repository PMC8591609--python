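"""Internal cavity volume from probe-radius sweeps of SASA-enclosed volumes.

The estimator follows the probe-sweep protocol used for dendrimer cavities:

1. For each probe radius ``r_p``, compute the volume ``V_sasa(r_p)`` enclosed
   by the solvent-accessible surface: every atom sphere is inflated by the
   probe radius, and a grid point counts as enclosed if it lies inside any
   inflated atom *or* cannot be reached from the box boundary through
   probe-free space (a flood fill from the boundary).  Probe-inaccessible
   pockets therefore count as enclosed — this is what lets the sweep see
   internal cavities that seal up as the probe grows.
2. Fit a straight line to ``V_sasa^(1/3)`` versus probe radius over the large
   probes (default r_p >= 0.4 nm), where internal structure is invisible and
   the cube root grows linearly with inflation.
3. The cavity volume is the deviation of the measured volume at a small
   evaluation probe (default 0.3 nm) from the fit's extrapolation:
   ``void = (a + b * r_eval)^3 - V_sasa(r_eval)``, clipped at zero.

For dendrimer:ligand complexes the ligand atoms are removed before the sweep,
so the comparison against the neat dendrimer isolates the structural effect of
binding rather than simple volume occupancy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .ensemble_io import ConformationEnsemble, Selector, select

#: Bondi van der Waals radii, nm
BONDI_RADII_NM = {
    "H": 0.120, "C": 0.170, "N": 0.155, "O": 0.152, "F": 0.147,
    "P": 0.180, "S": 0.180, "Cl": 0.175, "Br": 0.185, "I": 0.198,
    "Na": 0.227, "K": 0.275,
}

DEFAULT_PROBES = tuple(np.round(np.arange(0.3, 1.0001, 0.1), 10))


class VoidVolumeError(ValueError):
    pass


def atom_radii(ensemble: ConformationEnsemble,
               indices: np.ndarray | None = None,
               default: float | None = None) -> np.ndarray:
    """Per-atom radii in nm: explicit ensemble radii, else a van der Waals table.

    Bead ensembles carry their bead radius on ``ensemble.radii``; atomistic
    inputs fall back to the Bondi table keyed by element symbol.  Unknown
    elements use ``default`` when given, otherwise raise.
    """
    if indices is None:
        indices = np.arange(ensemble.n_atoms)
    if ensemble.radii is not None:
        return ensemble.radii[indices]
    out = np.empty(len(indices))
    for k, i in enumerate(indices):
        sym = str(ensemble.elements[i])
        r = BONDI_RADII_NM.get(sym, BONDI_RADII_NM.get(sym.capitalize(), default))
        if r is None:
            raise VoidVolumeError(f"no van der Waals radius for element {sym!r}")
        out[k] = r
    return out


def sasa_volume(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float,
    spacing: float = 0.05,
) -> float:
    """Volume (nm^3) enclosed by the solvent-accessible surface at one probe radius.

    Grid-based: occupancy marks points within ``radii + probe`` of any atom;
    connected components of free space are labelled and any component not
    touching the grid boundary (i.e. unreachable by the probe from outside)
    is counted as enclosed together with the occupied points.

    ``spacing`` is the grid step in nm; a step above half the probe radius
    triggers a warning since narrow channels may then be missed.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.ndim != 2 or coords.shape[0] == 0:
        raise VoidVolumeError("sasa_volume needs a non-empty (N, 3) frame")
    if probe < 0 or spacing <= 0:
        raise VoidVolumeError("probe must be >= 0 and spacing > 0")
    if probe > 0 and spacing > probe / 2:
        warnings.warn(
            f"grid spacing {spacing} nm exceeds half the probe radius {probe} nm; "
            "channel accessibility may be misjudged"
        )
    inflated = radii + probe
    margin = inflated.max() + 2 * spacing
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    occupied = np.zeros(shape, dtype=bool)
    # rasterise each inflated atom into its local sub-box
    for xyz, r in zip(coords, inflated):
        ijk0 = np.floor((xyz - r - lo) / spacing).astype(int)
        ijk1 = np.ceil((xyz + r - lo) / spacing).astype(int) + 1
        ijk0 = np.clip(ijk0, 0, shape - 1)
        ijk1 = np.clip(ijk1, 1, shape)
        ax = [np.arange(ijk0[d], ijk1[d]) * spacing + lo[d] - xyz[d] for d in range(3)]
        d2 = (ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
              + ax[2][None, None, :] ** 2)
        sub = occupied[ijk0[0]:ijk1[0], ijk0[1]:ijk1[1], ijk0[2]:ijk1[2]]
        sub |= d2 <= r * r
    free = ~occupied
    labels, _ = ndimage.label(free)
    boundary_labels = np.unique(np.concatenate([
        labels[0].ravel(), labels[-1].ravel(),
        labels[:, 0].ravel(), labels[:, -1].ravel(),
        labels[:, :, 0].ravel(), labels[:, :, -1].ravel(),
    ]))
    boundary_labels = boundary_labels[boundary_labels != 0]
    exterior = np.isin(labels, boundary_labels)
    enclosed = ~exterior  # occupied plus any free pocket not reaching the boundary
    return float(enclosed.sum()) * spacing ** 3


@dataclass
class ProbeSweep:
    """V_sasa across probe radii, with the cube-root fit and void estimate."""

    probes: np.ndarray            # nm, ascending
    volumes: np.ndarray           # nm^3
    fit_slope: float | None = None       # nm^2/3 per nm (cube-root space)
    fit_intercept: float | None = None
    fit_min: float | None = None
    eval_probe: float | None = None
    void_volume: float | None = None     # nm^3
    clipped: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.probes = np.asarray(self.probes, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if np.any(np.diff(self.probes) <= 0):
            raise VoidVolumeError("probe radii must be ascending")

    def fitted_volume(self, probe: float) -> float:
        if self.fit_slope is None:
            raise VoidVolumeError("sweep has no fit")
        return float((self.fit_intercept + self.fit_slope * probe) ** 3)

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame({"probe_nm": self.probes, "v_sasa_nm3": self.volumes})
        if self.fit_slope is not None:
            df["v_fit_nm3"] = [(self.fit_intercept + self.fit_slope * p) ** 3
                               for p in self.probes]
        return df


def probe_sweep(coords: np.ndarray, radii: np.ndarray,
                probes=DEFAULT_PROBES, spacing: float = 0.05) -> ProbeSweep:
    """V_sasa at each probe radius for one frame."""
    probes = np.asarray(probes, dtype=float)
    vols = np.array([sasa_volume(coords, radii, p, spacing) for p in probes])
    return ProbeSweep(probes=probes, volumes=vols, meta={"spacing": spacing})


def void_volume_estimate(
    coords: np.ndarray,
    radii: np.ndarray,
    probes=DEFAULT_PROBES,
    fit_min: float = 0.4,
    eval_probe: float = 0.3,
    spacing: float = 0.05,
    deviation_space: str = "volume",
) -> ProbeSweep:
    """Cavity volume of one frame by cube-root extrapolation across probes.

    ``deviation_space`` selects how the fit-line deviation is converted to a
    volume: ``"volume"`` (default) extrapolates the fitted cube root, cubes
    it, and subtracts the measured volume at ``eval_probe``;
    ``"cuberoot"`` takes the deviation in cube-root space and cubes that
    difference instead.  Negative estimates are clipped to zero and flagged.
    """
    probes = np.asarray(probes, dtype=float)
    if eval_probe not in probes:
        probes = np.sort(np.append(probes, eval_probe))
    fit_mask = probes >= fit_min
    if fit_mask.sum() < 2:
        raise VoidVolumeError(
            f"need >= 2 probe radii >= fit_min={fit_min} nm for the fit"
        )
    sweep = probe_sweep(coords, radii, probes, spacing)
    slope, intercept = np.polyfit(sweep.probes[fit_mask],
                                  np.cbrt(sweep.volumes[fit_mask]), 1)
    v_meas = float(sweep.volumes[np.searchsorted(sweep.probes, eval_probe)])
    pred_cbrt = intercept + slope * eval_probe
    if deviation_space == "volume":
        void = pred_cbrt ** 3 - v_meas
    elif deviation_space == "cuberoot":
        void = (pred_cbrt - np.cbrt(v_meas)) ** 3
    else:
        raise VoidVolumeError("deviation_space must be 'volume' or 'cuberoot'")
    clipped = void < 0
    sweep.fit_slope = float(slope)
    sweep.fit_intercept = float(intercept)
    sweep.fit_min = fit_min
    sweep.eval_probe = eval_probe
    sweep.void_volume = float(max(void, 0.0))
    sweep.clipped = bool(clipped)
    sweep.meta.update(deviation_space=deviation_space, v_measured_eval=v_meas)
    return sweep


def ensemble_void_volume(
    ensemble: ConformationEnsemble,
    selection: Selector | np.ndarray = ("core", "dendrimer"),
    frames: slice | None = None,
    **kwargs,
) -> tuple[float, list[ProbeSweep]]:
    """Mean cavity volume over frames of a selection; returns (mean, sweeps)."""
    idx = selection if isinstance(selection, np.ndarray) else select(ensemble, selection)
    radii = atom_radii(ensemble, idx, default=kwargs.pop("default_radius", None))
    frame_ids = range(ensemble.n_frames)[frames] if frames else range(ensemble.n_frames)
    sweeps = [void_volume_estimate(ensemble.coords[f, idx], radii, **kwargs)
              for f in frame_ids]
    return float(np.mean([s.void_volume for s in sweeps])), sweeps


def void_ratio(
    complex_ensemble: ConformationEnsemble,
    neat_ensemble: ConformationEnsemble,
    **kwargs,
) -> float:
    """Ratio of mean cavity volume with ligand bound (ligand removed before the
    sweep) to the neat dendrimer's mean cavity volume.

    A ratio below one indicates the bound ligand compacts the dendrimer and
    squeezes out internal cavities; near one, the scaffold is unperturbed.
    """
    has_rb = np.any(complex_ensemble.labels == "RB")
    if not has_rb:
        warnings.warn("complex ensemble has no RB atoms; ratio compares identical pipelines")
    v_complex, _ = ensemble_void_volume(complex_ensemble, ("core", "dendrimer"), **kwargs)
    v_neat, _ = ensemble_void_volume(neat_ensemble, ("core", "dendrimer"), **kwargs)
    if v_neat == 0:
        raise VoidVolumeError("neat ensemble has zero mean void volume")
    return v_complex / v_neat
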