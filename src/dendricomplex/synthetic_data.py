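"""Synthetic inputs with known ground truth for every pipeline stage.

Nothing here simulates physics.  The generators produce *statistically*
controllable stand-ins for the two kinds of experimental input the pipeline
consumes — titration curves/spectra, and conformational ensembles of
dendrimer-like bead structures — with the truth parameters recorded in the
output metadata so estimator-recovery tests close the loop.

Ensembles: a bead is placed per amine of a
:class:`~dendricomplex.dendrimer_model.DendrimerTopology`, grown outward from
a core bead along the branching tree with random branch directions; frames
differ by seeded angular noise whose magnitude is set by a stiffness
parameter.  High stiffness gives the narrow size distribution characteristic
of the more rigid PPI scaffold, low stiffness the broader one of flexible
PAMAM.  Ligand (RB) beads co-move with the dendrimer at radii controlled by
an internalization depth parameter; water/ion beads are labelled point
clouds.

Titrations: two-regime curves (linear binding limb, then a plateau at the
saturation response) and two-state emission-spectrum mixtures (free dye
peaking at 564 nm, bound at 575 nm, with a transient quench), both with
seeded Gaussian noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dendrimer_model import DendrimerTopology
from .ensemble_io import ConformationEnsemble
from .titration_assays import EmissionSpectrum, TitrationSeries

RB_BEAD_MASS = 973.0   # amu, rose bengal dianion
BEAD_MASS = 57.0       # amu, generic branch-unit bead


# ---------------------------------------------------------------------------
# titrations
# ---------------------------------------------------------------------------

@dataclass
class TitrationModel:
    """Truth parameters of a two-regime titration curve.

    Defaults emulate a zeta-potential titration of a cationic dendrimer with
    an anionic dye: initial response +40 mV decreasing linearly to a
    saturation plateau of -30 mV at the true stoichiometry ``n``, on a molar
    ratio grid 1..50.
    """

    n: float = 26.0
    initial: float = 40.0         # response at the first grid point
    plateau: float = -30.0        # saturation response
    noise_sd: float = 0.0
    ratios: np.ndarray = field(default_factory=lambda: np.arange(1.0, 51.0))
    response_kind: str = "zeta"
    seed: int = 0

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.ratios[0] < self.n < self.ratios[-1]:
            raise ValueError(
                f"true stoichiometry n={self.n} must lie inside the ratio grid "
                f"[{self.ratios[0]}, {self.ratios[-1]}]"
            )


def gen_titration(model: TitrationModel) -> TitrationSeries:
    """Two-segment titration curve with seeded additive Gaussian noise.

    The response falls linearly from ``initial`` at the first grid point to
    ``plateau`` exactly at ``n``, and stays at the plateau beyond.  The truth
    is recorded in ``series.meta["truth"]``.  A flat model (plateau equal to
    initial) is degenerate — generated, but flagged.
    """
    m = model
    x = m.ratios
    degenerate = m.plateau == m.initial
    if degenerate:
        warnings.warn("plateau equals initial response: degenerate flat titration")
        y = np.full_like(x, m.plateau)
        slope = 0.0
    else:
        slope = (m.plateau - m.initial) / (m.n - x[0])
        y = np.where(x < m.n, m.initial + slope * (x - x[0]), m.plateau)
    if m.noise_sd > 0:
        y = y + np.random.default_rng(m.seed).normal(0.0, m.noise_sd, x.size)
    return TitrationSeries(
        x=x, y=y, response_kind=m.response_kind,
        meta={"truth": {"n": m.n, "initial": m.initial, "plateau": m.plateau,
                        "pre_break_slope": slope, "noise_sd": m.noise_sd,
                        "seed": m.seed},
              "degenerate": degenerate},
    )


def gen_spectra_series(
    ratios: np.ndarray,
    n_true: float = 26.0,
    free_peak: float = 564.0,
    bound_peak: float = 575.0,
    width: float = 12.0,
    quench_depth: float = 0.5,
    wavelengths: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[EmissionSpectrum]:
    """Emission spectra across a titration as two-state Gaussian mixtures.

    At dye:dendrimer molar ratio x the bound fraction is theta = min(x/n, 1)
    (linear saturation at the true stoichiometry); the spectrum is
    ``A(theta) * [(1-theta) G(free_peak) + theta G(bound_peak)]`` with equal
    widths, so the peak red-shifts from 564 to 575 nm as binding saturates.
    ``A(theta) = 1 - 4 q theta (1-theta)`` reproduces the transient quench
    (intensity dips mid-titration, then recovers).
    """
    if wavelengths is None:
        wavelengths = np.arange(540.0, 650.5, 0.5)
    wavelengths = np.asarray(wavelengths, dtype=float)
    if not (wavelengths[0] <= free_peak <= wavelengths[-1]
            and wavelengths[0] <= bound_peak <= wavelengths[-1]):
        raise ValueError("peaks must lie within the wavelength range")
    if width <= 0:
        raise ValueError("width must be > 0")
    if not 0 <= quench_depth < 1:
        raise ValueError("quench_depth must be in [0, 1)")
    rng = np.random.default_rng(seed)
    g_free = np.exp(-0.5 * ((wavelengths - free_peak) / width) ** 2)
    g_bound = np.exp(-0.5 * ((wavelengths - bound_peak) / width) ** 2)
    spectra = []
    for x in np.asarray(ratios, dtype=float):
        theta = min(max(x / n_true, 0.0), 1.0)
        amp = 1.0 - 4.0 * quench_depth * theta * (1.0 - theta)
        inten = amp * ((1 - theta) * g_free + theta * g_bound)
        if noise_sd > 0:
            inten = np.clip(inten + rng.normal(0, noise_sd, inten.size), 0, None)
        spectra.append(EmissionSpectrum(
            wavelengths=wavelengths, intensities=inten, molar_ratio=float(x),
            meta={"truth": {"n": n_true, "theta": theta, "free_peak": free_peak,
                            "bound_peak": bound_peak, "quench_depth": quench_depth,
                            "noise_sd": noise_sd, "seed": seed}},
        ))
    return spectra


# ---------------------------------------------------------------------------
# bead ensembles
# ---------------------------------------------------------------------------

@dataclass
class BeadDendrimerModel:
    """Geometry/statistics parameters of a dendrimer-like bead ensemble.

    ``stiffness`` is dimensionless: per-frame branch directions are the base
    conformation's directions plus isotropic Gaussian noise of SD
    ``1/stiffness`` (per component, before renormalisation).  High stiffness
    -> nearly identical frames (narrow size distribution, PPI-like); low
    stiffness -> large conformational fluctuations (PAMAM-like).
    """

    topology: DendrimerTopology
    bead_radius: float = 0.12       # nm
    segment_length: float = 0.35    # nm between bonded beads
    stiffness: float = 20.0
    target_rog: float = 1.4         # nm, enforced time-mean RoG
    n_frames: int = 50
    bead_mass: float = BEAD_MASS
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.bead_radius, self.segment_length, self.stiffness,
               self.target_rog, self.bead_mass) <= 0:
            raise ValueError("geometric parameters must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def _tree_parents(topology: DendrimerTopology) -> tuple[np.ndarray, np.ndarray]:
    """Parent index per bead for the branching tree, core bead = index 0.

    Layers are laid out from the core outward (reversed topology order);
    counts double at each step, so bead i in a layer attaches to bead i//2 of
    the previous layer.  Returns (parents, depths) over beads 1..N (bead 0 is
    the core reference bead at the tree root).
    """
    counts = [layer.count for layer in topology.layers][::-1]  # core -> terminal
    parents = []
    layer_start = [1]
    for k, c in enumerate(counts):
        start = layer_start[-1]
        if k == 0:
            parents.extend([0] * c)
        else:
            prev_start = layer_start[-2]
            ratio = c // counts[k - 1]
            parents.extend(prev_start + i // ratio for i in range(c))
        layer_start.append(start + c)
    return np.asarray(parents, dtype=int), np.asarray(counts, dtype=int)


def gen_dendrimer_ensemble(model: BeadDendrimerModel) -> ConformationEnsemble:
    """Seeded bead ensemble over the topology's branching tree.

    Beads grow outward from a core bead with persistent random branch
    directions; each frame perturbs the directions by stiffness-scaled noise,
    and all frames are uniformly rescaled so the ensemble-mean RoG of the
    molecule (core + dendrimer beads) equals ``target_rog``.  Equal bead
    masses.  Deterministic in ``seed``.
    """
    m = model
    rng = np.random.default_rng(m.seed)
    parents, _ = _tree_parents(m.topology)
    n_beads = 1 + parents.size

    base_dirs = _unit(rng.normal(size=(parents.size, 3)))
    sigma = 1.0 / m.stiffness
    coords = np.zeros((m.n_frames, n_beads, 3))
    for f in range(m.n_frames):
        if sigma > 0:
            dirs = _unit(base_dirs + rng.normal(scale=sigma, size=base_dirs.shape))
        else:  # pragma: no cover - sigma is always > 0 for finite stiffness
            dirs = base_dirs
        for b in range(parents.size):
            coords[f, b + 1] = coords[f, parents[b]] + m.segment_length * dirs[b]

    masses = np.full(n_beads, m.bead_mass)
    labels = np.asarray(["core"] + ["dendrimer"] * parents.size, dtype=object)
    ens = ConformationEnsemble(
        coords=coords, masses=masses, labels=labels,
        elements=np.asarray(["C"] * n_beads, dtype=object),
        resids=np.concatenate([[1], np.full(parents.size, 2)]).astype(int),
        radii=np.full(n_beads, m.bead_radius),
    )
    from .shape_metrics import radius_of_gyration

    rog = np.asarray(radius_of_gyration(ens, ("core", "dendrimer")))
    scale = m.target_rog / rog.mean()
    ens.coords *= scale
    ens.meta = {
        "generator": "gen_dendrimer_ensemble",
        "truth": {
            "family": m.topology.spec.family.value,
            "generation": m.topology.spec.generation,
            "target_rog": m.target_rog, "stiffness": m.stiffness,
            "bead_radius": m.bead_radius,
            "segment_length": m.segment_length * scale,
            "seed": m.seed,
        },
    }
    return ens


def gen_complex_ensemble(
    base: ConformationEnsemble,
    n_ligands: int = 10,
    depth: str | float = "internal",
    ligand_radius: float = 0.2,
    ligand_mass: float = RB_BEAD_MASS,
    scaffold_compaction: float = 1.0,
    seed: int = 0,
) -> ConformationEnsemble:
    """Attach RB-labelled ligand beads to a dendrimer ensemble.

    Each ligand keeps a fixed direction from the core and a fixed radial
    factor relative to the dendrimer's per-frame RoG, so ligands co-move with
    the breathing of the scaffold.  ``depth`` controls internalization:
    ``"internal"`` draws radial factors in U(0.3, 0.8) (well inside the RoG),
    ``"surface"`` in U(1.2, 1.8) (outside), and a float f in U(f-0.1, f+0.1).

    ``scaffold_compaction`` rescales the dendrimer beads about the per-frame
    core center before ligands are placed, emulating the contraction a
    flexible scaffold undergoes on binding (values < 1 squeeze out internal
    cavities; 1.0 leaves the scaffold untouched, as for a rigid polymer).
    """
    if n_ligands <= 0:
        raise ValueError("n_ligands must be >= 1")
    if scaffold_compaction <= 0:
        raise ValueError("scaffold_compaction must be > 0")
    rng = np.random.default_rng(seed)
    if depth == "internal":
        factors = rng.uniform(0.3, 0.8, n_ligands)
    elif depth == "surface":
        factors = rng.uniform(1.2, 1.8, n_ligands)
    elif isinstance(depth, (int, float)):
        factors = rng.uniform(depth - 0.1, depth + 0.1, n_ligands)
    else:
        raise ValueError("depth must be 'internal', 'surface', or a radial factor")
    dirs = _unit(rng.normal(size=(n_ligands, 3)))

    from .ensemble_io import center_of_mass, select
    from .shape_metrics import radius_of_gyration

    dend = select(base, ("core", "dendrimer"))
    base_coords = base.coords
    if scaffold_compaction != 1.0:
        core_com = center_of_mass(base, select(base, "core"))
        base_coords = base_coords.copy()
        base_coords[:, dend] = (core_com[:, None, :]
                                + scaffold_compaction
                                * (base_coords[:, dend] - core_com[:, None, :]))
        from dataclasses import replace as _replace
        base = _replace(base, coords=base_coords)
    rog = np.asarray(radius_of_gyration(base, dend))
    # radial placement is referenced to the core bead, the same reference the
    # radial profiles use
    com = center_of_mass(base, select(base, "core"))
    lig = (com[:, None, :]
           + rog[:, None, None] * factors[None, :, None] * dirs[None, :, :])
    lig = lig + rng.normal(scale=0.02, size=lig.shape)  # small co-moving jitter

    n0 = base.n_atoms
    resids = (base.resids if base.resids is not None else np.ones(n0, dtype=int))
    out = ConformationEnsemble(
        coords=np.concatenate([base.coords, lig], axis=1),
        masses=np.concatenate([base.masses, np.full(n_ligands, ligand_mass)]),
        labels=np.concatenate([base.labels,
                               np.asarray(["RB"] * n_ligands, dtype=object)]),
        elements=np.concatenate([base.elements,
                                 np.asarray(["I"] * n_ligands, dtype=object)]),
        resids=np.concatenate([resids, resids.max() + 1 + np.arange(n_ligands)]),
        radii=(None if base.radii is None else
               np.concatenate([base.radii, np.full(n_ligands, ligand_radius)])),
        box=base.box,
    )
    out.meta = dict(base.meta)
    out.meta["complex_truth"] = {"n_ligands": n_ligands, "depth": depth,
                                 "radial_factors": factors.tolist(),
                                 "scaffold_compaction": scaffold_compaction,
                                 "seed": seed}
    return out


def add_point_cloud(
    base: ConformationEnsemble,
    tag: str,
    n_points: int,
    r_min: float = 0.0,
    r_max: float = 3.0,
    mass: float = 18.0,
    element: str = "O",
    seed: int = 0,
) -> ConformationEnsemble:
    """Add a labelled cloud (water/ions) uniform in a shell [r_min, r_max] nm.

    Points are drawn per frame around the per-frame core center, uniform in
    volume; densities are thus homogeneous in the shell — convenient for
    g(r) ~ 1 checks and RDF backgrounds.
    """
    from .ensemble_io import center_of_mass

    rng = np.random.default_rng(seed)
    com = center_of_mass(base, ("core", "dendrimer"))
    u = rng.uniform(r_min ** 3, r_max ** 3, (base.n_frames, n_points))
    r = np.cbrt(u)
    d = _unit(rng.normal(size=(base.n_frames, n_points, 3)))
    pts = com[:, None, :] + r[..., None] * d
    n0 = base.n_atoms
    resids = (base.resids if base.resids is not None else np.ones(n0, dtype=int))
    out = ConformationEnsemble(
        coords=np.concatenate([base.coords, pts], axis=1),
        masses=np.concatenate([base.masses, np.full(n_points, mass)]),
        labels=np.concatenate([base.labels, np.asarray([tag] * n_points, dtype=object)]),
        elements=np.concatenate([base.elements,
                                 np.asarray([element] * n_points, dtype=object)]),
        resids=np.concatenate([resids, resids.max() + 1 + np.arange(n_points)]),
        radii=(None if base.radii is None else
               np.concatenate([base.radii, np.full(n_points, 0.15)])),
        box=base.box,
    )
    out.meta = dict(base.meta)
    out.meta["clouds"] = list(base.meta.get("clouds", [])) + [
        {"tag": tag, "n_points": n_points, "r_min": r_min, "r_max": r_max,
         "seed": seed}]
    return out


def gen_planted_hbond_ensemble(
    n_frames: int = 10,
    n_planted: int = 5,
    n_decoy_donors: int = 10,
    n_decoy_acceptors: int = 20,
    acceptor_label: str = "water",
    seed: int = 0,
) -> tuple[ConformationEnsemble, np.ndarray, np.ndarray, np.ndarray]:
    """Frames with exactly ``n_planted`` geometric hydrogen bonds each.

    Planted donor-H...acceptor triplets are near-collinear with d(D,A) ~ 0.29
    nm (well inside the default criteria); decoy donors and acceptors are
    scattered too far apart to bond.  Returns (ensemble, donor indices,
    hydrogen indices, acceptor indices); donors/hydrogens are dendrimer
    atoms, acceptors carry ``acceptor_label`` (water oxygens by default;
    use "dendrimer" to plant internal bonds or "RB" for dye contacts).
    """
    rng = np.random.default_rng(seed)
    n_donors = n_planted + n_decoy_donors
    n_acc = n_planted + n_decoy_acceptors
    n_atoms = 2 * n_donors + n_acc  # D and H pairs, then acceptors
    coords = np.zeros((n_frames, n_atoms, 3))
    for f in range(n_frames):
        # planted triplets on a wide grid so they cannot interfere
        for k in range(n_planted):
            origin = np.array([3.0 * k, 0.0, 0.0]) + rng.normal(scale=0.05, size=3)
            axis = _unit(rng.normal(size=3))
            coords[f, 2 * k] = origin                        # donor
            coords[f, 2 * k + 1] = origin + 0.10 * axis      # hydrogen
            coords[f, 2 * n_donors + k] = origin + 0.29 * axis   # acceptor
        # decoys: far shell, pairwise separations >> cutoff
        for j in range(n_decoy_donors):
            origin = np.array([3.0 * j, 40.0, 0.0]) + rng.normal(scale=0.1, size=3)
            coords[f, 2 * (n_planted + j)] = origin
            coords[f, 2 * (n_planted + j) + 1] = origin + np.array([0.1, 0, 0])
        for j in range(n_decoy_acceptors):
            coords[f, 2 * n_donors + n_planted + j] = (
                np.array([3.0 * j, 80.0, 0.0]) + rng.normal(scale=0.1, size=3))
    labels = np.asarray(
        ["dendrimer", "dendrimer"] * n_donors + [acceptor_label] * n_acc,
        dtype=object)
    elements = np.asarray(["N", "H"] * n_donors + ["O"] * n_acc, dtype=object)
    masses = np.where(elements == "H", 1.0, np.where(elements == "O", 16.0, 14.0))
    ens = ConformationEnsemble(
        coords=coords, masses=masses.astype(float), labels=labels, elements=elements,
        meta={"generator": "gen_planted_hbond_ensemble",
              "truth": {"n_planted": n_planted,
                        "acceptor_label": acceptor_label, "seed": seed}},
    )
    donors = np.arange(n_donors) * 2
    hydrogens = donors + 1
    acceptors = 2 * n_donors + np.arange(n_acc)
    return ens, donors, hydrogens, acceptors


# ---------------------------------------------------------------------------
# analytic reference solids
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform unit vectors (golden-angle spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta), np.cos(phi)])


def gen_reference_solids(kind: str, seed: int = 0, n_frames: int = 1,
                         **params) -> ConformationEnsemble:
    """Analytic reference ensembles for shape and void oracles.

    kinds and their parameters (all lengths nm):

    * ``solid_ball``: ``radius`` (1.0), ``n_points`` (100000) — uniform in a
      ball; RoG -> sqrt(3/5) * radius, asphericity -> 0, no cavities.
    * ``bead_ball``: ``radius`` (1.0), ``bead_radius`` (0.2), ``spacing``
      (0.25) — overlapping beads on a cubic lattice filling a ball; a solid,
      cavity-free structure for the void estimator.
    * ``hollow_shell``: ``r_in`` (1.0), ``bead_radius`` (0.15), ``hole_radius``
      (0.5) — beads on a sphere of radius ``r_in + bead_radius + 0.3`` spaced
      so inter-bead holes admit a 0.3 nm probe but seal at 0.4 nm; cavity
      volume (4/3) pi r_in^3.  RoG of the bead centers equals the sphere
      radius exactly.
    * ``rod``: ``length`` (6.0), ``n_points`` (2000) — uniform on a thin
      segment; asphericity -> 0.25.
    * ``isotropic_cloud``: ``sigma`` (1.0), ``n_points`` (100000) — isotropic
      Gaussian; asphericity -> 0.

    All points are labelled ``dendrimer`` with unit masses; no core bead is
    added (a physical center bead would occupy cavity volume in the shell
    oracle).
    """
    rng = np.random.default_rng(seed)
    frames = []
    truth: dict = {"kind": kind, "seed": seed}
    radii = None
    for _ in range(n_frames):
        if kind == "solid_ball":
            R = params.get("radius", 1.0)
            n = params.get("n_points", 100_000)
            pts = rng.normal(size=(n, 3))
            pts = _unit(pts) * R * np.cbrt(rng.uniform(size=(n, 1)))
            truth.update(radius=R, rog=np.sqrt(3 / 5) * R)
        elif kind == "bead_ball":
            R = params.get("radius", 1.0)
            rb = params.get("bead_radius", 0.2)
            sp = params.get("spacing", 0.25)
            ax = np.arange(-R, R + sp / 2, sp)
            g = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), -1).reshape(-1, 3)
            pts = g[np.linalg.norm(g, axis=1) <= R]
            radii = np.full(len(pts), rb)
            truth.update(radius=R, bead_radius=rb,
                         total_volume=4 / 3 * np.pi * (R + rb) ** 3)
        elif kind == "hollow_shell":
            r_in = params.get("r_in", 1.0)
            rb = params.get("bead_radius", 0.15)
            spacing = params.get("shell_spacing", 2.0 * rb)
            aperture = params.get("aperture_clearance", 0.35)
            R = r_in + rb + 0.3
            # dense antipodally-paired shell: inter-bead gaps far below any
            # probe radius, so the wall itself is sealed everywhere; pairing
            # keeps the center of mass exactly at the origin so the
            # bead-center RoG equals the sphere radius to round-off
            n = max(24, int(round(4 * np.pi * R ** 2
                                  / (np.sqrt(3) / 2 * spacing ** 2))))
            full = _fibonacci_sphere(n)
            half = full[full[:, 2] > 0]
            pts = np.concatenate([half, -half]) * R
            if aperture > 0:
                # circular apertures at both poles, rimmed by an exact ring of
                # beads at axis distance rb + aperture: a probe of radius p
                # passes iff p < aperture (open at 0.3 nm, sealed at >= 0.4 nm
                # for the 0.35 nm default)
                a_r = rb + aperture
                alpha = np.arcsin(a_r / R)
                keep = np.abs(pts[:, 2]) < R * np.cos(alpha + spacing / R)
                m = int(np.ceil(2 * np.pi * a_r / (0.8 * spacing)))
                phi = 2 * np.pi * np.arange(m) / m
                ring = np.column_stack([a_r * np.cos(phi), a_r * np.sin(phi),
                                        np.full(m, R * np.cos(alpha))])
                pts = np.concatenate([pts[keep], ring, -ring])
            radii = np.full(len(pts), rb)
            truth.update(r_in=r_in, shell_radius=R, bead_radius=rb,
                         n_beads=len(pts), aperture_clearance=aperture,
                         cavity_volume=4 / 3 * np.pi * r_in ** 3, rog=R)
        elif kind == "rod":
            L = params.get("length", 6.0)
            n = params.get("n_points", 2000)
            z = rng.uniform(-L / 2, L / 2, n)
            pts = np.column_stack([np.zeros(n), np.zeros(n), z])
            truth.update(length=L, asphericity=0.25)
        elif kind == "isotropic_cloud":
            s = params.get("sigma", 1.0)
            n = params.get("n_points", 100_000)
            pts = rng.normal(scale=s, size=(n, 3))
            truth.update(sigma=s, rog=np.sqrt(3) * s)
        else:
            raise ValueError(f"unknown reference solid kind {kind!r}")
        frames.append(pts)
    coords = np.stack(frames)
    n_atoms = coords.shape[1]
    return ConformationEnsemble(
        coords=coords,
        masses=np.ones(n_atoms),
        labels=np.asarray(["dendrimer"] * n_atoms, dtype=object),
        elements=np.asarray(["C"] * n_atoms, dtype=object),
        radii=radii,
        meta={"generator": "gen_reference_solids", "truth": truth},
    )
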