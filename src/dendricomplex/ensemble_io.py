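"""Multi-frame coordinate ensembles: container, selections, and standard-format IO.

The in-memory container is :class:`ConformationEnsemble`: frames of labelled,
mass-annotated coordinates in nanometres.  Atoms carry a group tag from
:data:`GROUP_TAGS` (core, dendrimer, RB, water, ion_Na, ion_Cl, other); all
descriptor modules select atoms through these tags.

File IO goes through the field-standard readers: MDAnalysis for multi-frame
PDB and XYZ, mdtraj for (multi-frame) GRO.  Coordinates are stored internally
in nm (GRO convention); Angstrom-based formats are converted on ingest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import yaml

GROUP_TAGS = ("core", "dendrimer", "RB", "water", "ion_Na", "ion_Cl", "other")

#: residue names used when writing ensembles, and recognised when reading them back
TAG_TO_RESNAME = {
    "core": "COR",
    "dendrimer": "DEN",
    "RB": "RBD",
    "water": "HOH",
    "ion_Na": "NA",
    "ion_Cl": "CL",
    "other": "UNK",
}
DEFAULT_LABEL_MAP = {v: k for k, v in TAG_TO_RESNAME.items()}
DEFAULT_LABEL_MAP.update({"SOL": "water", "WAT": "water", "TIP3": "water",
                          "NA+": "ion_Na", "CL-": "ion_Cl", "RB": "RB"})

ANGSTROM_TO_NM = 0.1


class EnsembleError(ValueError):
    """Malformed ensemble or selection."""


@dataclass
class ConformationEnsemble:
    """Ordered frames of labelled 3D coordinates.

    Attributes
    ----------
    coords:
        Array of shape (n_frames, n_atoms, 3), in nm.
    masses:
        Per-atom masses in amu, strictly positive.
    labels:
        Per-atom group tags, each one of :data:`GROUP_TAGS`.  At most one
        core group exists; analytic reference solids may omit it, and
        operations that need the core reference raise when it is absent.
    elements:
        Per-atom element symbols (bead models use a carrier element).
    charges:
        Optional per-atom partial charges (e).
    resids:
        Optional per-atom residue/molecule ids; used e.g. to count distinct
        bound ligands.
    radii:
        Optional per-atom radii in nm (bead models record their bead radius
        here; atomistic inputs fall back to a van der Waals table).
    box:
        Optional per-frame orthorhombic box lengths, shape (n_frames, 3), nm.
    meta:
        Free-form provenance (generator truth parameters, seeds, units).
    """

    coords: np.ndarray
    masses: np.ndarray
    labels: np.ndarray
    elements: np.ndarray
    charges: np.ndarray | None = None
    resids: np.ndarray | None = None
    radii: np.ndarray | None = None
    box: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise EnsembleError(f"coords must be (frames, atoms, 3), got {self.coords.shape}")
        n = self.coords.shape[1]
        self.masses = np.asarray(self.masses, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        for name, arr in (("masses", self.masses), ("labels", self.labels),
                          ("elements", self.elements)):
            if arr.shape != (n,):
                raise EnsembleError(f"{name} must have shape ({n},), got {arr.shape}")
        if np.any(self.masses <= 0):
            raise EnsembleError("all masses must be > 0")
        unknown = set(self.labels) - set(GROUP_TAGS)
        if unknown:
            raise EnsembleError(f"unknown group tags {sorted(unknown)}; allowed: {GROUP_TAGS}")
        for name in ("charges", "resids", "radii"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=int if name == "resids" else float)
                if arr.shape != (n,):
                    raise EnsembleError(f"{name} must have shape ({n},)")
                setattr(self, name, arr)
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (self.n_frames, 3):
                raise EnsembleError("box must be (n_frames, 3) orthorhombic lengths in nm")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def subset(self, indices: np.ndarray) -> "ConformationEnsemble":
        """New ensemble restricted to the given atom indices (all frames)."""
        idx = np.asarray(indices, dtype=int)
        return ConformationEnsemble(
            coords=self.coords[:, idx],
            masses=self.masses[idx],
            labels=self.labels[idx],
            elements=self.elements[idx],
            charges=None if self.charges is None else self.charges[idx],
            resids=None if self.resids is None else self.resids[idx],
            radii=None if self.radii is None else self.radii[idx],
            box=self.box,
            meta=dict(self.meta),
        )


Selector = str | Iterable[str] | Callable[["ConformationEnsemble"], np.ndarray]


def select(ensemble: ConformationEnsemble, what: Selector) -> np.ndarray:
    """Resolve a tag, tag collection, or predicate to sorted atom indices.

    A predicate receives the ensemble and returns a boolean mask of length
    n_atoms.  An empty selection warns (it is frequently legitimate, e.g. a
    neat dendrimer has no RB atoms) and returns an empty index array.
    """
    if callable(what):
        mask = np.asarray(what(ensemble), dtype=bool)
        if mask.shape != (ensemble.n_atoms,):
            raise EnsembleError("selection predicate must return a length-n_atoms mask")
    else:
        tags = (what,) if isinstance(what, str) else tuple(what)
        unknown = set(tags) - set(GROUP_TAGS)
        if unknown:
            raise EnsembleError(f"unknown selection tags {sorted(unknown)}")
        mask = np.isin(ensemble.labels, tags)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        warnings.warn(f"selection {what!r} matched no atoms", stacklevel=2)
    return idx


def center_of_mass(
    ensemble: ConformationEnsemble,
    selection: Selector | np.ndarray = "core",
    frame: int | None = None,
) -> np.ndarray:
    """Mass-weighted mean position of a selection, in nm.

    With ``frame=None`` returns an (n_frames, 3) array of per-frame centers.
    """
    idx = selection if isinstance(selection, np.ndarray) else select(ensemble, selection)
    if idx.size == 0:
        raise EnsembleError("center_of_mass of an empty selection")
    m = ensemble.masses[idx]
    total = m.sum()
    if total <= 0:
        raise EnsembleError("zero total mass in selection")
    frames = ensemble.coords if frame is None else ensemble.coords[frame][None]
    com = np.einsum("fni,n->fi", frames[:, idx], m) / total
    return com if frame is None else com[0]


def load_label_map(path: str | Path) -> dict[str, str]:
    """Read a residue/atom-name -> group-tag mapping from YAML."""
    with open(path) as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, Mapping):
        raise EnsembleError(f"label map {path} must be a flat name->tag mapping")
    bad = {t for t in mapping.values() if t not in GROUP_TAGS}
    if bad:
        raise EnsembleError(f"label map contains unknown tags {sorted(bad)}")
    return dict(mapping)


def _infer_format(path: Path, format: str | None) -> str:
    fmt = (format or path.suffix.lstrip(".")).upper()
    if fmt not in ("PDB", "GRO", "XYZ"):
        raise EnsembleError(f"unsupported ensemble format {fmt!r} (PDB, GRO, XYZ)")
    return fmt


def _apply_label_map(names: Sequence[str], fallbacks: Sequence[str],
                     label_map: Mapping[str, str], strict: bool) -> np.ndarray:
    labels = []
    for name, fb in zip(names, fallbacks):
        tag = label_map.get(name, label_map.get(fb))
        if tag is None:
            if strict:
                raise EnsembleError(
                    f"no group tag for residue/atom name {name!r} (atom {fb!r}) "
                    "under strict mapping"
                )
            tag = "other"
        labels.append(tag)
    return np.asarray(labels, dtype=object)


def load_ensemble(
    path: str | Path,
    format: str | None = None,
    label_map: Mapping[str, str] | None = None,
    masses: Mapping[str, float] | np.ndarray | None = None,
    strict: bool = True,
) -> ConformationEnsemble:
    """Read a multi-frame PDB/GRO/XYZ file into a :class:`ConformationEnsemble`.

    ``label_map`` maps residue names (and, as a fallback, atom names) to group
    tags; the built-in map recognises the residue names this package writes
    plus common water/ion names.  ``masses`` optionally overrides the
    file-derived masses, either per group tag or as a full per-atom array.
    Coordinates are converted to nm (PDB/XYZ Angstroms x 0.1).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"ensemble file not found: {path}")
    fmt = _infer_format(path, format)
    lmap = dict(DEFAULT_LABEL_MAP)
    if label_map:
        lmap.update(label_map)

    if fmt == "GRO":
        import mdtraj as md

        traj = md.load(str(path))
        coords = np.array(traj.xyz, dtype=float)  # mdtraj is already nm
        atoms = list(traj.topology.atoms)
        names = [a.residue.name for a in atoms]
        atom_names = [a.name for a in atoms]
        file_masses = np.array(
            [a.element.mass if a.element is not None else 0.0 for a in atoms]
        )
        elements = np.asarray(
            [a.element.symbol if a.element is not None else "X" for a in atoms],
            dtype=object,
        )
        resids = np.array([a.residue.resSeq for a in atoms], dtype=int)
        box = None
        if traj.unitcell_lengths is not None:
            box = np.array(traj.unitcell_lengths, dtype=float)
    else:
        import MDAnalysis as mda

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
            coords = np.array([u.atoms.positions.copy() for _ in u.trajectory])
        coords *= ANGSTROM_TO_NM
        try:
            names = list(u.atoms.resnames)
        except (AttributeError, mda.exceptions.NoDataError):
            names = [""] * len(u.atoms)
        atom_names = list(u.atoms.names)
        try:
            file_masses = np.asarray(u.atoms.masses, dtype=float)
        except (AttributeError, mda.exceptions.NoDataError):
            file_masses = np.zeros(len(u.atoms))
        try:
            elements = np.asarray(u.atoms.elements, dtype=object)
        except (AttributeError, mda.exceptions.NoDataError):
            elements = np.asarray(
                ["".join(c for c in n if c.isalpha())[:2].capitalize() or "X"
                 for n in atom_names],
                dtype=object,
            )
        try:
            resids = np.asarray(u.atoms.resids, dtype=int)
        except (AttributeError, mda.exceptions.NoDataError):
            resids = np.zeros(len(u.atoms), dtype=int)
        box = None

    labels = _apply_label_map(names, atom_names, lmap, strict)

    if isinstance(masses, Mapping):
        out_masses = file_masses.copy()
        for tag, m in masses.items():
            out_masses[labels == tag] = m
    elif masses is not None:
        out_masses = np.asarray(masses, dtype=float)
    else:
        out_masses = file_masses
    if np.any(out_masses <= 0):
        # formats without mass metadata (XYZ with bead names): default to unit mass
        out_masses = np.where(out_masses > 0, out_masses, 1.0)

    return ConformationEnsemble(
        coords=coords, masses=out_masses, labels=labels, elements=elements,
        resids=resids, box=box, meta={"source": str(path), "format": fmt},
    )


def save_ensemble(ensemble: ConformationEnsemble, path: str | Path,
                  format: str | None = None) -> Path:
    """Write all frames to a multi-frame PDB, GRO, or XYZ file.

    Group tags become residue names per :data:`TAG_TO_RESNAME`, so a file
    written here reloads with the same labels under the default label map.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    n = ensemble.n_atoms
    resnames = [TAG_TO_RESNAME[t] for t in ensemble.labels]
    resids = (ensemble.resids if ensemble.resids is not None
              else np.arange(n, dtype=int))
    # compress (resid, label) runs into residue blocks
    blocks: list[tuple[str, int, list[int]]] = []
    for i in range(n):
        key = (resnames[i], int(resids[i]))
        if blocks and (blocks[-1][0], blocks[-1][1]) == key:
            blocks[-1][2].append(i)
        else:
            blocks.append((key[0], key[1], [i]))

    if fmt == "GRO":
        import mdtraj as md

        top = md.Topology()
        chain = top.add_chain()
        for rname, rid, idxs in blocks:
            res = top.add_residue(rname, chain, resSeq=rid)
            for i in idxs:
                sym = str(ensemble.elements[i])
                try:
                    elem = md.element.get_by_symbol(sym)
                except KeyError:
                    elem = md.element.carbon
                top.add_atom(f"{sym}{i + 1}", elem, res)
        traj = md.Trajectory(xyz=ensemble.coords.astype(np.float32), topology=top)
        if ensemble.box is not None:
            traj.unitcell_lengths = ensemble.box.astype(np.float32)
            traj.unitcell_angles = np.full((ensemble.n_frames, 3), 90.0, dtype=np.float32)
        traj.save_gro(str(path))
        return path

    import MDAnalysis as mda

    resindex = np.empty(n, dtype=int)
    for bi, (_, _, idxs) in enumerate(blocks):
        resindex[idxs] = bi
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n_atoms=n, n_residues=len(blocks), atom_resindex=resindex,
            trajectory=True,
        )
        u.add_TopologyAttr("names", [f"{e}{i + 1}"[:4] for i, e in enumerate(ensemble.elements)])
        u.add_TopologyAttr("elements", [str(e) for e in ensemble.elements])
        u.add_TopologyAttr("resnames", [b[0] for b in blocks])
        u.add_TopologyAttr("resids", [b[1] + 1 for b in blocks])
        u.add_TopologyAttr("masses", ensemble.masses)
        with mda.Writer(str(path), n_atoms=n, multiframe=True) as w:
            for f in range(ensemble.n_frames):
                u.atoms.positions = ensemble.coords[f] / ANGSTROM_TO_NM
                w.write(u.atoms)
    return path


def unwrap(ensemble: ConformationEnsemble,
           reference: Selector = "core") -> ConformationEnsemble:
    """Make the molecule whole across an orthorhombic box.

    Each atom is shifted by whole box vectors to its minimum-image position
    relative to the reference group's center; a no-op for box-free ensembles.
    Descriptor modules assume an intact molecule, so call this after loading
    wrapped trajectories.
    """
    if ensemble.box is None:
        return ensemble
    ref_idx = select(ensemble, reference)
    coords = ensemble.coords.copy()
    for f in range(ensemble.n_frames):
        ref = center_of_mass(ensemble, ref_idx, frame=f)
        L = ensemble.box[f]
        coords[f] -= L * np.round((coords[f] - ref) / L)
    out = replace(ensemble, coords=coords)
    out.meta = dict(ensemble.meta, unwrapped=True)
    return out
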