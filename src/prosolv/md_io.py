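"""Topology/trajectory data model, standard-format I/O and periodic geometry.

Internal units are the GROMACS conventions: nanometres for lengths and
picoseconds for times.  PDB files (angstrom) are converted at the boundary.
Atom and residue indices are 0-based internally; file-facing numbering
follows each format's own convention.

Structure formats (GRO, PDB) are parsed and written through MDAnalysis;
XTC and DCD frames go through mdtraj's low-level format readers.  A small
multi-frame XYZ dialect with a box comment line is provided for plain-text
fixtures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

PROTEIN_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HSD", "HSE", "HSP", "HID", "HIE", "HIP", "CYX", "MSE",
}

#: default residue-name -> molecule class rules (GROMACS/CHARMM aliases)
DEFAULT_CLASS_RULES: dict[str, str] = {
    **{r: "protein" for r in PROTEIN_RESNAMES},
    "SOL": "water", "TIP3": "water", "TIP3P": "water", "HOH": "water",
    "WAT": "water", "SPC": "water", "W": "water",
    "SUC": "disaccharide", "SUCR": "disaccharide", "TRE": "disaccharide",
    "TREH": "disaccharide", "MAL": "disaccharide", "SUG": "disaccharide",
    "NA": "cation", "NA+": "cation", "SOD": "cation", "K": "cation",
    "ZN": "cation", "ZN2": "cation", "MG": "cation", "CA2": "cation",
    "CL": "anion", "CL-": "anion", "CLA": "anion", "BR": "anion",
}

MOLECULE_CLASSES = ("protein", "water", "disaccharide", "cation", "anion")

_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "NA": 22.990, "CL": 35.45, "ZN": 65.38, "K": 39.098,
    "MG": 24.305, "BR": 79.904, "X": 12.0,
}


def element_from_name(name: str) -> str:
    """Guess the element from an atom name (PDB/GRO style)."""
    s = name.strip()
    if not s:
        return "X"
    up = s.upper()
    for two in ("NA", "CL", "ZN", "MG", "BR"):
        if up == two or up.startswith(two + "+") or up.startswith(two + "-"):
            return two
    head = up.lstrip("0123456789")
    return head[0] if head else "X"


def mass_of_element(element: str) -> float:
    return _MASSES.get(element.upper(), _MASSES["X"])


@dataclass(frozen=True)
class Box:
    """Cubic (or rectangular) periodic simulation cell, lengths in nm."""

    lengths: np.ndarray
    periodic: bool = True

    def __post_init__(self):
        lengths = np.asarray(self.lengths, dtype=float).reshape(3)
        object.__setattr__(self, "lengths", lengths)
        if self.periodic and np.any(lengths <= 0):
            raise ValueError(f"box lengths must be positive, got {lengths}")

    @property
    def volume(self) -> float:
        return float(np.prod(self.lengths))


@dataclass(frozen=True)
class Atom:
    """Single-atom record (a row view into a :class:`Topology`)."""

    index: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    molecule_id: int
    molecule_class: str
    mass: float
    charge_class: int


class Topology:
    """Column-oriented atom table with hydrogen-bond site annotations.

    ``donors`` is an (n, 2) integer array of (donor-heavy-atom, hydrogen)
    pairs and ``acceptors`` a 1-D array of acceptor atom indices; both may
    be empty until annotated.
    """

    def __init__(self, names, resindices, resnames, chain_ids=None,
                 resids=None, elements=None, masses=None, charges=None,
                 molecule_ids=None, molecule_classes=None,
                 donors=None, acceptors=None):
        self.names = np.asarray(names, dtype=object)
        n = len(self.names)
        self.resindices = np.asarray(resindices, dtype=int)
        self.resnames = np.asarray(resnames, dtype=object)
        if len(self.resindices) != n or len(self.resnames) != n:
            raise ValueError("per-atom arrays must share one length")
        self.chain_ids = (np.asarray(chain_ids, dtype=object)
                          if chain_ids is not None
                          else np.full(n, "", dtype=object))
        self.resids = (np.asarray(resids, dtype=int) if resids is not None
                       else self.resindices + 1)
        self.elements = (np.asarray(elements, dtype=object)
                         if elements is not None
                         else np.array([element_from_name(x) for x in self.names],
                                       dtype=object))
        self.masses = (np.asarray(masses, dtype=float) if masses is not None
                       else np.array([mass_of_element(e) for e in self.elements]))
        self.charges = (np.asarray(charges, dtype=int) if charges is not None
                        else np.zeros(n, dtype=int))
        self.molecule_ids = (np.asarray(molecule_ids, dtype=int)
                             if molecule_ids is not None
                             else np.full(n, -1, dtype=int))
        self.molecule_classes = (np.asarray(molecule_classes, dtype=object)
                                 if molecule_classes is not None
                                 else np.full(n, "", dtype=object))
        self.donors = (np.asarray(donors, dtype=int).reshape(-1, 2)
                       if donors is not None else np.empty((0, 2), dtype=int))
        self.acceptors = (np.asarray(acceptors, dtype=int)
                          if acceptors is not None else np.empty(0, dtype=int))

    # -- basic introspection -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def n_residues(self) -> int:
        return len(np.unique(self.resindices))

    def atom(self, i: int) -> Atom:
        return Atom(i, str(self.names[i]), str(self.elements[i]),
                    int(self.resindices[i]), str(self.resnames[i]),
                    str(self.chain_ids[i]), int(self.molecule_ids[i]),
                    str(self.molecule_classes[i]), float(self.masses[i]),
                    int(self.charges[i]))

    def atoms_of_class(self, cls: str) -> np.ndarray:
        return np.flatnonzero(self.molecule_classes == cls)

    def heavy_atoms(self) -> np.ndarray:
        return np.flatnonzero(self.elements != "H")

    def molecule_count(self, cls: str | None = None) -> int:
        sel = (slice(None) if cls is None
               else self.molecule_classes == cls)
        ids = self.molecule_ids[sel]
        return len(np.unique(ids[ids >= 0]))

    def chains(self) -> list[np.ndarray]:
        """Atom-index arrays, one per protein chain (molecule)."""
        out = []
        prot = self.molecule_classes == "protein"
        for mol in np.unique(self.molecule_ids[prot]):
            out.append(np.flatnonzero(prot & (self.molecule_ids == mol)))
        return out


@dataclass
class Frame:
    """One trajectory frame: positions (nm), time (ps) and the box."""

    time: float
    positions: np.ndarray
    box: Box

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates in frame")


class Trajectory:
    """Frames over a fixed topology.

    ``positions`` is (n_frames, n_atoms, 3) wrapped into the box;
    ``unwrapped``, when present, carries the continuous (image-corrected)
    coordinates required by displacement-based observables.
    """

    def __init__(self, topology: Topology, positions, times, box: Box,
                 unwrapped=None, metadata: dict | None = None):
        self.topology = topology
        self.positions = np.asarray(positions, dtype=float)
        self.times = np.asarray(times, dtype=float)
        self.box = box
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must be (n_frames, n_atoms, 3)")
        if self.positions.shape[0] != len(self.times):
            raise ValueError("times/positions frame count mismatch")
        if topology is not None and self.positions.shape[1] != topology.n_atoms:
            raise ValueError(
                f"atom count mismatch: trajectory {self.positions.shape[1]} "
                f"vs topology {topology.n_atoms}")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")
        self.unwrapped = (np.asarray(unwrapped, dtype=float)
                          if unwrapped is not None else None)
        self.metadata = dict(metadata or {})

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    def frame(self, i: int) -> Frame:
        return Frame(float(self.times[i]), self.positions[i], self.box)

    def __iter__(self):
        return (self.frame(i) for i in range(self.n_frames))


# ---------------------------------------------------------------------------
# periodic geometry
# ---------------------------------------------------------------------------

def minimal_image(a, b, box: Box) -> np.ndarray:
    """Shortest periodic image of the displacement b - a.

    Components land in [-L/2, L/2); at the exact half-box boundary the two
    candidate images have equal magnitude, so distance-based observables are
    unaffected by the choice of side.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = b - a
    if box is None or not box.periodic:
        return d
    L = box.lengths
    if np.any(L <= 0):
        raise ValueError("non-positive box length")
    return d - L * np.floor(d / L + 0.5)


def minimum_distance(a, b, box: Box) -> np.ndarray:
    return np.linalg.norm(minimal_image(a, b, box), axis=-1)


def wrap_positions(positions, box: Box) -> np.ndarray:
    pos = np.asarray(positions, dtype=float)
    if box is None or not box.periodic:
        return pos
    return np.mod(pos, box.lengths)


def unwrap_heuristic(positions, box: Box, max_step_fraction: float = 0.25):
    """Reconstruct continuous coordinates from wrapped frames.

    Valid only when every per-frame displacement is below
    ``max_step_fraction * L``; larger apparent jumps are treated as box
    crossings.  Raises if a corrected step still exceeds the limit.
    """
    pos = np.asarray(positions, dtype=float)
    steps = minimal_image(pos[:-1], pos[1:], box)
    limit = max_step_fraction * np.min(box.lengths)
    worst = np.abs(steps).max() if len(steps) else 0.0
    if worst >= limit:
        raise ValueError(
            f"unwrap heuristic invalid: per-step displacement {worst:.3g} nm "
            f"exceeds {limit:.3g} nm")
    out = np.empty_like(pos)
    out[0] = pos[0]
    np.cumsum(steps, axis=0, out=steps)
    out[1:] = pos[0] + steps
    return out


def make_molecules_whole(frame_positions, topology: Topology, box: Box):
    """Undo PBC wrapping within each molecule (anchor = first atom)."""
    pos = np.array(frame_positions, dtype=float)
    for mol in np.unique(topology.molecule_ids):
        idx = np.flatnonzero(topology.molecule_ids == mol)
        if len(idx) < 2:
            continue
        anchor = pos[idx[0]]
        pos[idx] = anchor + minimal_image(anchor, pos[idx], box)
    return pos


# ---------------------------------------------------------------------------
# molecule classification / detection
# ---------------------------------------------------------------------------

def classify_molecules(topology: Topology,
                       rules: Mapping[str, str] | None = None,
                       fallback: str | None = None) -> dict[str, int]:
    """Assign a molecule class to every atom from residue-name rules and
    partition atoms into molecules.

    Protein chains are detected from residue numbering (a decrease in the
    file-facing residue id, or a chain-id change, starts a new chain); every
    non-protein residue is one molecule.  Returns molecule counts per class.
    """
    rules = dict(DEFAULT_CLASS_RULES if rules is None else rules)
    classes = np.empty(topology.n_atoms, dtype=object)
    unknown = []
    for rn in np.unique(topology.resnames):
        cls = rules.get(str(rn).upper(), fallback)
        if cls is None:
            unknown.append(str(rn))
            continue
        if cls not in MOLECULE_CLASSES:
            raise ValueError(f"unknown molecule class {cls!r} for {rn}")
        classes[topology.resnames == rn] = cls
    if unknown:
        raise ValueError(
            "no classification rule for residue names: " + ", ".join(sorted(unknown)))
    topology.molecule_classes = classes

    mol_ids = np.full(topology.n_atoms, -1, dtype=int)
    next_id = 0
    # walk residues in atom order
    res_first = np.unique(topology.resindices, return_index=True)[1]
    res_order = topology.resindices[np.sort(res_first)]
    prev_protein = False
    prev_resid = None
    prev_chain = None
    for res in res_order:
        sel = topology.resindices == res
        i0 = np.flatnonzero(sel)[0]
        is_protein = classes[i0] == "protein"
        resid = topology.resids[i0]
        chain = topology.chain_ids[i0]
        if is_protein and prev_protein and resid > prev_resid and chain == prev_chain:
            mol_ids[sel] = next_id - 1      # continue current chain
        else:
            mol_ids[sel] = next_id
            next_id += 1
        prev_protein, prev_resid, prev_chain = is_protein, resid, chain
    topology.molecule_ids = mol_ids

    return {cls: topology.molecule_count(cls) for cls in MOLECULE_CLASSES}


def annotate_hbond_sites(topology: Topology, frame: Frame | None = None,
                         dh_cutoff: float = 0.12,
                         ions_as_acceptors: bool = False) -> Topology:
    """Infer donor (heavy, H) pairs and acceptor atoms.

    Hydrogens are attached to the nearest N/O of the same residue within
    ``dh_cutoff`` nm (coordinates required); acceptors are all N/O atoms.
    With ``ions_as_acceptors`` ions join the acceptor list, which lets the
    bridging analysis treat ion coordination like a hydrogen bond.
    """
    elements = topology.elements
    acc = np.flatnonzero((elements == "O") | (elements == "N"))
    if ions_as_acceptors:
        ion = np.isin(topology.molecule_classes, ("cation", "anion"))
        acc = np.union1d(acc, np.flatnonzero(ion))
    donors = []
    hydrogens = np.flatnonzero(elements == "H")
    if len(hydrogens):
        if frame is None:
            raise ValueError("coordinates needed to attach hydrogens to donors")
        pos = frame.positions
        for h in hydrogens:
            same_res = np.flatnonzero(
                (topology.resindices == topology.resindices[h])
                & ((elements == "O") | (elements == "N")))
            if not len(same_res):
                continue
            d = minimum_distance(pos[h], pos[same_res], frame.box)
            j = int(np.argmin(d))
            if d[j] <= dh_cutoff:
                donors.append((int(same_res[j]), int(h)))
    topology.donors = np.asarray(donors, dtype=int).reshape(-1, 2)
    topology.acceptors = acc
    return topology


# ---------------------------------------------------------------------------
# structure I/O (GRO / PDB via MDAnalysis)
# ---------------------------------------------------------------------------

def _require_cubicish(dimensions) -> Box | None:
    if dimensions is None or not np.any(dimensions[:3]):
        return None
    alpha, beta, gamma = dimensions[3:6]
    if not np.allclose([alpha, beta, gamma], 90.0, atol=1e-3):
        raise ValueError("triclinic boxes are not supported (cubic-only study)")
    return Box(np.asarray(dimensions[:3], dtype=float) / 10.0)   # A -> nm


def read_structure(path) -> tuple[Topology, Frame]:
    """Read a GRO or PDB file into (Topology, Frame), coordinates in nm."""
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path))
        except Exception as exc:          # noqa: BLE001 - re-raise with context
            raise ValueError(f"failed to parse {path.name}: {exc}") from exc
        atoms = u.atoms
        names = atoms.names
        resnames = atoms.resnames
        resindices = atoms.resindices
        resids = atoms.resids
        try:
            chain_ids = atoms.chainIDs
        except (AttributeError, mda.exceptions.NoDataError):
            chain_ids = np.full(len(atoms), "", dtype=object)
        box = _require_cubicish(u.dimensions)
        positions = atoms.positions / 10.0    # A -> nm
    topo = Topology(names=names, resindices=resindices, resnames=resnames,
                    chain_ids=chain_ids, resids=resids)
    frame = Frame(0.0, positions, box if box is not None else Box(np.ones(3), periodic=False))
    if box is None:
        frame.box = Box(np.ones(3) * np.inf, periodic=False)
    return topo, frame


def _to_mda_universe(topology: Topology, frame: Frame):
    import MDAnalysis as mda

    resindices = topology.resindices
    _, res_start = np.unique(resindices, return_index=True)
    res_start = np.sort(res_start)
    res_of_atom = np.searchsorted(res_start, np.arange(topology.n_atoms), side="right") - 1
    n_res = len(res_start)
    seg_of_res = np.zeros(n_res, dtype=int)
    u = mda.Universe.empty(topology.n_atoms, n_residues=n_res,
                           atom_resindex=res_of_atom,
                           residue_segindex=seg_of_res, trajectory=True)
    u.add_TopologyAttr("names", [str(x) for x in topology.names])
    u.add_TopologyAttr("resnames", [str(topology.resnames[i]) for i in res_start])
    u.add_TopologyAttr("resids", [int(topology.resids[i]) for i in res_start])
    u.add_TopologyAttr("masses", topology.masses)
    u.add_TopologyAttr("chainIDs",
                       [str(c) if str(c) else "A" for c in topology.chain_ids])
    u.add_TopologyAttr("elements", [str(e) for e in topology.elements])
    u.atoms.positions = frame.positions * 10.0    # nm -> A
    if frame.box is not None and frame.box.periodic and np.all(np.isfinite(frame.box.lengths)):
        u.dimensions = [*(frame.box.lengths * 10.0), 90.0, 90.0, 90.0]
    return u


def write_structure(path, topology: Topology, frame: Frame) -> None:
    """Write a GRO or PDB file (dispatch on extension)."""
    path = Path(path)
    u = _to_mda_universe(topology, frame)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


# ---------------------------------------------------------------------------
# trajectory I/O
# ---------------------------------------------------------------------------

def write_xyz_trajectory(path, trajectory: Trajectory) -> None:
    """Multi-frame XYZ dialect: comment line carries ``t= <ps> box= Lx Ly Lz``."""
    topo = trajectory.topology
    with open(path, "w") as fh:
        for i in range(trajectory.n_frames):
            fh.write(f"{trajectory.n_atoms}\n")
            L = trajectory.box.lengths
            fh.write(f"t= {trajectory.times[i]:.6f} box= {L[0]:.6f} {L[1]:.6f} {L[2]:.6f}\n")
            for j in range(trajectory.n_atoms):
                x, y, z = trajectory.positions[i, j]
                name = topo.names[j] if topo is not None else "X"
                fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz_trajectory(path, topology: Topology | None = None) -> Trajectory:
    frames, times, box = [], [], None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i, nframe = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise ValueError(f"line {i + 1}: expected atom count") from exc
        comment = lines[i + 1].split() if i + 1 < len(lines) else []
        t, L = float(nframe), None
        for k, tok in enumerate(comment):
            if tok in ("t=", "time="):
                t = float(comment[k + 1])
            if tok == "box=":
                L = [float(x) for x in comment[k + 1:k + 4]]
        if L is not None:
            box = Box(np.asarray(L))
        body = lines[i + 2:i + 2 + n]
        if len(body) < n:
            raise ValueError(f"truncated frame {nframe} in {path}")
        coords = np.array([[float(v) for v in ln.split()[1:4]] for ln in body])
        frames.append(coords)
        times.append(t)
        i += 2 + n
        nframe += 1
    pos = np.stack(frames)
    if topology is not None and pos.shape[1] != topology.n_atoms:
        raise ValueError(
            f"atom count mismatch: file {pos.shape[1]} vs topology {topology.n_atoms}")
    if box is None:
        box = Box(np.ones(3) * np.inf, periodic=False)
    return Trajectory(topology, pos, times, box)


def write_dcd_trajectory(path, trajectory: Trajectory) -> None:
    from mdtraj.formats import DCDTrajectoryFile

    L = trajectory.box.lengths * 10.0
    with DCDTrajectoryFile(str(path), "w") as fh:
        for i in range(trajectory.n_frames):
            fh.write(trajectory.positions[i] * 10.0,
                     cell_lengths=L, cell_angles=np.array([90.0, 90.0, 90.0]))


def read_dcd_trajectory(path, topology: Topology, times=None,
                        dt: float = 1.0, t0: float = 0.0) -> Trajectory:
    """Read a DCD; times come from ``times`` or ``t0 + dt * frame``."""
    from mdtraj.formats import DCDTrajectoryFile

    with DCDTrajectoryFile(str(path)) as fh:
        xyz, cell_lengths, _ = fh.read()
    if xyz.shape[1] != topology.n_atoms:
        raise ValueError(
            f"atom count mismatch: file {xyz.shape[1]} vs topology {topology.n_atoms}")
    box = Box(np.asarray(cell_lengths[0], dtype=float) / 10.0)
    if times is None:
        times = t0 + dt * np.arange(len(xyz))
    return Trajectory(topology, xyz / 10.0, times, box)


def write_xtc_trajectory(path, trajectory: Trajectory) -> None:
    from mdtraj.formats import XTCTrajectoryFile

    L = trajectory.box.lengths
    boxes = np.tile(np.diag(L), (trajectory.n_frames, 1, 1)).astype(np.float32)
    with XTCTrajectoryFile(str(path), "w") as fh:
        fh.write(trajectory.positions.astype(np.float32),
                 time=trajectory.times.astype(np.float32), box=boxes)


def read_xtc_trajectory(path, topology: Topology) -> Trajectory:
    from mdtraj.formats import XTCTrajectoryFile

    with XTCTrajectoryFile(str(path)) as fh:
        xyz, times, _, boxvec = fh.read()
    if xyz.shape[1] != topology.n_atoms:
        raise ValueError(
            f"atom count mismatch: file {xyz.shape[1]} vs topology {topology.n_atoms}")
    box = Box(np.asarray(np.diag(boxvec[0]), dtype=float))
    return Trajectory(topology, np.asarray(xyz, dtype=float),
                      np.asarray(times, dtype=float), box)


_TRAJ_READERS = {".xyz": read_xyz_trajectory, ".dcd": read_dcd_trajectory,
                 ".xtc": read_xtc_trajectory}
_TRAJ_WRITERS = {".xyz": write_xyz_trajectory, ".dcd": write_dcd_trajectory,
                 ".xtc": write_xtc_trajectory}


def read_trajectory(path, topology: Topology, **kw) -> Trajectory:
    """Read XTC/DCD/XYZ by extension; atom count checked against topology."""
    suffix = Path(path).suffix.lower()
    if suffix not in _TRAJ_READERS:
        raise ValueError(f"unsupported trajectory format {suffix!r}")
    return _TRAJ_READERS[suffix](path, topology, **kw)


def write_trajectory(path, trajectory: Trajectory) -> None:
    suffix = Path(path).suffix.lower()
    if suffix not in _TRAJ_WRITERS:
        raise ValueError(f"unsupported trajectory format {suffix!r}")
    _TRAJ_WRITERS[suffix](path, trajectory)
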