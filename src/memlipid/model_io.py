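"""Topology and trajectory I/O for bilayer-peptide systems.

Reads PDB topologies (protein chains plus POPC/POPA lipid residues),
trajectories in CHARMM/NAMD DCD or in the plain-text MTRAJ dialect, resolves
atom selections, and assigns lipids to leaflets.

Coordinates are in angstroms, times in picoseconds.  Residue numbering is
1-based author numbering from the PDB, so e.g. cRaf kinase-domain residues
are addressed as 340-648.  The box is orthorhombic; in-plane analyses apply
the minimum-image convention in x and y only, while z is treated as
non-periodic (the bilayer normal).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Default lipid headgroup atom sets (CHARMM36 atom names).  The phosphate
#: plus choline moiety for PC; the phosphate for PA.  User-overridable per
#: residue name via ``Topology(headgroup_sets=...)``; whether glycerol
#: carbons belong to the "headgroup" is deliberately configuration, not a
#: built-in guess.
DEFAULT_HEADGROUPS: dict[str, frozenset[str]] = {
    "POPC": frozenset({"N", "C11", "C12", "C13", "C14", "C15",
                       "P", "O11", "O12", "O13", "O14"}),
    "POPA": frozenset({"P", "O11", "O12", "O13", "O14"}),
}

LIPID_SPECIES = ("POPC", "POPA")

#: Standard amino-acid 3-letter -> 1-letter codes (plus common variants).
AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "HSD": "H", "HSE": "H", "HSP": "H",
}

ResidueKey = tuple[str, int]


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a topology."""

    atom_id: int
    atom_name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    is_heavy: bool


@dataclass(frozen=True)
class Residue:
    """A residue view: its identity plus indices into the atom table."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_indices: np.ndarray  # positions in the topology atom arrays

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.residue_number)

    @property
    def label(self) -> str:
        return f"{self.chain_id}/{self.residue_name}{self.residue_number}"


class Topology:
    """Column-oriented atom table with residue grouping and role map.

    Roles are assigned from residue names: standard amino acids are
    ``protein``, POPC/POPA are themselves, anything unknown is ``other``
    (with a logged warning unless a headgroup set is supplied for it).
    """

    def __init__(
        self,
        atom_id: Sequence[int],
        atom_name: Sequence[str],
        element: Sequence[str],
        residue_name: Sequence[str],
        residue_number: Sequence[int],
        chain_id: Sequence[str],
        headgroup_sets: Mapping[str, Iterable[str]] | None = None,
    ) -> None:
        self.atom_id = np.asarray(atom_id, dtype=np.int64)
        self.atom_name = np.asarray(atom_name, dtype=object)
        self.element = np.asarray([e.upper() for e in element], dtype=object)
        self.residue_name = np.asarray(residue_name, dtype=object)
        self.residue_number = np.asarray(residue_number, dtype=np.int64)
        self.chain_id = np.asarray(chain_id, dtype=object)

        n = len(self.atom_id)
        for arr in (self.atom_name, self.element, self.residue_name,
                    self.residue_number, self.chain_id):
            if len(arr) != n:
                raise ValueError("topology column lengths differ")
        ids, counts = np.unique(self.atom_id, return_counts=True)
        if np.any(counts > 1):
            dup = ids[counts > 1][0]
            raise ValueError(f"duplicate atom_id {dup} in topology")

        self.is_heavy = self.element != "H"

        self.headgroup_sets: dict[str, frozenset[str]] = {
            k: frozenset(v) for k, v in DEFAULT_HEADGROUPS.items()
        }
        if headgroup_sets:
            for k, v in headgroup_sets.items():
                self.headgroup_sets[k] = frozenset(v)

        self._build_residues()
        self._assign_roles()

    # -- construction helpers -------------------------------------------------

    def _build_residues(self) -> None:
        self.residues: list[Residue] = []
        self._residue_index: dict[ResidueKey, int] = {}
        # preserve first-appearance order
        order: dict[ResidueKey, list[int]] = {}
        names: dict[ResidueKey, str] = {}
        for i in range(self.n_atoms):
            key = (str(self.chain_id[i]), int(self.residue_number[i]))
            order.setdefault(key, []).append(i)
            names.setdefault(key, str(self.residue_name[i]))
        for key, idx in order.items():
            self._residue_index[key] = len(self.residues)
            self.residues.append(
                Residue(key[0], key[1], names[key], np.asarray(idx, dtype=np.int64))
            )

    def _assign_roles(self) -> None:
        self.species_map: dict[str, str] = {}
        for res in self.residues:
            rn = res.residue_name
            if rn in self.species_map:
                continue
            if rn in AA3_TO_1:
                self.species_map[rn] = "protein"
            elif rn in LIPID_SPECIES:
                self.species_map[rn] = rn
            elif rn in self.headgroup_sets:
                self.species_map[rn] = rn  # user-declared lipid species
            else:
                logger.warning(
                    "unknown residue name %r: assigning role 'other'", rn
                )
                self.species_map[rn] = "other"

    # -- basic accessors ------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atom_id)

    def atom(self, i: int) -> AtomRecord:
        return AtomRecord(
            int(self.atom_id[i]), str(self.atom_name[i]), str(self.element[i]),
            str(self.residue_name[i]), int(self.residue_number[i]),
            str(self.chain_id[i]), bool(self.is_heavy[i]),
        )

    def role(self, residue_name: str) -> str:
        return self.species_map.get(residue_name, "other")

    def residue(self, key: ResidueKey) -> Residue:
        return self.residues[self._residue_index[key]]

    def has_residue(self, key: ResidueKey) -> bool:
        return key in self._residue_index

    @property
    def protein_residues(self) -> list[Residue]:
        return [r for r in self.residues if self.role(r.residue_name) == "protein"]

    @property
    def lipid_residues(self) -> list[Residue]:
        return [r for r in self.residues
                if self.role(r.residue_name) in self.headgroup_sets]

    def protein_chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.protein_residues:
            seen.setdefault(r.chain_id, None)
        return list(seen)

    def headgroup_heavy_indices(self, res: Residue) -> np.ndarray:
        """Indices of the heavy headgroup atoms of a lipid residue."""
        hset = self.headgroup_sets[res.residue_name]
        idx = res.atom_indices
        mask = np.array(
            [self.atom_name[i] in hset and self.is_heavy[i] for i in idx],
            dtype=bool,
        )
        return idx[mask]

    def one_letter(self, res: Residue) -> str:
        try:
            return AA3_TO_1[res.residue_name]
        except KeyError:
            raise ValueError(f"no one-letter code for residue {res.label}")


@dataclass(frozen=True)
class SelectionSpec:
    """Declarative atom selection; resolves to a deterministic ordered list.

    ``resnum`` accepts a single number, an inclusive ``(lo, hi)`` range, or
    an explicit collection.  All criteria are ANDed; ``None`` means "any".
    """

    chain: str | None = None
    resnum: object = None
    resname: str | None = None
    name: str | None = None
    heavy_only: bool = False

    def resolve(self, top: Topology) -> np.ndarray:
        mask = np.ones(top.n_atoms, dtype=bool)
        if self.chain is not None:
            mask &= top.chain_id == self.chain
        if self.resname is not None:
            mask &= top.residue_name == self.resname
        if self.name is not None:
            mask &= top.atom_name == self.name
        if self.heavy_only:
            mask &= top.is_heavy
        if self.resnum is not None:
            rn = self.resnum
            if isinstance(rn, int):
                mask &= top.residue_number == rn
            elif isinstance(rn, tuple) and len(rn) == 2:
                mask &= (top.residue_number >= rn[0]) & (top.residue_number <= rn[1])
            else:
                mask &= np.isin(top.residue_number, list(rn))
        return np.nonzero(mask)[0]


@dataclass
class Frame:
    """One trajectory frame: time (ps), box lengths (A), coordinates (A)."""

    time: float
    box: np.ndarray      # (3,) Lx, Ly, Lz
    coords: np.ndarray   # (n_atoms, 3)


class Trajectory:
    """Ordered frames over a fixed topology with constant spacing dt (ps)."""

    def __init__(
        self,
        topology: Topology,
        coords: np.ndarray,
        box: np.ndarray,
        dt: float,
        t0: float = 0.0,
    ) -> None:
        coords = np.asarray(coords, dtype=np.float64)
        box = np.asarray(box, dtype=np.float64)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if coords.shape[1] != topology.n_atoms:
            raise ValueError(
                f"coordinate atom count {coords.shape[1]} != topology "
                f"atom count {topology.n_atoms}"
            )
        if box.shape != (coords.shape[0], 3):
            raise ValueError("box must have shape (n_frames, 3)")
        if np.any(box <= 0):
            raise ValueError("box lengths must be positive")
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.topology = topology
        self.coords = coords
        self.box = box
        self.dt = float(dt)
        self.t0 = float(t0)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_frames)

    def frame(self, i: int) -> Frame:
        return Frame(float(self.times[i]), self.box[i], self.coords[i])

    def subsample(self, stride: int) -> "Trajectory":
        if stride < 1:
            raise ValueError("stride must be >= 1")
        return Trajectory(self.topology, self.coords[::stride],
                          self.box[::stride], self.dt * stride, self.t0)


# ---------------------------------------------------------------------------
# PDB topology reading
# ---------------------------------------------------------------------------

def read_topology(path: str, headgroup_sets=None) -> Topology:
    """Read a PDB file into a :class:`Topology`.

    Roles are assigned from residue names; hydrogens are flagged from the
    element column where present, with a name-leading-H fallback heuristic
    (a logged warning notes when the fallback is used).
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    atoms = u.atoms

    names = [str(n) for n in atoms.names]
    try:
        elements = [str(e) for e in atoms.elements]
        if any(not e.strip() for e in elements):
            raise ValueError
    except Exception:
        logger.warning(
            "PDB lacks a usable element column; inferring elements from "
            "atom names (leading-H heuristic)"
        )
        elements = [_element_from_name(n) for n in names]

    try:
        chains = [str(c) for c in atoms.chainIDs]
    except Exception:
        chains = [str(s) for s in atoms.segids]
    chains = [c if c.strip() else "A" for c in chains]

    return Topology(
        atom_id=[int(i) for i in atoms.ids],
        atom_name=names,
        element=elements,
        residue_name=[str(r) for r in atoms.resnames],
        residue_number=[int(r) for r in atoms.resids],
        chain_id=chains,
        headgroup_sets=headgroup_sets,
    )


def _element_from_name(name: str) -> str:
    stripped = name.lstrip("0123456789")
    if stripped[:1].upper() == "H":
        return "H"
    two = stripped[:2].upper()
    if two in ("CL", "BR", "NA", "MG", "ZN", "FE", "CA"):
        # two-letter elements are rare in protein/lipid PDBs; CA is
        # ambiguous with C-alpha and resolved as carbon below
        if two != "CA":
            return two.capitalize().upper()
    return stripped[:1].upper()


# ---------------------------------------------------------------------------
# Trajectory reading / writing
# ---------------------------------------------------------------------------

MTRAJ_MAGIC = "#mtraj v1"


def read_trajectory(topology: Topology, path: str, dt: float | None = None) -> Trajectory:
    """Read a DCD or MTRAJ text trajectory over ``topology``.

    ``dt`` (ps) overrides any file metadata; for DCD it is required because
    DCD time metadata is unreliable across writers.
    """
    p = str(path)
    if p.lower().endswith(".dcd"):
        if dt is None:
            raise ValueError("dt must be given for DCD input")
        return _read_dcd(topology, p, dt)
    return _read_mtraj(topology, p, dt)


def _read_dcd(topology: Topology, path: str, dt: float) -> Trajectory:
    from MDAnalysis.coordinates.DCD import DCDReader

    coords, boxes = [], []
    with DCDReader(path) as reader:
        if reader.n_atoms != topology.n_atoms:
            raise ValueError(
                f"DCD atom count {reader.n_atoms} != topology atom count "
                f"{topology.n_atoms}"
            )
        for ts in reader:
            coords.append(np.array(ts.positions, dtype=np.float64))
            boxes.append(np.array(ts.dimensions[:3], dtype=np.float64))
    return Trajectory(topology, np.array(coords), np.array(boxes), dt)


def write_dcd(trajectory: Trajectory, path: str) -> None:
    import MDAnalysis as mda
    from MDAnalysis.coordinates.DCD import DCDWriter

    n = trajectory.topology.n_atoms
    u = mda.Universe.empty(n, trajectory=True)
    with DCDWriter(str(path), n_atoms=n) as w:
        for i in range(trajectory.n_frames):
            u.atoms.positions = trajectory.coords[i].astype(np.float32)
            u.dimensions = [*trajectory.box[i], 90.0, 90.0, 90.0]
            w.write(u.atoms)


def _read_mtraj(topology: Topology, path: str, dt: float | None) -> Trajectory:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith(MTRAJ_MAGIC):
            raise ValueError(f"{path}: not an MTRAJ v1 file")
        meta = dict(tok.split("=") for tok in header.split()[2:])
        natoms = int(meta["natoms"])
        file_dt = float(meta.get("dt_ps", 0.0))
        if natoms != topology.n_atoms:
            raise ValueError(
                f"{path}: natoms={natoms} != topology atom count "
                f"{topology.n_atoms}"
            )
        coords, boxes = [], []
        frame_no = 0
        while True:
            line = fh.readline()
            if not line:
                break
            line = line.strip()
            if not line:
                continue
            frame_no += 1
            if not line.startswith("box "):
                raise ValueError(
                    f"{path}: frame {frame_no}: expected 'box' line, got {line!r}"
                )
            boxes.append([float(x) for x in line.split()[1:4]])
            xyz = np.empty((natoms, 3))
            for j in range(natoms):
                row = fh.readline()
                if not row:
                    raise ValueError(
                        f"{path}: frame {frame_no}: truncated after "
                        f"{j} of {natoms} atoms"
                    )
                parts = row.split()
                if len(parts) != 4:
                    raise ValueError(
                        f"{path}: frame {frame_no}: malformed atom line {row!r}"
                    )
                xyz[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
            coords.append(xyz)
    if not coords:
        raise ValueError(f"{path}: no frames")
    use_dt = dt if dt is not None else file_dt
    if use_dt <= 0:
        raise ValueError(f"{path}: no usable dt (header dt_ps={file_dt})")
    return Trajectory(topology, np.array(coords), np.array(boxes), use_dt)


def write_mtraj(trajectory: Trajectory, path: str, precision: int = 6) -> None:
    """Write the MTRAJ v1 text dialect (read back bit-equal to the printed
    precision)."""
    top = trajectory.topology
    with open(str(path), "w") as fh:
        fh.write(f"{MTRAJ_MAGIC} natoms={top.n_atoms} dt_ps={trajectory.dt:g}\n")
        fmt = f"%d %.{precision}f %.{precision}f %.{precision}f\n"
        for i in range(trajectory.n_frames):
            bx = trajectory.box[i]
            fh.write(f"box %.{precision}f %.{precision}f %.{precision}f\n"
                     % (bx[0], bx[1], bx[2]))
            for j in range(top.n_atoms):
                x, y, z = trajectory.coords[i, j]
                fh.write(fmt % (top.atom_id[j], x, y, z))


def write_pdb(topology: Topology, coords: np.ndarray, path: str,
              box: np.ndarray | None = None) -> None:
    """Write a single-model PDB for ``topology`` at the given coordinates."""
    import MDAnalysis as mda

    n = topology.n_atoms
    resindex = np.empty(n, dtype=int)
    for ri, res in enumerate(topology.residues):
        resindex[res.atom_indices] = ri
    segidx = {}
    res_seg = []
    for res in topology.residues:
        segidx.setdefault(res.chain_id, len(segidx))
        res_seg.append(segidx[res.chain_id])
    u = mda.Universe.empty(
        n, n_residues=len(topology.residues), n_segments=len(segidx),
        atom_resindex=resindex, residue_segindex=np.asarray(res_seg),
        trajectory=True,
    )
    u.add_TopologyAttr("names", [str(x) for x in topology.atom_name])
    u.add_TopologyAttr("elements", [str(x) for x in topology.element])
    u.add_TopologyAttr("ids", topology.atom_id)
    u.add_TopologyAttr("resnames", [r.residue_name for r in topology.residues])
    u.add_TopologyAttr("resids", [r.residue_number for r in topology.residues])
    u.add_TopologyAttr("chainIDs",
                       [str(topology.chain_id[i]) for i in range(n)])
    u.add_TopologyAttr("segids", list(segidx))
    u.atoms.positions = np.asarray(coords, dtype=np.float32)
    if box is not None:
        u.dimensions = [*np.asarray(box, dtype=float), 90.0, 90.0, 90.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


# ---------------------------------------------------------------------------
# Leaflet assignment
# ---------------------------------------------------------------------------

def assign_leaflets(trajectory: Trajectory, frame_index: int = 0) -> dict[ResidueKey, str]:
    """Assign each lipid residue to the upper or lower leaflet.

    The midplane is the mean z of all lipid phosphorus atoms in the frame;
    a lipid with its P at z >= midplane is ``upper`` (ties go upper).
    """
    top = trajectory.topology
    lipids = top.lipid_residues
    if not lipids:
        raise ValueError("topology has no lipid residues")
    z = trajectory.coords[frame_index, :, 2]
    p_z: dict[ResidueKey, float] = {}
    for res in lipids:
        idx = [i for i in res.atom_indices if top.atom_name[i] == "P"]
        if not idx:
            raise ValueError(f"lipid {res.label} has no P atom")
        p_z[res.key] = float(z[idx[0]])
    mid = float(np.mean(list(p_z.values())))
    return {k: ("upper" if v >= mid else "lower") for k, v in p_z.items()}


# ---------------------------------------------------------------------------
# Periodic-distance helper shared by the analysis modules
# ---------------------------------------------------------------------------

def pair_distances(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """All-pairs Euclidean distances with minimum image in x and y only.

    ``a`` is (n, 3), ``b`` is (m, 3); returns an (n, m) matrix.  z is treated
    as non-periodic (the bilayer normal is not wrapped).
    """
    d = a[:, None, :] - b[None, :, :]
    for k in (0, 1):
        L = box[k]
        d[:, :, k] -= L * np.round(d[:, :, k] / L)
    return np.sqrt(np.sum(d * d, axis=2))


def xy_pair_distances(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """All-pairs in-plane (xy-projected) minimum-image distances."""
    d = a[:, None, :2] - b[None, :, :2]
    for k in (0, 1):
        L = box[k]
        d[:, :, k] -= L * np.round(d[:, :, k] / L)
    return np.sqrt(np.sum(d * d, axis=2))
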