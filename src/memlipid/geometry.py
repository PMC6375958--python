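"""Geometric episode analyses: salt bridges, shared lipids, helix
orientation, spine collinearity, and inter-chain independence.

Salt bridges pair basic side-chain nitrogens (Arg, Lys, His) with lipid
phosphate oxygens; an event is a maximal run of frames with the minimum
N...O distance within the cutoff (default 4.0 A, matching the residue-lipid
contact criterion).  Multivalent episodes are the intervals during which two
or more residues simultaneously hold salt bridges to the same lipid —
the "groove" arrangement in which one PA phosphate engages several basic
side chains at once.

Helix orientation is the angle between the best-fit axis through the helix
C-alpha atoms and the membrane normal (+z), folded into [0, 90] degrees; a
helix lying flat on the membrane reads ~90 degrees.  Spine collinearity is
the RMS deviation of side-chain centroids from their common best-fit line,
near zero when the regulatory-spine residues stack linearly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .contacts import ContactSeries
from .model_io import ResidueKey, Residue, Trajectory, pair_distances

logger = logging.getLogger(__name__)

BASIC_RESIDUES = {"ARG", "LYS", "HIS", "HSD", "HSE", "HSP"}
PHOSPHATE_OXYGENS = frozenset({"O11", "O12", "O13", "O14"})
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT", "HN", "HA"})

#: Regulatory-spine residue numbers for the cRaf kinase domain; the extended
#: set adds the NtA tryptophan that stacks onto the spine.
CRAF_SPINE = (397, 408, 466, 487)
CRAF_SPINE_EXTENDED = (342, 397, 408, 466, 487)


@dataclass(frozen=True)
class SaltBridgeEvent:
    """A maximal run of frames with a basic-N to phosphate-O salt bridge."""

    lipid: ResidueKey
    residue: ResidueKey
    start_frame: int
    end_frame: int   # inclusive
    t_i: float       # ps
    t_f: float       # ps


def _basic_nitrogens(top, res: Residue) -> np.ndarray:
    """Side-chain nitrogen atom indices of a basic residue."""
    idx = [i for i in res.atom_indices
           if top.element[i] == "N" and top.atom_name[i] != "N"]
    return np.asarray(idx, dtype=np.int64)


def _phosphate_atoms(top, res: Residue) -> np.ndarray:
    """Phosphate oxygen indices of a lipid; falls back to all headgroup
    heavy atoms for reduced (single-bead) lipid models."""
    idx = [i for i in res.atom_indices
           if top.atom_name[i] in PHOSPHATE_OXYGENS]
    if idx:
        return np.asarray(idx, dtype=np.int64)
    return top.headgroup_heavy_indices(res)


def salt_bridges(trajectory: Trajectory, d_sb: float = 4.0) -> list[SaltBridgeEvent]:
    """Detect residue-lipid salt-bridge events over the whole trajectory."""
    if d_sb < 0:
        raise ValueError("d_sb must be >= 0")
    top = trajectory.topology
    basics = [(r, _basic_nitrogens(top, r)) for r in top.protein_residues
              if r.residue_name in BASIC_RESIDUES]
    basics = [(r, n) for r, n in basics if n.size]
    if not basics:
        logger.warning("no basic residues with side-chain nitrogens")
        return []
    lipids = [(r, _phosphate_atoms(top, r)) for r in top.lipid_residues]
    lipids = [(r, o) for r, o in lipids if o.size]

    nf = trajectory.n_frames
    within = np.zeros((len(basics), len(lipids), nf), dtype=bool)
    for f in range(nf):
        coords = trajectory.coords[f]
        box = trajectory.box[f]
        for bi, (_, nidx) in enumerate(basics):
            for li, (_, oidx) in enumerate(lipids):
                d = pair_distances(coords[nidx], coords[oidx], box)
                within[bi, li, f] = d.min() <= d_sb

    events: list[SaltBridgeEvent] = []
    from .residence import _runs
    for bi, (bres, _) in enumerate(basics):
        for li, (lres, _) in enumerate(lipids):
            for s, e in _runs(within[bi, li]):
                events.append(SaltBridgeEvent(
                    lipid=lres.key, residue=bres.key,
                    start_frame=int(s), end_frame=int(e),
                    t_i=s * trajectory.dt, t_f=e * trajectory.dt,
                ))
    events.sort(key=lambda ev: (ev.lipid, ev.residue, ev.start_frame))
    return events


@dataclass(frozen=True)
class MultivalentInterval:
    """Frames during which >=2 residues bridge the same lipid at once."""

    lipid: ResidueKey
    start_frame: int
    end_frame: int   # inclusive
    residues: frozenset[ResidueKey]


def multivalent_episodes(events: list[SaltBridgeEvent]
                         ) -> dict[ResidueKey, list[MultivalentInterval]]:
    """Intervals of simultaneous multi-residue engagement per lipid.

    Consecutive frames with the same active residue set (of size >= 2) are
    collapsed into one interval; every interval is by construction a subset
    of each contributing event's span.
    """
    per_lipid: dict[ResidueKey, list[SaltBridgeEvent]] = {}
    for ev in events:
        per_lipid.setdefault(ev.lipid, []).append(ev)

    out: dict[ResidueKey, list[MultivalentInterval]] = {}
    for lipid, evs in per_lipid.items():
        nf = max(ev.end_frame for ev in evs) + 1
        active: list[set[ResidueKey]] = [set() for _ in range(nf)]
        for ev in evs:
            for f in range(ev.start_frame, ev.end_frame + 1):
                active[f].add(ev.residue)
        intervals: list[MultivalentInterval] = []
        cur_set: frozenset[ResidueKey] | None = None
        cur_start = 0
        for f in range(nf + 1):
            s = frozenset(active[f]) if f < nf and len(active[f]) >= 2 else None
            if s != cur_set:
                if cur_set is not None:
                    intervals.append(MultivalentInterval(
                        lipid, cur_start, f - 1, cur_set))
                cur_set = s
                cur_start = f
        if intervals:
            out[lipid] = intervals
    return out


@dataclass(frozen=True)
class SharedLipidEpisode:
    """A lipid's region-contact history: ordered windows of constant
    region-set, plus the total time spent touching >=2 regions at once."""

    lipid: ResidueKey
    windows: list[tuple[int, int, frozenset[str]]]  # (start, end, regions)
    multi_region_frames: int


def shared_lipid_regions(series: ContactSeries,
                         regions: dict[str, tuple[int, ...]] | None = None
                         ) -> list[SharedLipidEpisode]:
    """Track lipids shared between membrane-binding regions.

    For each lipid, consecutive frames with an identical set of contacted
    regions collapse into windows; frames with no region contact separate
    windows.  Episodes are ranked by total multi-region duration, so a
    single lipid handed between e.g. the polybasic cluster and the
    activation segment surfaces first.
    """
    from .contacts import CRAF_REGIONS
    regions = regions if regions is not None else CRAF_REGIONS

    region_rows: dict[str, list[int]] = {}
    for name, resnums in regions.items():
        rows = [i for i, k in enumerate(series.residue_keys)
                if k[1] in resnums]
        region_rows[name] = rows

    episodes: list[SharedLipidEpisode] = []
    nf = series.n_frames
    for li, lkey in enumerate(series.lipid_keys):
        col = series.contact[:, li, :]   # residues x frames
        sets: list[frozenset[str]] = []
        for f in range(nf):
            touched = frozenset(name for name, rows in region_rows.items()
                                if rows and col[rows, f].any())
            sets.append(touched)
        windows: list[tuple[int, int, frozenset[str]]] = []
        cur: frozenset[str] | None = None
        start = 0
        for f in range(nf + 1):
            s = sets[f] if f < nf and sets[f] else None
            if s != cur:
                if cur is not None:
                    windows.append((start, f - 1, cur))
                cur = s
                start = f
        if windows:
            multi = sum(e - s + 1 for s, e, rs in windows if len(rs) >= 2)
            episodes.append(SharedLipidEpisode(lkey, windows, multi))
    episodes.sort(key=lambda ep: ep.multi_region_frames, reverse=True)
    return episodes


def _fit_axis(points: np.ndarray) -> np.ndarray:
    """Unit direction of the best-fit 3D line through points (via SVD)."""
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[0]


def helix_orientation(trajectory: Trajectory,
                      helix_residues: tuple[int, int] | list[int] = (391, 408),
                      chain: str | None = None) -> np.ndarray:
    """Per-frame angle (degrees) between the helix axis and the membrane
    normal (+z), in [0, 90].

    The axis is the dominant direction of the best-fit line through the
    C-alpha atoms of ``helix_residues`` (an inclusive (lo, hi) span or an
    explicit list).  The sign ambiguity of the axis is folded away, so a
    membrane-flat helix reads ~90 degrees and a membrane-piercing one ~0.
    """
    top = trajectory.topology
    if isinstance(helix_residues, tuple) and len(helix_residues) == 2:
        lo, hi = helix_residues
        resnums = set(range(lo, hi + 1))
    else:
        resnums = set(helix_residues)
    ca = []
    for res in top.protein_residues:
        if res.residue_number in resnums and (chain is None or res.chain_id == chain):
            idx = [i for i in res.atom_indices if top.atom_name[i] == "CA"]
            if idx:
                ca.append(idx[0])
    if len(ca) < 4:
        raise ValueError(f"need >=4 C-alpha atoms in the helix span, got {len(ca)}")
    ca = np.asarray(ca)
    theta = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        axis = _fit_axis(trajectory.coords[f, ca])
        theta[f] = np.degrees(np.arccos(np.clip(abs(axis[2]), 0.0, 1.0)))
    return theta


def spine_collinearity(trajectory: Trajectory,
                       spine_residues: tuple[int, ...] = CRAF_SPINE,
                       chain: str | None = None) -> np.ndarray:
    """Per-frame RMS deviation (A) of spine side-chain centroids from their
    best-fit line.  Errors on glycine (no side chain) and on <3 residues."""
    top = trajectory.topology
    groups = []
    for res in top.protein_residues:
        if res.residue_number not in spine_residues:
            continue
        if chain is not None and res.chain_id != chain:
            continue
        if res.residue_name == "GLY":
            raise ValueError(f"glycine {res.label} has no side chain")
        side = [i for i in res.atom_indices
                if top.is_heavy[i] and top.atom_name[i] not in BACKBONE_ATOMS]
        if not side:
            raise ValueError(f"residue {res.label} has no side-chain heavy atoms")
        groups.append(np.asarray(side))
    if len(groups) < 3:
        raise ValueError(f"need >=3 spine residues, found {len(groups)}")

    rms = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        cents = np.array([trajectory.coords[f, g].mean(axis=0) for g in groups])
        axis = _fit_axis(cents)
        rel = cents - cents.mean(axis=0)
        perp = rel - np.outer(rel @ axis, axis)
        rms[f] = np.sqrt(np.mean(np.sum(perp * perp, axis=1)))
    return rms


def interchain_independence(trajectory: Trajectory,
                            chains: list[str] | None = None,
                            d_cut: float = 4.0):
    """Per-frame minimum heavy-atom distance between protein chains.

    Returns ``(pairs, dmin, flagged)``: the chain-pair list, an
    (n_frames, n_pairs) distance array, and a matching boolean array marking
    frames where a pair comes within ``d_cut`` — evidence that peptide
    copies are interacting rather than sampling the membrane independently.
    """
    top = trajectory.topology
    chains = chains or top.protein_chains()
    if len(chains) < 2:
        raise ValueError("need at least two protein chains")
    atom_idx = {}
    for ch in chains:
        idx = [i for res in top.protein_residues if res.chain_id == ch
               for i in res.atom_indices if top.is_heavy[i]]
        if not idx:
            raise ValueError(f"chain {ch!r} has no protein heavy atoms")
        atom_idx[ch] = np.asarray(idx)
    pairs = [(a, b) for i, a in enumerate(chains) for b in chains[i + 1:]]
    dmin = np.empty((trajectory.n_frames, len(pairs)))
    for f in range(trajectory.n_frames):
        coords = trajectory.coords[f]
        box = trajectory.box[f]
        for pi, (a, b) in enumerate(pairs):
            dmin[f, pi] = pair_distances(coords[atom_idx[a]],
                                         coords[atom_idx[b]], box).min()
    return pairs, dmin, dmin < d_cut
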