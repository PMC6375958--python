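"""Residue-lipid contact detection and contact-probability summaries.

A residue is in contact with a lipid in a frame when any protein heavy atom
of the residue lies within the cutoff distance (default 4.0 A) of any heavy
atom of the lipid headgroup.  Distances are 3D Euclidean with the minimum
image applied in x and y (the bilayer plane is periodic); both leaflets are
examined, though at 4 A only the proximal leaflet is geometrically
reachable.

Per-residue contact probability is the fraction of frames in contact with at
least one lipid; for systems containing several copies of an identical
peptide the probability is averaged positionally across the copies.
Stable-residue sets use a strict ``>`` threshold (e.g. residues in contact
for more than 50% or 80% of the frames).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_io import ResidueKey, Topology, Trajectory, pair_distances

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContactParams:
    """Contact criterion parameters.

    d_cut : cutoff distance in A (any protein heavy atom to any lipid
        headgroup heavy atom).
    protein_heavy_only : restrict the protein side to heavy atoms.
    """

    d_cut: float = 4.0
    protein_heavy_only: bool = True

    def __post_init__(self):
        if self.d_cut <= 0:
            raise ValueError("d_cut must be positive")


@dataclass
class ContactSeries:
    """Boolean residue x lipid x frame contact record."""

    residue_keys: list[ResidueKey]
    residue_names: list[str]
    lipid_keys: list[ResidueKey]
    lipid_species: list[str]
    contact: np.ndarray  # bool (n_residues, n_lipids, n_frames)
    dt: float            # ps

    @property
    def n_frames(self) -> int:
        return self.contact.shape[2]

    def any_lipid(self, species: str | None = None) -> np.ndarray:
        """Per-residue, per-frame membrane contact (OR over lipids)."""
        if species is None:
            sel = slice(None)
        else:
            sel = [i for i, s in enumerate(self.lipid_species) if s == species]
        return self.contact[:, sel, :].any(axis=1)

    def subsample(self, stride: int) -> "ContactSeries":
        if stride < 1:
            raise ValueError("stride must be >= 1")
        sub = self.contact[:, :, ::stride]
        if sub.shape[2] < 2:
            raise ValueError("fewer than 2 frames remain after subsampling")
        return ContactSeries(self.residue_keys, self.residue_names,
                             self.lipid_keys, self.lipid_species,
                             sub, self.dt * stride)


def _atom_groups(top: Topology, params: ContactParams):
    """Per-residue protein atom index lists and per-lipid headgroup lists."""
    prot = []
    for res in top.protein_residues:
        idx = res.atom_indices
        if params.protein_heavy_only:
            idx = idx[top.is_heavy[idx]]
        if len(idx) == 0:
            raise ValueError(f"residue {res.label} has no heavy atoms")
        prot.append((res, idx))
    lip = []
    for res in top.lipid_residues:
        idx = top.headgroup_heavy_indices(res)
        if len(idx) == 0:
            raise ValueError(f"lipid {res.label} has no headgroup heavy atoms")
        lip.append((res, idx))
    return prot, lip


def frame_contacts(trajectory: Trajectory, params: ContactParams,
                   frame_index: int) -> np.ndarray:
    """Boolean residue x lipid contact matrix for one frame."""
    top = trajectory.topology
    prot, lip = _atom_groups(top, params)
    if not prot or not lip:
        raise ValueError("need at least one protein residue and one lipid")
    coords = trajectory.coords[frame_index]
    box = trajectory.box[frame_index]

    prot_atoms = np.concatenate([idx for _, idx in prot])
    lip_atoms = np.concatenate([idx for _, idx in lip])
    d = pair_distances(coords[prot_atoms], coords[lip_atoms], box)

    out = np.zeros((len(prot), len(lip)), dtype=bool)
    pi = 0
    for r, (_, pidx) in enumerate(prot):
        li = 0
        block = d[pi:pi + len(pidx)]
        for c, (_, lidx) in enumerate(lip):
            out[r, c] = block[:, li:li + len(lidx)].min() <= params.d_cut
            li += len(lidx)
        pi += len(pidx)
    return out


def contact_series(trajectory: Trajectory, params: ContactParams | None = None,
                   start_ps: float = 0.0) -> ContactSeries:
    """Compute the full per-frame contact record of a trajectory.

    ``start_ps`` drops frames before that time (all frames by default).
    """
    params = params or ContactParams()
    top = trajectory.topology
    prot, lip = _atom_groups(top, params)
    if not prot or not lip:
        raise ValueError("need at least one protein residue and one lipid")
    frames = np.nonzero(trajectory.times >= start_ps)[0]
    contact = np.zeros((len(prot), len(lip), len(frames)), dtype=bool)
    for fi, f in enumerate(frames):
        contact[:, :, fi] = frame_contacts(trajectory, params, int(f))
    return ContactSeries(
        residue_keys=[r.key for r, _ in prot],
        residue_names=[r.residue_name for r, _ in prot],
        lipid_keys=[r.key for r, _ in lip],
        lipid_species=[top.role(r.residue_name) for r, _ in lip],
        contact=contact,
        dt=trajectory.dt,
    )


@dataclass
class ContactSummary:
    """Per-residue contact probabilities, optionally copy-averaged.

    ``table`` has one row per residue (or per equivalent position when
    chain groups were averaged) with columns ``chain, resnum, resname,
    p_contact`` plus one ``p_<species>`` column per lipid species.
    """

    table: pd.DataFrame
    species: list[str] = field(default_factory=list)

    def probability(self, key: ResidueKey) -> float:
        m = self.table[(self.table["chain"] == key[0]) &
                       (self.table["resnum"] == key[1])]
        if m.empty:
            raise KeyError(key)
        return float(m["p_contact"].iloc[0])

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path, index=False)


def contact_probability(series: ContactSeries,
                        chain_groups: list[list[str]] | None = None
                        ) -> ContactSummary:
    """Per-residue contact probability with averaging over identical chains.

    ``chain_groups`` lists sets of chain ids that are copies of the same
    peptide; probabilities are averaged at equivalent sequence positions
    (positional, so renumbered copies are tolerated).  The averaged value is
    reported once per position under the group's first chain.
    """
    species = sorted(set(series.lipid_species))
    any_c = series.any_lipid()
    p = any_c.mean(axis=1)
    p_sp = {s: series.any_lipid(s).mean(axis=1) for s in species}

    rows = []
    for i, (key, rname) in enumerate(zip(series.residue_keys,
                                         series.residue_names)):
        row = {"chain": key[0], "resnum": key[1], "resname": rname,
               "p_contact": p[i]}
        for s in species:
            row[f"p_{s}"] = p_sp[s][i]
        rows.append(row)
    df = pd.DataFrame(rows)

    if chain_groups:
        chains_in_groups = [c for g in chain_groups for c in g]
        if len(set(chains_in_groups)) != len(chains_in_groups):
            raise ValueError("a chain appears in more than one group")
        out_frames = [df[~df["chain"].isin(chains_in_groups)]]
        for group in chain_groups:
            members = []
            for ch in group:
                sub = df[df["chain"] == ch].sort_values("resnum")
                if sub.empty:
                    raise ValueError(f"chain {ch!r} not present in series")
                members.append(sub.reset_index(drop=True))
            lengths = {len(m) for m in members}
            if len(lengths) != 1:
                raise ValueError(
                    f"chains {group} have unequal residue counts {sorted(lengths)}"
                )
            seqs = {tuple(m["resname"]) for m in members}
            if len(seqs) != 1:
                raise ValueError(f"chains {group} are not identical copies")
            avg = members[0].copy()
            value_cols = ["p_contact"] + [f"p_{s}" for s in species]
            for col in value_cols:
                avg[col] = np.mean([m[col].to_numpy() for m in members], axis=0)
            out_frames.append(avg)
        df = pd.concat(out_frames, ignore_index=True)

    return ContactSummary(table=df, species=species)


def stable_residues(summary: ContactSummary, threshold: float,
                    species: str | None = None) -> set[ResidueKey]:
    """Residues whose contact probability strictly exceeds ``threshold``."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    col = "p_contact" if species is None else f"p_{species}"
    sel = summary.table[summary.table[col] > threshold]
    return {(str(r["chain"]), int(r["resnum"])) for _, r in sel.iterrows()}


#: Default membrane-contacting region presets for the cRaf kinase domain:
#: the N-terminal acidic region, the polybasic cluster on the aC-helix, and
#: the activation segment.
CRAF_REGIONS: dict[str, tuple[int, ...]] = {
    "NtA": (340, 341, 342),
    "basic": (391, 398, 399, 400, 401),
    "AS": (462, 463, 494, 495, 496, 497),
}


def region_summary(summary: ContactSummary,
                   regions: dict[str, tuple[int, ...]] | None = None,
                   threshold: float = 0.5,
                   chain: str | None = None):
    """Aggregate probabilities over named residue regions.

    Returns ``{region: (mean_probability, stable_member_set)}`` where the
    stable set applies the strict threshold within the region.  Overlapping
    regions are computed independently.
    """
    regions = regions if regions is not None else CRAF_REGIONS
    df = summary.table
    out = {}
    for name, resnums in regions.items():
        sub = df[df["resnum"].isin(resnums)]
        if chain is not None:
            sub = sub[sub["chain"] == chain]
        present = set(int(x) for x in sub["resnum"])
        missing = [r for r in resnums if r not in present]
        if missing:
            raise ValueError(f"region {name!r} references absent residues {missing}")
        mean_p = float(sub["p_contact"].mean())
        stable = {(str(r["chain"]), int(r["resnum"]))
                  for _, r in sub.iterrows() if r["p_contact"] > threshold}
        out[name] = (mean_p, stable)
    return out
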