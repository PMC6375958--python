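"""In-plane lipid distribution statistics.

Implements the two-dimensional radial distribution function g_2D(r) of lipid
phosphorus atoms around reference protein atoms, block-wise convergence
checks, and local species enrichment near a residue region.

g_2D(r) is computed from xy-projected minimum-image distances:

    g(r) = < n(r) > / (2 pi r dr rho)

where n(r) is the pair count in the annulus [r, r+dr) around a reference
atom and rho is the instantaneous in-plane number density of target lipids
in the scoped leaflet, N / (Lx * Ly).  Profiles are averaged over reference
atoms and frames; normalisation uses the per-frame box area since NPT boxes
fluctuate.  For a uniform lipid field g -> 1.

Reference-atom conventions: the basic-cluster reference atoms are the lysine
side-chain nitrogen NZ and an arginine guanidinium nitrogen.  Which arginine
nitrogen is intended by informal usage is ambiguous; the default here is NE,
with NH1/NH2 selectable via configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .contacts import ContactParams, ContactSeries, contact_series
from .model_io import (ResidueKey, Trajectory, assign_leaflets,
                       xy_pair_distances)

logger = logging.getLogger(__name__)

#: Default reference atom per basic residue type (overridable).
BASIC_REFERENCE_ATOMS = {"ARG": "NE", "LYS": "NZ", "HIS": "NE2"}


@dataclass
class RDFProfile:
    """A 2D radial distribution profile."""

    r_centers: np.ndarray   # A
    g: np.ndarray           # dimensionless
    dr: float               # A
    reference: str          # description of the reference atoms
    target_species: str
    leaflet: str
    window_ps: tuple[float, float]
    n_frames: int
    n_reference: int

    def to_csv(self, path: str, block_label: str = "full") -> None:
        import pandas as pd
        pd.DataFrame({"r_center": self.r_centers, "g": self.g,
                      "block_label": block_label}).to_csv(path, index=False)


def _target_phosphorus(trajectory: Trajectory, target_species: str,
                       leaflet: str) -> np.ndarray:
    """Atom indices of target-species P atoms in the scoped leaflet."""
    top = trajectory.topology
    lipids = [r for r in top.lipid_residues
              if top.role(r.residue_name) == target_species]
    if not lipids:
        raise ValueError(f"no lipids of species {target_species!r}")
    if leaflet != "both":
        labels = assign_leaflets(trajectory, 0)
        lipids = [r for r in lipids if labels[r.key] == leaflet]
        if not lipids:
            raise ValueError(
                f"no {target_species} lipids in the {leaflet} leaflet")
    idx = []
    for res in lipids:
        p = [i for i in res.atom_indices if top.atom_name[i] == "P"]
        if not p:
            raise ValueError(f"lipid {res.label} has no P atom")
        idx.append(p[0])
    return np.asarray(idx, dtype=np.int64)


def _auto_leaflet(trajectory: Trajectory, ref_idx: np.ndarray) -> str:
    """Leaflet whose P plane is nearest the reference atoms (frame 0)."""
    top = trajectory.topology
    labels = assign_leaflets(trajectory, 0)
    z = trajectory.coords[0, :, 2]
    planes = {}
    for leaf in ("upper", "lower"):
        zs = []
        for res in top.lipid_residues:
            if labels[res.key] != leaf:
                continue
            p = [i for i in res.atom_indices if top.atom_name[i] == "P"]
            zs.append(z[p[0]])
        planes[leaf] = np.mean(zs) if zs else np.inf
    ref_z = float(np.mean(z[ref_idx]))
    return min(planes, key=lambda k: abs(planes[k] - ref_z))


def rdf2d(trajectory: Trajectory,
          reference_atoms: np.ndarray,
          target_species: str = "POPA",
          leaflet: str = "auto",
          r_max: float = 12.0,
          dr: float = 0.2,
          window_ps: tuple[float, float] | None = None) -> RDFProfile:
    """In-plane radial distribution of target-species P atoms around
    reference atoms.

    ``reference_atoms`` are atom indices into the topology (e.g. from a
    :class:`~memlipid.model_io.SelectionSpec`).  ``leaflet`` is ``upper``,
    ``lower``, ``both``, or ``auto`` (the leaflet whose phosphate plane is
    nearest the reference atoms).  The profile is averaged over reference
    atoms and over the frames whose times fall in ``window_ps``.
    """
    reference_atoms = np.asarray(reference_atoms, dtype=np.int64)
    if reference_atoms.size == 0:
        raise ValueError("no reference atoms")
    box0 = trajectory.box[0]
    if r_max >= min(box0[0], box0[1]) / 2:
        raise ValueError("r_max must be below half the in-plane box length")

    if leaflet == "auto":
        leaflet = _auto_leaflet(trajectory, reference_atoms)
    targets = _target_phosphorus(trajectory, target_species, leaflet)

    times = trajectory.times
    if window_ps is None:
        frames = np.arange(trajectory.n_frames)
        window_ps = (float(times[0]), float(times[-1]))
    else:
        t0, t1 = window_ps
        if t1 <= t0:
            raise ValueError("empty time window")
        frames = np.nonzero((times >= t0) & (times <= t1))[0]
        if frames.size == 0:
            raise ValueError("no frames in the requested window")

    nbins = int(round(r_max / dr))
    edges = np.arange(nbins + 1) * dr
    accum = np.zeros(nbins)
    for f in frames:
        coords = trajectory.coords[f]
        box = trajectory.box[f]
        rho = targets.size / (box[0] * box[1])
        d = xy_pair_distances(coords[reference_atoms], coords[targets], box)
        counts, _ = np.histogram(d.ravel(), bins=edges)
        # average over reference atoms; normalise by this frame's density
        accum += counts / (reference_atoms.size * rho)
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell_area = 2.0 * np.pi * centers * dr
    g = accum / (frames.size * shell_area)
    return RDFProfile(
        r_centers=centers, g=g, dr=dr,
        reference=f"{reference_atoms.size} atoms",
        target_species=target_species, leaflet=leaflet,
        window_ps=window_ps, n_frames=int(frames.size),
        n_reference=int(reference_atoms.size),
    )


def rdf_convergence(trajectory: Trajectory,
                    reference_atoms: np.ndarray,
                    blocks: list[tuple[float, float]],
                    **rdf_kwargs):
    """Per-time-block RDF profiles plus a convergence metric.

    Returns ``(profiles, metrics)`` where ``profiles[(t0, t1)]`` is the
    block profile and ``metrics[(t0, t1)] = max_r |g_block - g_full|``.
    """
    full = rdf2d(trajectory, reference_atoms, **rdf_kwargs)
    profiles: dict[tuple[float, float], RDFProfile] = {}
    metrics: dict[tuple[float, float], float] = {}
    for t0, t1 in blocks:
        if t1 <= t0:
            raise ValueError(f"zero-length block ({t0}, {t1})")
        prof = rdf2d(trajectory, reference_atoms,
                     window_ps=(t0, t1), **rdf_kwargs)
        profiles[(t0, t1)] = prof
        metrics[(t0, t1)] = float(np.max(np.abs(prof.g - full.g)))
    return profiles, metrics


@dataclass
class EnrichmentResult:
    """Local vs global lipid species composition near a residue region.

    ``local_fraction`` is the frame-averaged count of near lipids of the
    species over the frame-averaged count of all near lipids; a lipid is
    "near" in a frame when it contacts at least one region residue under the
    contact criterion.  ``defined`` is False when no lipid was ever near.
    """

    species: str
    local_fraction: float
    global_fraction: float
    mean_near_species: float
    mean_near_total: float
    defined: bool


def enrichment(trajectory: Trajectory,
               region_residues: set[ResidueKey],
               params: ContactParams | None = None,
               species: str = "POPA",
               series: ContactSeries | None = None) -> EnrichmentResult:
    """Species enrichment among lipids near a residue region.

    A precomputed ``series`` may be passed to avoid recomputing contacts.
    The global fraction comes from topology counts, so e.g. a bilayer of
    366 POPC and 50 POPA has a global PA fraction of 0.120.
    """
    top = trajectory.topology
    missing = [k for k in region_residues if not top.has_residue(k)]
    if missing:
        raise ValueError(f"region references absent residues {sorted(missing)}")
    if series is None:
        series = contact_series(trajectory, params or ContactParams())

    region_idx = [i for i, k in enumerate(series.residue_keys)
                  if k in region_residues]
    if not region_idx:
        raise ValueError("region residues not present in contact series")

    # lipid x frame: near iff contacting >=1 region residue
    near = series.contact[region_idx].any(axis=0)
    sp = np.array([s == species for s in series.lipid_species])

    near_total = near.sum(axis=0).astype(float)           # per frame
    near_species = near[sp].sum(axis=0).astype(float)
    mean_total = float(near_total.mean())
    mean_species = float(near_species.mean())

    n_species = sum(1 for s in series.lipid_species if s == species)
    global_fraction = n_species / len(series.lipid_species)

    if mean_total == 0:
        logger.warning("no lipid was ever near the region; "
                       "local fraction undefined")
        return EnrichmentResult(species, float("nan"), global_fraction,
                                0.0, 0.0, defined=False)
    return EnrichmentResult(species, mean_species / mean_total,
                            global_fraction, mean_species, mean_total,
                            defined=True)
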