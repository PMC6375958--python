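"""Synthetic bilayer-peptide trajectory generator with known ground truth.

Emulates the geometry the analysis stack consumes — a two-leaflet PC/PA
bilayer (default composition 183 POPC + 25 POPA per leaflet, i.e. 12% PA)
with peptide residues at the interface — using single-bead lipids and
two-bead residues.  The analyses only ever examine headgroup heavy atoms
and phosphorus positions, so single-bead lipids exercise every code path at
a fraction of the data volume.  There is no energetics: free lipids perform
seeded periodic 2D random walks in their leaflet plane, and residue-lipid
binding follows explicit schedules.

Binding rules come in two modes.  *Scripted* rules pin a dedicated lipid
inside the contact radius of its partner residue for exact, pre-declared
frame intervals — these round-trip through the contact and residence
modules event-for-event.  *Stochastic* rules run a two-state (bound or
free) chain with per-frame unbinding probability ``p_unbind`` and
rebinding probability ``p_bind``, giving geometric dwell times with mean
residence time dt*(1-p_unbind)/p_unbind.  While a rule lipid is unbound it
is kept outside 1.5x the contact radius of its residue, and all other
lipids are excluded from that zone too, so a rule residue's contacts are
exactly its scheduled ones.  Residues without rules see ordinary chance
encounters with the diffusing lipid field.

All randomness flows from one seed through a numpy PCG64 generator; the
manifest records the seed, the algorithm, and the draw order so an
independent implementation can replay the walk.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .model_io import (ResidueKey, Topology, Trajectory, write_mtraj,
                       write_pdb)

logger = logging.getLogger(__name__)

RNG_ALGORITHM = "numpy-PCG64"
#: Documented draw order (recorded in every manifest):
DRAW_ORDER = (
    "1) initial lipid xy: uniform(0,1,(n_lipids,2))*[Lx,Ly], lipid order "
    "upper-POPC, upper-POPA, lower-POPC, lower-POPA; "
    "2) per frame f=1..n_frames-1: displacement block "
    "normal(0,sigma,(n_lipids,2)) added then wrapped; "
    "3) per binding rule in spec order: one uniform(0,1) state draw "
    "(stochastic rules only); "
    "4) per bound lipid tag in first-appearance order: two uniform(0,1) "
    "draws (radius^2 fraction, angle fraction) for placement jitter"
)


@dataclass(frozen=True)
class PeptideResidue:
    """One interface residue: a CA bead 5 A above the leaflet plane and a
    side-chain bead in the plane (nitrogen-named for basic residues)."""

    name: str          # 3-letter code
    number: int
    anchor_xy: tuple[float, float]
    chain: str = "A"
    leaflet: str = "upper"


@dataclass(frozen=True)
class BindingRule:
    """A dwell schedule between one residue and one dedicated lipid.

    ``intervals`` (scripted mode) are inclusive frame index pairs; exactly
    one of ``intervals`` / ``p_unbind`` must be given.  Rules sharing a
    ``lipid_tag`` drive the same lipid, which is how multivalent and
    region-shared lipid episodes are scripted.
    """

    residue: ResidueKey
    species: str = "POPA"
    intervals: tuple[tuple[int, int], ...] | None = None
    p_unbind: float | None = None
    p_bind: float = 0.1
    lipid_tag: str | None = None

    def mode(self) -> str:
        if (self.intervals is None) == (self.p_unbind is None):
            raise ValueError("exactly one of intervals/p_unbind must be set")
        return "scripted" if self.intervals is not None else "stochastic"


@dataclass
class SynthSpec:
    """Parameters of a synthetic run.

    Lipid counts are per leaflet; the defaults reproduce the reference
    bilayer composition of 183 POPC + 25 POPA per leaflet (12% PA overall)
    in a 120 x 120 A patch.  ``step_sigma`` is the per-frame Gaussian
    random-walk step (A) of a free lipid; ``contact_radius`` is the
    geometric binding radius and should match the analysis contact cutoff.
    """

    n_popc: int = 183
    n_popa: int = 25
    box: tuple[float, float, float] = (120.0, 120.0, 80.0)
    n_frames: int = 100
    dt: float = 10.0
    step_sigma: float = 1.0
    leaflet_z: float = 18.0
    contact_radius: float = 4.0
    peptides: tuple[PeptideResidue, ...] = ()
    rules: tuple[BindingRule, ...] = ()
    seed: int = 0


@dataclass
class GroundTruth:
    """What the generator actually scheduled, for recovery tests."""

    intervals: dict[tuple[ResidueKey, ResidueKey], list[tuple[int, int]]]
    leaflets: dict[ResidueKey, str]
    occupancy: dict[ResidueKey, float]     # rule residues only
    species_counts: dict[str, int]
    rule_lipids: dict[str, ResidueKey]     # lipid_tag -> lipid key
    n_frames: int
    dt: float
    seed: int


def _validate(spec: SynthSpec) -> None:
    if spec.n_popc < 0 or spec.n_popa < 0:
        raise ValueError("lipid counts must be >= 0")
    if spec.step_sigma < 0:
        raise ValueError("step_sigma must be >= 0")
    if spec.n_frames < 1:
        raise ValueError("need at least one frame")
    n_leaf = spec.n_popc + spec.n_popa
    if n_leaf:
        apl = spec.box[0] * spec.box[1] / n_leaf
        if apl < 60.0:
            raise ValueError(
                f"box too small: {apl:.1f} A^2/lipid < 60 A^2/lipid")
    for rule in spec.rules:
        rule.mode()
        if rule.intervals is not None:
            ivs = sorted(rule.intervals)
            for f0, f1 in ivs:
                if not (0 <= f0 <= f1 < spec.n_frames):
                    raise ValueError(
                        f"interval ({f0},{f1}) outside [0,{spec.n_frames})")
            for (a0, a1), (b0, b1) in zip(ivs, ivs[1:]):
                if b0 <= a1:
                    raise ValueError(
                        f"overlapping scripted intervals for {rule.residue}")


def generate(spec: SynthSpec) -> tuple[Topology, Trajectory, GroundTruth]:
    """Build topology, trajectory and ground truth from a spec (seeded)."""
    _validate(spec)
    Lx, Ly, Lz = spec.box
    rc = spec.contact_radius

    # ---- topology -------------------------------------------------------
    atom_id, atom_name, element, resname, resnum, chain = [], [], [], [], [], []
    base_coords = []

    def add_atom(name, elem, rn, num, ch, xyz):
        atom_id.append(len(atom_id) + 1)
        atom_name.append(name)
        element.append(elem)
        resname.append(rn)
        resnum.append(num)
        chain.append(ch)
        base_coords.append(xyz)

    side_bead = {"ARG": ("NH1", "N"), "LYS": ("NZ", "N"), "HIS": ("NE2", "N")}
    pep_anchor: dict[ResidueKey, np.ndarray] = {}
    for pep in spec.peptides:
        z_plane = spec.leaflet_z if pep.leaflet == "upper" else -spec.leaflet_z
        z_ca = z_plane + (5.0 if pep.leaflet == "upper" else -5.0)
        x, y = pep.anchor_xy
        add_atom("CA", "C", pep.name, pep.number, pep.chain, (x, y, z_ca))
        bead, elem = side_bead.get(pep.name, ("CB", "C"))
        add_atom(bead, elem, pep.name, pep.number, pep.chain, (x, y, z_plane))
        pep_anchor[(pep.chain, pep.number)] = np.array([x, y], dtype=float)

    lipid_keys: list[ResidueKey] = []
    lipid_species: list[str] = []
    lipid_leaflet: list[str] = []
    lipid_atom_row: list[int] = []
    lip_num = 0
    for leaf in ("upper", "lower"):
        z = spec.leaflet_z if leaf == "upper" else -spec.leaflet_z
        for species, count in (("POPC", spec.n_popc), ("POPA", spec.n_popa)):
            for _ in range(count):
                lip_num += 1
                lipid_atom_row.append(len(atom_id))
                add_atom("P", "P", species, lip_num, "L", (0.0, 0.0, z))
                lipid_keys.append(("L", lip_num))
                lipid_species.append(species)
                lipid_leaflet.append(leaf)

    top = Topology(atom_id, atom_name, element, resname, resnum, chain)
    n_lip = len(lipid_keys)

    # ---- rule wiring ----------------------------------------------------
    rules = list(spec.rules)
    for rule in rules:
        if rule.residue not in pep_anchor:
            raise ValueError(f"rule residue {rule.residue} not in peptide layout")

    # tag -> lipid assignment (rules sharing a tag share the lipid)
    tag_of_rule: list[str] = []
    tag_lipid: dict[str, int] = {}
    taken: set[int] = set()
    for k, rule in enumerate(rules):
        tag = rule.lipid_tag or f"rule{k}"
        tag_of_rule.append(tag)
        if tag in tag_lipid:
            if lipid_species[tag_lipid[tag]] != rule.species:
                raise ValueError(f"lipid tag {tag!r} used with two species")
            continue
        pep = next(p for p in spec.peptides
                   if (p.chain, p.number) == rule.residue)
        cand = [j for j in range(n_lip)
                if lipid_species[j] == rule.species
                and lipid_leaflet[j] == pep.leaflet and j not in taken]
        if not cand:
            raise ValueError(
                f"no free {rule.species} lipid in {pep.leaflet} leaflet "
                f"for rule on {rule.residue}")
        tag_lipid[tag] = cand[0]
        taken.add(cand[0])

    # anchors of rules with distinct tags must stay out of each other's
    # exclusion + binding reach so schedules cannot cross-contaminate
    rule_res_tags: dict[ResidueKey, set[str]] = {}
    for k, rule in enumerate(rules):
        rule_res_tags.setdefault(rule.residue, set()).add(tag_of_rule[k])
    res_list = list(rule_res_tags)
    for i, ra in enumerate(res_list):
        for rb in res_list[i + 1:]:
            if rule_res_tags[ra] & rule_res_tags[rb]:
                continue
            d = np.linalg.norm(pep_anchor[ra] - pep_anchor[rb])
            if d < 2.5 * rc:
                raise ValueError(
                    f"rule residues {ra} and {rb} with distinct lipids are "
                    f"{d:.1f} A apart; need >= {2.5 * rc:.1f} A")

    # ---- dynamics -------------------------------------------------------
    rng = np.random.default_rng(spec.seed)
    box_xy = np.array([Lx, Ly])
    pos = rng.uniform(0.0, 1.0, (n_lip, 2)) * box_xy if n_lip else \
        np.zeros((0, 2))

    n_atoms = top.n_atoms
    coords = np.empty((spec.n_frames, n_atoms, 3))
    boxes = np.tile(np.array([Lx, Ly, Lz]), (spec.n_frames, 1))
    base = np.array(base_coords, dtype=float) if n_atoms else \
        np.zeros((0, 3))

    scripted_bound = []
    for k, rule in enumerate(rules):
        if rule.mode() == "scripted":
            mask = np.zeros(spec.n_frames, dtype=bool)
            for f0, f1 in rule.intervals:
                mask[f0:f1 + 1] = True
            scripted_bound.append(mask)
        else:
            scripted_bound.append(None)
    stoch_state = [False] * len(rules)   # stochastic rules start unbound
    bound_record = np.zeros((len(rules), spec.n_frames), dtype=bool)

    exclusion = 1.5 * rc
    release = 1.6 * rc
    rule_anchor = [pep_anchor[r.residue] for r in rules]

    anchor_centers: list[np.ndarray] = []
    for a in rule_anchor:
        if not any(np.array_equal(a, c) for c in anchor_centers):
            anchor_centers.append(a)

    def _violated(j: int) -> np.ndarray | None:
        for center in anchor_centers:
            d = pos[j] - center
            d -= box_xy * np.round(d / box_xy)
            if np.hypot(d[0], d[1]) < exclusion:
                return center
        return None

    def push_clear(j: int) -> None:
        # repeat in case leaving one zone lands inside another
        for _ in range(20):
            center = _violated(j)
            if center is None:
                return
            d = pos[j] - center
            d -= box_xy * np.round(d / box_xy)
            norm = np.hypot(d[0], d[1])
            if norm < 1e-9:
                d = np.array([1.0, 0.0])
                norm = 1.0
            pos[j] = (center + d / norm * release) % box_xy
        raise RuntimeError("could not clear exclusion zones; anchors too dense")

    for f in range(spec.n_frames):
        if f > 0 and n_lip:
            pos[:] = (pos + rng.normal(0.0, spec.step_sigma, (n_lip, 2))) \
                % box_xy
        # rule state updates (spec order)
        for k, rule in enumerate(rules):
            if scripted_bound[k] is not None:
                bound_record[k, f] = scripted_bound[k][f]
            else:
                u = rng.uniform()
                if stoch_state[k]:
                    if u < rule.p_unbind:
                        stoch_state[k] = False
                else:
                    if u < rule.p_bind:
                        stoch_state[k] = True
                bound_record[k, f] = stoch_state[k]
        # placement per lipid tag (first-appearance order)
        bound_lipids: set[int] = set()
        seen_tags: list[str] = []
        for k in range(len(rules)):
            t = tag_of_rule[k]
            if t not in seen_tags:
                seen_tags.append(t)
        for tag in seen_tags:
            j = tag_lipid[tag]
            holders = [rule_anchor[k] for k in range(len(rules))
                       if tag_of_rule[k] == tag and bound_record[k, f]]
            if holders:
                centroid = np.mean(holders, axis=0)
                spread = max(np.linalg.norm(h - centroid) for h in holders)
                max_r = max(0.0, 0.8 * rc - spread)
                u_r, u_th = rng.uniform(), rng.uniform()
                r = max_r * np.sqrt(u_r)
                th = 2.0 * np.pi * u_th
                pos[j] = (centroid + [r * np.cos(th), r * np.sin(th)]) % box_xy
                bound_lipids.add(j)
        # exclusion zones around rule residues for every unbound lipid
        if rules and n_lip:
            for j in range(n_lip):
                if j not in bound_lipids:
                    push_clear(j)

        coords[f] = base
        if n_lip:
            coords[f, lipid_atom_row, 0] = pos[:, 0]
            coords[f, lipid_atom_row, 1] = pos[:, 1]

    traj = Trajectory(top, coords, boxes, spec.dt)

    # ---- ground truth ---------------------------------------------------
    intervals: dict[tuple[ResidueKey, ResidueKey], list[tuple[int, int]]] = {}
    occupancy: dict[ResidueKey, float] = {}
    for k, rule in enumerate(rules):
        lk = lipid_keys[tag_lipid[tag_of_rule[k]]]
        ivs = _mask_to_intervals(bound_record[k])
        intervals.setdefault((rule.residue, lk), []).extend(ivs)
    for key in intervals:
        intervals[key] = sorted(intervals[key])
    for res in rule_res_tags:
        mask = np.zeros(spec.n_frames, dtype=bool)
        for k, rule in enumerate(rules):
            if rule.residue == res:
                mask |= bound_record[k]
        occupancy[res] = float(mask.mean())

    species_counts = {"POPC": 2 * spec.n_popc, "POPA": 2 * spec.n_popa}
    gt = GroundTruth(
        intervals=intervals,
        leaflets={lipid_keys[j]: lipid_leaflet[j] for j in range(n_lip)},
        occupancy=occupancy,
        species_counts=species_counts,
        rule_lipids={t: lipid_keys[j] for t, j in tag_lipid.items()},
        n_frames=spec.n_frames, dt=spec.dt, seed=spec.seed,
    )
    return top, traj, gt


def _mask_to_intervals(mask: np.ndarray) -> list[tuple[int, int]]:
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return []
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks], [idx[-1]]))
    return [(int(s), int(e)) for s, e in zip(starts, ends)]


# ---------------------------------------------------------------------------
# Fixture round-tripping
# ---------------------------------------------------------------------------

def write_fixture(topology: Topology, trajectory: Trajectory,
                  ground_truth: GroundTruth, out_dir: str,
                  spec: SynthSpec | None = None) -> dict[str, str]:
    """Write topology.pdb, traj.mtraj and manifest.json to a directory.

    The manifest records the schedule, the seed, and the RNG algorithm and
    draw order, so an oracle in any language can replay the random walk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pdb = out / "topology.pdb"
    mtr = out / "traj.mtraj"
    man = out / "manifest.json"

    write_pdb(topology, trajectory.coords[0], str(pdb), trajectory.box[0])
    write_mtraj(trajectory, str(mtr))

    manifest = {
        "rng": {"algorithm": RNG_ALGORITHM, "seed": ground_truth.seed,
                "draw_order": DRAW_ORDER},
        "n_frames": ground_truth.n_frames,
        "dt_ps": ground_truth.dt,
        "species_counts": ground_truth.species_counts,
        "leaflets": {f"{c}/{n}": leaf
                     for (c, n), leaf in ground_truth.leaflets.items()},
        "occupancy": {f"{c}/{n}": occ
                      for (c, n), occ in ground_truth.occupancy.items()},
        "intervals": [
            {"residue": f"{rk[0]}/{rk[1]}", "lipid": f"{lk[0]}/{lk[1]}",
             "frames": list(map(list, ivs))}
            for (rk, lk), ivs in ground_truth.intervals.items()
        ],
        "rule_lipids": {t: f"{c}/{n}"
                        for t, (c, n) in ground_truth.rule_lipids.items()},
    }
    if spec is not None:
        manifest["spec"] = _spec_to_jsonable(spec)
    man.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return {"pdb": str(pdb), "mtraj": str(mtr), "manifest": str(man)}


def _spec_to_jsonable(spec: SynthSpec) -> dict:
    d = asdict(spec)
    d["peptides"] = [asdict(p) for p in spec.peptides]
    d["rules"] = [asdict(r) for r in spec.rules]
    return json.loads(json.dumps(d))


def spec_from_json(path_or_dict) -> SynthSpec:
    """Rebuild a SynthSpec from a manifest's ``spec`` block or a JSON file."""
    if isinstance(path_or_dict, (str, Path)):
        d = json.loads(Path(path_or_dict).read_text())
        d = d.get("spec", d)
    else:
        d = dict(path_or_dict)
    peptides = tuple(PeptideResidue(
        name=p["name"], number=p["number"],
        anchor_xy=tuple(p["anchor_xy"]), chain=p.get("chain", "A"),
        leaflet=p.get("leaflet", "upper")) for p in d.get("peptides", ()))
    rules = tuple(BindingRule(
        residue=tuple(r["residue"]), species=r.get("species", "POPA"),
        intervals=(tuple(tuple(iv) for iv in r["intervals"])
                   if r.get("intervals") else None),
        p_unbind=r.get("p_unbind"), p_bind=r.get("p_bind", 0.1),
        lipid_tag=r.get("lipid_tag")) for r in d.get("rules", ()))
    return SynthSpec(
        n_popc=d.get("n_popc", 183), n_popa=d.get("n_popa", 25),
        box=tuple(d.get("box", (120.0, 120.0, 80.0))),
        n_frames=d.get("n_frames", 100), dt=d.get("dt", 10.0),
        step_sigma=d.get("step_sigma", 1.0),
        leaflet_z=d.get("leaflet_z", 18.0),
        contact_radius=d.get("contact_radius", 4.0),
        peptides=peptides, rules=rules, seed=d.get("seed", 0),
    )
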