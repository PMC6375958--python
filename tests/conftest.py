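import numpy as np
import pytest

from memlipid.contacts import ContactSeries
from memlipid.model_io import Topology, Trajectory
from memlipid import synthetic


def make_topology(residues, headgroup_sets=None):
    """Build a Topology from [(chain, resnum, resname, [(name, element), ...])]."""
    atom_id, names, elements, resnames, resnums, chains = [], [], [], [], [], []
    for chain, num, rname, atoms in residues:
        for name, elem in atoms:
            atom_id.append(len(atom_id) + 1)
            names.append(name)
            elements.append(elem)
            resnames.append(rname)
            resnums.append(num)
            chains.append(chain)
    return Topology(atom_id, names, elements, resnames, resnums, chains,
                    headgroup_sets=headgroup_sets)


def make_trajectory(top, frames, box=(50.0, 50.0, 50.0), dt=10.0):
    """frames: list of (n_atoms, 3) coordinate arrays."""
    coords = np.asarray(frames, dtype=float)
    boxes = np.tile(np.asarray(box, dtype=float), (coords.shape[0], 1))
    return Trajectory(top, coords, boxes, dt)


def series_from_patterns(patterns, dt=10.0, lipid_species=None):
    """Build a ContactSeries from {(res_key, lip_key): "0110..."} patterns."""
    res_keys = sorted({rk for rk, _ in patterns})
    lip_keys = sorted({lk for _, lk in patterns})
    nf = len(next(iter(patterns.values())))
    contact = np.zeros((len(res_keys), len(lip_keys), nf), dtype=bool)
    for (rk, lk), pat in patterns.items():
        contact[res_keys.index(rk), lip_keys.index(lk)] = \
            np.array([c == "1" for c in pat])
    species = lipid_species or ["POPA"] * len(lip_keys)
    return ContactSeries(
        residue_keys=res_keys,
        residue_names=["ARG"] * len(res_keys),
        lipid_keys=lip_keys,
        lipid_species=species,
        contact=contact, dt=dt,
    )


def random_series(rng, n_res=3, n_lip=3, n_frames=100, p=0.5, dt=10.0):
    contact = rng.random((n_res, n_lip, n_frames)) < p
    return ContactSeries(
        residue_keys=[("A", 390 + i) for i in range(n_res)],
        residue_names=["ARG"] * n_res,
        lipid_keys=[("L", j + 1) for j in range(n_lip)],
        lipid_species=["POPA" if j % 2 == 0 else "POPC" for j in range(n_lip)],
        contact=contact, dt=dt,
    )


@pytest.fixture(scope="session")
def stochastic_fixture():
    """A long stochastic-dwell run: one ARG with p_unbind=0.01 on a PA lipid,
    enough frames for well over 500 completed dwell events."""
    spec = synthetic.SynthSpec(
        n_popc=2, n_popa=1, box=(20.0, 20.0, 60.0),
        n_frames=60_000, dt=10.0, step_sigma=2.0, seed=2024,
        peptides=(synthetic.PeptideResidue("ARG", 398, (10.0, 10.0)),),
        rules=(synthetic.BindingRule(residue=("A", 398), species="POPA",
                                     p_unbind=0.01, p_bind=0.1),),
    )
    top, traj, gt = synthetic.generate(spec)
    return spec, top, traj, gt


@pytest.fixture(scope="session")
def scripted_fixture():
    """A scripted multi-residue fixture exercising contacts, residence,
    enrichment, and shared-lipid episodes with exact ground truth."""
    # anchors of distinct-lipid rules must be >= 10 A apart
    peps = (
        synthetic.PeptideResidue("TYR", 340, (15.0, 45.0)),
        synthetic.PeptideResidue("ARG", 391, (15.0, 15.0)),
        synthetic.PeptideResidue("ARG", 398, (45.0, 15.0)),
        synthetic.PeptideResidue("LYS", 399, (45.0, 45.0)),
    )
    rules = (
        synthetic.BindingRule(residue=("A", 398), species="POPA",
                              intervals=((10, 49), (60, 79))),
        synthetic.BindingRule(residue=("A", 391), species="POPA",
                              intervals=((5, 74),)),
        synthetic.BindingRule(residue=("A", 399), species="POPC",
                              intervals=((0, 99),)),
    )
    spec = synthetic.SynthSpec(
        n_popc=30, n_popa=8, box=(60.0, 60.0, 70.0),
        n_frames=100, dt=10.0, step_sigma=1.5, seed=7,
        peptides=peps, rules=rules,
    )
    top, traj, gt = synthetic.generate(spec)
    return spec, top, traj, gt
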