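import numpy as np
import pytest

from memlipid import synthetic
from memlipid.contacts import contact_series
from memlipid.geometry import (SaltBridgeEvent, helix_orientation,
                               interchain_independence, multivalent_episodes,
                               salt_bridges, shared_lipid_regions,
                               spine_collinearity)

from conftest import make_topology, make_trajectory, series_from_patterns
from oracles import brute_salt_bridge_frames, point_line_rms


# ---------------------------------------------------------------- salt bridges

def _nz_po_system(o_z, n_frames=5):
    top = make_topology([
        ("A", 398, "ARG", [("CA", "C"), ("NH1", "N")]),
        ("L", 1, "POPA", [("P", "P"), ("O11", "O")]),
    ])
    coords = np.zeros((n_frames, 4, 3))
    coords[:, 1] = [0, 0, 0]          # NH1
    coords[:, 2] = [0, 0, o_z + 2]    # P (kept away)
    coords[:, 3] = [0, 0, o_z]        # O11
    coords[:, 0] = [0, 0, -8]         # CA far away
    return top, make_trajectory(top, coords)


def test_persistent_bridge_is_one_event():
    top, traj = _nz_po_system(3.5)
    events = salt_bridges(traj)
    assert len(events) == 1
    ev = events[0]
    assert (ev.start_frame, ev.end_frame) == (0, 4)
    assert ev.residue == ("A", 398) and ev.lipid == ("L", 1)


def test_zero_cutoff_yields_no_events():
    top, traj = _nz_po_system(3.5)
    assert salt_bridges(traj, d_sb=0.0) == []


def test_no_basic_residue_warns(caplog):
    top = make_topology([
        ("A", 1, "GLY", [("CA", "C")]),
        ("L", 1, "POPA", [("P", "P")]),
    ])
    traj = make_trajectory(top, np.zeros((1, 2, 3)))
    with caplog.at_level("WARNING", logger="memlipid.geometry"):
        assert salt_bridges(traj) == []
    assert caplog.records


def test_salt_bridge_agrees_with_brute_force():
    rng = np.random.default_rng(17)
    top = make_topology([
        ("A", 398, "ARG", [("NE", "N"), ("NH1", "N"), ("NH2", "N")]),
        ("L", 1, "POPA", [("O11", "O"), ("O12", "O"), ("O13", "O")]),
    ])
    coords = rng.uniform(0, 12, (10, 6, 3))
    traj = make_trajectory(top, coords, box=(30, 30, 30))
    events = salt_bridges(traj, d_sb=5.0)
    fast = np.zeros(10, dtype=bool)
    for ev in events:
        fast[ev.start_frame:ev.end_frame + 1] = True
    for f in range(10):
        slow = brute_salt_bridge_frames(coords[f, :3], coords[f, 3:],
                                        traj.box[f], 5.0)
        assert fast[f] == slow


def test_shared_pa_gives_two_overlapping_events():
    """Two arginines scripted onto one PA produce two full-span events on
    the same lipid."""
    peps = (
        synthetic.PeptideResidue("ARG", 391, (15.0, 15.0)),
        synthetic.PeptideResidue("ARG", 398, (19.0, 15.0)),
    )
    rules = (
        synthetic.BindingRule(("A", 391), "POPA", intervals=((0, 99),),
                              lipid_tag="pa1"),
        synthetic.BindingRule(("A", 398), "POPA", intervals=((0, 99),),
                              lipid_tag="pa1"),
    )
    spec = synthetic.SynthSpec(n_popc=8, n_popa=2, box=(40, 40, 60),
                               n_frames=100, seed=21, peptides=peps,
                               rules=rules)
    top, traj, gt = synthetic.generate(spec)
    events = salt_bridges(traj)
    shared = gt.rule_lipids["pa1"]
    ours = [e for e in events if e.lipid == shared]
    assert {e.residue for e in ours} == {("A", 391), ("A", 398)}
    assert all((e.start_frame, e.end_frame) == (0, 99) for e in ours)

    multi = multivalent_episodes(events)
    assert shared in multi
    iv = multi[shared]
    assert len(iv) == 1
    assert (iv[0].start_frame, iv[0].end_frame) == (0, 99)
    assert iv[0].residues == {("A", 391), ("A", 398)}


# ------------------------------------------------------- multivalent episodes

def _ev(res, lipid, s, e):
    return SaltBridgeEvent(lipid=lipid, residue=res, start_frame=s,
                           end_frame=e, t_i=s * 10.0, t_f=e * 10.0)


def test_overlap_interval_intersection():
    events = [_ev(("A", 391), ("L", 1), 0, 49),
              _ev(("A", 398), ("L", 1), 20, 69)]
    multi = multivalent_episodes(events)
    iv = multi[("L", 1)]
    assert len(iv) == 1
    assert (iv[0].start_frame, iv[0].end_frame) == (20, 49)


def test_disjoint_events_no_multivalency():
    events = [_ev(("A", 391), ("L", 1), 0, 9),
              _ev(("A", 398), ("L", 1), 20, 29)]
    assert multivalent_episodes(events) == {}


def test_three_residue_groove():
    peps = (
        synthetic.PeptideResidue("ARG", 391, (30.0, 30.0)),
        synthetic.PeptideResidue("ARG", 398, (32.0, 30.0)),
        synthetic.PeptideResidue("LYS", 399, (31.0, 31.7)),
    )
    rules = tuple(
        synthetic.BindingRule(("A", n), "POPA", intervals=((5, 44),),
                              lipid_tag="groove")
        for n in (391, 398, 399))
    spec = synthetic.SynthSpec(n_popc=10, n_popa=2, box=(60, 60, 60),
                               n_frames=50, seed=3, peptides=peps,
                               rules=rules)
    top, traj, gt = synthetic.generate(spec)
    multi = multivalent_episodes(salt_bridges(traj))
    iv = multi[gt.rule_lipids["groove"]]
    assert any(len(x.residues) == 3
               and (x.start_frame, x.end_frame) == (5, 44) for x in iv)


def test_multivalent_interval_subset_of_events():
    rng = np.random.default_rng(5)
    events = []
    for res in [("A", 391), ("A", 398), ("A", 399)]:
        f = 0
        while f < 80:
            s = f + int(rng.integers(0, 10))
            e = s + int(rng.integers(0, 15))
            if s >= 80:
                break
            events.append(_ev(res, ("L", 1), s, min(e, 79)))
            f = e + 2
    multi = multivalent_episodes(events)
    for iv in multi.get(("L", 1), []):
        for res in iv.residues:
            assert any(ev.residue == res
                       and ev.start_frame <= iv.start_frame
                       and ev.end_frame >= iv.end_frame
                       for ev in events)


# ------------------------------------------------------- shared lipid regions

REGIONS = {"NtA": (340, 341, 342), "basic": (391, 398, 399, 400, 401)}


def test_single_region_lipid_one_window():
    series = series_from_patterns({(("A", 340), ("L", 1)): "1111"})
    eps = shared_lipid_regions(series, REGIONS)
    assert len(eps) == 1
    assert eps[0].windows == [(0, 3, frozenset({"NtA"}))]
    assert eps[0].multi_region_frames == 0


def test_scripted_handoff_three_windows():
    """A -> A+B -> B produces three ordered windows."""
    series = series_from_patterns({
        (("A", 340), ("L", 1)): "111110000000000",
        (("A", 398), ("L", 1)): "000001111111111",
        (("A", 340), ("L", 2)): "000000000000000",
    })
    # overlap A and B on frames 5-9
    series.contact[0, 0, 5:10] = True
    eps = shared_lipid_regions(series, REGIONS)
    ep = next(e for e in eps if e.lipid == ("L", 1))
    assert ep.windows == [
        (0, 4, frozenset({"NtA"})),
        (5, 9, frozenset({"NtA", "basic"})),
        (10, 14, frozenset({"basic"})),
    ]
    assert ep.multi_region_frames == 5
    # episodes ranked by multi-region duration; untouched lipid absent
    assert all(e.lipid != ("L", 2) for e in eps)


def test_windows_partition_contact_frames():
    rng = np.random.default_rng(8)
    series = series_from_patterns({
        (("A", 340), ("L", 1)): "".join(rng.choice(["0", "1"], 40)),
        (("A", 398), ("L", 1)): "".join(rng.choice(["0", "1"], 40)),
    })
    eps = shared_lipid_regions(series, REGIONS)
    ep = eps[0]
    covered = set()
    for s, e, rs in ep.windows:
        assert rs
        for f in range(s, e + 1):
            assert f not in covered
            covered.add(f)
    in_contact = set(np.nonzero(series.contact[:, 0, :].any(axis=0))[0])
    assert covered == in_contact


def test_fixture_region_schedule_recovered(scripted_fixture):
    """The scripted PA lipid shared between two basic-cluster residues is
    ranked by its scheduled multi-region time."""
    _, top, traj, gt = scripted_fixture
    series = contact_series(traj)
    regions = {"r391": (391,), "r398": (398,)}
    eps = shared_lipid_regions(series, regions)
    by_lipid = {e.lipid: e for e in eps}
    lip391 = gt.rule_lipids["rule1"]
    ep = by_lipid[lip391]
    # rule1 bound 391 on frames 5-74; that lipid never touches 398
    assert all(rs == frozenset({"r391"}) for _, _, rs in ep.windows)
    assert sum(e - s + 1 for s, e, _ in ep.windows) == 70


# ------------------------------------------------------------- orientation

def _ideal_helix_x(n=36):   # 36 residues at 100 deg/res = 10 full turns
    t = np.arange(n)
    return np.stack([1.5 * t,
                     2.3 * np.cos(np.radians(100) * t),
                     2.3 * np.sin(np.radians(100) * t)], axis=1)


def _ca_trajectory(points):
    n = len(points)
    top = make_topology([("A", 391 + i, "ALA", [("CA", "C")])
                         for i in range(n)])
    coords = np.asarray(points, dtype=float)[None, :, :] + 50.0
    return make_trajectory(top, coords, box=(200, 200, 200))


def test_helix_along_x_is_perpendicular_to_normal():
    traj = _ca_trajectory(_ideal_helix_x())
    theta = helix_orientation(traj, (391, 426))
    assert abs(theta[0] - 90.0) <= 1.0


def test_helix_along_z_is_parallel_to_normal():
    pts = np.zeros((6, 3))
    pts[:, 2] = np.arange(6) * 1.5
    traj = _ca_trajectory(pts)
    theta = helix_orientation(traj, (391, 396))
    assert theta[0] <= 1e-5


def test_rotation_about_y_shifts_angle_exactly():
    pts = np.zeros((6, 3))
    pts[:, 2] = np.arange(6) * 1.5          # axis exactly +z, theta = 0
    alpha = np.radians(30)
    rot = np.array([[np.cos(alpha), 0, np.sin(alpha)],
                    [0, 1, 0],
                    [-np.sin(alpha), 0, np.cos(alpha)]])
    traj = _ca_trajectory(pts @ rot.T)
    theta = helix_orientation(traj, (391, 396))
    assert theta[0] == pytest.approx(30.0, abs=1e-9)


def test_angle_invariant_under_z_rotation_and_translation():
    pts = _ideal_helix_x()
    base = helix_orientation(_ca_trajectory(pts), (391, 401))[0]
    beta = np.radians(73)
    rotz = np.array([[np.cos(beta), -np.sin(beta), 0],
                     [np.sin(beta), np.cos(beta), 0],
                     [0, 0, 1]])
    moved = pts @ rotz.T + np.array([11.0, -4.0, 9.0])
    assert helix_orientation(_ca_trajectory(moved), (391, 401))[0] == \
        pytest.approx(base, abs=1e-9)


def test_too_few_calphas_errors():
    traj = _ca_trajectory(np.zeros((3, 3)))
    with pytest.raises(ValueError, match=">=4"):
        helix_orientation(traj, (391, 393))


# ------------------------------------------------------------- spine

def _spine_traj(centroids, resnames=None, numbers=(397, 408, 466, 487, 342)):
    n = len(centroids)
    resnames = resnames or ["PHE"] * n
    residues = [("A", numbers[i], resnames[i],
                 [("CA", "C"), ("CB", "C")]) for i in range(n)]
    top = make_topology(residues)
    coords = np.zeros((1, 2 * n, 3))
    for i, c in enumerate(centroids):
        coords[0, 2 * i] = np.asarray(c) + [0, 0, 5]   # CA elsewhere
        coords[0, 2 * i + 1] = c                        # side chain = CB
    return make_trajectory(top, coords, box=(100, 100, 100))


def test_collinear_spine_rms_zero():
    cents = [[i * 3.0, i * 1.0, i * 2.0] for i in range(4)]
    traj = _spine_traj(cents)
    rms = spine_collinearity(traj, (397, 408, 466, 487))
    assert rms[0] == pytest.approx(0.0, abs=1e-9)


def test_displaced_centroid_matches_closed_form():
    cents = [[0, 0, 0], [3, 0, 0], [6, 0, 0], [3, 2.0, 0]]
    traj = _spine_traj(cents)
    rms = spine_collinearity(traj, (397, 408, 466, 487))
    expected = point_line_rms([tuple(c) for c in cents])
    assert rms[0] == pytest.approx(expected, abs=1e-6)


def test_extended_collinear_spine_still_zero():
    cents = [[i * 2.0, i * 1.0, -i * 1.5] for i in range(5)]
    traj = _spine_traj(cents)
    rms = spine_collinearity(traj, (342, 397, 408, 466, 487))
    assert rms[0] == pytest.approx(0.0, abs=1e-9)


def test_glycine_in_spine_errors():
    traj = _spine_traj([[0, 0, 0], [1, 0, 0], [2, 0, 0]],
                       resnames=["PHE", "GLY", "PHE"])
    with pytest.raises(ValueError, match="glycine|GLY|no side chain"):
        spine_collinearity(traj, (397, 408, 466))


# ------------------------------------------------- interchain independence

def test_distant_chains_not_flagged():
    """Peptide copies placed ~60 A apart never flag at the 4 A cutoff."""
    top = make_topology([
        ("A", 1, "ALA", [("CA", "C")]),
        ("B", 1, "ALA", [("CA", "C")]),
    ])
    coords = np.zeros((3, 2, 3))
    coords[:, 1, 0] = 60.0
    traj = make_trajectory(top, coords, box=(200, 200, 200))
    pairs, dmin, flagged = interchain_independence(traj)
    assert pairs == [("A", "B")]
    assert np.allclose(dmin, 60.0)
    assert not flagged.any()


def test_overlapping_chains_always_flagged():
    top = make_topology([
        ("A", 1, "ALA", [("CA", "C")]),
        ("B", 1, "ALA", [("CA", "C")]),
    ])
    traj = make_trajectory(top, np.zeros((4, 2, 3)), box=(50, 50, 50))
    _, _, flagged = interchain_independence(traj)
    assert flagged.all()


def test_pairwise_minimum_matches_brute_force():
    rng = np.random.default_rng(23)
    top = make_topology([
        ("A", 1, "ALA", [(f"C{i}", "C") for i in range(1, 6)]),
        ("B", 1, "ALA", [(f"C{i}", "C") for i in range(1, 6)]),
    ])
    coords = rng.uniform(0, 30, (2, 10, 3))
    traj = make_trajectory(top, coords, box=(30, 30, 30))
    _, dmin, _ = interchain_independence(traj)
    from oracles import min_image_distance
    for f in range(2):
        slow = min(min_image_distance(coords[f, i], coords[f, j],
                                      traj.box[f])
                   for i in range(5) for j in range(5, 10))
        assert dmin[f, 0] == pytest.approx(slow, abs=1e-9)


def test_single_chain_errors():
    top = make_topology([("A", 1, "ALA", [("CA", "C")])])
    traj = make_trajectory(top, np.zeros((1, 1, 3)))
    with pytest.raises(ValueError, match="two protein chains"):
        interchain_independence(traj)
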