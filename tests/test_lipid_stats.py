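import numpy as np
import pytest

from memlipid import synthetic
from memlipid.contacts import ContactParams, contact_series
from memlipid.lipid_stats import enrichment, rdf2d, rdf_convergence

from conftest import make_topology, make_trajectory
from oracles import brute_rdf2d


def _field_system(n_lipids, n_frames, box=60.0, seed=0, sampler=None,
                  n_ref=1):
    """Reference CA atoms plus a 2D lipid field, all in the z=0 plane.

    A single reference sits at the box centre; additional references are
    laid out on a grid."""
    residues = [("A", i + 1, "GLY", [("CA", "C")]) for i in range(n_ref)]
    residues += [("L", j + 1, "POPA", [("P", "P")]) for j in range(n_lipids)]
    top = make_topology(residues)
    rng = np.random.default_rng(seed)
    coords = np.zeros((n_frames, top.n_atoms, 3))
    if n_ref == 1:
        coords[:, 0, :2] = box / 2
    else:
        side = int(np.ceil(np.sqrt(n_ref)))
        pts = [(box * (i + 1) / (side + 1), box * (j + 1) / (side + 1))
               for i in range(side) for j in range(side)][:n_ref]
        coords[:, :n_ref, :2] = pts
    for f in range(n_frames):
        if sampler is None:
            coords[f, n_ref:, :2] = rng.uniform(0, box, (n_lipids, 2))
        else:
            coords[f, n_ref:, :2] = sampler(rng, f)
    traj = make_trajectory(top, coords, box=(box, box, box))
    return top, traj


def test_uniform_field_gives_unity_within_poisson_bands():
    """g_2D(r) = 1 for an ideal 2D Poisson lipid field, within 3 sigma."""
    n_lipids, n_frames, box = 200, 400, 60.0
    top, traj = _field_system(n_lipids, n_frames, box=box, seed=11)
    prof = rdf2d(traj, np.array([0]), target_species="POPA", leaflet="both",
                 r_max=12.0, dr=0.4)
    rho = n_lipids / box**2
    n_expected = n_frames * rho * 2 * np.pi * prof.r_centers * prof.dr
    sigma_g = 1.0 / np.sqrt(n_expected)
    assert np.all(np.abs(prof.g - 1.0) <= 3 * sigma_g)


def test_single_fixed_lipid_occupies_one_bin():
    """A lone lipid pinned at xy-distance 4.0 A fills only the r=4 bin."""
    top, traj = _field_system(1, 5)
    traj.coords[:, 1, 0] = traj.coords[:, 0, 0] + 4.0
    traj.coords[:, 1, 1] = traj.coords[:, 0, 1]
    prof = rdf2d(traj, np.array([0]), leaflet="both", r_max=12.0, dr=0.2)
    occupied = np.nonzero(prof.g > 0)[0]
    assert len(occupied) == 1
    assert prof.r_centers[occupied[0]] == pytest.approx(4.1)


def test_matches_brute_force_normalisation():
    """One random 10-lipid frame equals hand pair-count + normalisation."""
    top, traj = _field_system(10, 1, seed=5)
    prof = rdf2d(traj, np.array([0]), leaflet="both", r_max=12.0, dr=0.5)
    ref_pt = [traj.coords[0, 0]]
    targets = [traj.coords[0, j] for j in range(1, 11)]
    expected = brute_rdf2d(ref_pt, targets, traj.box[0], 12.0, 0.5)
    np.testing.assert_allclose(prof.g, expected, rtol=1e-12)


def test_normalisation_recovers_neighbor_count():
    """Integrating rho*g(r)*2*pi*r dr gives the mean in-range pair count."""
    n_lipids, n_frames, box = 50, 20, 60.0
    top, traj = _field_system(n_lipids, n_frames, box=box, seed=8)
    r_max, dr = 12.0, 0.2
    prof = rdf2d(traj, np.array([0]), leaflet="both", r_max=r_max, dr=dr)
    rho = n_lipids / box**2
    integral = np.sum(rho * prof.g * 2 * np.pi * prof.r_centers * dr)
    # direct count of in-range pairs
    d = traj.coords[:, 1:, :2] - traj.coords[:, :1, :2]
    d -= box * np.round(d / box)
    r = np.hypot(d[..., 0], d[..., 1])
    direct = (r < r_max).sum() / n_frames
    assert integral == pytest.approx(direct, rel=1e-9)


def test_in_plane_translation_invariance():
    top, traj = _field_system(30, 3, seed=2)
    prof1 = rdf2d(traj, np.array([0]), leaflet="both", r_max=10.0, dr=0.5)
    shifted = make_trajectory(
        top, traj.coords + np.array([13.0, -8.0, 0.0]),
        box=tuple(traj.box[0]))
    prof2 = rdf2d(shifted, np.array([0]), leaflet="both", r_max=10.0, dr=0.5)
    np.testing.assert_allclose(prof1.g, prof2.g, atol=1e-12)


def test_r_max_must_fit_in_box():
    top, traj = _field_system(5, 1)
    with pytest.raises(ValueError, match="r_max"):
        rdf2d(traj, np.array([0]), leaflet="both", r_max=40.0)


def test_convergence_identity_and_stationarity():
    top, traj = _field_system(400, 400, seed=4, n_ref=9)
    refs = np.arange(9)
    # the whole trajectory as a single block: metric exactly 0
    span = (0.0, float(traj.times[-1]))
    _, metrics = rdf_convergence(traj, refs, [span],
                                 leaflet="both", r_max=10.0, dr=1.0)
    assert metrics[span] == 0.0
    # four equal blocks of a stationary field stay close to the full profile
    edges = np.linspace(0, traj.times[-1], 5)
    blocks = [(float(edges[i]), float(edges[i + 1])) for i in range(4)]
    _, metrics = rdf_convergence(traj, refs, blocks,
                                 leaflet="both", r_max=10.0, dr=1.0)
    assert all(m < 0.2 for m in metrics.values())


def test_convergence_flags_drifting_field():
    """Lipids biased toward the reference late in the run leave a larger
    block deviation than a stationary field does."""
    box, n_lipids, n_frames = 60.0, 100, 200

    def sampler(rng, f):
        xy = rng.uniform(0, box, (n_lipids, 2))
        if f >= n_frames // 2:   # second half: half the lipids cluster
            k = n_lipids // 2
            xy[:k] = box / 2 + rng.normal(0, 2.0, (k, 2))
        return xy

    top, traj = _field_system(n_lipids, n_frames, box=box, seed=6,
                              sampler=sampler)
    half = float(traj.times[-1]) / 2
    blocks = [(0.0, half), (half, float(traj.times[-1]))]
    _, metrics = rdf_convergence(traj, np.array([0]), blocks,
                                 leaflet="both", r_max=10.0, dr=0.5)
    assert max(metrics.values()) > 0.5


def test_zero_length_block_errors():
    top, traj = _field_system(5, 3)
    with pytest.raises(ValueError, match="zero-length"):
        rdf_convergence(traj, np.array([0]), [(10.0, 10.0)], leaflet="both",
                        r_max=10.0, dr=0.5)


def test_auto_leaflet_scope(scripted_fixture):
    """Auto scoping picks the leaflet holding the reference atom."""
    _, top, traj, gt = scripted_fixture
    from memlipid.model_io import SelectionSpec
    ref = SelectionSpec(chain="A", resnum=398, name="NH1").resolve(top)
    prof = rdf2d(traj, ref, target_species="POPA", r_max=12.0, dr=0.5)
    assert prof.leaflet == "upper"


def test_global_fraction_from_reference_composition():
    """A 366 POPC + 50 POPA bilayer has global PA fraction 0.120."""
    spec = synthetic.SynthSpec(
        n_popc=183, n_popa=25, n_frames=2, seed=0,
        peptides=(synthetic.PeptideResidue("ARG", 398, (60.0, 60.0)),))
    top, traj, gt = synthetic.generate(spec)
    res = enrichment(traj, {("A", 398)}, ContactParams())
    assert res.global_fraction == pytest.approx(0.120, abs=5e-4)


def test_null_fixture_local_matches_global():
    """With no binding bias the local PA fraction sits inside the binomial
    95% interval around the global fraction."""
    peps = tuple(synthetic.PeptideResidue("ARG", 390 + i,
                                          (20.0 + 20.0 * i, 30.0))
                 for i in range(4))
    spec = synthetic.SynthSpec(
        n_popc=44, n_popa=6, box=(100.0, 100.0, 70.0), n_frames=300,
        step_sigma=25.0, seed=13, peptides=peps)
    top, traj, gt = synthetic.generate(spec)
    series = contact_series(traj)
    region = set(series.residue_keys)
    res = enrichment(traj, region, series=series)
    n = res.mean_near_total * traj.n_frames     # pooled near-lipid count
    assert n > 50
    p0 = res.global_fraction
    half = 1.96 * np.sqrt(p0 * (1 - p0) / n)
    assert abs(res.local_fraction - p0) <= half


def test_sticky_pa_sites_enrich_local_fraction(scripted_fixture):
    """PA-only binding rules drive the local PA fraction above global."""
    _, top, traj, gt = scripted_fixture
    series = contact_series(traj)
    region = {("A", 391), ("A", 398)}    # the PA-scripted residues
    res = enrichment(traj, region, series=series)
    assert res.defined
    assert res.local_fraction > res.global_fraction


def test_no_lipid_near_flagged(caplog):
    top, traj = _field_system(3, 2)
    traj.coords[:, 1:, :2] = 5.0   # far from the centred reference? no:
    # park lipids 25+ A away in xy from the reference at (30, 30)
    res = enrichment(traj, {("A", 1)})
    assert not res.defined
    assert np.isnan(res.local_fraction)
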