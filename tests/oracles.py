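"""Independent brute-force reference implementations used by the tests.

Deliberately naive (plain loops, no shared code with the package internals)
so they serve as oracles for the fast implementations.
"""

from __future__ import annotations

import math


def min_image_distance(a, b, box):
    """3D distance with minimum image in x and y only (plain python)."""
    dx = a[0] - b[0]
    dy = a[1] - b[1]
    dz = a[2] - b[2]
    dx -= box[0] * round(dx / box[0])
    dy -= box[1] * round(dy / box[1])
    return math.sqrt(dx * dx + dy * dy + dz * dz)


def xy_distance(a, b, box):
    dx = a[0] - b[0]
    dy = a[1] - b[1]
    dx -= box[0] * round(dx / box[0])
    dy -= box[1] * round(dy / box[1])
    return math.hypot(dx, dy)


def brute_contacts(prot_groups, lip_groups, coords, box, d_cut):
    """All-pairs residue x lipid contact matrix.

    ``prot_groups``/``lip_groups`` are lists of atom-index lists; returns a
    nested list of booleans.
    """
    out = []
    for pidx in prot_groups:
        row = []
        for lidx in lip_groups:
            hit = False
            for i in pidx:
                for j in lidx:
                    if min_image_distance(coords[i], coords[j], box) <= d_cut:
                        hit = True
            row.append(hit)
        out.append(row)
    return out


def brute_motif_matches(sequence, elements, offset=0):
    """Position-by-position window matcher; elements are sets or None."""
    L = len(elements)
    hits = []
    for i in range(len(sequence)):
        if i + L > len(sequence):
            break
        ok = True
        for j, e in enumerate(elements):
            if e is not None and sequence[i + j] not in e:
                ok = False
                break
        if ok:
            hits.append((offset + i + 1, offset + i + L))
    return hits


def brute_rdf2d(ref_points, target_points, box, r_max, dr):
    """Single-frame 2D RDF by direct pair counting and hand normalisation."""
    nbins = int(round(r_max / dr))
    counts = [0] * nbins
    for rp in ref_points:
        for tp in target_points:
            r = xy_distance(rp, tp, box)
            b = int(r / dr)
            if b < nbins:
                counts[b] += 1
    rho = len(target_points) / (box[0] * box[1])
    g = []
    for b in range(nbins):
        r_c = (b + 0.5) * dr
        shell = 2.0 * math.pi * r_c * dr
        g.append(counts[b] / (len(ref_points) * shell * rho))
    return g


def brute_salt_bridge_frames(n_atoms_coords, o_atoms_coords, box, d_sb):
    """Whether min N...O distance <= d_sb, one frame."""
    best = float("inf")
    for a in n_atoms_coords:
        for b in o_atoms_coords:
            best = min(best, min_image_distance(a, b, box))
    return best <= d_sb


def point_line_rms(points):
    """RMS distance of 3D points from their best-fit line, via direct
    minimisation over sampled directions refined by the closed form for the
    perpendicular distance (uses the covariance principal axis obtained by
    power iteration, independent of numpy.linalg)."""
    n = len(points)
    cx = sum(p[0] for p in points) / n
    cy = sum(p[1] for p in points) / n
    cz = sum(p[2] for p in points) / n
    rel = [(p[0] - cx, p[1] - cy, p[2] - cz) for p in points]
    # covariance matrix
    C = [[sum(r[i] * r[j] for r in rel) for j in range(3)] for i in range(3)]
    v = (1.0, 0.5, 0.25)
    for _ in range(500):
        w = tuple(sum(C[i][j] * v[j] for j in range(3)) for i in range(3))
        norm = math.sqrt(sum(x * x for x in w))
        if norm == 0:
            return 0.0
        v = tuple(x / norm for x in w)
    total = 0.0
    for r in rel:
        proj = sum(r[i] * v[i] for i in range(3))
        d2 = sum(r[i] * r[i] for i in range(3)) - proj * proj
        total += max(d2, 0.0)
    return math.sqrt(total / n)
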