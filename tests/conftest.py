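import numpy as np
import pytest

from tmjoints.synthetic import generate_cohort


def projection_torsion(p1, p2, p3, p4):
    """Brute-force torsion oracle, independent of the package's formulation.

    Project p1 (relative to p2) and p4 (relative to p3) onto the plane
    perpendicular to the p2->p3 axis and measure the signed angle between
    the projected rays, clockwise positive when viewed from p2 toward p3.
    """
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    d = p3 - p2
    d = d / np.linalg.norm(d)
    u = p1 - p2
    w = p4 - p3
    up = u - np.dot(u, d) * d
    wp = w - np.dot(w, d) * d
    ang = np.degrees(np.arctan2(np.dot(np.cross(up, wp), d), np.dot(up, wp)))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def angle_diff(a, b):
    """Smallest absolute difference between two angles in degrees."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def random_quadruple(rng, scale=10.0, min_norm=1e-3):
    """A random non-degenerate 4-point configuration."""
    while True:
        pts = rng.normal(size=(4, 3)) * scale
        v1, v2, v3 = pts[0] - pts[1], pts[1] - pts[2], pts[2] - pts[3]
        if (np.linalg.norm(np.cross(v1, v2)) > min_norm
                and np.linalg.norm(np.cross(v2, v3)) > min_norm):
            return pts


TWO_RESIDUE_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.60  0.00           C
ATOM      2  CA BALA A   1       2.000   0.000   0.000  0.40  0.00           C
END
"""


@pytest.fixture(scope="session")
def small_cohort():
    """30 synthetic bundles, 3-6 TM, default angle model, fixed seed."""
    return generate_cohort(30, (3, 6), seed=42)


@pytest.fixture(scope="session")
def wide_cohort():
    """60 synthetic bundles spanning 3-14 TM for grouping analyses."""
    return generate_cohort(60, (3, 14), seed=7)
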