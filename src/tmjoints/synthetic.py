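"""Synthetic joint skeletons and full C-alpha bundles with known answers.

Torsion measurement has an exact inverse: internal-coordinate chain
extension (the NeRF construction used by every torsion-space structure
builder). A :class:`BundleSpec` prescribes segment lengths, planar angles
and torsions; :func:`build_chain` lays the joints down so those values are
recovered exactly, making the spec itself the oracle for the geometry
stack. :func:`write_bundle_pdb` dresses a skeleton in ideal alpha-helical
C-alpha traces plus HELIX records and an annotation table, so the full
PDB-to-statistics pipeline can be exercised end to end; the helix lattice
displaces terminal C-alphas from the skeleton by up to the helix radius,
so recovered torsions agree with the spec only to a few degrees there,
while the bare skeleton round trip stays exact.

Ideal-helix constants (1.5 A rise/residue, 100 deg twist/residue, 2.3 A
radius) are the conventional alpha-helix values; they are fixture
parameters, not fitted quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_topology import JointSet

HELIX_RISE = 1.5  # A per residue along the axis
HELIX_TWIST = 100.0  # degrees per residue
HELIX_RADIUS = 2.3  # A, C-alpha distance from axis
LOOP_CA_SPACING = 3.8  # A, nominal consecutive C-alpha distance in loops


@dataclass
class BundleSpec:
    """Internal-coordinate recipe for one synthetic joint skeleton.

    For n helices the skeleton has 2n points, hence 2n-1 distances d_i
    (alternating helix span, loop span), 2n-2 planar angles theta_i at the
    interior points, and 2n-3 torsions tau_k alternating omega, lambda.
    """

    protein_id: str
    n_helices: int
    segment_lengths: list[float]
    planar_angles: list[float]
    torsions: list[float]
    seed: int | None = None

    def __post_init__(self):
        n = self.n_helices
        if n < 2:
            raise ValueError(f"need >= 2 helices, got {n}")
        if len(self.segment_lengths) != 2 * n - 1:
            raise ValueError(
                f"expected {2 * n - 1} segment lengths, got {len(self.segment_lengths)}"
            )
        if len(self.planar_angles) != 2 * n - 2:
            raise ValueError(
                f"expected {2 * n - 2} planar angles, got {len(self.planar_angles)}"
            )
        if len(self.torsions) != 2 * n - 3:
            raise ValueError(f"expected {2 * n - 3} torsions, got {len(self.torsions)}")
        if any(d <= 0 for d in self.segment_lengths):
            raise ValueError("segment lengths must be positive")
        if any(not 0 < t < 180 for t in self.planar_angles):
            raise ValueError("planar angles must lie strictly in (0, 180)")
        if any(not -180 < t <= 180 for t in self.torsions):
            raise ValueError("torsions must lie in (-180, 180]")


def _place_next(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                d: float, theta_deg: float, tau_deg: float) -> np.ndarray:
    """Place point D so |CD|=d, angle(B,C,D)=theta and torsion(A,B,C,D)=tau.

    Frame and signs are chosen to be the exact inverse of
    :func:`tmjoints.geometry.torsion` (clockwise-positive convention).
    """
    theta = np.radians(theta_deg)
    tau = np.radians(tau_deg)
    bc = c - b
    bc_hat = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc_hat)
    n_norm = np.linalg.norm(n)
    if n_norm < 1e-12:
        raise ValueError("previous three points are collinear; torsion frame undefined")
    n_hat = n / n_norm
    m_hat = np.cross(n_hat, bc_hat)
    # local displacement: along the chain, in-plane, out-of-plane
    d2 = np.array([
        -d * np.cos(theta),
        d * np.sin(theta) * np.cos(tau),
        d * np.sin(theta) * np.sin(tau),
    ])
    return c + d2[0] * bc_hat + d2[1] * m_hat + d2[2] * n_hat


def build_chain(spec: BundleSpec) -> JointSet:
    """Lay the joint skeleton down from its internal coordinates.

    Canonical placement: P1 at the origin, P2 on +x, P3 in the xy-plane.
    Recomputing the dihedral series on the result reproduces
    ``spec.torsions`` to numerical precision — the module's core oracle.
    """
    d = spec.segment_lengths
    th = [np.radians(t) for t in spec.planar_angles]
    pts = [np.zeros(3), np.array([d[0], 0.0, 0.0])]
    # P3 in the xy-plane, planar angle theta_1 at P2
    pts.append(pts[1] + d[1] * np.array([-np.cos(th[0]), np.sin(th[0]), 0.0]))
    for k in range(2 * spec.n_helices - 3):
        pts.append(
            _place_next(pts[-3], pts[-2], pts[-1],
                        d[k + 2], spec.planar_angles[k + 1], spec.torsions[k])
        )
    return JointSet(protein_id=spec.protein_id, points=np.array(pts))


def _perpendicular(v: np.ndarray) -> np.ndarray:
    """Any unit vector perpendicular to v (deterministic choice)."""
    ref = np.array([0.0, 0.0, 1.0]) if abs(v[2]) < 0.9 * np.linalg.norm(v) else np.array([1.0, 0.0, 0.0])
    u = np.cross(v, ref)
    return u / np.linalg.norm(u)


@dataclass
class BundlePDB:
    """A rendered synthetic bundle: PDB text plus its annotation table."""

    protein_id: str
    pdb_text: str
    annotation_text: str
    segments: list[tuple[int, int]] = field(default_factory=list)


def write_bundle_pdb(joints: JointSet, residues_per_helix: int = 19,
                     chain_id: str = "A") -> BundlePDB:
    """Render a joint skeleton as an ideal-helix C-alpha PDB file.

    Each helix axis runs from its start joint to its end joint carrying
    ``residues_per_helix`` C-alphas on an ideal helical lattice whose axis
    is translated so the terminal C-alphas straddle the joints; when the
    net twist closes ((residues_per_helix - 1) * 100 a multiple of 360,
    e.g. the default 19) the terminals coincide with the joints and the
    recovered torsions match the skeleton to PDB rounding. Non-closing
    counts leave up to the helix radius in terminal offset and
    correspondingly larger torsion shifts. Loop residues are interpolated
    linearly between consecutive helices. The matching HELIX records and a
    segment-annotation table are emitted so the file is self-describing.
    """
    if residues_per_helix < 4:
        raise ValueError(f"need >= 4 residues per helix, got {residues_per_helix}")
    n = joints.n_helices
    m = residues_per_helix

    # helix lattices first, so loops can connect actual terminal C-alphas
    helix_coords: list[np.ndarray] = []
    for i in range(n):
        p_start, p_end = joints.points[2 * i], joints.points[2 * i + 1]
        axis = p_end - p_start
        length = np.linalg.norm(axis)
        axis_hat = axis / length
        u = _perpendicular(axis_hat)
        v = np.cross(axis_hat, u)
        rise = length / (m - 1)
        offsets = [
            HELIX_RADIUS * (np.cos(np.radians(HELIX_TWIST * j)) * u
                            + np.sin(np.radians(HELIX_TWIST * j)) * v)
            for j in range(m)
        ]
        # shift the axis so terminal C-alphas straddle the joints symmetrically;
        # when the twist closes ((m-1)*100 deg multiple of 360, e.g. m=19) the
        # terminals land exactly on the joints
        shift = (offsets[0] + offsets[-1]) / 2.0
        helix_coords.append(np.array([
            p_start - shift + axis_hat * (rise * j) + offsets[j] for j in range(m)
        ]))

    atoms: list[np.ndarray] = []
    segments: list[tuple[int, int]] = []
    resnum = 0
    for i in range(n):
        if i > 0:
            prev = atoms[-1]
            first = helix_coords[i][0]
            gap = np.linalg.norm(first - prev)
            n_loop = max(1, int(round(gap / LOOP_CA_SPACING)) - 1)
            for j in range(1, n_loop + 1):
                atoms.append(prev + (first - prev) * j / (n_loop + 1))
                resnum += 1
        start_resnum = resnum + 1
        atoms.extend(helix_coords[i])
        resnum += m
        segments.append((start_resnum, resnum))

    pdb_lines = []
    for h, (s, e) in enumerate(segments, start=1):
        pdb_lines.append(
            f"HELIX  {h:>3} {h:>3} ALA {chain_id} {s:>4}  ALA {chain_id} {e:>4}  1"
            f"{'':>30}{e - s + 1:>6}"
        )
    for idx, xyz in enumerate(atoms, start=1):
        x, y, z = xyz
        pdb_lines.append(
            f"ATOM  {idx:>5}  CA  ALA {chain_id}{idx:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    pdb_lines.append("END")

    ann_lines = ["protein_id\tchain\thelix_index\tstart_residue\tend_residue"]
    for h, (s, e) in enumerate(segments, start=1):
        ann_lines.append(f"{joints.protein_id}\t{chain_id}\t{h}\t{s}\t{e}")

    return BundlePDB(
        protein_id=joints.protein_id,
        pdb_text="\n".join(pdb_lines) + "\n",
        annotation_text="\n".join(ann_lines) + "\n",
        segments=segments,
    )


#: Default cohort angle model: omega concentrated in +-(10..40) degrees
#: (slanted antiparallel packing), lambda uniform over the full circle.
DEFAULT_ANGLE_MODEL = {
    "omega_abs_range": (10.0, 40.0),
    "lambda_range": (-180.0, 180.0),
    "helix_span": (26.0, 32.0),
    "loop_span": (10.0, 16.0),
    "planar_angle": (70.0, 110.0),
}


def generate_cohort(
    n_proteins: int,
    tm_range: tuple[int, int] = (3, 6),
    angle_model: dict | None = None,
    seed: int = 0,
    tm_counts: list[int] | None = None,
) -> list[BundleSpec]:
    """A reproducible cohort of randomized bundle specs.

    Helix counts are drawn uniformly from ``tm_range`` (or taken verbatim
    from ``tm_counts``). Omega targets are drawn from an equal mixture of
    U(-hi,-lo) and U(lo,hi) with (lo,hi) = ``omega_abs_range``; lambda
    targets from U over ``lambda_range``. Identical seeds yield identical
    cohorts.
    """
    if n_proteins < 1:
        raise ValueError(f"need >= 1 protein, got {n_proteins}")
    model = dict(DEFAULT_ANGLE_MODEL)
    if angle_model:
        model.update(angle_model)
    rng = np.random.default_rng(seed)
    if tm_counts is not None:
        if len(tm_counts) != n_proteins:
            raise ValueError("tm_counts length must equal n_proteins")
        counts = list(tm_counts)
    else:
        counts = rng.integers(tm_range[0], tm_range[1] + 1, size=n_proteins).tolist()

    specs = []
    for p, n in enumerate(counts):
        lengths = []
        for s in range(2 * n - 1):
            lo, hi = model["helix_span"] if s % 2 == 0 else model["loop_span"]
            lengths.append(float(rng.uniform(lo, hi)))
        planars = rng.uniform(*model["planar_angle"], size=2 * n - 2).tolist()
        torsions = []
        o_lo, o_hi = model["omega_abs_range"]
        l_lo, l_hi = model["lambda_range"]
        for k in range(2 * n - 3):
            if k % 2 == 0:  # omega target
                mag = rng.uniform(o_lo, o_hi)
                torsions.append(float(mag if rng.random() < 0.5 else -mag))
            else:  # lambda target
                torsions.append(float(rng.uniform(l_lo, l_hi)))
        specs.append(
            BundleSpec(
                protein_id=f"SYN{p + 1:03d}A",
                n_helices=int(n),
                segment_lengths=lengths,
                planar_angles=planars,
                torsions=torsions,
                seed=seed,
            )
        )
    return specs


def mirror_joints(joints: JointSet, suffix: str = "_M") -> JointSet:
    """Reflect a skeleton through the yz-plane (negates every torsion)."""
    pts = joints.points.copy()
    pts[:, 0] *= -1
    return JointSet(protein_id=joints.protein_id + suffix, points=pts)
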