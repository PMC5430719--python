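"""Signed torsion angles and the alternating omega/lambda dihedral series.

For a joint skeleton P_1..P_2n the k-th dihedral is the torsion over the
four consecutive joints P_k..P_{k+3}, k = 1..2n-3. Windows starting at an
odd joint span a Helix-Loop-Helix and are omega-type: omega_i measures the
relative tilt of helices H_i and H_{i+1} (0 deg is antiparallel, +-180 deg
parallel). Windows starting at an even joint span a Loop-Helix-Loop and are
lambda-type: lambda_i says whether H_{i+2} sits on the same (0 deg) or the
opposite (+-180 deg) side as H_i relative to H_{i+1}. An n-helix protein
therefore yields n-1 omega and n-2 lambda angles.

Sign convention: with V1 = P1-P2, V2 = P2-P3, V3 = P3-P4 and plane normals
n1 = V1 x V2, n2 = V2 x V3, the angle is atan2((n1 x V2_hat) . n2, n1 . n2).
This equals the projection reading "clockwise is positive, viewed from P2
toward P3" and matches the torsion convention of standard structural tools.
Angles are reported in degrees in (-180, 180]; exact -180 maps to +180 so
the trans configuration has a single representative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Triple is declared collinear when |normal| < this factor x product of arm lengths.
COLLINEARITY_RTOL = 1e-10


@dataclass(frozen=True)
class DihedralRecord:
    protein_id: str
    kind: str  # "omega" | "lambda"
    index: int  # 1-based i of omega_i / lambda_i
    angle_deg: float
    joint_indices: tuple[int, int, int, int]  # 1-based positions in the joint list

    def __post_init__(self):
        if self.kind not in ("omega", "lambda"):
            raise ValueError(f"kind must be 'omega' or 'lambda', got {self.kind!r}")
        first_odd = self.joint_indices[0] % 2 == 1
        if (self.kind == "omega") != first_odd:
            raise ValueError(
                f"{self.kind} record must start at an {'odd' if self.kind == 'omega' else 'even'} "
                f"joint, got joints {self.joint_indices}"
            )
        if not -180.0 < self.angle_deg <= 180.0:
            raise ValueError(f"angle {self.angle_deg} outside (-180, 180]")


@dataclass
class AngleSeries:
    """The ordered dihedral series (omega_1, lambda_1, omega_2, ...) of one protein."""

    protein_id: str
    n_helices: int
    records: list[DihedralRecord]

    def angles(self, kind: str | None = None) -> list[float]:
        return [r.angle_deg for r in self.records if kind is None or r.kind == kind]

    @property
    def omega(self) -> list[float]:
        return self.angles("omega")

    @property
    def lam(self) -> list[float]:
        return self.angles("lambda")


def torsion(p1, p2, p3, p4) -> float:
    """Signed torsion angle of four points, degrees in (-180, 180].

    Raises ValueError for coincident consecutive points ("degenerate
    segment") or a collinear triple ("undefined normal").
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    v1 = p1 - p2
    v2 = p2 - p3
    v3 = p3 - p4

    lengths = [np.linalg.norm(v) for v in (v1, v2, v3)]
    for i, ln in enumerate(lengths):
        if ln == 0.0:
            raise ValueError(f"degenerate segment: points {i + 1} and {i + 2} coincide")

    n1 = np.cross(v1, v2)
    n2 = np.cross(v2, v3)
    if np.linalg.norm(n1) < COLLINEARITY_RTOL * lengths[0] * lengths[1]:
        raise ValueError("undefined normal: points 1, 2, 3 are collinear")
    if np.linalg.norm(n2) < COLLINEARITY_RTOL * lengths[1] * lengths[2]:
        raise ValueError("undefined normal: points 2, 3, 4 are collinear")

    v2u = v2 / lengths[1]
    angle = np.degrees(np.arctan2(np.dot(np.cross(n1, v2u), n2), np.dot(n1, n2)))
    if angle <= -180.0:  # atan2 boundary: fold -180 onto +180
        angle += 360.0
    return float(angle)


def compute_series(joints) -> AngleSeries:
    """All 2n-3 dihedrals of a joint set, alternating omega, lambda, omega, ...

    Record k (1-based) uses joints P_k..P_{k+3}; odd k is omega_{(k+1)/2},
    even k is lambda_{k/2}. Degeneracy errors are re-raised annotated with
    the protein id and window position.
    """
    pts = joints.points
    m = len(pts)
    if m < 4:
        raise ValueError(f"{joints.protein_id}: need at least 4 joints, got {m}")
    records = []
    for k in range(1, m - 2):
        try:
            angle = torsion(pts[k - 1], pts[k], pts[k + 1], pts[k + 2])
        except ValueError as exc:
            raise ValueError(f"{joints.protein_id}: dihedral window {k}: {exc}") from exc
        if k % 2 == 1:
            kind, index = "omega", (k + 1) // 2
        else:
            kind, index = "lambda", k // 2
        records.append(
            DihedralRecord(
                protein_id=joints.protein_id,
                kind=kind,
                index=index,
                angle_deg=angle,
                joint_indices=(k, k + 1, k + 2, k + 3),
            )
        )
    return AngleSeries(protein_id=joints.protein_id, n_helices=m // 2, records=records)


def expected_counts(n_helices: int) -> tuple[int, int]:
    """(number of omega, number of lambda) angles for an n-helix protein."""
    if n_helices < 2:
        raise ValueError(f"need at least 2 helices, got {n_helices}")
    return n_helices - 1, max(n_helices - 2, 0)


def write_angles_tsv(series_collection: list[AngleSeries]) -> str:
    """TSV ``protein_id kind index angle_deg j1 j2 j3 j4`` (angles 1-decimal)."""
    lines = ["protein_id\tkind\tindex\tangle_deg\tj1\tj2\tj3\tj4"]
    for series in series_collection:
        for r in series.records:
            j = "\t".join(str(x) for x in r.joint_indices)
            lines.append(f"{r.protein_id}\t{r.kind}\t{r.index}\t{r.angle_deg:.1f}\t{j}")
    return "\n".join(lines) + "\n"


def read_angles_tsv(text: str) -> list[AngleSeries]:
    """Inverse of :func:`write_angles_tsv`, at the written 0.1-degree precision."""
    import io as _io

    import pandas as pd

    df = pd.read_csv(_io.StringIO(text), sep="\t")
    required = {"protein_id", "kind", "index", "angle_deg", "j1", "j2", "j3", "j4"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"angle TSV missing column(s): {', '.join(sorted(missing))}")
    # 1-decimal rounding in the writer can turn -179.96 into "-180.0"
    df["angle_deg"] = df["angle_deg"].where(df["angle_deg"] > -180.0, df["angle_deg"] + 360.0)
    out = []
    for pid, grp in df.groupby("protein_id", sort=False):
        grp = grp.sort_values("j1")
        records = [
            DihedralRecord(
                protein_id=str(pid),
                kind=str(r.kind),
                index=int(r.index),
                angle_deg=float(r.angle_deg),
                joint_indices=(int(r.j1), int(r.j2), int(r.j3), int(r.j4)),
            )
            for r in grp.itertuples()
        ]
        n_helices = (len(records) + 3) // 2
        out.append(AngleSeries(protein_id=str(pid), n_helices=n_helices, records=records))
    return out
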