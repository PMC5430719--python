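"""Read C-alpha coordinates and TM-helix annotations; derive joint points.

A polytopic membrane protein with n transmembrane helices H_1..H_n is
reduced to 2n joint points P_1..P_2n: the C-alpha atoms of the first and
last residue of each helix. Loops are the implicit gaps between helices and
carry no representation of their own. Everything downstream (the omega and
lambda dihedral series, pattern statistics, symmetry screening) operates on
this ordered point list.

Helix boundaries are an explicit input: either a tab-separated annotation
table (OPM/PDBTM-style residue ranges) or, as a fallback, the HELIX records
of the PDB header. Annotation tables take precedence because published
segment definitions, not secondary-structure re-assignment, are what make a
joint set reproducible.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ["protein_id", "chain", "helix_index", "start_residue", "end_residue"]


@dataclass
class CalphaTrace:
    """Ordered C-alpha record for one chain.

    ``residues`` preserves file order; each entry is
    ``(residue_number, insertion_code, xyz)`` with xyz in Angstroms.
    """

    chain_id: str
    residues: list[tuple[int, str, np.ndarray]]
    _index: dict[tuple[int, str], np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self._index = {(num, icode): xyz for num, icode, xyz in self.residues}
        if len(self._index) != len(self.residues):
            raise ValueError(f"duplicate residue identifiers in chain {self.chain_id!r}")

    def __len__(self) -> int:
        return len(self.residues)

    def coord(self, residue_number: int, icode: str = "") -> np.ndarray:
        """C-alpha coordinate of a residue, or KeyError if absent."""
        return self._index[(residue_number, icode)]

    def __contains__(self, key) -> bool:
        if isinstance(key, tuple):
            return key in self._index
        return (key, "") in self._index


@dataclass(frozen=True)
class HelixSegment:
    """One TM helix H_i as an author-numbered residue range (inclusive)."""

    index: int
    start_residue: int
    end_residue: int

    def __post_init__(self):
        if self.start_residue >= self.end_residue:
            raise ValueError(
                f"helix {self.index}: start_residue ({self.start_residue}) must be "
                f"< end_residue ({self.end_residue})"
            )


@dataclass
class ProteinTopology:
    """The ordered TM helix list of one protein chain."""

    protein_id: str
    chain_id: str
    segments: list[HelixSegment]

    def __post_init__(self):
        n = len(self.segments)
        if n < 2:
            raise ValueError(
                f"{self.protein_id}: {n} helix segment(s); at least 2 are required "
                "(a single helix defines no inter-helix dihedral)"
            )
        if n == 2:
            logger.warning(
                "%s: only 2 TM helices; a single omega angle and no lambda angle "
                "will be produced", self.protein_id,
            )
        self.segments = sorted(self.segments, key=lambda s: s.start_residue)
        for a, b in zip(self.segments, self.segments[1:]):
            if b.start_residue <= a.end_residue:
                raise ValueError(
                    f"{self.protein_id}: helix segments {a.index} and {b.index} overlap "
                    f"({a.start_residue}-{a.end_residue} vs {b.start_residue}-{b.end_residue})"
                )

    @property
    def n_helices(self) -> int:
        return len(self.segments)


@dataclass
class JointSet:
    """The 2n joint points P_1..P_2n of one protein, in helix order."""

    protein_id: str
    points: np.ndarray  # shape (2n, 3)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (m, 3) array")
        if self.points.shape[0] % 2 != 0:
            raise ValueError("joint count must be even (2 per helix)")

    @property
    def n_helices(self) -> int:
        return self.points.shape[0] // 2

    def __len__(self) -> int:
        return self.points.shape[0]


def read_calpha_coordinates(pdb_text: str, chain_id: str) -> CalphaTrace:
    """Extract one C-alpha per residue for ``chain_id`` from PDB text.

    Alternate locations collapse to a single conformer: altloc '' or 'A' is
    kept, with highest occupancy as the tiebreak. Raises ValueError when the
    chain is absent (naming the available chains) or carries no CA atoms.
    """
    structure = gemmi.read_pdb_string(pdb_text)
    if len(structure) == 0:
        raise ValueError("no models in PDB input")
    model = structure[0]
    chain = model.find_chain(chain_id)
    if chain is None:
        available = ", ".join(ch.name for ch in model) or "<none>"
        raise ValueError(f"chain {chain_id!r} not found; available chains: {available}")

    residues: list[tuple[int, str, np.ndarray]] = []
    for residue in chain:
        cas = [a for a in residue if a.name == "CA" and a.element.name != "Ca"]
        if not cas:
            continue
        ca = _pick_conformer(cas)
        num = residue.seqid.num
        icode = residue.seqid.icode.strip()
        residues.append((num, icode, np.array([ca.pos.x, ca.pos.y, ca.pos.z])))
    if not residues:
        raise ValueError(f"chain {chain_id!r} contains no CA atoms")
    return CalphaTrace(chain_id=chain_id, residues=residues)


def _pick_conformer(atoms):
    # single-conformer convention: blank altloc wins, then occupancy, then 'A'
    blank = [a for a in atoms if not a.altloc.strip()]
    if blank:
        return blank[0]
    return max(atoms, key=lambda a: (a.occ, a.altloc == "A"))


def read_segment_annotation(table_text: str) -> list[ProteinTopology]:
    """Parse a TM-segment annotation table into per-protein topologies.

    Expected tab-separated columns:
    ``protein_id  chain  helix_index  start_residue  end_residue``.
    Rows may appear in any order; segments are sorted and validated
    (start < end, no overlap) per protein.
    """
    df = pd.read_csv(io.StringIO(table_text), sep=r"\s+|\t", engine="python")
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing column(s): {', '.join(missing)}")

    topologies = []
    for pid, grp in df.groupby("protein_id", sort=True):
        chains = grp["chain"].astype(str).unique()
        if len(chains) > 1:
            raise ValueError(f"{pid}: multiple chains in one topology ({', '.join(chains)})")
        segments = [
            HelixSegment(int(r.helix_index), int(r.start_residue), int(r.end_residue))
            for r in grp.sort_values("helix_index").itertuples()
        ]
        topologies.append(ProteinTopology(str(pid), chains[0], segments))
    return topologies


def read_helix_records(pdb_text: str, chain_id: str) -> list[HelixSegment]:
    """HELIX header records for one chain, as a fallback segment source.

    Returns an empty list when the header has no HELIX records for the
    chain; malformed records are skipped with a logged warning.
    """
    segments = []
    count = 0
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith("HELIX"):
            continue
        try:
            init_chain = line[19]
            end_chain = line[31]
            start = int(line[21:25])
            end = int(line[33:37])
        except (IndexError, ValueError):
            logger.warning("skipping malformed HELIX record at line %d: %r", lineno, line)
            continue
        if init_chain != chain_id or end_chain != chain_id:
            continue
        count += 1
        try:
            segments.append(HelixSegment(index=count, start_residue=start, end_residue=end))
        except ValueError as exc:
            logger.warning("skipping HELIX record at line %d: %s", lineno, exc)
            count -= 1
    return segments


def extract_joints(trace: CalphaTrace, topology: ProteinTopology) -> JointSet:
    """Joint points [Ca(start_1), Ca(end_1), Ca(start_2), ...] for a topology.

    Boundary residues are matched on author residue number with an empty
    insertion code. A missing boundary residue is an error — never silently
    replaced by a neighbour, since a shifted joint changes the dihedrals.
    """
    points = []
    for seg in topology.segments:
        for resnum in (seg.start_residue, seg.end_residue):
            try:
                points.append(trace.coord(resnum))
            except KeyError:
                raise ValueError(
                    f"{topology.protein_id}: helix {seg.index} boundary residue "
                    f"{resnum} has no CA in chain {trace.chain_id!r}"
                ) from None
    return JointSet(protein_id=topology.protein_id, points=np.array(points))


def write_joints_tsv(joint_sets: list[JointSet]) -> str:
    """Interchange TSV ``protein_id  point_index  x  y  z`` (3-decimal A)."""
    lines = ["protein_id\tpoint_index\tx\ty\tz"]
    for js in joint_sets:
        for i, (x, y, z) in enumerate(js.points, start=1):
            lines.append(f"{js.protein_id}\t{i}\t{x:.3f}\t{y:.3f}\t{z:.3f}")
    return "\n".join(lines) + "\n"


def read_joints_tsv(text: str) -> list[JointSet]:
    """Inverse of :func:`write_joints_tsv` (coordinates at PDB precision)."""
    df = pd.read_csv(io.StringIO(text), sep="\t")
    out = []
    for pid, grp in df.groupby("protein_id", sort=False):
        grp = grp.sort_values("point_index")
        out.append(JointSet(protein_id=str(pid), points=grp[["x", "y", "z"]].to_numpy()))
    return out
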