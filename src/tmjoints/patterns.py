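"""Distribution and consecutive-pattern statistics over dihedral series.

The analyses here mirror how backbone-dihedral statistics are read off a
Ramachandran plot, lifted to the macroscopic joint level: a 2-D omega/lambda
scatter identifies allowed and disallowed helix arrangements, histograms
summarise each angle type, and consecutive sign (or quadrant) k-mers of the
per-protein angle sequences quantify how helices align and extend. (+,+)
omega dyads and (-,-) lambda dyads both correspond to zig-zag helix
packing/extension. Counts are pooled over a cohort and their sampling
spread is estimated by bootstrap resampling of the window-level
observations (500 replicates by default).

Boundary rules (all measure-zero events, fixed once and tested): an exact
0-degree angle counts as "+" with a logged warning; quadrant edges close on
the side away from zero, so A = (0, 90], B = (90, 180], -A = [-90, 0),
-B = (-180, -90), with 0 itself in A.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .geometry import AngleSeries

logger = logging.getLogger(__name__)

SIGNS = ("+", "-")
QUADRANTS = ("A", "B", "-A", "-B")

#: TM-size groups used for size-dependence analyses.
DEFAULT_TM_GROUPS = ((3, 6), (7, 10), (11, 14))


@dataclass(frozen=True)
class SignSequence:
    """Ordered +/- signature of one protein's omega or lambda angles."""

    protein_id: str
    kind: str
    signs: tuple[str, ...]


@dataclass(frozen=True)
class QuadrantSequence:
    """Ordered A/B/-A/-B labels of one protein's lambda angles."""

    protein_id: str
    labels: tuple[str, ...]


@dataclass
class PatternCounts:
    """Pooled k-mer counts over a cohort, zero-filled over the full alphabet."""

    window: int
    alphabet: str  # "sign" | "quadrant"
    counts: dict[tuple[str, ...], int]
    bootstrap_sd: dict[tuple[str, ...], float] = field(default_factory=dict)
    group_label: str | None = None

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def sign_of(angle_deg: float) -> str:
    """"+" for (0, 180], "-" for (-180, 0); exact 0 counts as "+"."""
    if angle_deg == 0.0:
        logger.warning("angle exactly 0 classified as '+' (boundary rule)")
        return "+"
    return "+" if angle_deg > 0 else "-"


def classify_quadrant(angle_deg: float) -> str:
    """Quadrant label of a lambda angle: A, B, -A or -B."""
    if not -180.0 < angle_deg <= 180.0:
        raise ValueError(f"angle {angle_deg} outside (-180, 180]")
    if angle_deg == 0.0:
        logger.warning("angle exactly 0 classified as 'A' (boundary rule)")
        return "A"
    if 0 < angle_deg <= 90:
        return "A"
    if angle_deg > 90:
        return "B"
    if angle_deg >= -90:
        return "-A"
    return "-B"


def sign_sequence(series: AngleSeries, kind: str) -> SignSequence:
    return SignSequence(
        protein_id=series.protein_id,
        kind=kind,
        signs=tuple(sign_of(a) for a in series.angles(kind)),
    )


def quadrant_sequence(series: AngleSeries) -> QuadrantSequence:
    return QuadrantSequence(
        protein_id=series.protein_id,
        labels=tuple(classify_quadrant(a) for a in series.lam),
    )


def consecutive_patterns(seq, k: int) -> list[tuple[str, ...]]:
    """All overlapping windows of length k, in order; only adjacent angles
    form a pattern (a gapped pair like omega_i with omega_{i+2} never does).
    """
    if k not in (2, 3):
        raise ValueError(f"window length must be 2 or 3, got {k}")
    symbols = seq.signs if isinstance(seq, SignSequence) else seq.labels
    return [tuple(symbols[i : i + k]) for i in range(len(symbols) - k + 1)]


def _alphabet_symbols(alphabet: str) -> tuple[str, ...]:
    if alphabet == "sign":
        return SIGNS
    if alphabet == "quadrant":
        return QUADRANTS
    raise ValueError(f"alphabet must be 'sign' or 'quadrant', got {alphabet!r}")


def count_patterns(
    series_collection: list[AngleSeries],
    kind: str,
    k: int,
    alphabet: str = "sign",
    groups: tuple[tuple[int, int], ...] | None = None,
    bootstrap_reps: int = 0,
    seed: int | None = None,
    resample_proteins: bool = False,
) -> list[PatternCounts]:
    """Pooled k-mer counts of omega or lambda signatures across a cohort.

    ``alphabet='quadrant'`` is only meaningful for lambda angles (the
    4-region partition is defined on the full-circle lambda distribution)
    and is rejected for omega. With ``groups`` (inclusive TM-count bins,
    e.g. ``DEFAULT_TM_GROUPS``) one PatternCounts per bin is returned,
    otherwise a single pooled one. ``bootstrap_reps > 0`` attaches
    bootstrap SDs (see :func:`bootstrap_sd`).
    """
    symbols = _alphabet_symbols(alphabet)
    if alphabet == "quadrant" and kind != "lambda":
        raise ValueError("quadrant patterns are defined for lambda angles only")

    def windows_of(series):
        if alphabet == "sign":
            seq = sign_sequence(series, kind)
        else:
            seq = quadrant_sequence(series)
        return consecutive_patterns(seq, k)

    bins = groups if groups is not None else (None,)
    out = []
    for bin_ in bins:
        if bin_ is None:
            members = series_collection
            label = None
        else:
            lo, hi = bin_
            members = [s for s in series_collection if lo <= s.n_helices <= hi]
            label = f"{lo}-{hi} TM"
        observations = [w for s in members for w in windows_of(s)]
        per_protein = [windows_of(s) for s in members] if resample_proteins else None
        counts = {pat: 0 for pat in product(symbols, repeat=k)}
        counts.update(Counter(observations))
        sd = {}
        if bootstrap_reps > 0 and observations:
            sd = bootstrap_sd(
                observations,
                B=bootstrap_reps,
                seed=seed,
                alphabet=alphabet,
                k=k,
                protein_groups=per_protein,
            )
        out.append(
            PatternCounts(window=k, alphabet=alphabet, counts=counts,
                          bootstrap_sd=sd, group_label=label)
        )
    return out


def bootstrap_sd(
    observations: list[tuple[str, ...]],
    B: int = 500,
    seed: int | None = None,
    alphabet: str = "sign",
    k: int | None = None,
    protein_groups: list[list[tuple[str, ...]]] | None = None,
) -> dict[tuple[str, ...], float]:
    """Bootstrap standard deviation of each pattern count.

    Resamples the window-level observations with replacement to the
    original size B times and re-tallies; the SD of each pattern's count
    over the replicates is returned (zero-count patterns get SD 0).
    ``protein_groups`` switches the resampling unit from individual windows
    to whole proteins.
    """
    if B < 1:
        raise ValueError(f"need B >= 1 bootstrap replicates, got {B}")
    if not observations:
        raise ValueError("no observations to bootstrap")
    if k is None:
        k = len(observations[0])
    patterns = list(product(_alphabet_symbols(alphabet), repeat=k))
    pat_index = {p: i for i, p in enumerate(patterns)}

    rng = np.random.default_rng(seed)
    if protein_groups is not None:
        units = protein_groups
    else:
        units = [[obs] for obs in observations]
    unit_vectors = np.zeros((len(units), len(patterns)), dtype=np.int64)
    for u, unit in enumerate(units):
        for obs in unit:
            unit_vectors[u, pat_index[obs]] += 1

    n_units = len(units)
    tallies = np.empty((B, len(patterns)), dtype=np.int64)
    for b in range(B):
        idx = rng.integers(0, n_units, size=n_units)
        tallies[b] = unit_vectors[idx].sum(axis=0)
    sds = tallies.std(axis=0)
    return {p: float(sds[i]) for p, i in pat_index.items()}


@dataclass
class AngleDistributions:
    """Scatter pairs, histograms and per-position pools of a cohort."""

    scatter: list[tuple[str, int, float, float]]  # (protein_id, i, omega_i, lambda_i)
    omega_hist: tuple[np.ndarray, np.ndarray]  # (counts, bin_edges)
    lambda_hist: tuple[np.ndarray, np.ndarray]
    omega_by_position: dict[int, list[float]]
    lambda_by_position: dict[int, list[float]]
    omega_all: list[float]
    lambda_all: list[float]

    def omega_fraction_in(self, low: float, high: float) -> float:
        """Fraction of all omega angles inside [low, high]."""
        if not self.omega_all:
            raise ValueError("no omega angles")
        arr = np.asarray(self.omega_all)
        return float(np.mean((arr >= low) & (arr <= high)))


def angle_distributions(
    series_collection: list[AngleSeries], bin_width: float = 20.0
) -> AngleDistributions:
    """Distribution summaries of a cohort's omega and lambda angles.

    Scatter pairs join omega_i with lambda_i (the two share three of their
    four joints); the last omega of each protein is unpaired and appears
    only in the marginals. Histogram bins of ``bin_width`` degrees are
    aligned to 0 and cover (-180, 180].
    """
    if not series_collection:
        raise ValueError("empty series collection")
    if bin_width <= 0 or 360.0 % bin_width != 0:
        raise ValueError(f"bin width must divide 360, got {bin_width}")

    scatter = []
    omega_all: list[float] = []
    lambda_all: list[float] = []
    omega_by_pos: dict[int, list[float]] = {}
    lambda_by_pos: dict[int, list[float]] = {}
    for series in series_collection:
        om = series.omega
        lam = series.lam
        omega_all.extend(om)
        lambda_all.extend(lam)
        for i, a in enumerate(om, start=1):
            omega_by_pos.setdefault(i, []).append(a)
        for i, a in enumerate(lam, start=1):
            lambda_by_pos.setdefault(i, []).append(a)
        for i, (o, l) in enumerate(zip(om, lam), start=1):
            scatter.append((series.protein_id, i, o, l))

    edges = np.arange(-180.0, 180.0 + bin_width, bin_width)
    omega_hist = np.histogram(omega_all, bins=edges)
    lambda_hist = np.histogram(lambda_all, bins=edges)
    return AngleDistributions(
        scatter=scatter,
        omega_hist=omega_hist,
        lambda_hist=lambda_hist,
        omega_by_position=omega_by_pos,
        lambda_by_position=lambda_by_pos,
        omega_all=omega_all,
        lambda_all=lambda_all,
    )


def write_pattern_tsv(pattern_counts: list[PatternCounts]) -> str:
    """TSV ``pattern  count  bootstrap_sd  group`` over one or more groups."""
    lines = ["pattern\tcount\tbootstrap_sd\tgroup"]
    for pc in pattern_counts:
        group = pc.group_label or "all"
        for pat in sorted(pc.counts):
            sd = pc.bootstrap_sd.get(pat, float("nan"))
            lines.append(f"{','.join(pat)}\t{pc.counts[pat]}\t{sd:.3f}\t{group}")
    return "\n".join(lines) + "\n"


def write_scatter_tsv(dist: AngleDistributions) -> str:
    lines = ["protein_id\tindex\tomega_i\tlambda_i"]
    for pid, i, o, l in dist.scatter:
        lines.append(f"{pid}\t{i}\t{o:.1f}\t{l:.1f}")
    return "\n".join(lines) + "\n"


def write_histogram_tsv(dist: AngleDistributions) -> str:
    lines = ["bin_low\tbin_high\tcount\tkind"]
    for kind, (counts, edges) in (("omega", dist.omega_hist), ("lambda", dist.lambda_hist)):
        for lo, hi, c in zip(edges[:-1], edges[1:], counts):
            lines.append(f"{lo:.0f}\t{hi:.0f}\t{c}\t{kind}")
    return "\n".join(lines) + "\n"
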