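"""Screen a cohort for mirror-image lambda-sign signatures.

Two proteins with the same helix count whose lambda signatures are exact
elementwise negations of one another trace out macroscopically
mirror-symmetric helix extensions — the joint-level analogue of a pair of
stereoisomers. The lambda signs are the screening criterion because lambda
varies over the full circle while omega is confined near 0, so lambda
dominates the global arrangement. The screen is purely computational;
confirming 3-D symmetry of a candidate pair is left to human review, for
which per-pair angle tables are emitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .geometry import AngleSeries
from .patterns import SignSequence, sign_sequence

_NEGATE = {"+": "-", "-": "+"}


@dataclass(frozen=True)
class SymmetryCandidatePair:
    protein_a: str
    protein_b: str
    n_helices: int
    signature_a: SignSequence
    signature_b: SignSequence


def lambda_signature(series: AngleSeries) -> SignSequence:
    """The ordered sign vector of a protein's lambda angles."""
    if series.n_helices < 3:
        raise ValueError(
            f"{series.protein_id}: lambda signature needs >= 3 helices, "
            f"got {series.n_helices}"
        )
    return sign_sequence(series, "lambda")


def negated(signature: SignSequence) -> tuple[str, ...]:
    return tuple(_NEGATE[s] for s in signature.signs)


def find_symmetric_candidates(
    cohort: list[AngleSeries], mode: str = "negated"
) -> list[SymmetryCandidatePair]:
    """All unordered protein pairs with mirrored lambda signatures.

    Pairs require equal helix counts. The default (and recommended) mode
    demands exact elementwise sign negation; ``mode='palindromic'`` instead
    accepts a signature equal to the reverse of the other's negation, an
    alternative reading kept available but off by default. Output is
    ordered lexicographically by (protein_a, protein_b); each pair appears
    once with protein_a < protein_b.
    """
    if mode not in ("negated", "palindromic"):
        raise ValueError(f"unknown mode {mode!r}")
    if not cohort:
        raise ValueError("empty cohort")
    sigs = {s.protein_id: lambda_signature(s) for s in cohort if s.n_helices >= 3}
    n_of = {s.protein_id: s.n_helices for s in cohort}
    pairs = []
    for a, b in combinations(sorted(sigs), 2):
        if n_of[a] != n_of[b]:
            continue
        target = negated(sigs[a])
        if mode == "palindromic":
            target = target[::-1]
        if sigs[b].signs == target:
            pairs.append(
                SymmetryCandidatePair(
                    protein_a=a,
                    protein_b=b,
                    n_helices=n_of[a],
                    signature_a=sigs[a],
                    signature_b=sigs[b],
                )
            )
    return pairs


def write_pairs_tsv(pairs: list[SymmetryCandidatePair]) -> str:
    """TSV ``protein_a  protein_b  n_helices  signature_a  signature_b``."""
    lines = ["protein_a\tprotein_b\tn_helices\tsignature_a\tsignature_b"]
    for p in pairs:
        sa = "".join(p.signature_a.signs)
        sb = "".join(p.signature_b.signs)
        lines.append(f"{p.protein_a}\t{p.protein_b}\t{p.n_helices}\t{sa}\t{sb}")
    return "\n".join(lines) + "\n"
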