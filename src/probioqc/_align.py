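"""Low-level alignment helpers built on edlib.

edlib reports extended CIGAR strings over the alphabet ``= X I D`` where
``I`` is a base present in the query but not the target and ``D`` the
reverse.  Identity is defined as matched columns over total alignment
columns, the same decision variable as a percent-identity cutoff on a
BLAST hit.
"""

from __future__ import annotations

import re
from typing import NamedTuple

import edlib

_CIGAR_RE = re.compile(r"(\d+)([=XID])")

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)

# IUPAC nucleotide codes accepted in reads and genomes.
IUPAC_NUCLEOTIDES = frozenset("ACGTRYSWKMBDHVN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide sequence (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_nucleotides(seq: str) -> None:
    """Raise ``ValueError`` if *seq* contains non-IUPAC characters."""
    bad = set(seq.upper()) - IUPAC_NUCLEOTIDES
    if bad:
        raise ValueError(
            f"sequence contains non-IUPAC nucleotide characters: {sorted(bad)}"
        )


def cigar_columns(cigar: str) -> tuple[int, int]:
    """Return ``(matches, columns)`` for an extended CIGAR string."""
    matches = 0
    columns = 0
    for n, op in _CIGAR_RE.findall(cigar):
        n = int(n)
        columns += n
        if op == "=":
            matches += n
    return matches, columns


class InfixHit(NamedTuple):
    """Best semi-global placement of a query inside a target."""

    edit_distance: int
    identity: float
    start: int  # 1-based inclusive on target
    end: int  # 1-based inclusive on target
    cigar: str


def align_infix(query: str, target: str, k: int = -1) -> InfixHit | None:
    """Best infix (semi-global) alignment of *query* within *target*.

    Returns ``None`` when no alignment with edit distance <= *k* exists.
    Coordinates are 1-based inclusive on the target.
    """
    res = edlib.align(query, target, mode="HW", task="path", k=k)
    if res["editDistance"] < 0:
        return None
    start0, end0 = res["locations"][0]
    matches, columns = cigar_columns(res["cigar"])
    return InfixHit(
        edit_distance=res["editDistance"],
        identity=matches / columns if columns else 0.0,
        start=start0 + 1,
        end=end0 + 1,
        cigar=res["cigar"],
    )


def infix_distance(query: str, target: str, k: int = -1) -> int:
    """Edit distance of the best infix placement (-1 if above *k*)."""
    return edlib.align(query, target, mode="HW", task="distance", k=k)["editDistance"]


def global_identity(a: str, b: str) -> tuple[float, str]:
    """Global (Needleman-Wunsch) identity between two sequences.

    Works for nucleotide or amino-acid strings; returns
    ``(identity, cigar)`` with identity = matches / alignment columns.
    """
    res = edlib.align(a, b, mode="NW", task="path")
    matches, columns = cigar_columns(res["cigar"])
    return (matches / columns if columns else 1.0, res["cigar"])


def local_identity(query: str, target: str) -> tuple[float, str]:
    """Identity of the best infix placement of *query* in *target*."""
    hit = align_infix(query, target)
    assert hit is not None
    return hit.identity, hit.cigar


def gap_runs(cigar: str) -> list[tuple[int, int, str]]:
    """Extract gap runs from a global CIGAR.

    Returns ``[(position_on_a, length, kind), ...]`` where *kind* is
    ``"deletion_in_a"`` for ``D`` runs (absent from the first sequence)
    and ``"insertion_in_a"`` for ``I`` runs, and *position_on_a* is the
    1-based position on the first sequence immediately left of (for D)
    or at the start of (for I) the gap.
    """
    runs = []
    pos_a = 0
    for n, op in _CIGAR_RE.findall(cigar):
        n = int(n)
        if op in "=X":
            pos_a += n
        elif op == "I":
            runs.append((pos_a + 1, n, "insertion_in_a"))
            pos_a += n
        elif op == "D":
            runs.append((pos_a, n, "deletion_in_a"))
    return runs
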