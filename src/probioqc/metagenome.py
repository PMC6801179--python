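"""Read assignment, ORF-based strain abundance, resistome screen, indel analysis.

Reads are placed on each panel genome by semi-global alignment in both
orientations; the decision variable is percent nucleotide identity with
a >98% cutoff, reads shorter than 80 bp are discarded, and relative
strain abundance is computed from counts of assigned reads whose
alignment midpoint falls inside an annotated ORF.  Ties between
near-identical strains are split fractionally and resolved downstream
by diagnostic-SNP typing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from ._align import (
    align_infix,
    global_identity,
    infix_distance,
    local_identity,
    revcomp,
    validate_nucleotides,
)
from .synthetic_data import UNASSIGNED, GenomePanel, ReadSet

DEFAULT_MIN_IDENTITY = 0.98
DEFAULT_MIN_LENGTH = 80
# substitute for E-value screening: the alignment must span most of the read
MIN_SPAN_FRACTION = 0.9


@dataclass
class Assignment:
    """Placement of one read on the panel (or a reason it has none)."""

    read_id: str
    strain_id: str  # UNASSIGNED when no hit passes the thresholds
    identity: float
    start: int = 0  # 1-based inclusive on the assigned genome
    end: int = 0
    orientation: str = "+"
    in_orf: bool = False
    tie: bool = False
    tied_strains: tuple[str, ...] = ()
    reason: str = ""  # "", "short", "low_identity", "short_span"


@dataclass
class AbundanceProfile:
    """Per-strain ORF-hit counts and the derived relative abundances."""

    orf_hit_count: dict[str, float]
    total_hit_count: dict[str, float]
    relative_abundance: dict[str, float] | None
    n_reads: int
    n_assigned: int
    n_unassigned: int
    n_discarded_short: int
    n_ambiguous: int


@dataclass
class ARGHit:
    query_id: str
    arg_id: str
    identity: float
    aligned_length: int


@dataclass
class IndelReport:
    gaps: list[tuple[int, int, str]] = field(default_factory=list)
    length_bp: int = 0
    in_frame: bool = True
    aa_difference: int | None = 0
    multi_indel: bool = False


def _orf_trees(panel: GenomePanel) -> dict[str, IntervalTree]:
    trees = {}
    for sid, intervals in panel.orfs.items():
        trees[sid] = IntervalTree.from_tuples(
            (start, end + 1) for start, end, _ in intervals
        )
    return trees


def _exact_hits(read: str, panel: GenomePanel) -> list[tuple[str, int, str]]:
    """(strain, 0-based position, orientation) for exact substring matches."""
    hits = []
    rc = revcomp(read)
    for sid in panel.strain_ids():
        genome = panel.sequences[sid]
        pos = genome.find(read)
        if pos >= 0:
            hits.append((sid, pos, "+"))
            continue
        pos = genome.find(rc)
        if pos >= 0:
            hits.append((sid, pos, "-"))
    return hits


def assign_read(
    read: str,
    panel: GenomePanel,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_length: int = DEFAULT_MIN_LENGTH,
    read_id: str = "read",
    _trees: dict[str, IntervalTree] | None = None,
) -> Assignment:
    """Best-identity placement of one read across all panel genomes.

    Both orientations are scored; identity is matched columns over
    alignment columns of the best semi-global placement.  The read is
    left UNASSIGNED when shorter than *min_length*, when the best
    identity is below *min_identity*, or when the alignment spans less
    than 90% of the read.  When several strains share the best score
    the tie flag is set and the lexicographically ordered tied strains
    recorded (the near-identical pair case).
    """
    read = read.upper()
    validate_nucleotides(read)
    if len(read) < min_length:
        return Assignment(read_id, UNASSIGNED, 0.0, reason="short")

    trees = _trees if _trees is not None else _orf_trees(panel)

    exact = _exact_hits(read, panel)
    if exact:
        winners = []
        for sid, pos0, orient in exact:
            winners.append((sid, pos0 + 1, pos0 + len(read), orient, 1.0))
    else:
        # edlib per strain/orientation; cap the search at 10% errors so
        # clearly foreign reads fail fast but sub-threshold identities
        # (e.g. 0.97) are still reported.
        k = max(4, len(read) // 10)
        rc = revcomp(read)
        best: dict[str, tuple[int, str]] = {}
        best_d = None
        for sid in panel.strain_ids():
            genome = panel.sequences[sid]
            for orient, seq in (("+", read), ("-", rc)):
                d = infix_distance(seq, genome, k=k)
                if d < 0:
                    continue
                if sid not in best or d < best[sid][0]:
                    best[sid] = (d, orient)
            if sid in best and (best_d is None or best[sid][0] < best_d):
                best_d = best[sid][0]
        if best_d is None:
            return Assignment(read_id, UNASSIGNED, 0.0, reason="low_identity")
        winners = []
        for sid, (d, orient) in sorted(best.items()):
            if d != best_d:
                continue
            seq = read if orient == "+" else rc
            hit = align_infix(seq, panel.sequences[sid])
            assert hit is not None
            winners.append((sid, hit.start, hit.end, orient, hit.identity))

    # deterministic primary winner: panel order, forward before reverse
    order = {sid: i for i, sid in enumerate(panel.strain_ids())}
    winners.sort(key=lambda w: (order[w[0]], w[3]))
    sid, start, end, orient, identity = winners[0]
    span = end - start + 1
    if identity < min_identity:
        return Assignment(read_id, UNASSIGNED, identity, reason="low_identity")
    if span < MIN_SPAN_FRACTION * len(read):
        return Assignment(read_id, UNASSIGNED, identity, reason="short_span")
    mid = (start + end) // 2
    return Assignment(
        read_id=read_id,
        strain_id=sid,
        identity=identity,
        start=start,
        end=end,
        orientation=orient,
        in_orf=bool(trees[sid][mid]),
        tie=len(winners) > 1,
        tied_strains=tuple(w[0] for w in winners),
    )


def assign_reads(
    reads: ReadSet,
    panel: GenomePanel,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> list[Assignment]:
    trees = _orf_trees(panel)
    return [
        assign_read(seq, panel, min_identity, min_length, read_id=rid, _trees=trees)
        for rid, seq in zip(reads.ids, reads.sequences)
    ]


def profile_reads(
    reads: ReadSet,
    panel: GenomePanel,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_length: int = DEFAULT_MIN_LENGTH,
    assignments: list[Assignment] | None = None,
    count_mode: str = "reads_in_orfs",
) -> tuple[AbundanceProfile, list[Assignment]]:
    """Strain relative abundance from ORF-hit counts.

    A read contributes to a strain when its alignment midpoint falls
    inside an annotated ORF of that strain; ambiguous (tied) reads are
    split equally among the tied strains so the pair total is
    preserved.  ``count_mode="distinct_orfs"`` instead counts the
    number of distinct ORFs hit per strain (alternative reading of an
    ORF-count abundance; not the default).
    """
    if not panel.orfs:
        raise ValueError("panel has no ORF annotations")
    if count_mode not in ("reads_in_orfs", "distinct_orfs"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    trees = _orf_trees(panel)
    if assignments is None:
        assignments = assign_reads(reads, panel, min_identity, min_length)

    ids = panel.strain_ids()
    orf_hits = {sid: 0.0 for sid in ids}
    total_hits = {sid: 0.0 for sid in ids}
    distinct: dict[str, set] = {sid: set() for sid in ids}
    n_short = n_unassigned = n_ambiguous = 0
    for asg, seq in zip(assignments, reads.sequences):
        if asg.strain_id == UNASSIGNED:
            if asg.reason == "short":
                n_short += 1
            else:
                n_unassigned += 1
            continue
        members = asg.tied_strains if asg.tie else (asg.strain_id,)
        if asg.tie:
            n_ambiguous += 1
        weight = 1.0 / len(members)
        for sid in members:
            total_hits[sid] += weight
            # midpoint on this strain's own coordinates
            if sid == asg.strain_id:
                mid = (asg.start + asg.end) // 2
            else:
                query = seq.upper() if asg.orientation == "+" else revcomp(seq.upper())
                hit = align_infix(query, panel.sequences[sid])
                if hit is None:
                    continue
                mid = (hit.start + hit.end) // 2
            hits = trees[sid][mid]
            if hits:
                orf_hits[sid] += weight
                for iv in hits:
                    distinct[sid].add((iv.begin, iv.end))

    if count_mode == "distinct_orfs":
        counts = {sid: float(len(distinct[sid])) for sid in ids}
    else:
        counts = orf_hits
    total = sum(counts.values())
    abundance = {sid: counts[sid] / total for sid in ids} if total > 0 else None
    n_assigned = len(reads) - n_short - n_unassigned
    profile = AbundanceProfile(
        orf_hit_count=orf_hits,
        total_hit_count=total_hits,
        relative_abundance=abundance,
        n_reads=len(reads),
        n_assigned=n_assigned,
        n_unassigned=n_unassigned,
        n_discarded_short=n_short,
        n_ambiguous=n_ambiguous,
    )
    return profile, assignments


def expected_read_count(
    strain_cfu: float, total_cfu: float, total_reads: float
) -> tuple[float, float]:
    """Theoretical read coverage of one strain in a blend.

    Returns ``(expected_reads, blend_fraction_percent)`` where the
    fraction is strain CFU over total CFU: a strain at 1e9 CFU in a
    450e9 CFU blend sequenced to 6e6 reads is expected in ~13333 reads
    (0.22% of the blend).
    """
    if total_cfu <= 0:
        raise ValueError("total_cfu must be positive")
    if strain_cfu > total_cfu:
        raise ValueError("strain_cfu cannot exceed total_cfu")
    fraction = strain_cfu / total_cfu
    return fraction * total_reads, fraction * 100.0


def screen_resistome(
    proteins: list[tuple[str, str]],
    arg_db: list[tuple[str, str]],
    min_aa_identity: float = 0.80,
    mode: str = "global",
) -> list[ARGHit]:
    """Screen amino-acid sequences against a reference ARG panel.

    Identity is matched columns over alignment columns (global by
    default; ``mode="local"`` uses the best infix placement of the
    query).  Hits with identity above *min_aa_identity* are returned
    sorted by decreasing identity.
    """
    if not arg_db:
        warnings.warn("empty ARG reference database; no hits possible")
        return []
    if mode not in ("global", "local"):
        raise ValueError(f"unknown mode {mode!r}")
    hits = []
    for qid, qseq in proteins:
        for aid, aseq in arg_db:
            if mode == "global":
                ident, cigar = global_identity(qseq, aseq)
            else:
                ident, cigar = local_identity(qseq, aseq)
            # strict > per the identity-cutoff convention; a zero
            # threshold degenerates to reporting every pair
            if ident > min_aa_identity or min_aa_identity <= 0:
                from ._align import cigar_columns

                _, columns = cigar_columns(cigar)
                hits.append(ARGHit(qid, aid, ident, columns))
    hits.sort(key=lambda h: (-h.identity, h.query_id, h.arg_id))
    return hits


def compare_indel_alleles(gene_a: str, gene_b: str) -> IndelReport:
    """Locate the indel separating two alleles of a gene.

    The alleles are aligned globally with affine gap penalties, so a
    contiguous indel is reported as one gap rather than scattered
    unit-cost gaps.  Gap positions are on *gene_a*.  With a single gap,
    ``length_bp`` is its length, ``in_frame`` holds when it is a
    multiple of 3, and the amino-acid difference is length/3
    (undefined for frameshifts).
    """
    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=-2,
        open_gap_score=-10,
        extend_gap_score=-0.5,
    )
    aln = aligner.align(gene_a, gene_b)[0]
    gaps = _gaps_from_blocks(aln.aligned)
    if not gaps:
        return IndelReport(gaps=[], length_bp=0, in_frame=True, aa_difference=0)
    length = gaps[0][1] if len(gaps) == 1 else sum(g[1] for g in gaps)
    in_frame = length % 3 == 0
    return IndelReport(
        gaps=gaps,
        length_bp=length,
        in_frame=in_frame,
        aa_difference=length // 3 if in_frame else None,
        multi_indel=len(gaps) > 1,
    )


def _gaps_from_blocks(aligned) -> list[tuple[int, int, str]]:
    """Gap runs from PairwiseAligner aligned-block coordinates.

    Returns ``(position_on_a, length, kind)`` tuples, 1-based, where
    ``deletion_in_a`` means the bases are present in *gene_b* only.
    """
    blocks_a, blocks_b = aligned
    gaps = []
    for i in range(1, len(blocks_a)):
        gap_a = int(blocks_a[i][0] - blocks_a[i - 1][1])
        gap_b = int(blocks_b[i][0] - blocks_b[i - 1][1])
        if gap_a > 0:
            gaps.append((int(blocks_a[i - 1][1]) + 1, gap_a, "insertion_in_a"))
        if gap_b > 0:
            gaps.append((int(blocks_a[i - 1][1]), gap_b, "deletion_in_a"))
    return gaps
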