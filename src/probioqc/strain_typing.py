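"""Diagnostic-SNP deconvolution of a near-identical strain pair.

Two strains that differ only at a handful of diagnostic positions (and
one small indel) cannot be separated by whole-read identity: almost
every read from either strain ties.  Reads that do cover a diagnostic
position carry a discriminating allele, and the ratio of
strain-specific allele counts estimates the internal mixing ratio of
the pair.

Two aggregation methods are provided.  ``per_position_mean`` computes
the strain-A fraction at each informative position and averages the
per-position percentages; ``pooled`` sums strain-specific read counts
across positions first and takes a single ratio.  On the same counts
the two can differ by a few tenths of a percentage point; both are
exposed and the default is ``per_position_mean``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._align import align_infix, revcomp
from .metagenome import Assignment
from .synthetic_data import UNASSIGNED, DiagnosticLocus, GenomePanel, ReadSet

#: bases required on each side of a diagnostic position before an
#: allele (in particular a deletion) is called from a read
MIN_FLANK = 5

#: half-width of the haplotype window used for allele matching
_WINDOW = 7


@dataclass
class SNPTableRow:
    snp_id: str
    position: int  # 1-based on the reference member of the pair
    allele: str  # a base, or "del" for a single-base deletion
    strains: frozenset[str]


@dataclass
class DiagnosticSNPTable:
    """Rows of (snp_id, position, allele, carrier strains)."""

    rows: list[SNPTableRow]

    @classmethod
    def from_panel(cls, panel: GenomePanel) -> "DiagnosticSNPTable":
        rows = [
            SNPTableRow(loc.locus_id, loc.position, allele, strains)
            for loc in panel.diagnostic_loci
            for allele, strains in loc.alleles.items()
        ]
        return cls(rows)

    def positions(self) -> dict[str, int]:
        return {r.snp_id: r.position for r in self.rows}

    def informative_rows(self, pair: tuple[str, str]) -> list[SNPTableRow]:
        """Rows whose allele is specific to exactly one pair member."""
        a, b = pair
        out = []
        for r in self.rows:
            in_a, in_b = a in r.strains, b in r.strains
            if in_a != in_b:
                out.append(r)
        return out

    def informative_snp_ids(self, pair: tuple[str, str]) -> list[str]:
        seen: list[str] = []
        for r in self.informative_rows(pair):
            if r.snp_id not in seen:
                seen.append(r.snp_id)
        return seen


@dataclass
class AlleleTally:
    """Read counts per (snp_id, allele), with an explicit other-bucket."""

    counts: dict[tuple[str, str], float] = field(default_factory=dict)
    other: dict[str, int] = field(default_factory=dict)
    n_informative_reads: int = 0

    def add(self, snp_id: str, allele: str, n: float = 1) -> None:
        key = (snp_id, allele)
        self.counts[key] = self.counts.get(key, 0) + n

    def position_total(self, snp_id: str) -> float:
        return sum(v for (s, _), v in self.counts.items() if s == snp_id)


def _haplotype_windows(
    panel: GenomePanel, locus: DiagnosticLocus, ref_id: str
) -> dict[str, str]:
    """Short reference-context sequence for each allele at a locus."""
    ref = panel.sequences[ref_id]
    p0 = locus.position - 1
    left = ref[max(0, p0 - _WINDOW) : p0]
    right = ref[p0 + 1 : p0 + 1 + _WINDOW]
    windows = {}
    for allele in locus.alleles:
        if allele == "del":
            windows[allele] = left + right
        else:
            windows[allele] = left + allele + right
    return windows


def tally_alleles(
    reads: ReadSet,
    assignments: list[Assignment],
    snp_table: DiagnosticSNPTable,
    panel: GenomePanel,
    pair: tuple[str, str] | None = None,
) -> AlleleTally:
    """Count observed alleles at each diagnostic position.

    Reads assigned to either pair member (ties included) are placed on
    the reference member's coordinates; for every diagnostic position
    covered with at least ``MIN_FLANK`` bases of context on both sides,
    the read segment is matched against the haplotype window of each
    listed allele (edit distance; best must be unique and <= 1).
    Segments matching no listed allele are counted in the other-bucket,
    never silently dropped.
    """
    pair = pair or panel.pair
    if pair is None:
        raise ValueError("no near-identical pair specified")
    ref_id = pair[0]
    ref_genome = panel.sequences[ref_id]
    loci = {loc.locus_id: loc for loc in panel.diagnostic_loci}
    table_positions = snp_table.positions()
    windows = {
        snp_id: _haplotype_windows(panel, loci[snp_id], ref_id)
        for snp_id in table_positions
        if snp_id in loci
    }

    tally = AlleleTally()
    pair_set = set(pair)
    for asg, seq in zip(assignments, reads.sequences):
        if asg.strain_id == UNASSIGNED:
            continue
        members = set(asg.tied_strains) if asg.tie else {asg.strain_id}
        if not members & pair_set:
            continue
        oriented = seq.upper() if asg.orientation == "+" else revcomp(seq.upper())
        # span on the reference member's coordinates
        if asg.strain_id == ref_id:
            start, end = asg.start, asg.end
        else:
            hit = align_infix(oriented, ref_genome)
            if hit is None:
                continue
            start, end = hit.start, hit.end
        informative = False
        for snp_id, pos in table_positions.items():
            if snp_id not in windows:
                continue
            if not (start + MIN_FLANK <= pos <= end - MIN_FLANK):
                continue
            allele = _call_allele(oriented, windows[snp_id])
            if allele is None:
                tally.other[snp_id] = tally.other.get(snp_id, 0) + 1
            else:
                tally.add(snp_id, allele)
            informative = True
        if informative:
            tally.n_informative_reads += 1
    return tally


def _call_allele(read: str, allele_windows: dict[str, str]) -> str | None:
    """Match haplotype windows inside the read; best must be unique and near-exact."""
    best_allele, best_d, second = None, None, None
    for allele, window in allele_windows.items():
        hit = align_infix(window, read)
        d = hit.edit_distance if hit is not None else len(window)
        if best_d is None or d < best_d:
            best_allele, second, best_d = allele, best_d, d
        elif second is None or d < second:
            second = d
    if best_d is None or best_d > 1:
        return None
    if second is not None and second == best_d:
        return None  # ambiguous
    return best_allele


def strain_percentages(
    tally: AlleleTally,
    snp_table: DiagnosticSNPTable,
    pair: tuple[str, str],
    method: str = "per_position_mean",
) -> dict:
    """Pair mixing percentages from strain-specific allele counts.

    Percentage of strain A = reads specific for A x 100 / (reads
    specific for A + reads specific for B), either per informative
    position and then averaged (``per_position_mean``) or on counts
    pooled across positions (``pooled``).  Alleles shared by both pair
    members are uninformative and excluded.
    """
    if method not in ("per_position_mean", "pooled"):
        raise ValueError(f"unknown method {method!r}")
    a, b = pair
    per_position: dict[str, tuple[float, float]] = {}
    for row in snp_table.informative_rows(pair):
        count = tally.counts.get((row.snp_id, row.allele), 0)
        ca, cb = per_position.get(row.snp_id, (0.0, 0.0))
        if a in row.strains:
            ca += count
        else:
            cb += count
        per_position[row.snp_id] = (ca, cb)
    # drop positions with no informative reads
    per_position = {k: v for k, v in per_position.items() if v[0] + v[1] > 0}
    if not per_position:
        raise ValueError("no informative reads at any diagnostic position")

    if method == "per_position_mean":
        ratios = [ca / (ca + cb) for ca, cb in per_position.values()]
        pct_a = 100.0 * sum(ratios) / len(ratios)
    else:
        tot_a = sum(ca for ca, _ in per_position.values())
        tot_b = sum(cb for _, cb in per_position.values())
        pct_a = 100.0 * tot_a / (tot_a + tot_b)
    return {
        "percentages": {a: pct_a, b: 100.0 - pct_a},
        "method": method,
        "n_positions": len(per_position),
        "n_informative_reads": tally.n_informative_reads,
        "per_position_counts": {k: {a: v[0], b: v[1]} for k, v in per_position.items()},
    }


def apportion_pair(
    abundance: dict[str, float],
    pair: tuple[str, str],
    percentages: dict[str, float],
) -> dict[str, float]:
    """Re-split the pair's combined abundance by the SNP-based ratio.

    Whole-read assignment preserves the pair total (ties are split
    50/50) but not the internal ratio; this replaces the two members'
    abundances with the pair total apportioned by *percentages*.
    """
    a, b = pair
    total = abundance[a] + abundance[b]
    out = dict(abundance)
    out[a] = total * percentages[a] / 100.0
    out[b] = total * percentages[b] / 100.0
    return out
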