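"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate, at desk scale, the data types produced when a
multi-strain probiotic product is characterised end-to-end: shotgun
reads from an 8-strain blend dominated by *Streptococcus thermophilus*,
a near-identical *Bifidobacterium animalis* subsp. *lactis* strain pair
that differs only at diagnostic SNP loci plus one 54-bp in-frame indel,
SYTO24/PI cytometry event tables with counting beads, a cFSE-stained
suspension whose urease-positive subpopulation shifts on urea exposure,
linear OD420 kinetics from an ONPG assay, Ct-vs-log10(cells) qPCR
calibration data, and a label-free proteomics intensity matrix with a
small fraction of lot-differential proteins.

Every generator is deterministic given its seed and attaches its truth
(strain of origin, population label, true slope, true differential set)
to the returned object so downstream recovery tests are self-contained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._align import validate_nucleotides

UNASSIGNED = "UNASSIGNED"

# Strain roster mimicking a commercial 8-strain blend: one dominant
# Streptococcus, a near-identical Bifidobacterium pair, four
# lactobacilli and one B. breve.
DEFAULT_STRAINS: tuple[tuple[str, str], ...] = (
    ("S_thermophilus_BT01", "Streptococcus thermophilus"),
    ("B_lactis_BI04", "Bifidobacterium animalis subsp. lactis"),
    ("B_lactis_BL03", "Bifidobacterium animalis subsp. lactis"),
    ("L_paracasei_BP07", "Lacticaseibacillus paracasei"),
    ("L_acidophilus_BA05", "Lactobacillus acidophilus"),
    ("L_plantarum_BP06", "Lactiplantibacillus plantarum"),
    ("L_helveticus_BD08", "Lactobacillus helveticus"),
    ("B_breve_BB02", "Bifidobacterium breve"),
)

DEFAULT_PAIR = ("B_lactis_BI04", "B_lactis_BL03")

# Blend composition used as the default simulation truth (fractions of
# reads; dominant species ~63%, the near-identical pair at a ~73:27
# internal ratio).  Normalised to sum exactly to 1.
_RAW_ABUNDANCE = np.array([63.4, 12.7, 4.55, 9.9, 7.2, 1.7, 0.4, 0.2])
DEFAULT_ABUNDANCE: tuple[float, ...] = tuple(_RAW_ABUNDANCE / _RAW_ABUNDANCE.sum())


# --------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------


@dataclass(frozen=True)
class StrainInfo:
    strain_id: str
    species: str
    circular: bool = False


@dataclass(frozen=True)
class DiagnosticLocus:
    """One diagnostic position: allele symbol -> strains carrying it.

    *position* is 1-based on the genome of the reference member of the
    near-identical pair.  The allele symbol ``"del"`` denotes a
    single-base deletion relative to that reference.
    """

    locus_id: str
    position: int
    alleles: dict[str, frozenset[str]]


@dataclass(frozen=True)
class IndelInfo:
    strain_id: str  # strain carrying the deletion
    position: int  # 1-based first deleted base on the reference member
    length_bp: int
    in_frame: bool


@dataclass
class GenomePanel:
    """Reference panel: strain genomes, ORF intervals, diagnostic loci."""

    strains: list[StrainInfo]
    sequences: dict[str, str]
    orfs: dict[str, list[tuple[int, int, str]]]  # 1-based inclusive
    diagnostic_loci: list[DiagnosticLocus] = field(default_factory=list)
    indels: list[IndelInfo] = field(default_factory=list)
    pair: tuple[str, str] | None = None
    seed: int | None = None

    def strain_ids(self) -> list[str]:
        return [s.strain_id for s in self.strains]

    def validate(self) -> None:
        for sid, intervals in self.orfs.items():
            n = len(self.sequences[sid])
            for start, end, strand in intervals:
                if not (1 <= start <= end <= n):
                    raise ValueError(f"ORF {start}-{end} outside genome {sid} (len {n})")
                if strand not in "+-":
                    raise ValueError(f"bad strand {strand!r}")
        for locus in self.diagnostic_loci:
            if len(locus.alleles) != len(set(locus.alleles)):
                raise ValueError(f"duplicate alleles at locus {locus.locus_id}")
        for indel in self.indels:
            if indel.in_frame != (indel.length_bp % 3 == 0):
                raise ValueError("in_frame flag inconsistent with indel length")


@dataclass
class ReadSet:
    """Shotgun reads plus optional per-read truth labels."""

    ids: list[str]
    sequences: list[str]
    truth_strain: list[str] | None = None
    truth_position: list[int] | None = None  # 1-based start on source genome
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.ids)

    def validate(self, panel: GenomePanel | None = None) -> None:
        if any(len(s) == 0 for s in self.sequences):
            raise ValueError("empty read sequence")
        if panel is not None and self.truth_strain is not None:
            known = set(panel.strain_ids())
            missing = set(self.truth_strain) - known
            if missing:
                raise ValueError(f"truth labels reference unknown strains: {missing}")


@dataclass
class KineticSeries:
    """One OD420 kinetic trace; readings in mOD, time in seconds."""

    time_s: np.ndarray
    od420_mod: np.ndarray
    replicate_id: str = "r1"
    true_slope_mod_per_min: float | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.od420_mod = np.asarray(self.od420_mod, dtype=float)
        if len(self.time_s) != len(self.od420_mod):
            raise ValueError("time and OD vectors differ in length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time points must be strictly increasing")


# --------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------


@dataclass
class GenomeConfig:
    n_strains: int = 8
    genome_length: int = 20_000
    orf_length: int = 900  # multiple of 3; ORFs tile >50% of each genome
    orf_gap: int = 300
    pair: tuple[str, str] = DEFAULT_PAIR
    n_diagnostic_snps: int = 4
    indel_length: int = 54
    indel_in_frame: bool = True


@dataclass
class ReadConfig:
    n_reads: int = 50_000
    read_length: int = 150
    substitution_error_rate: float = 0.001
    abundance: tuple[float, ...] = DEFAULT_ABUNDANCE


@dataclass
class PopulationModel:
    """Log10-space cluster for one cytometry subpopulation."""

    fl1_mean: float
    fl3_mean: float
    sd: float = 0.15


@dataclass
class CytometryConfig:
    n_events: int = 20_000
    # live: SYTO24-bright/PI-dim; damaged: both; dead: SYTO24-dim/PI-bright.
    fractions: tuple[float, float, float] = (0.82, 0.09, 0.09)
    live: PopulationModel = field(default_factory=lambda: PopulationModel(4.5, 1.5))
    damaged: PopulationModel = field(default_factory=lambda: PopulationModel(4.5, 3.5))
    dead: PopulationModel = field(default_factory=lambda: PopulationModel(2.0, 3.5))
    fsc_mean_log10: float = 4.3
    fsc_sd: float = 0.15
    cell_fl2_mean_log10: float = 1.0
    bead_count: int = 5_000
    bead_fl2_mean_log10: float = 5.0
    bead_sd: float = 0.1


@dataclass
class CfseConfig:
    n_events: int = 20_000
    base_mean_log10: float = 4.0
    sd: float = 0.05
    urease_positive_fraction: float = 0.521
    shift_percent: float = 60.0


@dataclass
class OdConfig:
    n_points: int = 60
    interval_s: float = 30.0
    slope_mod_per_min: float = 8.8
    intercept_mod: float = 50.0
    noise_sd_mod: float = 0.5


@dataclass
class LfqConfig:
    n_proteins_per_strain: int = 207
    n_replicates: int = 3
    base_log10_range: tuple[float, float] = (5.0, 10.0)
    replicate_sd: float = 0.05
    fraction_differential: float = 0.032
    effect_size_log10: float = 1.2
    missing_rate: float = 0.01


@dataclass
class QpcrConfig:
    slope: float = -3.32  # Ct per log10 cells; ~100% amplification efficiency
    intercept: float = 38.0
    noise_sd: float = 0.2
    n_replicates: int = 3


@dataclass
class SimulationConfig:
    """All knobs for the synthetic study, with the blend conditions as defaults."""

    seed: int = 0
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    reads: ReadConfig = field(default_factory=ReadConfig)
    cytometry: CytometryConfig = field(default_factory=CytometryConfig)
    cfse: CfseConfig = field(default_factory=CfseConfig)
    od: OdConfig = field(default_factory=OdConfig)
    lfq: LfqConfig = field(default_factory=LfqConfig)
    qpcr: QpcrConfig = field(default_factory=QpcrConfig)

    def __post_init__(self) -> None:
        ab = np.asarray(self.reads.abundance, dtype=float)
        if abs(ab.sum() - 1.0) > 1e-9:
            raise ValueError("abundance fractions must sum to 1 within 1e-9")
        if np.any(ab < 0):
            raise ValueError("abundance fractions must be non-negative")
        for rate in (
            self.reads.substitution_error_rate,
            self.lfq.fraction_differential,
            self.lfq.missing_rate,
            self.cfse.urease_positive_fraction,
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {rate} outside [0, 1]")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


# --------------------------------------------------------------------
# Genome and read generation
# --------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _tile_orfs(length: int, orf_len: int, gap: int) -> list[tuple[int, int, str]]:
    orfs = []
    start = 1
    strand = "+"
    while start + orf_len - 1 <= length:
        orfs.append((start, start + orf_len - 1, strand))
        strand = "-" if strand == "+" else "+"
        start += orf_len + gap
    return orfs


def make_toy_genomes(config: SimulationConfig) -> GenomePanel:
    """Generate the strain panel, including the near-identical pair.

    All strains receive independent random genomes except the
    designated pair: the second member is a copy of the first with one
    substitution per diagnostic locus and one in-frame deletion inside
    an ORF.  ORFs tile >50% of each genome on alternating strands.
    """
    g = config.genome
    if g.n_strains < 2:
        raise ValueError("at least 2 strains are required")
    if g.indel_in_frame and g.indel_length % 3 != 0:
        raise ValueError("in-frame indel length must be a multiple of 3")
    if g.n_strains > len(DEFAULT_STRAINS):
        names = list(DEFAULT_STRAINS) + [
            (f"strain_{i:02d}", f"species_{i:02d}")
            for i in range(len(DEFAULT_STRAINS), g.n_strains)
        ]
    else:
        names = list(DEFAULT_STRAINS)[: g.n_strains]
    ids = [n[0] for n in names]
    ref_id, alt_id = g.pair
    if ref_id not in ids or alt_id not in ids:
        raise ValueError(f"pair {g.pair} not among strains {ids}")

    rng = np.random.default_rng(config.seed)
    sequences: dict[str, str] = {}
    orfs: dict[str, list[tuple[int, int, str]]] = {}
    for sid in ids:
        if sid == alt_id:
            continue  # derived from the reference member below
        seq = "".join(rng.choice(_BASES, size=g.genome_length))
        sequences[sid] = seq
        orfs[sid] = _tile_orfs(g.genome_length, g.orf_length, g.orf_gap)

    ref_seq = sequences[ref_id]
    period = g.orf_length + g.orf_gap

    def in_orf(pos: int) -> bool:
        return (pos - 1) % period < g.orf_length

    # Diagnostic SNP positions: spread through the genome, inside ORFs,
    # clear of the indel site and of each other.
    indel_pos = _pick_indel_position(g)
    snp_positions: list[int] = []
    step = g.genome_length // (g.n_diagnostic_snps + 1)
    pos = step
    while len(snp_positions) < g.n_diagnostic_snps:
        p = pos
        while not in_orf(p) or abs(p - indel_pos) < g.indel_length + 20:
            p += 7
        snp_positions.append(p)
        pos += step
    snp_positions.sort()

    alt_chars = list(ref_seq)
    loci: list[DiagnosticLocus] = []
    others = frozenset(ids) - {ref_id, alt_id}
    for i, p in enumerate(snp_positions, start=1):
        ref_base = ref_seq[p - 1]
        alt_base = _BASES[(np.flatnonzero(_BASES == ref_base)[0] + 1) % 4]
        alt_chars[p - 1] = alt_base
        loci.append(
            DiagnosticLocus(
                locus_id=f"SNP{i}",
                position=p,
                alleles={ref_base: frozenset({ref_id}), str(alt_base): frozenset({alt_id})},
            )
        )
    # One uninformative locus shared by the whole panel, tallied but
    # excluded from percentage computation downstream.
    shared_pos = snp_positions[0] + 40
    loci.append(
        DiagnosticLocus(
            locus_id="SNP_shared",
            position=shared_pos,
            alleles={ref_seq[shared_pos - 1]: frozenset({ref_id, alt_id}) | others},
        )
    )

    # In-frame deletion in the second pair member, inside an ORF.
    del0 = indel_pos - 1
    alt_seq = "".join(alt_chars[:del0] + alt_chars[del0 + g.indel_length :])
    sequences[alt_id] = alt_seq
    orfs[alt_id] = _shift_orfs(orfs[ref_id], indel_pos, g.indel_length)

    panel = GenomePanel(
        strains=[StrainInfo(sid, sp) for sid, sp in names],
        sequences=sequences,
        orfs=orfs,
        diagnostic_loci=loci,
        indels=[IndelInfo(alt_id, indel_pos, g.indel_length, g.indel_length % 3 == 0)],
        pair=(ref_id, alt_id),
        seed=config.seed,
    )
    panel.validate()
    return panel


def _pick_indel_position(g: GenomeConfig) -> int:
    """First position of the deleted block, wholly inside one ORF."""
    period = g.orf_length + g.orf_gap
    # middle of the ORF just left of the genome midpoint
    block = (g.genome_length // 2) // period
    start = block * period + 1  # ORF start
    pos = start + (g.orf_length - g.indel_length) // 2
    pos -= (pos - start) % 3  # keep the deletion codon-aligned
    return pos


def _shift_orfs(
    orfs: list[tuple[int, int, str]], del_pos: int, del_len: int
) -> list[tuple[int, int, str]]:
    del_end = del_pos + del_len - 1
    out = []
    for start, end, strand in orfs:
        if end < del_pos:
            out.append((start, end, strand))
        elif start > del_end:
            out.append((start - del_len, end - del_len, strand))
        else:  # ORF containing the deletion shrinks
            out.append((start, end - del_len, strand))
    return out


def simulate_reads(panel: GenomePanel, config: SimulationConfig) -> ReadSet:
    """Draw single-end reads from the panel at the configured blend.

    Each read originates from a strain with probability equal to its
    abundance fraction, starts uniformly along the genome, and receives
    independent substitution errors at the configured rate.
    """
    rc = config.reads
    ids = panel.strain_ids()
    ab = np.asarray(rc.abundance, dtype=float)
    if len(ab) != len(ids):
        raise ValueError(
            f"abundance vector length {len(ab)} != number of strains {len(ids)}"
        )
    for sid in ids:
        if rc.read_length > len(panel.sequences[sid]):
            raise ValueError(f"read length exceeds genome length of {sid}")

    rng = np.random.default_rng(config.seed)
    strain_idx = rng.choice(len(ids), size=rc.n_reads, p=ab)
    read_ids, seqs, truth_s, truth_p = [], [], [], []
    base_to_int = {b: i for i, b in enumerate("ACGT")}
    for i in range(rc.n_reads):
        sid = ids[strain_idx[i]]
        genome = panel.sequences[sid]
        start0 = int(rng.integers(0, len(genome) - rc.read_length + 1))
        read = genome[start0 : start0 + rc.read_length]
        if rc.substitution_error_rate > 0:
            n_err = rng.binomial(rc.read_length, rc.substitution_error_rate)
            if n_err:
                positions = rng.choice(rc.read_length, size=n_err, replace=False)
                chars = list(read)
                for p in positions:
                    shift = int(rng.integers(1, 4))
                    chars[p] = "ACGT"[(base_to_int.get(chars[p], 0) + shift) % 4]
                read = "".join(chars)
        read_ids.append(f"read_{i:06d}")
        seqs.append(read)
        truth_s.append(sid)
        truth_p.append(start0 + 1)
    rs = ReadSet(read_ids, seqs, truth_s, truth_p, seed=config.seed)
    rs.validate(panel)
    return rs


# --------------------------------------------------------------------
# Cytometry event generation
# --------------------------------------------------------------------

CYTOMETRY_COLUMNS = ["FSC", "FL1", "FL2", "FL3", "label"]


def simulate_cytometry(config: SimulationConfig) -> pd.DataFrame:
    """SYTO24/PI event table: live/damaged/dead clusters plus beads.

    Channels are linear-scale fluorescence drawn from log-normal
    clusters (instruments collect these as logarithmic signals); the
    ``label`` column carries the truth population of each event.
    """
    c = config.cytometry
    fracs = np.asarray(c.fractions, dtype=float)
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError("population fractions must sum to 1")
    models = {"live": c.live, "damaged": c.damaged, "dead": c.dead}
    min_sep = min(
        abs(c.live.fl1_mean - c.dead.fl1_mean),
        abs(c.live.fl3_mean - c.damaged.fl3_mean),
    )
    if min_sep < 0.1:
        import warnings

        warnings.warn("cluster means closer than 0.1 log10 units; gating unreliable")

    rng = np.random.default_rng(config.seed)
    labels = rng.choice(["live", "damaged", "dead"], size=c.n_events, p=fracs)
    rows = {col: np.empty(c.n_events + c.bead_count) for col in CYTOMETRY_COLUMNS[:4]}
    for name, model in models.items():
        mask = labels == name
        n = int(mask.sum())
        rows["FL1"][: c.n_events][mask] = 10 ** rng.normal(model.fl1_mean, model.sd, n)
        rows["FL3"][: c.n_events][mask] = 10 ** rng.normal(model.fl3_mean, model.sd, n)
    rows["FSC"][: c.n_events] = 10 ** rng.normal(c.fsc_mean_log10, c.fsc_sd, c.n_events)
    rows["FL2"][: c.n_events] = 10 ** rng.normal(c.cell_fl2_mean_log10, 0.2, c.n_events)
    # counting beads: bright in FL2, tight FSC
    nb = c.bead_count
    rows["FSC"][c.n_events :] = 10 ** rng.normal(4.0, c.bead_sd, nb)
    rows["FL1"][c.n_events :] = 10 ** rng.normal(3.0, c.bead_sd, nb)
    rows["FL2"][c.n_events :] = 10 ** rng.normal(c.bead_fl2_mean_log10, c.bead_sd, nb)
    rows["FL3"][c.n_events :] = 10 ** rng.normal(3.0, c.bead_sd, nb)
    df = pd.DataFrame(rows)
    df["label"] = np.concatenate([labels, np.repeat("bead", nb)])
    df.attrs["seed"] = config.seed
    return df


def simulate_cfse_pair(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """cFSE fluorescence tables: before urea, after, and two controls.

    In the ``after`` table the urease-positive subset's fluorescence is
    multiplied by ``1 + shift_percent/100``; the CCCP and flurofamide
    control tables reproduce the pre-urea distribution (transport or
    urease blocked, hence no intracellular alkalinisation).
    """
    c = config.cfse
    if c.shift_percent < 0:
        raise ValueError("shift_percent must be >= 0")
    rng = np.random.default_rng(config.seed)
    positive = rng.random(c.n_events) < c.urease_positive_fraction
    base = 10 ** rng.normal(c.base_mean_log10, c.sd, c.n_events)

    def table(values: np.ndarray) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "FSC": 10 ** rng.normal(4.3, 0.15, c.n_events),
                "FL1": values,
                "label": np.where(positive, "urease_positive", "urease_negative"),
            }
        )
        df.attrs["seed"] = config.seed
        return df

    before = table(base)
    shifted = base.copy()
    shifted[positive] *= 1.0 + c.shift_percent / 100.0
    after = table(shifted)
    after_cccp = table(10 ** rng.normal(c.base_mean_log10, c.sd, c.n_events))
    after_fluro = table(10 ** rng.normal(c.base_mean_log10, c.sd, c.n_events))
    return before, after, after_cccp, after_fluro


# --------------------------------------------------------------------
# Kinetics, qPCR, LFQ
# --------------------------------------------------------------------


def simulate_od_kinetics(config: SimulationConfig, n_replicates: int = 1) -> list[KineticSeries]:
    """Linear OD420 traces: OD(t) = intercept + slope*t + noise."""
    c = config.od
    if c.noise_sd_mod < 0:
        raise ValueError("noise sd must be non-negative")
    rng = np.random.default_rng(config.seed)
    t = np.arange(c.n_points) * c.interval_s
    out = []
    for r in range(n_replicates):
        od = c.intercept_mod + c.slope_mod_per_min * (t / 60.0)
        if c.noise_sd_mod > 0:
            od = od + rng.normal(0.0, c.noise_sd_mod, c.n_points)
        out.append(
            KineticSeries(t, od, replicate_id=f"r{r + 1}", true_slope_mod_per_min=c.slope_mod_per_min)
        )
    return out


def simulate_qpcr(
    calibration: QpcrConfig,
    cell_counts: list[float],
    noise_sd: float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Ct triplicates per sample from a linear calibration model.

    Ct = intercept + slope*log10(cells) + Gaussian noise, with
    ``n_replicates`` rows per sample (assays are run in triplicate).
    """
    if calibration.slope >= 0:
        raise ValueError("calibration slope must be negative (Ct falls as template rises)")
    if any(c <= 0 for c in cell_counts):
        raise ValueError("cell counts must be positive")
    sd = calibration.noise_sd if noise_sd is None else noise_sd
    rng = np.random.default_rng(seed)
    rows = []
    for i, cells in enumerate(cell_counts):
        mu = calibration.intercept + calibration.slope * math.log10(cells)
        for r in range(calibration.n_replicates):
            ct = mu + (rng.normal(0.0, sd) if sd > 0 else 0.0)
            rows.append({"sample": f"s{i + 1}", "true_cells": cells, "replicate": r + 1, "ct": ct})
    df = pd.DataFrame(rows)
    df.attrs["seed"] = seed
    return df


LFQ_META_COLUMNS = [
    "protein_id",
    "species",
    "n_peptides",
    "n_unique",
    "n_unmodified",
    "contaminant_flag",
    "reversed_flag",
]


def simulate_lfq(
    panel: GenomePanel, config: SimulationConfig
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Protein x sample LFQ intensity matrix for two lots.

    Returns ``(matrix, lot_b_columns, lot_c_columns)``.  The matrix
    carries proteinGroups-like metadata columns, linear intensities with
    zeros encoding missing values, and two truth columns:
    ``true_differential`` and ``true_effect_log10``.
    """
    c = config.lfq
    if c.n_replicates < 2:
        raise ValueError("at least 2 replicates per lot are required")
    rng = np.random.default_rng(config.seed)
    species = [s.species for s in panel.strains]
    n = c.n_proteins_per_strain * len(species)
    lo, hi = c.base_log10_range
    base = rng.uniform(lo, hi, n)
    n_diff = round(c.fraction_differential * n)
    diff_idx = rng.choice(n, size=n_diff, replace=False)
    effect = np.zeros(n)
    effect[diff_idx] = rng.choice([-1.0, 1.0], size=n_diff) * c.effect_size_log10

    cols_b = [f"B{r + 1}" for r in range(c.n_replicates)]
    cols_c = [f"C{r + 1}" for r in range(c.n_replicates)]
    data = {}
    for col in cols_b:
        data[col] = 10 ** (base + rng.normal(0.0, c.replicate_sd, n))
    for col in cols_c:
        data[col] = 10 ** (base + effect + rng.normal(0.0, c.replicate_sd, n))
    matrix = pd.DataFrame(data)
    if c.missing_rate > 0:
        mask = rng.random(matrix.shape) < c.missing_rate
        matrix = matrix.mask(pd.DataFrame(mask, columns=matrix.columns), 0.0)

    meta = pd.DataFrame(
        {
            "protein_id": [f"P{i:05d}" for i in range(n)],
            "species": np.repeat(species, c.n_proteins_per_strain),
            "n_peptides": rng.integers(2, 20, n),
            "n_unique": rng.integers(1, 10, n),
            "n_unmodified": rng.integers(1, 10, n),
            "contaminant_flag": False,
            "reversed_flag": False,
        }
    )
    out = pd.concat([meta, matrix], axis=1)
    out["true_differential"] = False
    out.loc[diff_idx, "true_differential"] = True
    out["true_effect_log10"] = effect
    out.attrs["seed"] = config.seed
    return out, cols_b, cols_c
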