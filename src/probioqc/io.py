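"""Readers and writers for the plain-text interchange formats.

Genomes travel as FASTA, ORFs as a GFF-like TSV (1-based inclusive),
diagnostic loci as TSV, reads as FASTQ (Phred+33, constant quality),
cytometry events and kinetics as CSV, and LFQ matrices as TSV with a
proteinGroups-like metadata block.  Biopython handles FASTA/FASTQ;
pandas handles the tabular formats.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synthetic_data import (
    DiagnosticLocus,
    GenomePanel,
    IndelInfo,
    KineticSeries,
    ReadSet,
    StrainInfo,
)


# ---------------------------------------------------------------- panel


def write_panel(panel: GenomePanel, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta = out / "panel.fa"
    records = [
        SeqRecord(Seq(panel.sequences[s.strain_id]), id=s.strain_id, description=s.species)
        for s in panel.strains
    ]
    SeqIO.write(records, fasta, "fasta")

    orfs = out / "panel_orfs.tsv"
    rows = [
        {"seqid": sid, "start": a, "end": b, "strand": strand}
        for sid, intervals in panel.orfs.items()
        for a, b, strand in intervals
    ]
    pd.DataFrame(rows).to_csv(orfs, sep="\t", index=False)

    loci = out / "diagnostic_loci.tsv"
    rows = [
        {
            "locus_id": loc.locus_id,
            "position": loc.position,
            "allele": allele,
            "strain_ids": ",".join(sorted(strains)),
        }
        for loc in panel.diagnostic_loci
        for allele, strains in loc.alleles.items()
    ]
    pd.DataFrame(rows, columns=["locus_id", "position", "allele", "strain_ids"]).to_csv(
        loci, sep="\t", index=False
    )

    meta = out / "panel_meta.json"
    meta.write_text(
        json.dumps(
            {
                "strains": [
                    {"strain_id": s.strain_id, "species": s.species, "circular": s.circular}
                    for s in panel.strains
                ],
                "pair": list(panel.pair) if panel.pair else None,
                "indels": [
                    {
                        "strain_id": i.strain_id,
                        "position": i.position,
                        "length_bp": i.length_bp,
                        "in_frame": i.in_frame,
                    }
                    for i in panel.indels
                ],
                "seed": panel.seed,
            },
            indent=2,
        )
    )
    return {"fasta": fasta, "orfs": orfs, "loci": loci, "meta": meta}


def read_panel(dir_path: str | Path) -> GenomePanel:
    d = Path(dir_path)
    meta = json.loads((d / "panel_meta.json").read_text())
    sequences = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(d / "panel.fa", "fasta")
    }
    orf_df = pd.read_csv(d / "panel_orfs.tsv", sep="\t")
    orfs: dict[str, list[tuple[int, int, str]]] = {sid: [] for sid in sequences}
    for row in orf_df.itertuples():
        orfs[row.seqid].append((int(row.start), int(row.end), str(row.strand)))
    loci_df = pd.read_csv(d / "diagnostic_loci.tsv", sep="\t")
    loci: list[DiagnosticLocus] = []
    for (locus_id, position), grp in loci_df.groupby(["locus_id", "position"], sort=False):
        alleles = {
            str(r.allele): frozenset(str(r.strain_ids).split(","))
            for r in grp.itertuples()
        }
        loci.append(DiagnosticLocus(str(locus_id), int(position), alleles))
    panel = GenomePanel(
        strains=[StrainInfo(s["strain_id"], s["species"], s["circular"]) for s in meta["strains"]],
        sequences=sequences,
        orfs=orfs,
        diagnostic_loci=loci,
        indels=[IndelInfo(i["strain_id"], i["position"], i["length_bp"], i["in_frame"]) for i in meta["indels"]],
        pair=tuple(meta["pair"]) if meta["pair"] else None,
        seed=meta["seed"],
    )
    panel.validate()
    return panel


# ---------------------------------------------------------------- reads


def write_reads(reads: ReadSet, out_dir: str | Path, quality: int = 35) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fastq = out / "reads.fq"
    with open(fastq, "w") as fh:
        for rid, seq in zip(reads.ids, reads.sequences):
            qual = chr(quality + 33) * len(seq)
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
    paths = {"fastq": fastq}
    if reads.truth_strain is not None:
        truth = out / "reads_truth.tsv"
        pd.DataFrame(
            {
                "read_id": reads.ids,
                "strain_id": reads.truth_strain,
                "position": reads.truth_position,
            }
        ).to_csv(truth, sep="\t", index=False)
        paths["truth"] = truth
    return paths


def read_reads(fastq: str | Path, truth: str | Path | None = None) -> ReadSet:
    ids, seqs = [], []
    for rec in SeqIO.parse(str(fastq), "fastq"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    truth_s = truth_p = None
    if truth is not None:
        df = pd.read_csv(truth, sep="\t").set_index("read_id").loc[ids]
        truth_s = df["strain_id"].tolist()
        truth_p = df["position"].tolist()
    return ReadSet(ids, seqs, truth_s, truth_p)


# ------------------------------------------------------------- tabular


def write_events(events: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    events.to_csv(path, index=False)
    return path


def read_events(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_kinetics(series: list[KineticSeries], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frames = [
        pd.DataFrame(
            {"replicate_id": s.replicate_id, "time_s": s.time_s, "od420": s.od420_mod}
        )
        for s in series
    ]
    pd.concat(frames).to_csv(path, index=False)
    return path


def read_kinetics(path: str | Path) -> list[KineticSeries]:
    df = pd.read_csv(path)
    out = []
    for rid, grp in df.groupby("replicate_id", sort=False):
        out.append(
            KineticSeries(
                grp["time_s"].to_numpy(),
                grp["od420"].to_numpy(),
                replicate_id=str(rid),
            )
        )
    return out


def write_lfq(matrix: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(path, sep="\t", index=False)
    return path


def read_lfq(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    SeqIO.write(
        [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records],
        path,
        "fasta",
    )
    return path


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
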