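"""End-to-end QC run: execute every stage, aggregate a machine-readable report.

The report covers the quality criteria a multi-strain probiotic product
should meet: taxonomy/composition (strain abundance from shotgun reads,
pair deconvolution), safety (resistome screen), viability (gated counts
against the declared live-cell claim), process reproducibility (urease
and beta-galactosidase lot comparison), qPCR species loads, and the
metaproteomic lot similarity summary.  A stage failure is recorded in
place; the report is still emitted with the stage marked failed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Callable

from . import __version__
from . import cytometry as cyto
from . import enzymes, metagenome, proteomics, qpcr, strain_typing
from . import synthetic_data as synth

logger = logging.getLogger("probioqc")

#: thresholds surfaced in the config, with the pipeline defaults
DEFAULT_THRESHOLDS = {
    "min_identity": 0.98,
    "min_read_length": 80,
    "arg_min_identity": 0.80,
    "lfq_floor": 4.3,
    "p_threshold": 0.01,
    "ratio_threshold": 1.0,
    "alpha": 0.05,
}

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "n_reads": 5000,
    "thresholds": DEFAULT_THRESHOLDS,
    # bead stock sized so the default simulation reads ~3.8e11 live
    # cells per gram of product (10 g suspended in 100 ml, counted at
    # a 1:100 dilution)
    "cytometry": {"beads_per_ml": 1.16e8, "dilution_factor": 100.0, "grams_per_ml": 0.1},
    "claims": {"declared_live_cfu_per_g": 1.0e11},
}


def _merged(config: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in (config or {}).items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def run_qc(config: dict | None = None, out_dir: str | Path | None = None) -> dict:
    """Run the full synthetic QC pipeline and return the report dict.

    The synthetic-data module generates every input at the configured
    seed; each stage then analyses its input exactly as it would a real
    product file.  Deterministic given the seed (modulo no timestamps
    in the report).
    """
    cfg = _merged(config)
    seed = int(cfg["seed"])
    thr = cfg["thresholds"]
    sim = synth.SimulationConfig(seed=seed)
    sim.reads.n_reads = int(cfg["n_reads"])

    report: dict[str, Any] = {
        "tool": "probioqc",
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "config_hash": _config_hash(cfg),
        "stages": {},
        "checks": {},
    }

    def stage(name: str, fn: Callable[[], dict]) -> dict | None:
        try:
            result = fn()
            report["stages"][name] = {"status": "ok", **result}
            logger.info("stage %s ok", name)
            return result
        except Exception as exc:  # stage failure must not sink the report
            logger.exception("stage %s failed", name)
            report["stages"][name] = {"status": "failed", "error": str(exc)}
            return None

    panel = synth.make_toy_genomes(sim)
    reads = synth.simulate_reads(panel, sim)

    def _profile() -> dict:
        profile, assignments = metagenome.profile_reads(
            reads, panel, thr["min_identity"], thr["min_read_length"]
        )
        snp_table = strain_typing.DiagnosticSNPTable.from_panel(panel)
        tally = strain_typing.tally_alleles(reads, assignments, snp_table, panel)
        pct = strain_typing.strain_percentages(tally, snp_table, panel.pair)
        abundance = profile.relative_abundance
        if abundance is not None:
            abundance = strain_typing.apportion_pair(
                abundance, panel.pair, pct["percentages"]
            )
        return {
            "relative_abundance": abundance,
            "n_reads": profile.n_reads,
            "n_assigned": profile.n_assigned,
            "n_unassigned": profile.n_unassigned,
            "n_discarded_short": profile.n_discarded_short,
            "n_ambiguous": profile.n_ambiguous,
            "pair_percentages": pct["percentages"],
            "pair_method": pct["method"],
        }

    def _resistome() -> dict:
        # translate the first ORF of each pair member as a stand-in
        # proteome, screened against a tetW-like entry derived from it
        proteins = []
        for sid in panel.strain_ids()[:2]:
            start, end, _ = panel.orfs[sid][0]
            seq = panel.sequences[sid][start - 1 : end]
            proteins.append((f"{sid}_orf1", _translate(seq)))
        db = [("tetW_like", proteins[0][1])]
        hits = metagenome.screen_resistome(proteins, db, thr["arg_min_identity"])
        return {
            "n_hits": len(hits),
            "hits": [dataclasses.asdict(h) for h in hits],
        }

    def _viability() -> dict:
        events = synth.simulate_cytometry(sim)
        c = sim.cytometry
        gates = cyto.GateSpec.from_cluster_means(
            (c.live.fl1_mean, c.live.fl3_mean),
            (c.damaged.fl1_mean, c.damaged.fl3_mean),
            (c.dead.fl1_mean, c.dead.fl3_mean),
        )
        result = cyto.gate_events(events, gates)
        cc = cfg["cytometry"]
        conc = cyto.absolute_concentration(
            result, cc["beads_per_ml"], cc["dilution_factor"], cc["grams_per_ml"]
        )
        return {
            "counts": result.counts,
            "fractions": result.fractions,
            "n_beads": result.n_beads,
            "concentrations": conc,
        }

    def _urease() -> dict:
        before, after, after_cccp, after_fluro = synth.simulate_cfse_pair(sim)
        r_urea = enzymes.urease_activity(before, after)
        r_cccp = enzymes.urease_activity(before, after_cccp, condition="cccp")
        r_fluro = enzymes.urease_activity(before, after_fluro, condition="flurofamide")
        controls = enzymes.control_check(r_urea, r_cccp, r_fluro)
        return {
            "percent_increase": r_urea.percent_increase,
            "cccp_percent": r_cccp.percent_increase,
            "flurofamide_percent": r_fluro.percent_increase,
            "controls": controls,
        }

    def _betagal() -> dict:
        series = synth.simulate_od_kinetics(sim, n_replicates=4)
        result = enzymes.beta_gal_activity(series)
        return {
            "mean_au": result.mean_au,
            "sd_au": result.sd_au,
            "n_replicates": result.n_replicates,
        }

    def _qpcr() -> dict:
        standards = [10.0**e for e in range(4, 9)]
        cal_ct = synth.simulate_qpcr(sim.qpcr, standards, noise_sd=0.0, seed=seed)
        curve = qpcr.fit_calibration(
            cal_ct["true_cells"].tolist(), cal_ct["ct"].tolist(), species="panel"
        )
        sample = synth.simulate_qpcr(sim.qpcr, [1.0e6], seed=seed + 1)
        quant = qpcr.quantify(sample["ct"].tolist(), curve)
        return {
            "slope": curve.slope,
            "r_squared": curve.r_squared,
            "efficiency": curve.efficiency,
            "mean_cells": quant.mean_cells,
            "sd_cells": quant.sd_cells,
            "formatted": quant.formatted(),
        }

    def _proteomics() -> dict:
        matrix, cols_b, cols_c = synth.simulate_lfq(panel, sim)
        filtered, log = proteomics.filter_proteins(matrix)
        logmat = proteomics.log_transform_impute(
            filtered, cols_b + cols_c, thr["lfq_floor"]
        )
        _, summary = proteomics.differential(
            logmat,
            cols_b,
            cols_c,
            p_threshold=thr["p_threshold"],
            ratio_threshold=thr["ratio_threshold"],
        )
        _, mean_r = proteomics.replicate_correlation(logmat, cols_b)
        return {
            "filter_log": log,
            "n_tested": summary.n_tested,
            "n_significant": summary.n_significant,
            "percent_significant": summary.percent_significant,
            "mean_replicate_pearson_r": mean_r,
        }

    stage("metagenome", _profile)
    stage("resistome", _resistome)
    viab = stage("viability", _viability)
    stage("urease", _urease)
    stage("betagal", _betagal)
    stage("qpcr", _qpcr)
    stage("proteomics", _proteomics)

    claim = cfg["claims"].get("declared_live_cfu_per_g")
    if claim is not None and viab is not None:
        live_per_g = viab["concentrations"]["G1"]["per_g"]
        report["checks"]["live_count_meets_claim"] = {
            "declared_per_g": claim,
            "measured_per_g": live_per_g,
            "pass": bool(live_per_g >= claim),
        }
    report["checks"]["all_stages_ok"] = all(
        s["status"] == "ok" for s in report["stages"].values()
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "qc_report.json").write_text(json.dumps(report, indent=2, default=float))
        (out / "qc_summary.txt").write_text(summarize_report(report))
    validate_report(report)
    return report


_CODON_TABLE = None


def _translate(seq: str) -> str:
    from Bio.Seq import Seq

    aa = str(Seq(seq[: len(seq) - len(seq) % 3]).translate())
    return aa.replace("*", "X") or "M"


REPORT_REQUIRED_KEYS = {
    "tool": str,
    "version": str,
    "seed": int,
    "config": dict,
    "config_hash": str,
    "stages": dict,
    "checks": dict,
}


def validate_report(report: dict) -> None:
    """Structural validation of the QC report against its schema."""
    for key, typ in REPORT_REQUIRED_KEYS.items():
        if key not in report:
            raise ValueError(f"report missing key {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(f"report key {key!r} has wrong type")
    for name, stage in report["stages"].items():
        if "status" not in stage or stage["status"] not in ("ok", "failed"):
            raise ValueError(f"stage {name!r} lacks a valid status")


def summarize_report(report: dict) -> str:
    lines = [f"probioqc {report['version']}  seed={report['seed']}  config={report['config_hash']}"]
    for name, stage in report["stages"].items():
        status = stage["status"]
        lines.append(f"[{status:>6}] {name}")
        if name == "metagenome" and status == "ok" and stage["relative_abundance"]:
            for sid, frac in sorted(
                stage["relative_abundance"].items(), key=lambda kv: -kv[1]
            ):
                lines.append(f"          {sid:<22} {100 * frac:6.2f} %")
        if name == "betagal" and status == "ok":
            lines.append(
                f"          AU = {stage['mean_au']:.2f} ± {stage['sd_au']:.2f} mOD/min"
            )
        if name == "urease" and status == "ok":
            lines.append(
                f"          shift = {stage['percent_increase']:.1f} % "
                f"(CCCP {stage['cccp_percent']:.1f} %, flurofamide {stage['flurofamide_percent']:.1f} %)"
            )
        if name == "proteomics" and status == "ok":
            lines.append(
                f"          {stage['n_significant']}/{stage['n_tested']} proteins differential "
                f"({stage['percent_significant']:.1f} %)"
            )
    for check, payload in report["checks"].items():
        if isinstance(payload, dict):
            lines.append(f"check {check}: {'PASS' if payload['pass'] else 'FAIL'}")
        else:
            lines.append(f"check {check}: {'PASS' if payload else 'FAIL'}")
    return "\n".join(lines) + "\n"
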