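"""Label-free metaproteomic lot comparison.

Post-identification statistics on a proteinGroups-like intensity
matrix: peptide-evidence filtering, log10 transform with missing
values (zero intensities) imputed at a fixed floor of 4.3 (slightly
below the lowest measured log10 intensity), per-protein two-sample
t-tests between lots, and a dual significance rule — a protein is
called differential only when its abundance deviates by more than a
factor of 10 (|log10 ratio| > 1) AND p < 0.01.  No multiple-testing
correction is applied in the headline call; Benjamini-Hochberg q-values
are available as an extra column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_FLOOR = 4.3
META_REQUIRED = ["protein_id", "n_peptides", "n_unique", "n_unmodified", "contaminant_flag", "reversed_flag"]


def filter_proteins(matrix: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Peptide-evidence filter.

    Keeps proteins identified by >= 2 peptides, of which >= 1 unique
    and >= 1 unmodified; reversed (decoy) hits are deleted; contaminants
    are kept but remain flagged for downstream display.
    Returns the filtered matrix and a removal log.
    """
    missing = [c for c in META_REQUIRED if c not in matrix.columns]
    if missing:
        raise ValueError(f"missing metadata columns: {missing}")
    n0 = len(matrix)
    reversed_mask = matrix["reversed_flag"].astype(bool)
    evidence = (
        (matrix["n_peptides"] >= 2)
        & (matrix["n_unique"] >= 1)
        & (matrix["n_unmodified"] >= 1)
    )
    kept = matrix.loc[~reversed_mask & evidence].reset_index(drop=True)
    log = {
        "input": n0,
        "removed_reversed": int(reversed_mask.sum()),
        "removed_insufficient_peptides": int((~evidence & ~reversed_mask).sum()),
        "kept": len(kept),
        "contaminants_flagged": int(kept["contaminant_flag"].astype(bool).sum()),
    }
    return kept, log


def log_transform_impute(
    matrix: pd.DataFrame,
    sample_cols: list[str],
    floor: float = DEFAULT_FLOOR,
) -> pd.DataFrame:
    """log10-transform intensities; zeros (missing) become the floor value.

    The floor makes ratio calculations possible for proteins absent
    from one lot; the transformed matrix never goes below it, so a
    protein undetected everywhere renders as a constant floor row.
    """
    out = matrix.copy()
    vals = out[sample_cols].to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValueError("negative intensities are invalid")
    with np.errstate(divide="ignore"):
        logged = np.where(vals > 0, np.log10(np.where(vals > 0, vals, 1.0)), floor)
    out[sample_cols] = np.maximum(logged, floor)
    return out


@dataclass
class DifferentialSummary:
    n_tested: int
    n_significant: int
    percent_significant: float
    n_up_a: int  # significant and more abundant in the first lot
    n_up_b: int


def differential(
    logmatrix: pd.DataFrame,
    lot_a_cols: list[str],
    lot_b_cols: list[str],
    test: str = "student",
    p_threshold: float = 0.01,
    ratio_threshold: float = 1.0,
) -> tuple[pd.DataFrame, DifferentialSummary]:
    """Per-protein two-sample t-test and the factor-10 + p<0.01 call.

    The log10 ratio is mean(lot A) - mean(lot B).  ``significant`` is
    the conjunction |log10 ratio| > ratio_threshold AND p < p_threshold;
    contaminants are volcano-classed separately and excluded from the
    headline significant count.
    """
    if len(lot_a_cols) < 2 or len(lot_b_cols) < 2:
        raise ValueError("at least 2 replicates per lot are required")
    if test not in ("student", "welch"):
        raise ValueError(f"unknown test {test!r}")
    a = logmatrix[lot_a_cols].to_numpy(dtype=float)
    b = logmatrix[lot_b_cols].to_numpy(dtype=float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    ratio = mean_a - mean_b
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # constant (floor-imputed) rows trip scipy's precision warning;
        # their p-values are overwritten by the convention below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=(test == "student"))
    # zero variance in both lots: p=1 when means equal, else 0
    degenerate = np.isnan(p)
    p = np.where(degenerate & (ratio == 0), 1.0, p)
    p = np.where(degenerate & (ratio != 0), 0.0, p)

    contaminant = (
        logmatrix["contaminant_flag"].astype(bool).to_numpy()
        if "contaminant_flag" in logmatrix.columns
        else np.zeros(len(logmatrix), dtype=bool)
    )
    passes_rule = (np.abs(ratio) > ratio_threshold) & (p < p_threshold)
    significant = passes_rule & ~contaminant

    result = logmatrix.copy()
    result["mean_log10_a"] = mean_a
    result["mean_log10_b"] = mean_b
    result["log10_ratio"] = ratio
    result["t_statistic"] = t
    result["p_value"] = p
    with np.errstate(divide="ignore"):
        result["neg_log10_p"] = -np.log10(p)
    result["q_value"] = _benjamini_hochberg(p)
    result["significant"] = significant
    result["volcano_class"] = np.where(
        contaminant, "contaminant", np.where(significant, "significant", "ns")
    )
    summary = DifferentialSummary(
        n_tested=len(result),
        n_significant=int(significant.sum()),
        percent_significant=100.0 * significant.sum() / len(result) if len(result) else 0.0,
        n_up_a=int((significant & (ratio > 0)).sum()),
        n_up_b=int((significant & (ratio < 0)).sum()),
    )
    return result, summary


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.clip(ranked, 0, 1)
    return q


def volcano_table(result: pd.DataFrame) -> pd.DataFrame:
    """Volcano coordinates: x = log10 ratio, y = -log10 p, class column."""
    return result[["protein_id", "log10_ratio", "neg_log10_p", "volcano_class"]].rename(
        columns={"log10_ratio": "x", "neg_log10_p": "y", "volcano_class": "class"}
    )


def replicate_correlation(
    logmatrix: pd.DataFrame,
    cols: list[str],
    exclude_imputed: bool = False,
    floor: float = DEFAULT_FLOOR,
) -> tuple[pd.DataFrame, float]:
    """Pairwise Pearson correlations between replicate columns.

    Computed over proteins on the log scale, by default including
    floor-imputed values; with ``exclude_imputed`` a protein is dropped
    from a pair when either value sits at the floor.  Constant columns
    yield undefined (NaN) correlations, which are reported as such and
    excluded from the mean.
    """
    if len(cols) < 2:
        raise ValueError("need at least two columns")
    rows = []
    for i, ci in enumerate(cols):
        for cj in cols[i + 1 :]:
            x = logmatrix[ci].to_numpy(dtype=float)
            y = logmatrix[cj].to_numpy(dtype=float)
            if exclude_imputed:
                keep = (x > floor) & (y > floor)
                x, y = x[keep], y[keep]
            if len(x) < 2 or x.std() == 0 or y.std() == 0:
                r = np.nan
            else:
                r = float(np.corrcoef(x, y)[0, 1])
            rows.append({"col_a": ci, "col_b": cj, "pearson_r": r})
    table = pd.DataFrame(rows)
    mean_r = float(table["pearson_r"].mean(skipna=True))
    return table, mean_r


def housekeeping_table(
    logmatrix: pd.DataFrame,
    allow_list: list[tuple[str, str]],
    sample_cols: list[str],
    floor: float = DEFAULT_FLOOR,
) -> pd.DataFrame:
    """Per-sample log10 abundance of selected housekeeping proteins.

    Rows are ordered by descending mean abundance; a listed protein
    absent from the matrix is emitted as an all-floor row with a
    warning (the table renders undetected entries at the floor value).
    """
    indexed = logmatrix.set_index("protein_id")
    rows = []
    for pid, species in allow_list:
        if pid in indexed.index:
            vals = indexed.loc[pid, sample_cols].astype(float).tolist()
        else:
            warnings.warn(f"housekeeping protein {pid} absent; emitting floor row")
            vals = [floor] * len(sample_cols)
        rows.append([pid, species, *vals])
    table = pd.DataFrame(rows, columns=["protein_id", "species", *sample_cols])
    table["row_mean"] = table[sample_cols].mean(axis=1)
    table = table.sort_values("row_mean", ascending=False, kind="mergesort").drop(
        columns="row_mean"
    )
    return table.reset_index(drop=True)
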