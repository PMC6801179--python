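"""SYTO24/PI viability gating, bead-referenced absolute counts, lot comparison.

Events are gated on the (log10 FL1, log10 FL3) plane after an FSC
threshold: live cells (AFc) are SYTO24-bright/PI-dim, damaged cells
(Dc) show both signals, dead cells (nAFc) are SYTO24-dim/PI-bright.
Counting beads identified on FL2 convert gate counts into absolute
concentrations.  Damaged cells are excluded from viable totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_FSC_THRESHOLD = 5000.0


@dataclass
class GateSpec:
    """Rectangular gates in (log10 FL1, log10 FL3) plus a bead gate on log10 FL2.

    ``gates`` maps gate name -> (fl1_lo, fl1_hi, fl3_lo, fl3_hi); the
    canonical names are G1 (live), G2 (damaged), G3 (dead).
    """

    gates: dict[str, tuple[float, float, float, float]]
    fsc_threshold: float = DEFAULT_FSC_THRESHOLD
    bead_fl2_range: tuple[float, float] = (3.0, np.inf)

    def __post_init__(self) -> None:
        names = list(self.gates)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if _overlap(self.gates[a], self.gates[b]):
                    raise ValueError(f"gates {a} and {b} overlap")

    @classmethod
    def from_cluster_means(
        cls,
        live: tuple[float, float],
        damaged: tuple[float, float],
        dead: tuple[float, float],
        fsc_threshold: float = DEFAULT_FSC_THRESHOLD,
        bead_fl2_boundary: float = 3.0,
    ) -> "GateSpec":
        """Place gate boundaries at midpoints between cluster means.

        This auto-placement is intended for synthetic data with known
        cluster means; real instruments require operator-set gates.
        """
        fl1_cut = (live[0] + dead[0]) / 2.0
        fl3_cut = (live[1] + damaged[1]) / 2.0
        big = 12.0
        return cls(
            gates={
                "G1": (fl1_cut, big, -big, fl3_cut),
                "G2": (fl1_cut, big, fl3_cut, big),
                "G3": (-big, fl1_cut, fl3_cut, big),
            },
            fsc_threshold=fsc_threshold,
            bead_fl2_range=(bead_fl2_boundary, np.inf),
        )


def _overlap(a: tuple, b: tuple) -> bool:
    return a[0] < b[1] and b[0] < a[1] and a[2] < b[3] and b[2] < a[3]


GATE_POPULATION = {"G1": "live", "G2": "damaged", "G3": "dead"}


@dataclass
class ViabilityResult:
    counts: dict[str, int]
    n_events: int
    n_beads: int
    n_excluded_nonpositive: int
    n_below_fsc: int
    n_ungated: int
    fractions: dict[str, float] = field(default_factory=dict)
    gate_labels: pd.Series | None = None

    @property
    def n_gated(self) -> int:
        return sum(self.counts.values())


def gate_events(events: pd.DataFrame, gates: GateSpec) -> ViabilityResult:
    """Assign each event to at most one gate.

    Events with any non-positive channel value are excluded (and
    counted); the FSC threshold is applied first; beads are identified
    on log10 FL2 before cell gating; remaining events fall into at most
    one rectangular gate, or are counted as ungated background.
    """
    n = len(events)
    if n == 0:
        return ViabilityResult({g: 0 for g in gates.gates}, 0, 0, 0, 0, 0, {})
    channels = ["FSC", "FL1", "FL2", "FL3"]
    present = [c for c in channels if c in events.columns]
    vals = events[present].to_numpy(dtype=float)
    positive = (vals > 0).all(axis=1)
    n_excluded = int((~positive).sum())

    df = events.loc[positive]
    above = df["FSC"].to_numpy() >= gates.fsc_threshold
    n_below = int((~above).sum())
    df = df.loc[above]

    lfl2 = np.log10(df["FL2"].to_numpy()) if "FL2" in df.columns else np.full(len(df), -np.inf)
    lo, hi = gates.bead_fl2_range
    is_bead = (lfl2 >= lo) & (lfl2 < hi)
    n_beads = int(is_bead.sum())
    cells = df.loc[~is_bead]

    lfl1 = np.log10(cells["FL1"].to_numpy())
    lfl3 = np.log10(cells["FL3"].to_numpy())
    labels = np.full(len(cells), "ungated", dtype=object)
    counts = {}
    for name, (a, b, c, d) in gates.gates.items():
        mask = (lfl1 >= a) & (lfl1 < b) & (lfl3 >= c) & (lfl3 < d)
        assert not np.any(mask & (labels != "ungated")), "gates must be disjoint"
        labels[mask] = name
        counts[name] = int(mask.sum())
    n_ungated = int((labels == "ungated").sum())
    gated = sum(counts.values())
    fractions = {g: counts[g] / gated for g in counts} if gated else {}
    return ViabilityResult(
        counts=counts,
        n_events=n,
        n_beads=n_beads,
        n_excluded_nonpositive=n_excluded,
        n_below_fsc=n_below,
        n_ungated=n_ungated,
        fractions=fractions,
        gate_labels=pd.Series(labels, index=cells.index),
    )


def absolute_concentration(
    result: ViabilityResult,
    beads_added_per_ml: float,
    dilution_factor: float = 1.0,
    grams_per_ml: float = 0.1,
    bead_events: int | None = None,
) -> dict[str, dict[str, float]]:
    """Bead-referenced absolute concentration per gate.

    cells/ml = gate count x (beads added per ml / bead events) x
    dilution; cells/g divides by the suspension density (10 g in
    100 ml -> 0.1 g/ml).
    """
    nb = result.n_beads if bead_events is None else bead_events
    if nb <= 0:
        raise ValueError("no bead events; absolute count undefined")
    out = {}
    for gate, count in result.counts.items():
        per_ml = count * (beads_added_per_ml / nb) * dilution_factor
        out[gate] = {"per_ml": per_ml, "per_g": per_ml / grams_per_ml}
    return out


@dataclass
class LotComparison:
    t_statistic: float
    p_value: float
    significant: bool
    alpha: float = 0.05


def compare_lots(
    values_a,
    values_b,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> LotComparison:
    """Two-sided unpaired t-test between replicate measurements of two lots.

    Student's equal-variance test by default; Welch via
    ``equal_var=False``.  With zero variance in both groups, p is 1
    for equal means and 0 otherwise by convention.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("at least 2 replicates per lot are required")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
        t = 0.0 if p == 1.0 else np.inf
    else:
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        t, p = float(t), float(p)
    return LotComparison(t, p, bool(p < alpha), alpha)
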