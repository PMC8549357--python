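"""Filter-efficacy statistics: per-filter and OR-combined removal counts,
unique-detection percentages and the value-added ratio, for the FP and TP
strata separately.

Percentages are rounded half-up.  The default "reporting" mode computes the
value-added ratio from the two *rounded* percentages (so printed tables are
internally reproducible from their own printed numbers); an exact mode is
available via ``decimals=None``.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .comparator import FP, TP, LabeledCall
from .filter_engine import FilterOutcomes


def round_half_up(x: float, decimals: int) -> float:
    """Plain half-up rounding at ``decimals`` (ties away from zero)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pct(count: float, denominator: float, decimals: Optional[int] = 2) -> Optional[float]:
    """100 * count / denominator, rounded half-up; None if denominator is 0."""
    if denominator == 0:
        return None
    value = 100.0 * count / denominator
    if decimals is None:
        return value
    return round_half_up(value, decimals)


def value_added_ratio(
    removed_fp_pct: float,
    removed_tp_pct: float,
    decimals: Optional[int] = 2,
) -> Optional[float]:
    """Ratio of %FP removed to %TP removed.

    With ``decimals`` set (reporting mode), both percentages are first
    rounded to that precision and the quotient is rounded likewise; with
    ``decimals=None`` the raw quotient is returned.  Returns None when the
    TP percentage is (or rounds to) zero.
    """
    if removed_fp_pct < 0 or removed_tp_pct < 0:
        raise ValueError("percentages must be non-negative")
    if decimals is not None:
        removed_fp_pct = round_half_up(removed_fp_pct, decimals)
        removed_tp_pct = round_half_up(removed_tp_pct, decimals)
    if removed_tp_pct == 0:
        return None
    ratio = removed_fp_pct / removed_tp_pct
    return ratio if decimals is None else round_half_up(ratio, decimals)


@dataclass
class EfficacyRow:
    """One row of the efficacy table (one filter, or the OR-combined 'any')."""

    name: str
    applicable_fp: int
    removed_fp: int
    removed_fp_pct: Optional[float]
    unique_fp: Optional[int]
    unique_fp_pct: Optional[float]
    applicable_tp: int
    removed_tp: int
    removed_tp_pct: Optional[float]
    value_added_ratio: Optional[float]


ANY_ROW = "any"


def compute_efficacy(
    outcomes: FilterOutcomes,
    labels: Optional[Sequence[str]] = None,
    decimals: Optional[int] = 2,
) -> List[EfficacyRow]:
    """Efficacy rows for each filter plus the OR-combined 'any' row.

    Counts are restricted per filter to the calls where it is applicable;
    ``unique_fp`` counts FPs removed by that filter and by no other.  The
    'any' row uses the union of removed sets over the full FP/TP totals.
    Requires independent-mode outcomes for table semantics.
    """
    if labels is None:
        labels = [lc.label for lc in outcomes.calls]
    labels = np.asarray(labels)
    fp_mask = labels == FP
    tp_mask = labels == TP

    n = len(outcomes.calls)
    removal_count = np.zeros(n, dtype=int)
    for spec in outcomes.specs:
        removal_count += outcomes.removed[spec.name]

    rows: List[EfficacyRow] = []
    any_removed = outcomes.removed_by_any
    rows.append(
        EfficacyRow(
            name=ANY_ROW,
            applicable_fp=int(fp_mask.sum()),
            removed_fp=int((any_removed & fp_mask).sum()),
            removed_fp_pct=pct((any_removed & fp_mask).sum(), fp_mask.sum(), decimals),
            unique_fp=None,
            unique_fp_pct=None,
            applicable_tp=int(tp_mask.sum()),
            removed_tp=int((any_removed & tp_mask).sum()),
            removed_tp_pct=pct((any_removed & tp_mask).sum(), tp_mask.sum(), decimals),
            value_added_ratio=_row_ratio(
                (any_removed & fp_mask).sum(), fp_mask.sum(),
                (any_removed & tp_mask).sum(), tp_mask.sum(), decimals,
            ),
        )
    )
    for spec in outcomes.specs:
        app = outcomes.applicable[spec.name]
        rem = outcomes.removed[spec.name]
        unique = rem & (removal_count == 1)
        app_fp = int((app & fp_mask).sum())
        app_tp = int((app & tp_mask).sum())
        rem_fp = int((rem & fp_mask).sum())
        rem_tp = int((rem & tp_mask).sum())
        rows.append(
            EfficacyRow(
                name=spec.name,
                applicable_fp=app_fp,
                removed_fp=rem_fp,
                removed_fp_pct=pct(rem_fp, app_fp, decimals),
                unique_fp=int((unique & fp_mask).sum()),
                unique_fp_pct=pct((unique & fp_mask).sum(), app_fp, decimals),
                applicable_tp=app_tp,
                removed_tp=rem_tp,
                removed_tp_pct=pct(rem_tp, app_tp, decimals),
                value_added_ratio=_row_ratio(rem_fp, app_fp, rem_tp, app_tp, decimals),
            )
        )
    return rows


def _row_ratio(rem_fp, app_fp, rem_tp, app_tp, decimals) -> Optional[float]:
    fp_pct = pct(rem_fp, app_fp, decimals)
    tp_pct = pct(rem_tp, app_tp, decimals)
    if fp_pct is None or tp_pct is None:
        return None
    # percentages already rounded when decimals is set; pass through raw
    return value_added_ratio(fp_pct, tp_pct, decimals)


def efficacy_frame(rows: Sequence[EfficacyRow]) -> pd.DataFrame:
    """Tabulate efficacy rows, columns named exactly as the row fields."""
    return pd.DataFrame([vars(r) for r in rows]).set_index("name")


# ---------------------------------------------------------------------------
# distribution summaries (the density-plot data, as histograms)

DEFAULT_BINS: Dict[str, np.ndarray] = {
    "qual": np.linspace(0, 3000, 61),
    "qd": np.linspace(0, 60, 61),
    "vaf": np.linspace(0, 1, 21),
    "depth": np.linspace(0, 600, 61),
    "alt_reads": np.linspace(0, 600, 61),
    "dist_snp": np.linspace(0, 1000, 51),
    "dist_indel": np.linspace(0, 1000, 51),
    "strand_min_pct": np.linspace(0, 50, 26),
    "direction_min_pct": np.linspace(0, 50, 26),
}


def summarize_distributions(
    labeled: Sequence[LabeledCall],
    bins: Optional[Mapping[str, np.ndarray]] = None,
) -> pd.DataFrame:
    """Fixed-bin histograms of each characteristic, split TP vs FP.

    Values beyond the outer edges are clipped into the end bins.  Returns a
    long-format frame: characteristic, label, bin_left, bin_right, count.
    """
    if bins is None:
        bins = DEFAULT_BINS
    records = []
    for characteristic, edges in bins.items():
        edges = np.asarray(edges, dtype=float)
        for label in (TP, FP):
            values = [
                lc.characteristics.get(characteristic)
                for lc in labeled
                if lc.label == label
                and lc.characteristics.available(characteristic)
            ]
            if values:
                clipped = np.clip(np.asarray(values, dtype=float), edges[0], edges[-1])
                counts, _ = np.histogram(clipped, bins=edges)
            else:
                counts = np.zeros(len(edges) - 1, dtype=int)
            for left, right, count in zip(edges[:-1], edges[1:], counts):
                records.append(
                    {
                        "characteristic": characteristic,
                        "label": label,
                        "bin_left": left,
                        "bin_right": right,
                        "count": int(count),
                    }
                )
    return pd.DataFrame.from_records(records)
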