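"""Hard filters over labeled calls.

Every filter is a "discard if value <= threshold" rule on one of the nine
characteristics, applicable only where that characteristic is available.
Two application modes exist: *independent* (each filter evaluated on the raw
call set — the semantics behind per-filter efficacy tables) and *sequential*
(proximity/thinning filters applied last, with neighbour distances
recomputed on the calls surviving every other filter, so a true call is not
discarded merely for sitting next to an already-removed false one).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, FrozenSet, List, Sequence

import numpy as np

from .comparator import LabeledCall
from .vcf_model import CallCharacteristics, distances_to_nearest

#: characteristics whose value depends on the surrounding call set
PROXIMITY_CHARACTERISTICS = frozenset({"dist_snp", "dist_indel"})

SNP_STRATUM = "SNP"
INDEL_STRATUM = "indel"


@dataclass(frozen=True)
class FilterSpec:
    """One hard-filter rule: discard where characteristic <= threshold."""

    name: str
    characteristic: str
    threshold: float
    applies_to: FrozenSet[str] = frozenset({SNP_STRATUM})

    def __post_init__(self) -> None:
        if self.characteristic not in CallCharacteristics.NAMES:
            raise ValueError(f"unknown characteristic {self.characteristic!r}")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")


def default_snp_filters() -> List[FilterSpec]:
    """The nine default SNP filters (discard-if-<=)."""
    snp = frozenset({SNP_STRATUM})
    return [
        FilterSpec("snp_qual", "qual", 30, snp),
        FilterSpec("snp_qd", "qd", 1, snp),
        FilterSpec("snp_vaf", "vaf", 0.95, snp),
        FilterSpec("snp_depth", "depth", 5, snp),
        FilterSpec("snp_alt_reads", "alt_reads", 5, snp),
        FilterSpec("snp_dist_snp", "dist_snp", 3, snp),
        FilterSpec("snp_dist_indel", "dist_indel", 10, snp),
        FilterSpec("snp_strand_min_pct", "strand_min_pct", 5, snp),
        FilterSpec("snp_direction_min_pct", "direction_min_pct", 5, snp),
    ]


def default_indel_filters() -> List[FilterSpec]:
    """The six default indel filters (no QD, alt-read or direction rule)."""
    indel = frozenset({INDEL_STRATUM})
    return [
        FilterSpec("indel_qual", "qual", 20, indel),
        FilterSpec("indel_vaf", "vaf", 0.95, indel),
        FilterSpec("indel_depth", "depth", 10, indel),
        FilterSpec("indel_dist_snp", "dist_snp", 3, indel),
        FilterSpec("indel_dist_indel", "dist_indel", 10, indel),
        FilterSpec("indel_strand_min_pct", "strand_min_pct", 5, indel),
    ]


def load_filters(path) -> List[FilterSpec]:
    """Load filter specs from a TSV: name, characteristic, threshold, applies_to.

    ``applies_to`` is a comma-separated subset of {SNP, indel}.
    """
    specs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("name\t"):
                continue
            name, characteristic, threshold, applies = line.split("\t")[:4]
            specs.append(
                FilterSpec(
                    name,
                    characteristic,
                    float(threshold),
                    frozenset(applies.split(",")),
                )
            )
    return specs


@dataclass
class FilterOutcomes:
    """Per-call, per-filter applicability and removal flags.

    ``stage`` is 0 for retained calls, 1/2 for the removal stage in
    sequential mode, and 1 for every removed call in independent mode.
    """

    calls: List[LabeledCall]
    specs: List[FilterSpec]
    applicable: Dict[str, np.ndarray]
    removed: Dict[str, np.ndarray]
    stage: np.ndarray

    @property
    def removed_by_any(self) -> np.ndarray:
        out = np.zeros(len(self.calls), dtype=bool)
        for spec in self.specs:
            out |= self.removed[spec.name]
        return out

    def filter_strings(self) -> List[str]:
        """Per-call FILTER column content: failing filter names, or PASS."""
        out = []
        for i in range(len(self.calls)):
            failing = [s.name for s in self.specs if self.removed[s.name][i]]
            out.append(";".join(failing) if failing else "PASS")
        return out


def _evaluate(spec: FilterSpec, lc: LabeledCall) -> tuple:
    """(applicable, removed) of one spec on one call."""
    stratum = lc.stratum
    if stratum is None or stratum not in spec.applies_to:
        return False, False
    value = lc.characteristics.get(spec.characteristic)
    if value is None:
        return False, False
    return True, value <= spec.threshold


def apply_filters_independent(
    calls: Sequence[LabeledCall], specs: Sequence[FilterSpec]
) -> FilterOutcomes:
    """Evaluate every filter on the raw call set (efficacy-table semantics)."""
    calls = list(calls)
    specs = list(specs)
    _check_unique_names(specs)
    n = len(calls)
    applicable = {s.name: np.zeros(n, dtype=bool) for s in specs}
    removed = {s.name: np.zeros(n, dtype=bool) for s in specs}
    for i, lc in enumerate(calls):
        for spec in specs:
            app, rem = _evaluate(spec, lc)
            applicable[spec.name][i] = app
            removed[spec.name][i] = rem
    any_removed = np.zeros(n, dtype=bool)
    for s in specs:
        any_removed |= removed[s.name]
    stage = np.where(any_removed, 1, 0)
    return FilterOutcomes(calls, specs, applicable, removed, stage)


def apply_filters_sequential(
    calls: Sequence[LabeledCall], specs: Sequence[FilterSpec]
) -> FilterOutcomes:
    """Two-stage thinning mode.

    Stage 1 applies every non-proximity filter as in independent mode.
    Stage 2 recomputes dist_snp/dist_indel over the surviving calls only,
    then applies the proximity filters to the survivors.
    """
    calls = list(calls)
    specs = list(specs)
    _check_unique_names(specs)
    stage1_specs = [
        s for s in specs if s.characteristic not in PROXIMITY_CHARACTERISTICS
    ]
    proximity_specs = [
        s for s in specs if s.characteristic in PROXIMITY_CHARACTERISTICS
    ]
    out1 = apply_filters_independent(calls, stage1_specs)
    n = len(calls)

    survivor_idx = [i for i in range(n) if not out1.removed_by_any[i]]
    survivors = [calls[i] for i in survivor_idx]
    order = sorted(range(len(survivors)), key=lambda j: (
        survivors[j].call.chrom, survivors[j].call.pos,
        survivors[j].call.ref, survivors[j].call.alt,
    ))
    sorted_calls = [survivors[j].call for j in order]
    dists = distances_to_nearest(sorted_calls)
    new_chars: Dict[int, CallCharacteristics] = {}
    for rank, j in enumerate(order):
        d_snp, d_indel = dists[rank]
        new_chars[survivor_idx[j]] = replace(
            survivors[j].characteristics, dist_snp=d_snp, dist_indel=d_indel
        )

    applicable = dict(out1.applicable)
    removed = dict(out1.removed)
    for spec in proximity_specs:
        app = np.zeros(n, dtype=bool)
        rem = np.zeros(n, dtype=bool)
        for i in survivor_idx:
            lc = replace(calls[i], characteristics=new_chars[i])
            app[i], rem[i] = _evaluate(spec, lc)
        applicable[spec.name] = app
        removed[spec.name] = rem

    stage = np.zeros(n, dtype=int)
    for s in stage1_specs:
        stage[removed[s.name]] = 1
    stage2_removed = np.zeros(n, dtype=bool)
    for s in proximity_specs:
        stage2_removed |= removed[s.name]
    stage[stage2_removed & (stage == 0)] = 2
    return FilterOutcomes(calls, specs, applicable, removed, stage)


def _check_unique_names(specs: Sequence[FilterSpec]) -> None:
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate filter names in {names}")
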