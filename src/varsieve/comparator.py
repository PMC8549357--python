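"""Classify pipeline calls against a truth set (TP/FP/FN) and compute
precision/recall/F-score, at position+allele granularity on a haploid
genome.

This is a deliberately simple exact-key matcher: both query and truth are
assumed normalized against the same reference, genotypes are irrelevant
(haploid, forced homozygous), and calls overlapping ambiguous regions are
excluded from all counting.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

from .errors import ContigMismatchError
from .truth_builder import TruthSet
from .vcf_model import (
    PASS,
    UNSET,
    CallCharacteristics,
    TagDialect,
    VariantCall,
    VarClass,
    distances_to_nearest,
    extract_characteristics,
)

TP = "TP"
FP = "FP"

_INDEL_CLASSES = (VarClass.INS, VarClass.DEL)


@dataclass
class LabeledCall:
    """A PASS, confident-region query call with its TP/FP label.

    ``in_characterization_set`` marks calls eligible for the downstream
    filter analysis: biallelic site, plain SNP/INS/DEL class, not derived
    from an MNP, ACGT alleles only.
    """

    call: VariantCall
    characteristics: CallCharacteristics
    label: str
    in_characterization_set: bool

    @property
    def stratum(self) -> Optional[str]:
        if self.call.var_class is VarClass.SNP:
            return "SNP"
        if self.call.var_class in _INDEL_CLASSES:
            return "indel"
        return None


@dataclass(frozen=True)
class PerformanceMetrics:
    tp: int
    fp: int
    fn: int
    precision: Optional[float]
    recall: Optional[float]
    f_score: Optional[float]


def compute_metrics(tp: int, fp: int, fn: int) -> PerformanceMetrics:
    """precision = TP/(TP+FP); recall = TP/(TP+FN); F = harmonic mean.

    Zero-denominator combinations are reported as None, never as 0.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp > 0 else None
    recall = tp / (tp + fn) if tp + fn > 0 else None
    f_score = None
    if precision is not None and recall is not None and precision + recall > 0:
        f_score = 2 * precision * recall / (precision + recall)
    return PerformanceMetrics(tp, fp, fn, precision, recall, f_score)


def _stratum_of(var_class: Optional[VarClass]) -> Optional[str]:
    if var_class is VarClass.SNP:
        return "SNP"
    if var_class in _INDEL_CLASSES:
        return "indel"
    return None


def compare(
    query: Sequence[VariantCall],
    truth: TruthSet,
    dialect: Optional[TagDialect] = None,
) -> Tuple[List[LabeledCall], Dict[str, PerformanceMetrics]]:
    """Label query calls TP/FP against the truth set and compute metrics.

    Non-PASS calls are ignored (an unset FILTER column counts as passing).
    Calls whose reference footprint intersects an ambiguous region are
    excluded from counting entirely.  Metrics are stratified by SNP vs
    indel; FNs are truth variants with no matching PASS query key.

    Distance characteristics are computed over the scored query call set;
    the other characteristics are extracted under ``dialect`` when given.
    """
    contigs = set(truth.contig_lengths)
    for c in query:
        if c.chrom not in contigs:
            raise ContigMismatchError(
                f"query contig {c.chrom!r} absent from truth contigs {sorted(contigs)}"
            )

    scored = [
        c
        for c in query
        if c.filter_status in (PASS, UNSET)
        and not truth.ambiguous_positions.overlaps(c.chrom, *c.ref_footprint)
    ]
    scored.sort(key=lambda c: (c.chrom, c.pos, c.ref, c.alt))
    dists = distances_to_nearest(scored)

    truth_keys = truth.keys
    labeled: List[LabeledCall] = []
    matched = set()
    fp_keys_by_stratum: Dict[str, set] = {"SNP": set(), "indel": set()}
    for call, (d_snp, d_indel) in zip(scored, dists):
        label = TP if call.key in truth_keys else FP
        if label == TP:
            matched.add(call.key)
        else:
            stratum = _stratum_of(call.var_class)
            if stratum is not None:
                fp_keys_by_stratum[stratum].add(call.key)
        if dialect is not None:
            chars = extract_characteristics(call, dialect)
        else:
            chars = CallCharacteristics(qual=call.qual)
        chars = replace(chars, dist_snp=d_snp, dist_indel=d_indel)
        in_char = (
            call.site_alt_count == 1
            and not call.mnp_derived
            and not call.is_ambiguous_allele
            and call.var_class in (VarClass.SNP, VarClass.INS, VarClass.DEL)
        )
        labeled.append(LabeledCall(call, chars, label, in_char))

    metrics = {}
    for stratum in ("SNP", "indel"):
        truth_stratum = {
            v.key for v in truth.variants if _stratum_of(v.var_class) == stratum
        }
        tp = len(matched & truth_stratum)
        fn = len(truth_stratum) - tp
        fp = len(fp_keys_by_stratum[stratum])
        metrics[stratum] = compute_metrics(tp, fp, fn)
    return labeled, metrics


def characterization_subset(
    labeled: Sequence[LabeledCall],
) -> Dict[str, Dict[str, List[LabeledCall]]]:
    """Split the characterization-eligible calls by stratum and label.

    Returns ``{"SNP": {"TP": [...], "FP": [...]}, "indel": {...}}``.
    """
    out: Dict[str, Dict[str, List[LabeledCall]]] = {
        "SNP": {TP: [], FP: []},
        "indel": {TP: [], FP: []},
    }
    for lc in labeled:
        if not lc.in_characterization_set:
            continue
        stratum = lc.stratum
        if stratum is not None:
            out[stratum][lc.label].append(lc)
    return out
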