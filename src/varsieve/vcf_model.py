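"""Variant-call data model: parsing, normalization, classification and
extraction of per-call positional characteristics.

The nine characteristics handled here are: call quality (QUAL), quality by
depth (QD), variant allele frequency, read depth, number of variant-supporting
reads, distance to the nearest SNP, distance to the nearest indel, and the
percentage of variant-supporting reads on the least-covered strand and in the
least-covered mapping direction.  Because callers encode these in different
INFO/FORMAT tags, extraction is driven by a :class:`TagDialect`; an unmapped
characteristic is *unavailable*, never zero.
"""

from __future__ import annotations

import configparser
import numbers
from bisect import bisect_left
from dataclasses import dataclass, field, fields, replace
from enum import Enum
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import pysam

from .errors import (
    AmbiguousAlleleError,
    ReferenceMismatchError,
    TagInconsistencyError,
    UnsortedInputError,
    VcfParseError,
)

ACGT = frozenset("ACGT")

#: FILTER column states
PASS = "PASS"
FAIL = "FAIL"
UNSET = "UNSET"


class VarClass(str, Enum):
    SNP = "SNP"
    INS = "INS"
    DEL = "DEL"
    MNP = "MNP"
    COMPLEX = "COMPLEX"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def classify_variant(ref: str, alt: str) -> VarClass:
    """Classify a (ref, alt) allele pair.

    Raises :class:`AmbiguousAlleleError` if either allele contains a
    character outside {A, C, G, T}.
    """
    if not ref or not alt:
        raise ValueError("alleles must be non-empty")
    if not (set(ref) <= ACGT and set(alt) <= ACGT):
        raise AmbiguousAlleleError(f"ambiguity character in alleles {ref}>{alt}")
    if len(ref) == 1 and len(alt) == 1:
        return VarClass.SNP
    if len(ref) < len(alt) and alt.startswith(ref):
        return VarClass.INS
    if len(ref) > len(alt) and ref.startswith(alt):
        return VarClass.DEL
    if len(ref) == len(alt):
        return VarClass.MNP
    return VarClass.COMPLEX


@dataclass
class VariantCall:
    """One normalized VCF record (one ALT allele).

    ``pos`` is the 1-based VCF position (anchor base for indels).
    ``site_alt_count`` records how many ALT alleles the originating record
    had, so the biallelic restriction can be enforced downstream.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: Optional[float] = None
    filter_status: str = UNSET
    tags: Dict[str, object] = field(default_factory=dict)
    pipeline_id: str = ""
    site_alt_count: int = 1
    mnp_derived: bool = False
    var_class: Optional[VarClass] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        self.ref = self.ref.upper()
        self.alt = self.alt.upper()
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.var_class is None and not self.is_ambiguous_allele:
            self.var_class = classify_variant(self.ref, self.alt)

    @property
    def is_ambiguous_allele(self) -> bool:
        """True if ref or alt contains a non-ACGT character."""
        return not (set(self.ref) <= ACGT and set(self.alt) <= ACGT)

    @property
    def key(self) -> Tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def ref_footprint(self) -> Tuple[int, int]:
        """0-based half-open interval covered by the REF allele."""
        return (self.pos - 1, self.pos - 1 + len(self.ref))


@dataclass
class CallCharacteristics:
    """The nine per-call statistics; ``None`` means unavailable.

    ``qd_from_tag`` records whether QD came from a caller tag (True), the
    qual/alt_reads fallback (False), or is unavailable (None).
    """

    qual: Optional[float] = None
    qd: Optional[float] = None
    vaf: Optional[float] = None
    depth: Optional[float] = None
    alt_reads: Optional[float] = None
    dist_snp: Optional[float] = None
    dist_indel: Optional[float] = None
    strand_min_pct: Optional[float] = None
    direction_min_pct: Optional[float] = None
    qd_from_tag: Optional[bool] = None

    NAMES = (
        "qual",
        "qd",
        "vaf",
        "depth",
        "alt_reads",
        "dist_snp",
        "dist_indel",
        "strand_min_pct",
        "direction_min_pct",
    )

    def get(self, name: str) -> Optional[float]:
        if name not in self.NAMES:
            raise KeyError(f"unknown characteristic {name!r}")
        return getattr(self, name)

    def available(self, name: str) -> bool:
        return self.get(name) is not None

    def as_dict(self) -> Dict[str, Optional[float]]:
        return {name: getattr(self, name) for name in self.NAMES}


@dataclass(frozen=True)
class TagDialect:
    """Mapping from characteristics to the VCF tags that encode them.

    Any field left ``None`` makes the corresponding characteristic
    unavailable for calls parsed under this dialect.
    """

    dialect_id: str
    depth: Optional[str] = None
    alt_reads: Optional[str] = None
    qd: Optional[str] = None
    vaf: Optional[str] = None
    alt_forward: Optional[str] = None
    alt_reverse: Optional[str] = None
    alt_left: Optional[str] = None
    alt_right: Optional[str] = None
    depth_note: str = ""


#: Freebayes-style dialect: everything the characterization needs.
GENERIC_DIALECT = TagDialect(
    dialect_id="generic",
    depth="DP",
    alt_reads="AO",
    vaf="AF",
    alt_forward="SAF",
    alt_reverse="SAR",
    alt_left="RPL",
    alt_right="RPR",
    depth_note="absolute read count",
)

#: GATK-style dialect: QD tag present, no strand/placement counts.
GATKISH_DIALECT = TagDialect(
    dialect_id="gatkish",
    depth="DP",
    alt_reads="AO",
    qd="QD",
    depth_note="internally filtered read count",
)

#: Minimal dialect: depth and alt-read count only.
LEAN_DIALECT = TagDialect(dialect_id="lean", depth="DP", alt_reads="AO")

BUILTIN_DIALECTS: Dict[str, TagDialect] = {
    d.dialect_id: d for d in (GENERIC_DIALECT, GATKISH_DIALECT, LEAN_DIALECT)
}


def load_dialects(path) -> Dict[str, TagDialect]:
    """Load dialect definitions from an INI file (one section per dialect)."""
    parser = configparser.ConfigParser()
    with open(path) as fh:
        parser.read_file(fh)
    valid = {f.name for f in fields(TagDialect)} - {"dialect_id"}
    out = {}
    for section in parser.sections():
        kwargs = {}
        for key, value in parser.items(section):
            if key not in valid:
                raise ValueError(f"unknown dialect field {key!r} in [{section}]")
            kwargs[key] = value
        out[section] = TagDialect(dialect_id=section, **kwargs)
    return out


# ---------------------------------------------------------------------------
# parsing


def _per_alt(value, alt_index: int, n_alts: int):
    """Pick the per-ALT element of a tuple-valued tag (Number=A or =R)."""
    if isinstance(value, tuple):
        if len(value) == n_alts:
            return value[alt_index]
        if len(value) == n_alts + 1:  # Number=R: REF first
            return value[alt_index + 1]
        if len(value) == 1:
            return value[0]
        return value
    return value


def _filter_state(record: "pysam.VariantRecord") -> str:
    keys = list(record.filter.keys())
    if not keys:
        return UNSET
    if keys == [PASS] or keys == ["."]:
        return PASS
    return FAIL


def parse_vcf(
    path,
    pipeline_id: str = "",
    dialect: Optional[TagDialect] = None,
) -> List[VariantCall]:
    """Read a VCF 4.x file (plain or bgzipped) into :class:`VariantCall`s.

    Multi-allelic records are split into one call per ALT allele;
    ``site_alt_count`` preserves the original ALT count.  The ``dialect``
    argument is accepted for interface symmetry; tags are stored raw and
    interpreted later by :func:`extract_characteristics`.
    """
    del dialect  # tags stored raw; the dialect matters at extraction time
    calls: List[VariantCall] = []
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"{path}: {exc}") from exc
    with vf:
        record_no = 0
        try:
            for record in vf:
                record_no += 1
                alts = record.alts or ()
                n_alts = len(alts)
                if n_alts == 0:
                    continue  # reference-only record
                tags_common: Dict[str, object] = dict(record.info)
                sample_tags: Dict[str, object] = {}
                if record.samples:
                    first = record.samples[0]
                    for tag in first.keys():
                        if tag == "GT":
                            continue
                        sample_tags[tag] = first[tag]
                for i, alt in enumerate(alts):
                    tags = {
                        k: _per_alt(v, i, n_alts) for k, v in tags_common.items()
                    }
                    tags.update(
                        {k: _per_alt(v, i, n_alts) for k, v in sample_tags.items()}
                    )
                    calls.append(
                        VariantCall(
                            chrom=record.chrom,
                            pos=record.pos,
                            ref=record.ref,
                            alt=str(alt),
                            qual=record.qual,
                            filter_status=_filter_state(record),
                            tags=tags,
                            pipeline_id=pipeline_id,
                            site_alt_count=n_alts,
                        )
                    )
        except (ValueError, OSError) as exc:
            raise VcfParseError(
                f"{path}: malformed VCF near record {record_no + 1}: {exc}"
            ) from exc
    return calls


# ---------------------------------------------------------------------------
# normalization


def _contig_seq(reference: Union[str, Mapping[str, str]], chrom: str) -> str:
    if isinstance(reference, str):
        return reference
    try:
        return reference[chrom]
    except KeyError as exc:
        raise ReferenceMismatchError(f"contig {chrom!r} not in reference") from exc


def normalize_call(
    call: VariantCall, reference: Union[str, Mapping[str, str]]
) -> List[VariantCall]:
    """Normalize one call: trim, left-align indels, decompose MNPs.

    Returns a position-sorted list of calls.  MNPs become per-base SNPs
    flagged ``mnp_derived``; complex substitutions stay whole with class
    COMPLEX.  Ambiguous-allele calls are returned unchanged (they are
    excluded from characterization anyway).
    """
    seq = _contig_seq(reference, call.chrom).upper()
    ref, alt, pos = call.ref, call.alt, call.pos
    if seq[pos - 1 : pos - 1 + len(ref)] != ref:
        raise ReferenceMismatchError(
            f"{call.chrom}:{pos} REF {ref} != reference "
            f"{seq[pos - 1:pos - 1 + len(ref)]!r}"
        )
    if call.is_ambiguous_allele:
        return [call]

    # right-trim shared suffix, extending left through the reference when
    # one allele would empty out (standard left-alignment)
    while True:
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
            continue
        if ref[-1] == alt[-1] and pos > 1:
            base = seq[pos - 2]
            ref, alt, pos = base + ref[:-1], base + alt[:-1], pos - 1
            continue
        break
    # left-trim shared prefix down to the minimal representation
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1

    var_class = classify_variant(ref, alt)
    common = dict(
        qual=call.qual,
        filter_status=call.filter_status,
        pipeline_id=call.pipeline_id,
        site_alt_count=call.site_alt_count,
    )
    if var_class is VarClass.MNP:
        out = []
        for offset, (r, a) in enumerate(zip(ref, alt)):
            if r == a:
                continue
            out.append(
                VariantCall(
                    chrom=call.chrom,
                    pos=pos + offset,
                    ref=r,
                    alt=a,
                    tags=dict(call.tags),
                    mnp_derived=True,
                    **common,
                )
            )
        return out
    return [
        VariantCall(
            chrom=call.chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            tags=dict(call.tags),
            mnp_derived=call.mnp_derived,
            **common,
        )
    ]


def normalize_calls(
    calls: Sequence[VariantCall], reference: Union[str, Mapping[str, str]]
) -> List[VariantCall]:
    """Normalize a collection of calls and return them coordinate-sorted."""
    out: List[VariantCall] = []
    for call in calls:
        out.extend(normalize_call(call, reference))
    out.sort(key=lambda c: (c.chrom, c.pos, c.ref, c.alt))
    return out


# ---------------------------------------------------------------------------
# characteristic extraction


def _numeric(value) -> Optional[float]:
    if value is None:
        return None
    if isinstance(value, bool):
        return float(value)
    if isinstance(value, numbers.Real):
        return float(value)
    try:
        return float(value)
    except (TypeError, ValueError):
        return None


def extract_characteristics(
    call: VariantCall, dialect: TagDialect
) -> CallCharacteristics:
    """Compute the nine characteristics for one call under a tag dialect.

    Unmapped or missing tags yield ``None`` (unavailable).  Distances to
    neighbouring calls cannot be computed from a single call; use
    :func:`distances_to_nearest` to fill them in.
    """

    def tag_value(tag: Optional[str]) -> Optional[float]:
        if tag is None or tag not in call.tags:
            return None
        return _numeric(call.tags[tag])

    depth = tag_value(dialect.depth)
    alt_reads = tag_value(dialect.alt_reads)
    if depth == 0 and alt_reads is not None and alt_reads > 0:
        raise TagInconsistencyError(
            f"{call.chrom}:{call.pos} depth=0 but alt_reads={alt_reads}"
        )

    vaf = tag_value(dialect.vaf)
    if vaf is None and depth is not None and alt_reads is not None and depth > 0:
        vaf = alt_reads / depth

    qd = tag_value(dialect.qd)
    qd_from_tag: Optional[bool] = True if qd is not None else None
    if qd is None and call.qual is not None and alt_reads:
        qd = call.qual / alt_reads
        qd_from_tag = False

    def min_share(a: Optional[float], b: Optional[float]) -> Optional[float]:
        if a is None or b is None or a + b <= 0:
            return None
        return 100.0 * min(a, b) / (a + b)

    strand = min_share(tag_value(dialect.alt_forward), tag_value(dialect.alt_reverse))
    direction = min_share(tag_value(dialect.alt_left), tag_value(dialect.alt_right))

    return CallCharacteristics(
        qual=call.qual,
        qd=qd,
        vaf=vaf,
        depth=depth,
        alt_reads=alt_reads,
        strand_min_pct=strand,
        direction_min_pct=direction,
        qd_from_tag=qd_from_tag,
    )


# ---------------------------------------------------------------------------
# distances


def _nearest_other(positions: List[int], pos: int) -> Optional[int]:
    """Nearest element of a sorted unique position list != pos, or None."""
    i = bisect_left(positions, pos)
    left = i - 1
    right = i + 1 if i < len(positions) and positions[i] == pos else i
    best = None
    if left >= 0:
        best = pos - positions[left]
    if right < len(positions):
        d = positions[right] - pos
        best = d if best is None else min(best, d)
    return best


def distances_to_nearest(
    calls: Sequence[VariantCall],
) -> List[Tuple[Optional[int], Optional[int]]]:
    """Per-call distance to the nearest SNP and nearest indel call.

    ``calls`` must be sorted by (chrom, pos).  Neighbours at the call's own
    position are excluded (distances are between distinct positions), so a
    call never counts itself.  Returns ``None`` where no qualifying
    neighbour exists on the contig.
    """
    order = [(c.chrom, c.pos) for c in calls]
    if order != sorted(order):
        raise UnsortedInputError("calls must be sorted by (chrom, pos)")

    snp_pos: Dict[str, List[int]] = {}
    indel_pos: Dict[str, List[int]] = {}
    for c in calls:
        if c.var_class is VarClass.SNP:
            bucket = snp_pos
        elif c.var_class in (VarClass.INS, VarClass.DEL):
            bucket = indel_pos
        else:
            continue
        lst = bucket.setdefault(c.chrom, [])
        if not lst or lst[-1] != c.pos:
            lst.append(c.pos)

    out = []
    for c in calls:
        d_snp = _nearest_other(snp_pos.get(c.chrom, []), c.pos)
        d_indel = _nearest_other(indel_pos.get(c.chrom, []), c.pos)
        out.append((d_snp, d_indel))
    return out


def attach_distances(
    calls: Sequence[VariantCall],
    characteristics: Sequence[CallCharacteristics],
) -> List[CallCharacteristics]:
    """Return copies of ``characteristics`` with distance fields filled."""
    dists = distances_to_nearest(calls)
    return [
        replace(ch, dist_snp=ds, dist_indel=di)
        for ch, (ds, di) in zip(characteristics, dists)
    ]
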