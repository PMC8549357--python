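"""Truth-set construction.

Two independent pieces of evidence feed the truth set: (i) per-base pileup
consensus masking of the assembly (low-quality and discordant-call
positions), and (ii) a consensus/ambiguous partition of variant calls made
by a whole-genome-alignment parameter sweep.  Running the aligners
themselves is out of scope — their output VCFs are inputs here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

from .errors import ContigMismatchError
from .intervals import GenomeIntervals
from .vcf_model import VariantCall, VarClass


@dataclass(frozen=True)
class PileupColumn:
    """One per-base pileup summary row (1-based position)."""

    chrom: str
    pos: int
    depth: int
    max_base_count: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not 0 <= self.max_base_count <= self.depth:
            raise ValueError(
                f"max_base_count {self.max_base_count} outside [0, {self.depth}] "
                f"at {self.chrom}:{self.pos}"
            )


@dataclass
class TruthSet:
    """Truth variants plus the confident/ambiguous genome partition."""

    variants: List[VariantCall]
    confident_regions: GenomeIntervals
    ambiguous_positions: GenomeIntervals
    contig_lengths: Dict[str, int]
    n_input_vcfs: int = 0

    @property
    def keys(self) -> Set[Tuple[str, int, str, str]]:
        return {v.key for v in self.variants}

    def count(self, stratum: str) -> int:
        """Number of truth variants in a stratum ('SNP' or 'indel')."""
        if stratum == "SNP":
            return sum(1 for v in self.variants if v.var_class is VarClass.SNP)
        if stratum == "indel":
            return sum(
                1
                for v in self.variants
                if v.var_class in (VarClass.INS, VarClass.DEL)
            )
        raise ValueError(f"unknown stratum {stratum!r}")


def load_pileup_tsv(path) -> List[PileupColumn]:
    """Read a pileup summary TSV: chrom, pos, depth, max_base_count."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, pos, depth, maxc = line.split("\t")[:4]
            out.append(PileupColumn(chrom, int(pos), int(depth), int(maxc)))
    return out


def read_fai(path) -> Dict[str, int]:
    """Contig lengths from a FASTA index (.fai)."""
    lengths = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split("\t")
            if len(parts) >= 2:
                lengths[parts[0]] = int(parts[1])
    return lengths


def mask_low_quality(
    columns: Sequence[PileupColumn],
    contig_lengths: Mapping[str, int],
    min_consensus: float = 0.99,
) -> GenomeIntervals:
    """Mask positions with no coverage or a sub-threshold consensus base.

    A position is masked iff depth == 0 OR max_base_count/depth <
    ``min_consensus`` (strict: a consensus fraction exactly at the
    threshold is kept).  Positions absent from ``columns`` imply depth 0
    and are masked.  The comparison is done in exact rational arithmetic
    so that e.g. 99/100 against 0.99 is not perturbed by float rounding.
    """
    threshold = Fraction(min_consensus).limit_denominator(10**6)
    seen: Set[Tuple[str, int]] = set()
    unmasked = []
    for col in columns:
        key = (col.chrom, col.pos)
        if key in seen:
            raise ValueError(f"duplicate pileup column at {col.chrom}:{col.pos}")
        seen.add(key)
        if col.chrom not in contig_lengths:
            raise ContigMismatchError(f"contig {col.chrom!r} not in contig_lengths")
        if col.depth > 0 and Fraction(col.max_base_count, col.depth) >= threshold:
            unmasked.append((col.chrom, col.pos - 1, col.pos))
    return GenomeIntervals(unmasked).complement(contig_lengths)


def mask_discordant(
    mask: GenomeIntervals, discordant_calls: Iterable[VariantCall]
) -> GenomeIntervals:
    """Add the reference footprint of each discordant call to the mask."""
    extra = [(c.chrom, *c.ref_footprint) for c in discordant_calls]
    return mask.union(GenomeIntervals(extra))


def build_consensus(
    vcfs: Sequence[Sequence[VariantCall]],
    contig_lengths: Mapping[str, int],
) -> TruthSet:
    """Intersect n normalized call sets into a truth set.

    Consensus variants are those present (by chrom/pos/ref/alt key) in all
    n inputs; keys seen in at least one but not all inputs are ambiguous.
    The ambiguous reference footprints are excluded from the confident
    regions, and any consensus variant whose footprint touches an
    ambiguous interval is dropped so that every truth variant lies in
    confident territory.
    """
    if len(vcfs) == 0:
        raise ValueError("need at least one input VCF")
    n = len(vcfs)
    counts: Dict[Tuple[str, int, str, str], int] = {}
    first_seen: Dict[Tuple[str, int, str, str], VariantCall] = {}
    for calls in vcfs:
        for key in {c.key for c in calls}:
            counts[key] = counts.get(key, 0) + 1
        for c in calls:
            if c.chrom not in contig_lengths:
                raise ContigMismatchError(
                    f"contig {c.chrom!r} not in contig_lengths"
                )
            first_seen.setdefault(c.key, c)

    ambiguous_fp = [
        (first_seen[k].chrom, *first_seen[k].ref_footprint)
        for k, cnt in counts.items()
        if cnt < n
    ]
    ambiguous = GenomeIntervals(ambiguous_fp)
    confident = ambiguous.complement(contig_lengths)

    consensus = [
        first_seen[k]
        for k, cnt in counts.items()
        if cnt == n and not ambiguous.overlaps(first_seen[k].chrom, *first_seen[k].ref_footprint)
    ]
    consensus.sort(key=lambda c: (c.chrom, c.pos, c.ref, c.alt))
    return TruthSet(
        variants=consensus,
        confident_regions=confident,
        ambiguous_positions=ambiguous,
        contig_lengths=dict(contig_lengths),
        n_input_vcfs=n,
    )


def truth_from_files(truth_vcf, confident_bed, fai) -> TruthSet:
    """Assemble a TruthSet from a truth VCF + confident BED + .fai."""
    from .vcf_model import parse_vcf

    contig_lengths = read_fai(fai)
    confident = GenomeIntervals.from_bed(confident_bed)
    ambiguous = confident.complement(contig_lengths)
    variants = [c for c in parse_vcf(truth_vcf, pipeline_id="truth")]
    return TruthSet(
        variants=variants,
        confident_regions=confident,
        ambiguous_positions=ambiguous,
        contig_lengths=contig_lengths,
        n_input_vcfs=1,
    )


def _grid_values(grid: Tuple[int, int, int]) -> List[int]:
    start, stop, step = grid
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    return list(range(start, stop + 1, step))


def enumerate_sweep(
    grids: Sequence[Tuple[int, int, int]], mode: str = "product"
) -> List[Tuple[int, ...]]:
    """Enumerate whole-genome-alignment sweep parameter tuples.

    ``grids`` is a list of inclusive (start, stop, step) ranges.  Mode
    'product' takes the cartesian product (nucmer-style -c/-g/-b sweep);
    mode 'lockstep' zips equal-length ranges (paftools-style -l/-L, which
    move together) — a single grid is paired with itself.
    """
    values = [_grid_values(g) for g in grids]
    if mode == "product":
        return list(itertools.product(*values))
    if mode == "lockstep":
        if not values:
            return []
        if len(values) == 1:
            values = values * 2
        if len({len(v) for v in values}) != 1:
            raise ValueError("lockstep ranges must have equal lengths")
        return list(zip(*values))
    raise ValueError(f"unknown mode {mode!r}")
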