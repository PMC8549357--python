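"""Synthetic references, truth sets and pipeline call sets.

The generator produces, for a given seed: a random haploid reference, a
planted truth set (SNPs and 1-10 bp indels inside confident regions), and
per-pipeline VCFs containing TPs (at the profile's recall), FNs (implicit)
and two classes of FP — "data-deficient" (low depth/quality, removable by
minimum-threshold filters) and "data-surfeit" (high depth and quality,
immune to them).  FPs are preferentially placed near truth indels.
Characteristics are drawn directly from per-class distributions; read-level
simulation is deliberately out of scope because every downstream stage
consumes only VCF tags.

Ground-truth labels go to a sidecar table, never into the VCF itself.
"""

from __future__ import annotations

import sys
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam

from .intervals import GenomeIntervals
from .truth_builder import TruthSet
from .vcf_model import (
    BUILTIN_DIALECTS,
    FAIL,
    PASS,
    TagDialect,
    VariantCall,
    VarClass,
    normalize_call,
)

if sys.version_info >= (3, 11):
    import tomllib
else:  # pragma: no cover
    import tomli as tomllib

BASES = np.array(list("ACGT"))

TP_CLASS = "tp"
DEFICIENT = "deficient"
SURFEIT = "surfeit"


@dataclass
class CharacteristicModel:
    """Per-class distribution settings for the simulated characteristics.

    Defaults are invented but chosen so that the default hard-filter
    thresholds cleanly separate TPs from data-deficient FPs while
    data-surfeit FPs sail past every minimum-threshold rule.
    """

    tp_depth_mean: float = 60.0
    tp_depth_shape: float = 20.0  # negative binomial size parameter
    tp_qual_range: Tuple[float, float] = (200.0, 2000.0)
    deficient_depth_lam: float = 3.0
    deficient_qual_range: Tuple[float, float] = (2.0, 20.0)
    deficient_vaf_range: Tuple[float, float] = (0.5, 1.0)
    surfeit_depth_lam: float = 400.0
    surfeit_qual_range: Tuple[float, float] = (1000.0, 3000.0)


@dataclass
class PipelineProfile:
    """Error profile and tag dialect of one simulated pipeline."""

    pipeline_id: str
    dialect: TagDialect
    recall_snp: float = 0.95
    recall_indel: float = 0.90
    fp_snps: int = 50
    fp_indels: int = 10
    model: CharacteristicModel = field(default_factory=CharacteristicModel)

    def __post_init__(self) -> None:
        for p in (self.recall_snp, self.recall_indel):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"recall must be in [0, 1], got {p}")
        if min(self.fp_snps, self.fp_indels) < 0:
            raise ValueError("FP counts must be non-negative")


@dataclass
class SimulationConfig:
    seed: int
    contigs: Dict[str, int]
    n_snps: int = 100
    n_indels: int = 20
    ambiguous_fraction: float = 0.005
    fp_deficient_fraction: float = 0.9
    p_near: float = 0.5
    near_window: int = 10
    profiles: List[PipelineProfile] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name, length in self.contigs.items():
            if length <= 0:
                raise ValueError(f"zero-length contig {name!r}")
        if min(self.n_snps, self.n_indels) < 0:
            raise ValueError("variant densities must be >= 0")
        for frac in (self.ambiguous_fraction, self.fp_deficient_fraction, self.p_near):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction {frac} outside [0, 1]")

    @classmethod
    def from_toml(cls, path) -> "SimulationConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        profiles = []
        for p in raw.pop("profiles", []):
            dialect_id = p.pop("dialect", "generic")
            model = CharacteristicModel(**p.pop("model", {}))
            profiles.append(
                PipelineProfile(
                    dialect=BUILTIN_DIALECTS[dialect_id], model=model, **p
                )
            )
        raw["contigs"] = {k: int(v) for k, v in raw.get("contigs", {}).items()}
        return cls(profiles=profiles, **raw)


# ---------------------------------------------------------------------------
# reference and truth


def generate_reference(config: SimulationConfig, rng=None) -> Dict[str, str]:
    """Uniform-random ACGT contigs; reproducible for a given seed."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return {
        name: "".join(rng.choice(BASES, size=length))
        for name, length in config.contigs.items()
    }


def _sample_ambiguous(config: SimulationConfig, rng) -> GenomeIntervals:
    """Random ~20 bp ambiguous intervals up to the configured fraction."""
    chunk = 20
    ivs = []
    for chrom, length in config.contigs.items():
        n_chunks = int(round(length * config.ambiguous_fraction / chunk))
        for _ in range(n_chunks):
            start = int(rng.integers(0, max(1, length - chunk)))
            ivs.append((chrom, start, min(start + chunk, length)))
    return GenomeIntervals(ivs)


class _Occupancy:
    """Tracks reference bases already claimed by a variant footprint."""

    def __init__(self) -> None:
        self._used: Dict[str, set] = {}

    def free(self, chrom: str, start: int, end: int) -> bool:
        used = self._used.get(chrom, set())
        return all(i not in used for i in range(start, end))

    def claim(self, chrom: str, start: int, end: int) -> None:
        self._used.setdefault(chrom, set()).update(range(start, end))


def _random_locus(config: SimulationConfig, rng) -> Tuple[str, int]:
    names = list(config.contigs)
    lengths = np.array([config.contigs[n] for n in names], dtype=float)
    chrom = names[int(rng.choice(len(names), p=lengths / lengths.sum()))]
    pos = int(rng.integers(1, config.contigs[chrom] + 1))
    return chrom, pos


def _make_snp(reference, chrom, pos, rng) -> VariantCall:
    ref = reference[chrom][pos - 1]
    alt = str(rng.choice([b for b in "ACGT" if b != ref]))
    return VariantCall(chrom=chrom, pos=pos, ref=ref, alt=alt)


def _make_indel(reference, chrom, pos, rng) -> Optional[VariantCall]:
    seq = reference[chrom]
    length = int(rng.integers(1, 11))
    if rng.random() < 0.5:  # deletion
        if pos - 1 + 1 + length > len(seq):
            return None
        ref = seq[pos - 1 : pos + length]
        alt = ref[0]
    else:  # insertion
        ref = seq[pos - 1]
        alt = ref + "".join(rng.choice(BASES, size=length))
    return VariantCall(chrom=chrom, pos=pos, ref=ref, alt=alt)


def plant_truth(
    reference: Mapping[str, str], config: SimulationConfig, rng=None
) -> TruthSet:
    """Plant non-overlapping truth SNPs and indels inside confident regions.

    Variants are normalized against the reference before acceptance so the
    truth keys are canonical; footprints never overlap each other or the
    ambiguous intervals.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 1])
    contig_lengths = {c: len(s) for c, s in reference.items()}
    ambiguous = _sample_ambiguous(config, rng)
    confident = ambiguous.complement(contig_lengths)
    if config.n_snps + 11 * config.n_indels > confident.total_length():
        raise ValueError("requested variants exceed available positions")

    occupancy = _Occupancy()
    variants: List[VariantCall] = []

    def try_place(maker, n_wanted: int) -> None:
        placed = 0
        attempts = 0
        limit = 2000 * max(1, n_wanted)
        while placed < n_wanted:
            attempts += 1
            if attempts > limit:
                raise RuntimeError("could not place requested truth variants")
            chrom, pos = _random_locus(config, rng)
            call = maker(reference, chrom, pos, rng)
            if call is None:
                continue
            call = normalize_call(call, reference)[0]
            start, end = call.ref_footprint
            if not confident.covers(call.chrom, start, end):
                continue
            if not occupancy.free(call.chrom, start, end):
                continue
            occupancy.claim(call.chrom, start, end)
            variants.append(call)
            placed += 1

    try_place(_make_snp, config.n_snps)
    try_place(_make_indel, config.n_indels)
    variants.sort(key=lambda c: (c.chrom, c.pos, c.ref, c.alt))
    return TruthSet(
        variants=variants,
        confident_regions=confident,
        ambiguous_positions=ambiguous,
        contig_lengths=contig_lengths,
        n_input_vcfs=1,
    )


# ---------------------------------------------------------------------------
# pipeline simulation


def _draw_characteristics(cls: str, model: CharacteristicModel, rng) -> Dict[str, float]:
    if cls == TP_CLASS:
        p = model.tp_depth_shape / (model.tp_depth_shape + model.tp_depth_mean)
        depth = int(max(1, rng.negative_binomial(model.tp_depth_shape, p)))
        alt = depth
        qual = float(rng.uniform(*model.tp_qual_range))
    elif cls == DEFICIENT:
        depth = int(max(1, rng.poisson(model.deficient_depth_lam)))
        vaf = float(rng.uniform(*model.deficient_vaf_range))
        alt = int(min(depth, max(1, round(vaf * depth))))
        qual = float(rng.uniform(*model.deficient_qual_range))
    elif cls == SURFEIT:
        depth = int(max(1, rng.poisson(model.surfeit_depth_lam)))
        alt = depth
        qual = float(rng.uniform(*model.surfeit_qual_range))
    else:
        raise ValueError(f"unknown class {cls!r}")
    forward = int(rng.binomial(alt, 0.5))
    left = int(rng.binomial(alt, 0.5))
    return {
        "depth": depth,
        "alt_reads": alt,
        "vaf": alt / depth,
        "qual": qual,
        "alt_forward": forward,
        "alt_reverse": alt - forward,
        "alt_left": left,
        "alt_right": alt - left,
    }


def _tags_for(dialect: TagDialect, drawn: Mapping[str, float]) -> Dict[str, object]:
    tags: Dict[str, object] = {}
    if dialect.depth:
        tags[dialect.depth] = int(drawn["depth"])
    if dialect.alt_reads:
        tags[dialect.alt_reads] = int(drawn["alt_reads"])
    if dialect.vaf:
        tags[dialect.vaf] = round(float(drawn["vaf"]), 6)
    if dialect.qd:
        tags[dialect.qd] = round(drawn["qual"] / max(1, drawn["alt_reads"]), 4)
    if dialect.alt_forward:
        tags[dialect.alt_forward] = int(drawn["alt_forward"])
    if dialect.alt_reverse:
        tags[dialect.alt_reverse] = int(drawn["alt_reverse"])
    if dialect.alt_left:
        tags[dialect.alt_left] = int(drawn["alt_left"])
    if dialect.alt_right:
        tags[dialect.alt_right] = int(drawn["alt_right"])
    return tags


def profile_rng(config: SimulationConfig, profile: PipelineProfile):
    """Deterministic per-pipeline generator derived from the global seed."""
    return np.random.default_rng(
        [config.seed, 2, zlib.crc32(profile.pipeline_id.encode())]
    )


def simulate_pipeline_vcf(
    truth: TruthSet,
    profile: PipelineProfile,
    config: SimulationConfig,
    reference: Mapping[str, str],
    rng=None,
) -> Tuple[List[VariantCall], pd.DataFrame]:
    """Emit one pipeline's call set plus its ground-truth sidecar table.

    Each truth variant is emitted as a TP with probability equal to the
    per-type recall.  FPs land at non-truth keys inside confident regions;
    with probability ``p_near`` an FP is placed within ``near_window`` bp
    of a truth indel (falling back to uniform placement, with a warning,
    when the truth set has no indels).  The sidecar records per emitted
    call: position key, class, TP/FP label and FP class.
    """
    if rng is None:
        rng = profile_rng(config, profile)

    truth_indel_anchors = [
        (v.chrom, v.pos)
        for v in truth.variants
        if v.var_class in (VarClass.INS, VarClass.DEL)
    ]
    if config.p_near > 0 and not truth_indel_anchors:
        warnings.warn(
            "p_near > 0 but the truth set has no indels; "
            "placing all FPs uniformly",
            stacklevel=2,
        )

    calls: List[VariantCall] = []
    sidecar_rows: List[Dict[str, object]] = []
    occupancy = _Occupancy()
    used_keys = set(truth.keys)
    for v in truth.variants:
        occupancy.claim(v.chrom, *v.ref_footprint)

    def emit(call: VariantCall, label: str, fp_class: str) -> None:
        calls.append(call)
        sidecar_rows.append(
            {
                "chrom": call.chrom,
                "pos": call.pos,
                "ref": call.ref,
                "alt": call.alt,
                "var_class": str(call.var_class),
                "label": label,
                "fp_class": fp_class,
            }
        )

    # true positives (truth variants surviving the per-type recall draw)
    for v in truth.variants:
        recall = (
            profile.recall_snp
            if v.var_class is VarClass.SNP
            else profile.recall_indel
        )
        if rng.random() >= recall:
            continue  # false negative: simply absent from the VCF
        drawn = _draw_characteristics(TP_CLASS, profile.model, rng)
        emit(
            VariantCall(
                chrom=v.chrom,
                pos=v.pos,
                ref=v.ref,
                alt=v.alt,
                qual=drawn["qual"],
                filter_status=PASS,
                tags=_tags_for(profile.dialect, drawn),
                pipeline_id=profile.pipeline_id,
            ),
            "TP",
            "",
        )

    def place_fp(maker) -> VariantCall:
        for _ in range(2000):
            if truth_indel_anchors and rng.random() < config.p_near:
                chrom, anchor = truth_indel_anchors[
                    int(rng.integers(len(truth_indel_anchors)))
                ]
                offset = int(rng.integers(1, config.near_window + 1))
                pos = anchor + offset * (1 if rng.random() < 0.5 else -1)
                if not 1 <= pos <= truth.contig_lengths[chrom]:
                    continue
            else:
                chrom, pos = _random_locus(config, rng)
            try:
                call = maker(reference, chrom, pos, rng)
            except ValueError:
                continue
            if call is None:
                continue
            call = normalize_call(call, reference)[0]
            start, end = call.ref_footprint
            if not truth.confident_regions.covers(call.chrom, start, end):
                continue
            if call.key in used_keys or not occupancy.free(call.chrom, start, end):
                continue
            occupancy.claim(call.chrom, start, end)
            used_keys.add(call.key)
            return call
        raise RuntimeError("could not place a false-positive call")

    for maker, count in ((_make_snp, profile.fp_snps), (_make_indel, profile.fp_indels)):
        for _ in range(count):
            fp_class = (
                DEFICIENT
                if rng.random() < config.fp_deficient_fraction
                else SURFEIT
            )
            placed = place_fp(maker)
            drawn = _draw_characteristics(fp_class, profile.model, rng)
            emit(
                VariantCall(
                    chrom=placed.chrom,
                    pos=placed.pos,
                    ref=placed.ref,
                    alt=placed.alt,
                    qual=drawn["qual"],
                    filter_status=PASS,
                    tags=_tags_for(profile.dialect, drawn),
                    pipeline_id=profile.pipeline_id,
                ),
                "FP",
                fp_class,
            )

    order = sorted(
        range(len(calls)),
        key=lambda i: (calls[i].chrom, calls[i].pos, calls[i].ref, calls[i].alt),
    )
    calls = [calls[i] for i in order]
    sidecar = pd.DataFrame([sidecar_rows[i] for i in order])
    return calls, sidecar


# ---------------------------------------------------------------------------
# on-disk fixtures


_INT_TAGS = {"DP", "AO", "SAF", "SAR", "RPL", "RPR"}


def write_vcf(
    path,
    calls: Sequence[VariantCall],
    contig_lengths: Mapping[str, int],
    filter_strings: Optional[Sequence[str]] = None,
) -> None:
    """Write calls as a plain-text VCF 4.2 with a well-formed header.

    INFO definitions are derived from the tags present in the calls
    (Integer for known count tags, Float otherwise).  ``filter_strings``
    overrides the FILTER column, e.g. to annotate failing filter names.
    """
    info_keys: List[str] = []
    for c in calls:
        for k in c.tags:
            if k not in info_keys:
                info_keys.append(k)
    any_fail = any(c.filter_status == FAIL for c in calls)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=varsieve\n")
        for chrom, length in contig_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        if any_fail:
            fh.write('##FILTER=<ID=FAIL,Description="Failed caller filters">\n')
        if filter_strings is not None:
            names = sorted(
                {n for fs in filter_strings for n in fs.split(";") if n != "PASS"}
            )
            for n in names:
                fh.write(f'##FILTER=<ID={n},Description="Hard filter {n}">\n')
        for key in info_keys:
            vtype = "Integer" if key in _INT_TAGS else "Float"
            fh.write(
                f'##INFO=<ID={key},Number=1,Type={vtype},Description="{key}">\n'
            )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, c in enumerate(calls):
            qual = "." if c.qual is None else f"{c.qual:.6g}"
            if filter_strings is not None:
                flt = filter_strings[i]
            elif c.filter_status == PASS:
                flt = "PASS"
            elif c.filter_status == FAIL:
                flt = "FAIL"
            else:
                flt = "."
            if c.tags:
                info = ";".join(f"{k}={v}" for k, v in c.tags.items())
            else:
                info = "."
            fh.write(
                f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t{qual}\t{flt}\t{info}\n"
            )


def write_fasta(path, reference: Mapping[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def make_fixture_suite(config: SimulationConfig, outdir) -> Dict[str, object]:
    """Generate and write the full fixture set; deterministic per seed.

    Writes reference FASTA (+ .fai), truth VCF, confident/ambiguous BEDs,
    and one VCF + sidecar label TSV per pipeline profile.  Returns a
    manifest of the written paths plus the in-memory truth set.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference = generate_reference(config)
    truth = plant_truth(reference, config)

    fasta = outdir / "reference.fasta"
    write_fasta(fasta, reference)
    pysam.faidx(str(fasta))

    truth_vcf = outdir / "truth.vcf"
    write_vcf(truth_vcf, truth.variants, truth.contig_lengths)
    confident_bed = outdir / "confident.bed"
    truth.confident_regions.to_bed(confident_bed)
    ambiguous_bed = outdir / "ambiguous.bed"
    truth.ambiguous_positions.to_bed(ambiguous_bed)

    manifest: Dict[str, object] = {
        "reference": fasta,
        "fai": Path(str(fasta) + ".fai"),
        "truth_vcf": truth_vcf,
        "confident_bed": confident_bed,
        "ambiguous_bed": ambiguous_bed,
        "pipelines": {},
        "truth": truth,
    }
    for profile in config.profiles:
        calls, sidecar = simulate_pipeline_vcf(truth, profile, config, reference)
        vcf_path = outdir / f"{profile.pipeline_id}.vcf"
        write_vcf(vcf_path, calls, truth.contig_lengths)
        labels_path = outdir / f"{profile.pipeline_id}.labels.tsv"
        sidecar.to_csv(labels_path, sep="\t", index=False)
        manifest["pipelines"][profile.pipeline_id] = {
            "vcf": vcf_path,
            "labels": labels_path,
        }
    return manifest
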