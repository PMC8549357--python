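import numpy as np
import pytest

import varsieve as vs


@pytest.fixture(scope="session")
def sim_config():
    return vs.SimulationConfig(
        seed=7,
        contigs={"chr1": 60_000},
        n_snps=150,
        n_indels=25,
        ambiguous_fraction=0.005,
        fp_deficient_fraction=0.85,
        p_near=0.5,
        near_window=10,
        profiles=[
            vs.PipelineProfile(
                "p1",
                vs.BUILTIN_DIALECTS["generic"],
                recall_snp=0.95,
                recall_indel=0.9,
                fp_snps=200,
                fp_indels=30,
            )
        ],
    )


@pytest.fixture(scope="session")
def sim_bundle(sim_config):
    """One fully simulated dataset shared across tests (read-only)."""
    reference = vs.generate_reference(sim_config)
    truth = vs.plant_truth(reference, sim_config)
    profile = sim_config.profiles[0]
    calls, sidecar = vs.simulate_pipeline_vcf(truth, profile, sim_config, reference)
    labeled, metrics = vs.compare(calls, truth, profile.dialect)
    return {
        "config": sim_config,
        "reference": reference,
        "truth": truth,
        "profile": profile,
        "calls": calls,
        "sidecar": sidecar,
        "labeled": labeled,
        "metrics": metrics,
    }


@pytest.fixture(scope="session")
def fixture_dir(sim_config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixtures")
    manifest = vs.make_fixture_suite(sim_config, outdir)
    return manifest


def write_vcf_text(path, body, contigs=(("chr1", 100000),), info_defs=()):
    """Write a minimal VCF file from raw data lines."""
    lines = ["##fileformat=VCFv4.2"]
    for name, length in contigs:
        lines.append(f"##contig=<ID={name},length={length}>")
    default_infos = [
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="depth">',
        '##INFO=<ID=AO,Number=A,Type=Integer,Description="alt obs">',
        '##INFO=<ID=QD,Number=1,Type=Float,Description="qual by depth">',
        '##INFO=<ID=SAF,Number=1,Type=Integer,Description="alt fwd">',
        '##INFO=<ID=SAR,Number=1,Type=Integer,Description="alt rev">',
        '##FILTER=<ID=q10,Description="low quality">',
    ]
    lines.extend(default_infos)
    lines.extend(info_defs)
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    lines.extend(line for line in body.strip().splitlines() if line.strip())
    path.write_text("\n".join(lines) + "\n")
    return path


def make_labeled(
    pos,
    label="FP",
    var_class=vs.VarClass.SNP,
    chrom="chr1",
    ref=None,
    alt=None,
    site_alt_count=1,
    mnp_derived=False,
    **characteristics,
):
    """Construct a LabeledCall with explicit characteristic values."""
    if var_class is vs.VarClass.SNP:
        ref = ref or "A"
        alt = alt or "G"
    elif var_class is vs.VarClass.INS:
        ref = ref or "A"
        alt = alt or "AT"
    elif var_class is vs.VarClass.DEL:
        ref = ref or "AT"
        alt = alt or "A"
    call = vs.VariantCall(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        qual=characteristics.get("qual"),
        filter_status="PASS",
        site_alt_count=site_alt_count,
        mnp_derived=mnp_derived,
    )
    chars = vs.CallCharacteristics(**characteristics)
    in_char = site_alt_count == 1 and not mnp_derived
    return vs.LabeledCall(call, chars, label, in_char)


def random_labeled_calls(rng, n=500):
    """Random labeled calls with randomly missing characteristics.

    Positions are random and the distance characteristics are computed
    from the actual call geometry, so proximity-filter invariants hold.
    """
    positions = sorted(rng.choice(np.arange(1, 40 * n), size=n, replace=False))
    out = []
    for pos in positions:
        chars = {}
        for name, low, high in [
            ("qual", 0, 100),
            ("qd", 0, 10),
            ("vaf", 0, 1),
            ("depth", 0, 50),
            ("alt_reads", 0, 50),
            ("strand_min_pct", 0, 50),
            ("direction_min_pct", 0, 50),
        ]:
            if rng.random() < 0.8:
                chars[name] = float(rng.uniform(low, high))
        label = "FP" if rng.random() < 0.4 else "TP"
        var_class = vs.VarClass.SNP if rng.random() < 0.8 else vs.VarClass.INS
        out.append(make_labeled(pos=int(pos), label=label, var_class=var_class, **chars))
    dists = vs.distances_to_nearest([lc.call for lc in out])
    for lc, (d_snp, d_indel) in zip(out, dists):
        lc.characteristics.dist_snp = d_snp
        lc.characteristics.dist_indel = d_indel
    return out
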