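"""Shared fixtures: toy VCF builders and cached simulated panels."""

from __future__ import annotations

import numpy as np
import pytest

from sweepscan.synthetic_data import SweepSimParams, simulate_sweep_panel

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=1,length=100000000>\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_toy_vcf(path, samples, records):
    """Write a VCF from (chrom, pos, ref, alt, [genotype strings]) records."""
    lines = [VCF_HEADER.rstrip("\n")]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    for chrom, pos, ref, alt, gts in records:
        lines.append(
            f"{chrom}\t{pos}\t{chrom}:{pos}\t{ref}\t{alt}\t.\t.\t.\tGT\t" + "\t".join(gts)
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def write_filter_toy_vcf(path):
    """100-site toy panel: 85 clean, 7 triallelic, 5 MAF=0, 3 high-missing.

    20 diploid samples; the failing site classes do not overlap, so exactly
    85 sites survive the default filters.
    """
    n_samples = 20
    samples = [f"S{i + 1:02d}" for i in range(n_samples)]
    records = []
    kinds = ["clean"] * 85 + ["triallelic"] * 7 + ["low_maf"] * 5 + ["missing"] * 3
    rng = np.random.default_rng(7)
    rng.shuffle(kinds)
    for i, kind in enumerate(kinds):
        pos = 1000 * (i + 1)
        alt = "C"
        gts = ["0/0"] * n_samples
        if kind == "clean":
            # two het carriers: MAF 2/40 = 0.05 >= 0.01, no missing
            gts[0] = "0/1"
            gts[1] = "0/1"
        elif kind == "triallelic":
            alt = "C,G"
            gts[0] = "0/1"
            gts[1] = "0/2"
        elif kind == "low_maf":
            pass  # all homozygous reference: MAF 0 < 0.01
        elif kind == "missing":
            gts[0] = "0/1"
            gts[1] = "./."
            gts[2] = "./."
            gts[3] = "./."  # missing rate 3/20 = 0.15 > 0.1
        records.append(("1", pos, "A", alt, gts))
    write_toy_vcf(path, samples, records)
    pops = path.parent / "filter_toy.pops.tsv"
    pops.write_text("".join(f"{s}\tpopA\n" for s in samples))
    return path, pops


@pytest.fixture
def filter_toy(tmp_path):
    return write_filter_toy_vcf(tmp_path / "toy100.vcf")


@pytest.fixture
def toy_vcf(tmp_path):
    def make(samples, records, name="toy.vcf"):
        return write_toy_vcf(tmp_path / name, samples, records)

    return make


@pytest.fixture(scope="session")
def sweep_panel_seed1():
    """Default-parameter sweep panel (seed 1), shared across tests."""
    haps, truth, _ = simulate_sweep_panel(SweepSimParams(seed=1))
    return haps, truth


@pytest.fixture(scope="session")
def small_panel_seed3():
    """A smaller sweep panel for I/O round-trip tests."""
    params = SweepSimParams(
        n_target_samples=20, n_ref_samples=20, n_sites=2_000, seed=3
    )
    haps, truth, _ = simulate_sweep_panel(params)
    return haps, truth
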