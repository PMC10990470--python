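"""Two-population synthetic data with planted sweeps and admixture.

The sweep simulator emits phased haplotypes for a diverged target/reference
population pair.  The neutral background is site-independent: each site has
an ancestral frequency drawn from a truncated U-shaped spectrum, and the two
population frequencies are obtained by independent Balding–Nichols drift
around it, with the per-branch drift coefficient equal to the requested
background F_ST (for two populations each drifted by F from a common
ancestor, the ratio-of-sums Weir–Cockerham estimator has expectation F in
the large-sample limit).  A hard sweep is planted by copying one founder
haplotype into a fraction of target haplotypes around the core position,
with per-site copy probability decaying exponentially with distance, which
produces both an allele-frequency differential and extended haplotype
homozygosity.

The admixture simulator draws allele-frequency panels for a (target; refA,
refB) trio under Balding–Nichols drift, with the target formed either as an
alpha-mixture of the drifted reference frequencies or by pure drift from
the refA branch, providing signed ground truth for f3 testing.

All outputs are deterministic functions of the seed; the background and the
sweep use separate RNG streams so a no-sweep run with the same seed shares
its neutral background with the swept run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import betainc, betaincinv

from sweepscan._errors import ValidationError
from sweepscan.genotype_io import (
    GenotypeMatrix,
    HaplotypeSet,
    make_site_table,
    write_vcf,
)

NUCLEOTIDES = np.array(list("ACGT"))


@dataclass
class SweepSimParams:
    """Study conditions for the two-population sweep panel."""

    n_target_samples: int = 50
    n_ref_samples: int = 50
    n_sites: int = 10_000
    chrom_length_bp: int = 30_000_000
    chrom: str = "1"
    # (alpha, beta, lo, hi) of the truncated-Beta ancestral frequency spectrum
    mu_sfs: tuple[float, float, float, float] = (0.5, 0.5, 0.02, 0.98)
    sweep_pos_bp: int = 15_000_000
    sweep_freq_target: float = 0.9
    sweep_halo_bp: int = 200_000
    divergence_fst: float = 0.1
    seed: int = 0
    target_name: str = "target"
    ref_name: str = "reference"

    def validate(self) -> None:
        if not (0.0 <= self.sweep_freq_target <= 1.0):
            raise ValidationError("sweep_freq_target must be in [0, 1]")
        if not (0.0 <= self.divergence_fst < 0.5):
            raise ValidationError("divergence_fst must be in [0, 0.5)")
        if self.sweep_freq_target > 0 and not (
            1 <= self.sweep_pos_bp <= self.chrom_length_bp
        ):
            raise ValidationError(
                f"sweep_pos_bp {self.sweep_pos_bp} outside chromosome "
                f"[1, {self.chrom_length_bp}]"
            )
        if self.n_sites < 2 or self.n_sites > self.chrom_length_bp:
            raise ValidationError("n_sites must be in [2, chrom_length_bp]")
        a, b, lo, hi = self.mu_sfs
        if not (0.0 <= lo < hi <= 1.0) or a <= 0 or b <= 0:
            raise ValidationError("invalid mu_sfs specification")


@dataclass
class SweepTruth:
    """Simulator ground truth used by recovery tests and the demo report."""

    core_snp_id: str | None
    core_pos_bp: int | None
    carrier_haplotypes: list[int]
    realized_core_freq: dict[str, float]
    admixture_alpha: float | None = None
    # per-population generating (pre-sampling) frequencies; arrays, not serialized
    generating_freq: dict[str, np.ndarray] | None = field(default=None, repr=False)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = asdict(self)
        payload.pop("generating_freq", None)
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return path


def _truncated_beta(
    rng: np.random.Generator, a: float, b: float, lo: float, hi: float, size: int
) -> np.ndarray:
    """Inverse-CDF sampling of a Beta(a, b) truncated to [lo, hi]."""
    u = rng.uniform(betainc(a, b, lo), betainc(a, b, hi), size=size)
    return betaincinv(a, b, u)


def _balding_nichols(
    rng: np.random.Generator, p0: np.ndarray, f: float
) -> np.ndarray:
    """Drift population frequencies around p0 with coefficient f."""
    if f <= 0.0:
        return p0.copy()
    ratio = (1.0 - f) / f
    return rng.beta(np.maximum(p0 * ratio, 1e-12), np.maximum((1.0 - p0) * ratio, 1e-12))


def _draw_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """n distinct sorted positions in [1, length], uniform."""
    pool = np.unique(rng.integers(1, length + 1, size=int(n * 1.2) + 16))
    while len(pool) < n:
        pool = np.unique(
            np.concatenate([pool, rng.integers(1, length + 1, size=n)])
        )
    pick = rng.choice(len(pool), size=n, replace=False)
    return np.sort(pool[pick])


def simulate_sweep_panel(
    params: SweepSimParams, out_dir: str | Path | None = None
) -> tuple[HaplotypeSet, SweepTruth, dict[str, Path] | None]:
    """Simulate the two-population phased panel with an optional planted sweep.

    Returns the haplotype set, the ground truth, and (when ``out_dir`` is
    given) the paths of the emitted VCF, population file, genetic-map file
    and truth JSON.
    """
    params.validate()
    ss = np.random.SeedSequence(params.seed)
    bg_seq, sweep_seq = ss.spawn(2)
    rng_bg = np.random.default_rng(bg_seq)
    rng_sw = np.random.default_rng(sweep_seq)

    m = params.n_sites
    pos = _draw_positions(rng_bg, m, params.chrom_length_bp)
    a, b, lo, hi = params.mu_sfs
    p0 = _truncated_beta(rng_bg, a, b, lo, hi, m)
    p_t = _balding_nichols(rng_bg, p0, params.divergence_fst)
    p_r = _balding_nichols(rng_bg, p0, params.divergence_fst)

    n_hap_t = 2 * params.n_target_samples
    n_hap_r = 2 * params.n_ref_samples
    H_t = (rng_bg.random((n_hap_t, m)) < p_t).astype(np.uint8)
    H_r = (rng_bg.random((n_hap_r, m)) < p_r).astype(np.uint8)

    ref_idx = rng_bg.integers(0, 4, size=m)
    alt_off = rng_bg.integers(1, 4, size=m)
    ref_allele = NUCLEOTIDES[ref_idx]
    alt_allele = NUCLEOTIDES[(ref_idx + alt_off) % 4]

    core: int | None = None
    carriers: list[int] = []
    if params.sweep_freq_target > 0:
        core = int(np.argmin(np.abs(pos - params.sweep_pos_bp)))
        founder = int(rng_sw.integers(0, n_hap_t))
        # the sweep always acts on the alternate allele at the core
        H_t[founder, core] = 1
        n_carriers = int(round(params.sweep_freq_target * n_hap_t))
        n_carriers = max(1, n_carriers)
        others = np.delete(np.arange(n_hap_t), founder)
        extra = rng_sw.choice(others, size=n_carriers - 1, replace=False)
        carrier_arr = np.sort(np.concatenate([[founder], extra]))
        halo = np.abs(pos - pos[core]) <= params.sweep_halo_bp
        widx = np.flatnonzero(halo)
        copy_p = np.exp(-np.abs(pos[widx] - pos[core]) / float(params.sweep_halo_bp))
        founder_row = H_t[founder, widx].copy()
        copy_mask = rng_sw.random((len(carrier_arr), len(widx))) < copy_p
        block = H_t[np.ix_(carrier_arr, widx)]
        H_t[np.ix_(carrier_arr, widx)] = np.where(copy_mask, founder_row, block)
        carriers = [int(i) for i in carrier_arr]

    sites = make_site_table(
        [params.chrom] * m, pos, ref_allele, alt_allele
    )
    samples_t = [f"T{i + 1:04d}" for i in range(params.n_target_samples)]
    samples_r = [f"R{i + 1:04d}" for i in range(params.n_ref_samples)]
    pop_of = {s: params.target_name for s in samples_t}
    pop_of.update({s: params.ref_name for s in samples_r})
    haps = HaplotypeSet(
        sites=sites,
        haplotypes=np.concatenate([H_t, H_r], axis=0),
        sample_of_hap=[s for s in samples_t + samples_r for _ in range(2)],
        pop_of=pop_of,
    )
    truth = SweepTruth(
        core_snp_id=None if core is None else str(sites["snp_id"].iloc[core]),
        core_pos_bp=None if core is None else int(pos[core]),
        carrier_haplotypes=carriers,
        realized_core_freq={
            params.target_name: float(H_t[:, core].mean()) if core is not None else float("nan"),
            params.ref_name: float(H_r[:, core].mean()) if core is not None else float("nan"),
        },
        generating_freq={params.target_name: p_t, params.ref_name: p_r},
    )

    paths: dict[str, Path] | None = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        vcf_path = write_vcf(haps, out_dir / "panel.vcf")
        pop_path = out_dir / "panel.pops.tsv"
        pop_path.write_text(
            "".join(f"{s}\t{pop_of[s]}\n" for s in samples_t + samples_r)
        )
        map_path = out_dir / "panel.map.tsv"
        map_path.write_text(
            "".join(
                f"{params.chrom}\t{p}\t{p * 1e-6:.8f}\n" for p in pos
            )
        )
        truth_path = truth.to_json(out_dir / "truth.json")
        paths = {
            "vcf": vcf_path,
            "pops": pop_path,
            "map": map_path,
            "truth": truth_path,
        }
    return haps, truth, paths


# ---------------------------------------------------------------------------
# admixture trio


@dataclass
class AdmixSimParams:
    """Study conditions for the (target; refA, refB) admixture trio."""

    n_snps: int = 50_000
    p0_sfs: tuple[float, float, float, float] = (0.5, 0.5, 0.02, 0.98)
    f_a: float = 0.1
    f_b: float = 0.1
    f_c: float = 0.01
    alpha: float | None = 0.5  # None => pure drift from the refA branch
    n_target: int = 20
    n_ref_a: int = 20
    n_ref_b: int = 20
    spacing_bp: int = 1_000
    chrom: str = "1"
    seed: int = 0

    def validate(self) -> None:
        for name, f in (("f_a", self.f_a), ("f_b", self.f_b), ("f_c", self.f_c)):
            if not (0.0 < f < 1.0):
                raise ValidationError(f"{name} must be in (0, 1), got {f}")
        if self.alpha is not None and not (0.0 <= self.alpha <= 1.0):
            raise ValidationError("alpha must be in [0, 1] or None")
        if min(self.n_target, self.n_ref_a, self.n_ref_b) < 1:
            raise ValidationError("sample sizes must be positive")


@dataclass
class AdmixtureTrioResult:
    """Genotypes, derived allele counts, and generating-frequency truth."""

    genotypes: GenotypeMatrix
    counts: dict[str, np.ndarray]  # pop -> (n_sites, 2) [n_alleles, alt]
    truth: dict[str, np.ndarray | float | None] = field(default_factory=dict)


def simulate_admixture_trio(params: AdmixSimParams) -> AdmixtureTrioResult:
    """Draw the trio's genotype panel under Balding–Nichols drift.

    refA and refB drift independently from the ancestral frequency with
    coefficients f_a and f_b; the target is the alpha-mixture of the two
    drifted frequencies (or, when ``alpha`` is None, the refA frequency)
    further drifted by f_c.  Diploid dosages are binomial draws at the
    stated sample sizes.
    """
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    m = params.n_snps
    a, b, lo, hi = params.p0_sfs
    p0 = _truncated_beta(rng, a, b, lo, hi, m)
    p_a = _balding_nichols(rng, p0, params.f_a)
    p_b = _balding_nichols(rng, p0, params.f_b)
    if params.alpha is None:
        p_mix = p_a
    else:
        p_mix = params.alpha * p_a + (1.0 - params.alpha) * p_b
    p_c = _balding_nichols(rng, p_mix, params.f_c)

    pops = {
        "target": (params.n_target, p_c),
        "refA": (params.n_ref_a, p_a),
        "refB": (params.n_ref_b, p_b),
    }
    pos = params.spacing_bp * (np.arange(m, dtype=np.int64) + 1)
    sites = make_site_table(
        [params.chrom] * m,
        pos,
        ["A"] * m,
        ["C"] * m,
    )
    samples: list[str] = []
    pop_of: dict[str, str] = {}
    blocks: list[np.ndarray] = []
    counts: dict[str, np.ndarray] = {}
    for prefix, (pop, (n, p)) in zip("TAB", pops.items()):
        names = [f"{prefix}{i + 1:04d}" for i in range(n)]
        dos = rng.binomial(2, p, size=(n, m)).astype(np.int8)
        samples.extend(names)
        pop_of.update({s: pop for s in names})
        blocks.append(dos)
        counts[pop] = np.column_stack(
            [np.full(m, 2 * n, dtype=np.int64), dos.sum(axis=0, dtype=np.int64)]
        )
    gm = GenotypeMatrix(
        sites=sites,
        samples=samples,
        dosage=np.concatenate(blocks, axis=0),
        pop_of=pop_of,
    )
    truth = {
        "p0": p0,
        "p_refA": p_a,
        "p_refB": p_b,
        "p_mix": p_mix,
        "p_target": p_c,
        "alpha": params.alpha,
    }
    return AdmixtureTrioResult(genotypes=gm, counts=counts, truth=truth)


def synthetic_gene_grid(
    chrom: str,
    chrom_length_bp: int,
    spacing_bp: int = 250_000,
    gene_length_bp: int = 20_000,
) -> pd.DataFrame:
    """Synthetic deterministic gene annotation: a regular grid of gene models.

    Used by the demo so that cluster annotation can be exercised without an
    external GFF; IDs are SYNGENE_<k> and intervals are 1-based inclusive.
    """
    starts = np.arange(spacing_bp, chrom_length_bp - gene_length_bp, spacing_bp)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + gene_length_bp - 1,
            "gene_id": [f"SYNGENE_{i + 1:04d}" for i in range(len(starts))],
        }
    )
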