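"""Constituent selection statistics: Weir–Cockerham F_ST, XP-EHH, dSAF.

F_ST is the Weir & Cockerham (1984) two-population moment estimator
theta-hat = a / (a + b + c) built from the among-population (a), among-
individual (b) and within-individual (c) variance components.  Because the
interface takes allele counts rather than genotypes, the observed
heterozygosity entering b and c is replaced by its random-union-of-gametes
expectation 2p(1-p) * n_al/(n_al - 1); fixed differences still return
exactly 1 and negative estimates are retained unclipped.

EHH at a core SNP is the probability that two random haplotypes from the
population are identical over the interval from the core out to a flanking
SNP; following the cross-population convention it is computed over all
haplotypes without partitioning by core allele, equals 1 at distance zero,
and the walk stops once EHH falls below a cutoff (default 0.05).  iHH is
the trapezoidal integral of EHH over genetic distance summed over both
sides, with integration terminating at gaps larger than ``max_gap_bp``
(default 200 kb).  XP-EHH is ln(iHH_target) - ln(iHH_reference) per core
SNP; dSAF is the signed alt-allele frequency difference target minus
reference.  Standardization is a genome-wide z-score with sample (n-1)
standard deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numba
import numpy as np

from sweepscan._errors import DataError, ValidationError
from sweepscan.genotype_io import HaplotypeSet

EHH_CUTOFF_DEFAULT = 0.05
MAX_GAP_BP_DEFAULT = 200_000


@dataclass
class SiteStatTrack:
    """A per-SNP statistic vector keyed by SNP ID (``chrom:pos``).

    Undefined values are NaN, never silently zero.
    """

    snp_ids: np.ndarray
    values: np.ndarray
    stat_name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.snp_ids.shape != self.values.shape:
            raise ValidationError("snp_ids and values must have equal length")

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)


@dataclass
class EHHCurve:
    """One side of an EHH decay curve anchored at a core SNP."""

    snp_id: str
    side: str  # "left" | "right"
    indices: np.ndarray  # site indices, starting at the core
    distances: np.ndarray  # bp offsets from the core (>= 0)
    ehh: np.ndarray

    def __post_init__(self) -> None:
        if self.ehh[0] != 1.0:
            raise ValidationError("EHH curve must start at 1 at the core")


# ---------------------------------------------------------------------------
# F_ST


def _as_counts(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    counts = np.asarray(counts)
    if counts.ndim != 2 or counts.shape[1] != 2:
        raise ValidationError("counts must have shape (n_sites, 2): [n_alleles, alt]")
    return counts[:, 0].astype(float), counts[:, 1].astype(float)


def wc_components(
    counts_a: np.ndarray, counts_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir–Cockerham variance components (a, b, c) per site, two populations.

    Sample sizes are diploid-equivalent (allele count / 2); heterozygosity
    uses the random-union-of-gametes expectation.  Sites where either
    population has fewer than two alleles sampled, or where the pooled mean
    sample size is 1, yield NaN components.
    """
    nal_a, alt_a = _as_counts(counts_a)
    nal_b, alt_b = _as_counts(counts_b)
    if nal_a.shape != nal_b.shape:
        raise ValidationError("mismatched site lists between populations")
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = alt_a / nal_a
        p2 = alt_b / nal_b
        h1 = 2.0 * p1 * (1.0 - p1) * nal_a / (nal_a - 1.0)
        h2 = 2.0 * p2 * (1.0 - p2) * nal_b / (nal_b - 1.0)
        n1 = nal_a / 2.0
        n2 = nal_b / 2.0
        r = 2.0
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (
            nbar
            / nc
            * (
                s2
                - (pbar * (1.0 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0)
                / (nbar - 1.0)
            )
        )
        b = (
            nbar
            / (nbar - 1.0)
            * (
                pbar * (1.0 - pbar)
                - s2 * (r - 1.0) / r
                - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
            )
        )
        c = hbar / 2.0
    bad = (nal_a < 2) | (nal_b < 2) | (nbar <= 1.0)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def fst_weir_cockerham(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    snp_ids: np.ndarray | None = None,
) -> SiteStatTrack:
    """Per-site Weir–Cockerham theta-hat between two populations.

    Sites monomorphic across both populations are undefined (NaN);
    negative estimates are retained so downstream ranks are unaffected
    by clipping.
    """
    a, b, c = wc_components(counts_a, counts_b)
    denom = a + b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.where(denom != 0.0, a / denom, np.nan)
    if snp_ids is None:
        snp_ids = np.array([f"site{i}" for i in range(len(theta))], dtype=object)
    return SiteStatTrack(
        snp_ids=np.asarray(snp_ids, dtype=object),
        values=theta,
        stat_name="FST",
        params={"estimator": "weir_cockerham_1984"},
    )


def fst_genome_wide(counts_a: np.ndarray, counts_b: np.ndarray) -> float:
    """Ratio-of-sums genome-wide Weir–Cockerham F_ST."""
    a, b, c = wc_components(counts_a, counts_b)
    ok = ~np.isnan(a)
    denom = float(np.sum(a[ok] + b[ok] + c[ok]))
    if denom == 0.0:
        raise DataError("no polymorphic sites for genome-wide F_ST")
    return float(np.sum(a[ok]) / denom)


# ---------------------------------------------------------------------------
# EHH / iHH


def _hap_matrix(haps: HaplotypeSet | np.ndarray) -> np.ndarray:
    if isinstance(haps, HaplotypeSet):
        return haps.haplotypes
    return np.asarray(haps, dtype=np.uint8)


def ehh_at_core(
    haps: HaplotypeSet | np.ndarray,
    core_index: int,
    ehh_cutoff: float = EHH_CUTOFF_DEFAULT,
    positions: np.ndarray | None = None,
) -> tuple[EHHCurve, EHHCurve]:
    """EHH decay curves left and right of a core SNP.

    EHH(d) = sum_h C(n_h, 2) / C(n, 2) where n_h counts haplotypes sharing
    an identical sequence over [core, core +/- d] (core allele included for
    d >= 1; EHH(0) = 1 by convention).  Each side is evaluated at successive
    SNPs outward until EHH drops below ``ehh_cutoff`` (that terminal
    sub-cutoff point is kept, so iHH integrates down through it) or the
    chromosome end is reached.
    """
    H = _hap_matrix(haps)
    n = H.shape[0]
    if n < 2:
        raise ValidationError("EHH requires at least two haplotypes")
    m = H.shape[1]
    if not (0 <= core_index < m):
        raise ValidationError(f"core index {core_index} out of range [0, {m})")
    if positions is None:
        if isinstance(haps, HaplotypeSet):
            positions = haps.sites["pos"].to_numpy()
        else:
            positions = np.arange(m, dtype=np.int64)
    if isinstance(haps, HaplotypeSet):
        chroms = haps.sites["chrom"].to_numpy()
        core_chrom = chroms[core_index]
    else:
        chroms = None
        core_chrom = None
    snp_id = (
        str(haps.sites["snp_id"].iloc[core_index])
        if isinstance(haps, HaplotypeSet)
        else f"site{core_index}"
    )

    denom = n * (n - 1)
    curves = []
    for side, step in (("left", -1), ("right", 1)):
        idx = [core_index]
        dist = [0]
        ehh_vals = [1.0]
        _, groups = np.unique(H[:, core_index], return_inverse=True)
        j = core_index + step
        while 0 <= j < m:
            if chroms is not None and chroms[j] != core_chrom:
                break
            keys = groups.astype(np.int64) * 2 + H[:, j]
            _, groups, counts = np.unique(keys, return_inverse=True, return_counts=True)
            num = int(np.sum(counts * (counts - 1)))
            e = num / denom
            idx.append(j)
            dist.append(int(abs(positions[j] - positions[core_index])))
            ehh_vals.append(e)
            if e < ehh_cutoff:
                break
            j += step
        curves.append(
            EHHCurve(
                snp_id=snp_id,
                side=side,
                indices=np.asarray(idx, dtype=np.int64),
                distances=np.asarray(dist, dtype=np.int64),
                ehh=np.asarray(ehh_vals, dtype=float),
            )
        )
    return curves[0], curves[1]


def ihh(
    left: EHHCurve,
    right: EHHCurve,
    positions: np.ndarray,
    cm: np.ndarray,
    max_gap_bp: int = MAX_GAP_BP_DEFAULT,
) -> float:
    """Integrated EHH: trapezoid over genetic distance, both sides summed.

    Physical gaps larger than ``max_gap_bp`` between successive curve
    points terminate integration on that side.
    """
    total = 0.0
    for curve in (left, right):
        idx = curve.indices
        for k in range(len(idx) - 1):
            gap = abs(int(positions[idx[k + 1]]) - int(positions[idx[k]]))
            if gap > max_gap_bp:
                break
            dcm = abs(float(cm[idx[k + 1]]) - float(cm[idx[k]]))
            total += 0.5 * (curve.ehh[k] + curve.ehh[k + 1]) * dcm
    return total


@numba.njit(cache=True)
def _ihh_scan_kernel(H, pos, cm, cutoff, max_gap):  # pragma: no cover - jit
    n_hap, m = H.shape
    out = np.zeros(m, dtype=np.float64)
    denom = float(n_hap * (n_hap - 1))
    groups = np.empty(n_hap, dtype=np.int64)
    newg = np.empty(n_hap, dtype=np.int64)
    label = np.empty(2 * n_hap + 2, dtype=np.int64)
    for core in range(m):
        total = 0.0
        for side in range(2):
            step = -1 if side == 0 else 1
            # group by the core allele (EHH(0) = 1 by convention)
            ng = 0
            label[0] = -1
            label[1] = -1
            for h in range(n_hap):
                k = np.int64(H[h, core])
                if label[k] < 0:
                    label[k] = ng
                    ng += 1
                groups[h] = label[k]
            prev_e = 1.0
            prev_pos = pos[core]
            prev_cm = cm[core]
            j = core + step
            while 0 <= j < m:
                gap = pos[j] - prev_pos
                if gap < 0:
                    gap = -gap
                if gap > max_gap:
                    break
                nkeys = 2 * ng
                for k in range(nkeys):
                    label[k] = -1
                ng2 = 0
                for h in range(n_hap):
                    k = groups[h] * 2 + np.int64(H[h, j])
                    if label[k] < 0:
                        label[k] = ng2
                        ng2 += 1
                    newg[h] = label[k]
                # pair-identity count from class sizes
                counts = np.zeros(ng2, dtype=np.int64)
                for h in range(n_hap):
                    counts[newg[h]] += 1
                num = 0
                for g in range(ng2):
                    num += counts[g] * (counts[g] - 1)
                e = num / denom
                dcm = cm[j] - prev_cm
                if dcm < 0:
                    dcm = -dcm
                total += 0.5 * (prev_e + e) * dcm
                if e < cutoff:
                    break
                for h in range(n_hap):
                    groups[h] = newg[h]
                ng = ng2
                prev_e = e
                prev_pos = pos[j]
                prev_cm = cm[j]
                j += step
        out[core] = total
    return out


def ihh_scan(
    haps: HaplotypeSet,
    ehh_cutoff: float = EHH_CUTOFF_DEFAULT,
    max_gap_bp: int = MAX_GAP_BP_DEFAULT,
) -> np.ndarray:
    """iHH at every SNP for one population, per chromosome."""
    H = np.ascontiguousarray(haps.haplotypes, dtype=np.uint8)
    if H.shape[0] < 2:
        raise ValidationError("iHH scan requires at least two haplotypes")
    pos = haps.sites["pos"].to_numpy(dtype=np.int64)
    cm = haps.sites["cm"].to_numpy(dtype=np.float64)
    out = np.empty(len(pos), dtype=float)
    chrom = haps.sites["chrom"].to_numpy()
    start = 0
    for c in dict.fromkeys(chrom):
        mask = chrom == c
        idx = np.flatnonzero(mask)
        out[idx] = _ihh_scan_kernel(
            np.ascontiguousarray(H[:, idx]),
            pos[idx],
            cm[idx],
            float(ehh_cutoff),
            float(max_gap_bp),
        )
        start += len(idx)
    return out


def xpehh(
    haps_target: HaplotypeSet,
    haps_ref: HaplotypeSet,
    ehh_cutoff: float = EHH_CUTOFF_DEFAULT,
    max_gap_bp: int = MAX_GAP_BP_DEFAULT,
) -> SiteStatTrack:
    """Raw XP-EHH = ln(iHH_target) - ln(iHH_reference) per core SNP.

    Positive values indicate longer haplotype homozygosity in the target.
    Sites where either iHH is zero are undefined.
    """
    ids_t = haps_target.sites["snp_id"].to_numpy()
    ids_r = haps_ref.sites["snp_id"].to_numpy()
    if len(ids_t) != len(ids_r) or not np.array_equal(ids_t, ids_r):
        raise ValidationError("target and reference haplotype sets must share sites")
    ihh_t = ihh_scan(haps_target, ehh_cutoff, max_gap_bp)
    ihh_r = ihh_scan(haps_ref, ehh_cutoff, max_gap_bp)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(
            (ihh_t > 0) & (ihh_r > 0), np.log(ihh_t) - np.log(ihh_r), np.nan
        )
    return SiteStatTrack(
        snp_ids=np.asarray(ids_t, dtype=object),
        values=values,
        stat_name="XPEHH",
        params={"ehh_cutoff": ehh_cutoff, "max_gap_bp": max_gap_bp},
    )


# ---------------------------------------------------------------------------
# dSAF and standardization


def delta_saf(
    freq_target: np.ndarray,
    freq_ref: np.ndarray,
    snp_ids: np.ndarray | None = None,
) -> SiteStatTrack:
    """Directional allele-frequency change, alt allele, target minus reference."""
    freq_target = np.asarray(freq_target, dtype=float)
    freq_ref = np.asarray(freq_ref, dtype=float)
    if freq_target.shape != freq_ref.shape:
        raise ValidationError("frequency vectors must be aligned")
    values = freq_target - freq_ref
    if snp_ids is None:
        snp_ids = np.array([f"site{i}" for i in range(len(values))], dtype=object)
    return SiteStatTrack(
        snp_ids=np.asarray(snp_ids, dtype=object),
        values=values,
        stat_name="dSAF",
        params={"convention": "alt_allele_target_minus_reference"},
    )


def standardize(track: SiteStatTrack) -> SiteStatTrack:
    """Genome-wide z-score of a track (sample sd, denominator n-1).

    Undefined input values stay undefined; the defined subset of the output
    has mean 0 and sd 1.
    """
    ok = track.defined()
    if int(ok.sum()) < 2:
        raise DataError(f"standardize({track.stat_name}): fewer than 2 defined values")
    x = track.values[ok]
    mu = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0.0 or not math.isfinite(sd):
        raise DataError(f"standardize({track.stat_name}): zero variance")
    z = np.full_like(track.values, np.nan)
    z[ok] = (x - mu) / sd
    return SiteStatTrack(
        snp_ids=track.snp_ids.copy(),
        values=z,
        stat_name=f"z{track.stat_name}",
        params={**track.params, "standardized": "sample_sd_n_minus_1"},
    )
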