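"""Population structure (PCA) and f3 admixture tests.

PCA follows the standard genotype-PCA recipe: per-site mean centering,
scaling by sqrt(p(1-p)) (Patterson normalization), mean imputation of
missing dosages, and eigendecomposition of the sample covariance; variance
fractions are normalized over the first 20 components.

The f3 statistic for a trio (target C; references A, B) is the genome-wide
mean of (c-a)(c-b) with the finite-sample heterozygosity correction for
the target, h_c/n_c with h_c = n_c c(1-c)/(n_c - 1), which makes the
per-site estimator unbiased for the population-frequency quantity.  A
significantly negative f3 indicates the target is admixed between lineages
related to the two references; strong drift in the target after admixture
pushes f3 upward and can mask the signal.  Standard errors come from a
weighted block jackknife over contiguous physical blocks (default 5 Mb)
with SNP-count weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from sweepscan._errors import DataError, ValidationError
from sweepscan.genotype_io import MISSING, GenotypeMatrix, allele_counts

Z_ADMIXTURE_DEFAULT = -3.0
BLOCK_SIZE_BP_DEFAULT = 5_000_000


@dataclass
class PCAResult:
    """Sample coordinates, eigenvalues, and normalized variance fractions."""

    samples: list[str]
    coords: np.ndarray  # (n_samples, n_components)
    eigenvalues: np.ndarray  # all retained eigenvalues, descending
    variance_fraction: np.ndarray  # normalized over the first 20 components


@dataclass
class F3Result:
    """One trio's genome-wide f3 estimate with jackknife uncertainty."""

    target: str
    ref_a: str
    ref_b: str
    f3_hat: float
    se: float
    z: float
    n_blocks: int
    n_snps: int
    admixture_signal: bool


def pca(gm: GenotypeMatrix, n_components: int = 10) -> PCAResult:
    """Genotype PCA with Patterson normalization and mean imputation."""
    if gm.n_samples < 3:
        raise ValidationError("PCA requires at least 3 samples")
    D = gm.dosage.astype(float)
    miss = gm.dosage == MISSING
    D[miss] = np.nan
    mu = np.nanmean(D, axis=0)
    inds = np.where(miss)
    D[inds] = mu[inds[1]]
    p = mu / 2.0
    poly = (p > 0.0) & (p < 1.0)
    if int(poly.sum()) < 2:
        raise DataError("PCA requires at least 2 polymorphic sites")
    X = (D[:, poly] - mu[poly]) / np.sqrt(p[poly] * (1.0 - p[poly]))
    m = X.shape[1]
    # eigendecomposition of the sample covariance via SVD of X
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    eigenvalues = s**2 / m
    nonzero = eigenvalues > 1e-12 * eigenvalues[0]
    # a single informative axis is legal (e.g. two internally identical
    # groups); only a fully degenerate matrix is an error
    if int(nonzero.sum()) < 1 or eigenvalues[0] <= 0:
        raise DataError("no nonzero eigenvalues")
    eigenvalues = eigenvalues[nonzero]
    U = U[:, nonzero]
    s = s[nonzero]
    k = min(n_components, len(eigenvalues))
    denom = float(eigenvalues[:20].sum())
    return PCAResult(
        samples=list(gm.samples),
        coords=U[:, :k] * s[:k],
        eigenvalues=eigenvalues,
        variance_fraction=eigenvalues / denom,
    )


# ---------------------------------------------------------------------------
# f3


def f3_statistic(
    counts_target: np.ndarray,
    counts_ref_a: np.ndarray,
    counts_ref_b: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site unbiased f3 values for (target; refA, refB).

    ``counts_*`` are (n_sites, 2) arrays of [n_alleles, alt_count].  Sites
    monomorphic across all three populations are dropped; the returned mask
    marks the retained sites.  Raises when the target has fewer than two
    sampled alleles at a retained site.
    """
    ct = np.asarray(counts_target, dtype=float)
    ca = np.asarray(counts_ref_a, dtype=float)
    cb = np.asarray(counts_ref_b, dtype=float)
    if not (ct.shape == ca.shape == cb.shape):
        raise ValidationError("count tables must be aligned")
    n_c, alt_c = ct[:, 0], ct[:, 1]
    n_a, alt_a = ca[:, 0], ca[:, 1]
    n_b, alt_b = cb[:, 0], cb[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        c = alt_c / n_c
        a = alt_a / n_a
        b = alt_b / n_b
    total_alt = alt_c + alt_a + alt_b
    total_n = n_c + n_a + n_b
    keep = (total_alt > 0) & (total_alt < total_n) & (n_a > 0) & (n_b > 0) & (n_c > 0)
    if np.any(n_c[keep] < 2):
        raise ValidationError("f3 requires at least 2 sampled target alleles per site")
    c, a, b, n_c = c[keep], a[keep], b[keep], n_c[keep]
    correction = c * (1.0 - c) / (n_c - 1.0)  # = h_c / n_c
    values = (c - a) * (c - b) - correction
    return values, keep


def block_jackknife(
    per_site_values: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    block_size_bp: int = BLOCK_SIZE_BP_DEFAULT,
) -> tuple[float, float, float]:
    """Weighted block jackknife (SNP-count weights) of a per-site mean.

    Blocks are contiguous physical windows of ``block_size_bp`` per
    chromosome.  Returns (estimate, se, z) where the estimate is the plain
    genome-wide mean; a degenerate zero-variance input is reported as
    se = 0 with z undefined (NaN).
    """
    x = np.asarray(per_site_values, dtype=float)
    chrom = np.asarray(chrom)
    pos = np.asarray(pos, dtype=np.int64)
    if not (len(x) == len(chrom) == len(pos)):
        raise ValidationError("values, chrom and pos must be aligned")
    block_key = pd.Series(
        [f"{c}:{(p - 1) // block_size_bp}" for c, p in zip(chrom, pos)]
    )
    groups = pd.DataFrame({"x": x, "block": block_key}).groupby("block", sort=False)
    sums = groups["x"].sum().to_numpy()
    sizes = groups["x"].size().to_numpy().astype(float)
    g = len(sums)
    if g < 10:
        raise DataError(
            f"only {g} non-empty blocks; use a smaller block size (need >= 10)"
        )
    n = float(sizes.sum())
    total = float(sums.sum())
    theta = total / n
    theta_minus = (total - sums) / (n - sizes)
    h = n / sizes
    tau = h * theta - (h - 1.0) * theta_minus
    theta_jack = g * theta - float(np.sum((1.0 - sizes / n) * theta_minus))
    var = float(np.sum((tau - theta_jack) ** 2 / (h - 1.0)) / g)
    se = float(np.sqrt(max(var, 0.0)))
    z = theta / se if se > 0 else float("nan")
    return theta, se, z


def f3_trio_report(
    gm: GenotypeMatrix,
    trios: list[tuple[str, str, str]],
    block_size_bp: int = BLOCK_SIZE_BP_DEFAULT,
    z_threshold: float = Z_ADMIXTURE_DEFAULT,
) -> pd.DataFrame:
    """Genome-wide f3 with jackknife SE for each (target, refA, refB) trio.

    A trio is flagged as carrying an admixture signal when z < z_threshold
    (default -3).
    """
    populations = set(gm.pop_of.values())
    results: list[F3Result] = []
    for target, ref_a, ref_b in trios:
        for name in (target, ref_a, ref_b):
            if name not in populations:
                raise ValidationError(f"unknown population label {name!r}")
        ct = allele_counts(gm, target)
        ca = allele_counts(gm, ref_a)
        cb = allele_counts(gm, ref_b)
        values, keep = f3_statistic(ct, ca, cb)
        chrom = gm.sites["chrom"].to_numpy()[keep]
        pos = gm.sites["pos"].to_numpy()[keep]
        f3_hat, se, z = block_jackknife(values, chrom, pos, block_size_bp)
        n_blocks = len(
            {f"{c}:{(p - 1) // block_size_bp}" for c, p in zip(chrom, pos)}
        )
        results.append(
            F3Result(
                target=target,
                ref_a=ref_a,
                ref_b=ref_b,
                f3_hat=f3_hat,
                se=se,
                z=z,
                n_blocks=n_blocks,
                n_snps=int(keep.sum()),
                admixture_signal=bool(np.isfinite(z) and z < z_threshold),
            )
        )
    return pd.DataFrame([r.__dict__ for r in results])
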