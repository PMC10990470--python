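"""Composite selection signal: rank-combination, smoothing, clusters, genes.

Each constituent statistic is converted to fractional ranks r_i/(n+1),
mapped to standard-normal quantiles, and the k rank-z tracks are averaged
per SNP.  The mean is scaled by its own empirical standard deviation (or
analytically by 1/sqrt(k)) and converted to a one-sided -log10 p score,
the CSS.  Scores are averaged in centered 20 kb sliding windows, and a SNP
in the empirical top 0.1% of smoothed scores is declared significant only
when at least five other top-1% SNPs lie within a flanking span (default
+/- 500 kb); significant SNPs within that span of each other merge into
cluster regions, which are finally annotated with genes overlapping the
regions extended by +/- 500 kb.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import norm, rankdata

from sweepscan._errors import DataError, ValidationError
from sweepscan.genotype_io import chrom_sort_key, merge_by_snp_id
from sweepscan.selection_stats import SiteStatTrack

log = logging.getLogger(__name__)

WINDOW_BP_DEFAULT = 20_000
TOP_FRAC_DEFAULT = 0.001
FLANK_FRAC_DEFAULT = 0.01
MIN_FLANKERS_DEFAULT = 5
FLANK_SPAN_BP_DEFAULT = 500_000
GENE_FLANK_BP_DEFAULT = 500_000


@dataclass
class CSSResult:
    """Per-SNP composite selection signal scores and empirical thresholds."""

    sites: pd.DataFrame  # snp_id, chrom, pos (genome order)
    rank_z: dict[str, np.ndarray]
    mean_z: np.ndarray
    css: np.ndarray
    css_smoothed: np.ndarray | None = None
    thresholds: dict[str, float] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    @property
    def n_snps(self) -> int:
        return len(self.sites)

    def to_frame(self) -> pd.DataFrame:
        out = self.sites.copy()
        for name, z in self.rank_z.items():
            out[f"rank_z_{name}"] = z
        out["mean_z"] = self.mean_z
        out["css"] = self.css
        if self.css_smoothed is not None:
            out["css_smoothed"] = self.css_smoothed
        return out


@dataclass
class ClusterRegion:
    """A significant genomic interval (1-based inclusive member-SNP span)."""

    chrom: str
    start: int
    end: int
    member_snp_ids: list[str]
    n_top1_support: int
    genes: list[str] = field(default_factory=list)

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


# ---------------------------------------------------------------------------
# rank transforms and combination


def fractional_ranks(values: np.ndarray) -> np.ndarray:
    """Ascending fractional ranks r_i/(n+1) in (0, 1); ties share mean ranks.

    NaN inputs stay NaN and do not consume ranks.
    """
    values = np.asarray(values, dtype=float)
    ok = ~np.isnan(values)
    n = int(ok.sum())
    if n < 2:
        raise DataError("fractional_ranks requires at least 2 defined values")
    out = np.full(values.shape, np.nan)
    out[ok] = rankdata(values[ok], method="average") / (n + 1)
    return out


def rank_to_z(frac_ranks: np.ndarray) -> np.ndarray:
    """Standard-normal quantiles of fractional ranks (must lie in (0, 1))."""
    r = np.asarray(frac_ranks, dtype=float)
    ok = ~np.isnan(r)
    if np.any((r[ok] <= 0.0) | (r[ok] >= 1.0)):
        raise ValidationError("fractional ranks must lie strictly inside (0, 1)")
    out = np.full(r.shape, np.nan)
    out[ok] = norm.ppf(r[ok])
    return out


def css_combine(
    z_tracks: Mapping[str, np.ndarray],
    sites: pd.DataFrame,
    variance_mode: str = "empirical",
) -> CSSResult:
    """Combine aligned rank-z tracks into the raw CSS score.

    mean_z is the per-SNP average of the k tracks; its scale sigma-bar is
    the empirical sample sd of mean_z (default, self-calibrating when the
    constituents are correlated) or the analytic 1/sqrt(k) for independent
    constituents.  css = -log10(1 - Phi(mean_z / sigma-bar)).
    """
    if len(z_tracks) < 2:
        raise ValidationError("css_combine requires at least two tracks")
    arrays = []
    n = len(sites)
    for name, z in z_tracks.items():
        z = np.asarray(z, dtype=float)
        if len(z) != n:
            raise ValidationError(f"track {name!r} is not aligned with the site table")
        arrays.append(z)
    stack = np.vstack(arrays)
    if np.isnan(stack).any():
        raise ValidationError("css_combine requires fully defined aligned tracks")
    mean_z = stack.mean(axis=0)
    k = stack.shape[0]
    if variance_mode == "empirical":
        sigma = float(np.std(mean_z, ddof=1))
        if sigma == 0.0:
            raise DataError("mean_z has zero variance")
    elif variance_mode == "analytic":
        sigma = 1.0 / math.sqrt(k)
    else:
        raise ValidationError(f"unknown variance_mode {variance_mode!r}")
    # -log10 of the upper-tail p, computed in log space to keep precision
    css = -norm.logsf(mean_z / sigma) / math.log(10.0)
    return CSSResult(
        sites=sites.reset_index(drop=True),
        rank_z={name: arr for name, arr in zip(z_tracks, arrays)},
        mean_z=mean_z,
        css=css,
        params={"variance_mode": variance_mode, "sigma_bar": sigma, "k": k},
    )


def css_from_tracks(
    tracks: Sequence[SiteStatTrack],
    variance_mode: str = "empirical",
) -> CSSResult:
    """Full CSS path: merge by SNP ID, rank-transform each track, combine.

    SNPs undefined in any constituent are excluded (intersection semantics).
    """
    merged = merge_by_snp_id(tracks)
    value_cols = [c for c in merged.columns if c not in ("snp_id", "chrom", "pos")]
    ok = ~merged[value_cols].isna().any(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.info("css_from_tracks: dropped %d SNPs with undefined constituents", n_dropped)
    merged = merged.loc[ok].reset_index(drop=True)
    z_tracks = {
        c: rank_to_z(fractional_ranks(merged[c].to_numpy())) for c in value_cols
    }
    return css_combine(z_tracks, merged[["snp_id", "chrom", "pos"]], variance_mode)


# ---------------------------------------------------------------------------
# smoothing


def smooth_windows(
    css: CSSResult, window_bp: int = WINDOW_BP_DEFAULT, mode: str = "sliding"
) -> CSSResult:
    """Window-average the CSS scores per chromosome.

    ``sliding`` (default): per-SNP centered window, mean of css over SNPs
    within +/- window_bp/2 (inclusive).  ``tumbling``: disjoint windows of
    ``window_bp``; every member SNP receives the window mean.
    """
    pos = css.sites["pos"].to_numpy(dtype=np.int64)
    chrom = css.sites["chrom"].to_numpy()
    smoothed = np.empty(css.n_snps, dtype=float)
    half = window_bp / 2.0
    for c in dict.fromkeys(chrom):
        idx = np.flatnonzero(chrom == c)
        p = pos[idx]
        x = css.css[idx]
        if mode == "sliding":
            lo = np.searchsorted(p, p - half, side="left")
            hi = np.searchsorted(p, p + half, side="right")
            csum = np.concatenate([[0.0], np.cumsum(x)])
            smoothed[idx] = (csum[hi] - csum[lo]) / (hi - lo)
        elif mode == "tumbling":
            bins = (p - p.min()) // window_bp
            df = pd.DataFrame({"bin": bins, "x": x})
            smoothed[idx] = df.groupby("bin")["x"].transform("mean").to_numpy()
        else:
            raise ValidationError(f"unknown smoothing mode {mode!r}")
    out = CSSResult(
        sites=css.sites,
        rank_z=css.rank_z,
        mean_z=css.mean_z,
        css=css.css,
        css_smoothed=smoothed,
        thresholds=dict(css.thresholds),
        params={**css.params, "window_bp": window_bp, "smoothing": mode},
    )
    return out


# ---------------------------------------------------------------------------
# cluster calling


def call_clusters(
    css: CSSResult,
    top_frac: float = TOP_FRAC_DEFAULT,
    flank_frac: float = FLANK_FRAC_DEFAULT,
    min_flankers: int = MIN_FLANKERS_DEFAULT,
    flank_span_bp: int = FLANK_SPAN_BP_DEFAULT,
) -> list[ClusterRegion]:
    """Call significant cluster regions from smoothed CSS scores.

    The top ``top_frac`` (default 0.1%) and ``flank_frac`` (default 1%)
    sets are the ceil(frac * n) highest smoothed scores; their empirical
    cutoffs are recorded on ``css.thresholds``.  A top-0.1% SNP is
    significant iff at least ``min_flankers`` *other* top-1% SNPs lie
    within ``flank_span_bp`` on the same chromosome; significant SNPs
    within ``flank_span_bp`` of each other merge into one region spanning
    the member SNP positions.
    """
    if css.css_smoothed is None:
        raise ValidationError("call_clusters requires smoothed CSS (run smooth_windows)")
    n = css.n_snps
    if n < int(round(1.0 / top_frac)):
        raise DataError(
            f"only {n} SNPs; need at least {int(round(1.0 / top_frac))} for "
            f"top_frac={top_frac} (provide a larger input)"
        )
    k_top = math.ceil(top_frac * n)
    k_flank = math.ceil(flank_frac * n)
    order = np.argsort(-css.css_smoothed, kind="stable")
    top_idx = order[:k_top]
    flank_idx = order[:k_flank]
    css.thresholds["top"] = float(css.css_smoothed[order[k_top - 1]])
    css.thresholds["flank"] = float(css.css_smoothed[order[k_flank - 1]])
    css.params.update(
        {
            "top_frac": top_frac,
            "flank_frac": flank_frac,
            "min_flankers": min_flankers,
            "flank_span_bp": flank_span_bp,
        }
    )
    log.info(
        "cluster calling: n=%d, top cutoff %.4f (%d SNPs), flank cutoff %.4f (%d SNPs), "
        "flank span +/-%d bp",
        n,
        css.thresholds["top"],
        k_top,
        css.thresholds["flank"],
        k_flank,
        flank_span_bp,
    )

    pos = css.sites["pos"].to_numpy(dtype=np.int64)
    chrom = css.sites["chrom"].to_numpy()
    snp_ids = css.sites["snp_id"].to_numpy()
    flank_by_chrom: dict[str, np.ndarray] = {}
    for c in dict.fromkeys(chrom[flank_idx]):
        p = np.sort(pos[flank_idx[chrom[flank_idx] == c]])
        flank_by_chrom[c] = p

    significant: list[int] = []
    for i in top_idx:
        p = flank_by_chrom.get(chrom[i])
        if p is None:
            continue
        lo = np.searchsorted(p, pos[i] - flank_span_bp, side="left")
        hi = np.searchsorted(p, pos[i] + flank_span_bp, side="right")
        n_others = int(hi - lo) - 1  # exclude the SNP itself
        if n_others >= min_flankers:
            significant.append(int(i))
    if not significant:
        return []

    sig = sorted(significant, key=lambda i: (chrom_sort_key(chrom[i]), pos[i]))
    clusters: list[ClusterRegion] = []
    group: list[int] = [sig[0]]
    for i in sig[1:]:
        if chrom[i] == chrom[group[-1]] and pos[i] - pos[group[-1]] <= flank_span_bp:
            group.append(i)
        else:
            clusters.append(_make_cluster(group, chrom, pos, snp_ids, flank_by_chrom, flank_span_bp))
            group = [i]
    clusters.append(_make_cluster(group, chrom, pos, snp_ids, flank_by_chrom, flank_span_bp))
    return clusters


def _make_cluster(
    group: list[int],
    chrom: np.ndarray,
    pos: np.ndarray,
    snp_ids: np.ndarray,
    flank_by_chrom: dict[str, np.ndarray],
    flank_span_bp: int,
) -> ClusterRegion:
    c = chrom[group[0]]
    start = int(min(pos[i] for i in group))
    end = int(max(pos[i] for i in group))
    p = flank_by_chrom.get(c, np.empty(0, dtype=np.int64))
    lo = np.searchsorted(p, start - flank_span_bp, side="left")
    hi = np.searchsorted(p, end + flank_span_bp, side="right")
    return ClusterRegion(
        chrom=str(c),
        start=start,
        end=end,
        member_snp_ids=[str(snp_ids[i]) for i in group],
        n_top1_support=int(hi - lo),
    )


# ---------------------------------------------------------------------------
# gene annotation


def read_genes(path: str | Path) -> pd.DataFrame:
    """Read gene intervals from BED (0-based half-open) or GFF3 (gene rows).

    Returns a frame with 1-based inclusive ``start``/``end`` and ``gene_id``.
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _read_genes_gff3(path)
    return _read_genes_bed(path)


def _read_genes_bed(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if df.shape[1] < 3:
        raise ValidationError(f"BED file {path} needs at least 3 columns")
    out = pd.DataFrame(
        {
            "chrom": df[0].astype(str),
            "start": df[1].astype(int) + 1,  # BED is 0-based half-open
            "end": df[2].astype(int),
            "gene_id": (
                df[3].astype(str)
                if df.shape[1] >= 4
                else [f"gene{i + 1}" for i in range(len(df))]
            ),
        }
    )
    return out


def _read_genes_gff3(path: Path) -> pd.DataFrame:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows = []
    for feat in db.features_of_type("gene"):
        gene_id = (
            feat.attributes.get("Name", [None])[0]
            or feat.attributes.get("ID", [feat.id])[0]
        )
        rows.append((str(feat.seqid), int(feat.start), int(feat.end), gene_id))
    if not rows:
        raise DataError(f"no gene features found in {path}")
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


def annotate_clusters(
    clusters: Sequence[ClusterRegion],
    genes: pd.DataFrame,
    flank_bp: int = GENE_FLANK_BP_DEFAULT,
) -> list[ClusterRegion]:
    """Attach genes overlapping each cluster extended by ``flank_bp``.

    A gene overlaps when its 1-based inclusive interval intersects
    [start - flank_bp, end + flank_bp] (clamped at 1); the boundary is
    inclusive, so a gene ending exactly flank_bp upstream is included.
    """
    for col in ("chrom", "start", "end", "gene_id"):
        if col not in genes.columns:
            raise ValidationError(f"gene table missing column {col!r}")
    gene_chroms = set(genes["chrom"].astype(str))
    missing = sorted({c.chrom for c in clusters} - gene_chroms)
    if missing:
        raise ValidationError(
            "cluster chromosomes absent from gene annotation: " + ", ".join(missing)
        )
    trees: dict[str, IntervalTree] = {}
    for c, sub in genes.groupby("chrom", sort=False):
        trees[str(c)] = IntervalTree.from_tuples(
            (int(s), int(e) + 1, g)
            for s, e, g in zip(sub["start"], sub["end"], sub["gene_id"])
        )
    out: list[ClusterRegion] = []
    for cl in clusters:
        lo = max(1, cl.start - flank_bp)
        hi = cl.end + flank_bp
        hits = trees[cl.chrom].overlap(lo, hi + 1)
        found = sorted({iv.data for iv in hits})
        out.append(
            ClusterRegion(
                chrom=cl.chrom,
                start=cl.start,
                end=cl.end,
                member_snp_ids=list(cl.member_snp_ids),
                n_top1_support=cl.n_top1_support,
                genes=found,
            )
        )
    return out


def clusters_to_frame(clusters: Sequence[ClusterRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [c.chrom for c in clusters],
            "start": [c.start for c in clusters],
            "end": [c.end for c in clusters],
            "n_members": [len(c.member_snp_ids) for c in clusters],
            "n_top1_support": [c.n_top1_support for c in clusters],
            "member_snp_ids": [",".join(c.member_snp_ids) for c in clusters],
            "genes": [",".join(c.genes) for c in clusters],
        }
    )


def shared_genes(
    gene_sets: Mapping[str, pd.DataFrame | Sequence[str]],
) -> tuple[list[str], pd.DataFrame]:
    """Intersect per-population gene sets; tally shared genes per chromosome.

    Each value is either a frame with ``gene_id`` (and optionally ``chrom``)
    or a plain gene-ID sequence.  Returns the sorted shared IDs and a
    per-chromosome count/fraction table (empty when no chromosome
    information is available).
    """
    if len(gene_sets) < 2:
        raise ValidationError("shared_genes requires at least two gene sets")
    ids: list[set[str]] = []
    chrom_of: dict[str, str] = {}
    for value in gene_sets.values():
        if isinstance(value, pd.DataFrame):
            ids.append(set(value["gene_id"].astype(str)))
            if "chrom" in value.columns:
                for g, c in zip(value["gene_id"].astype(str), value["chrom"].astype(str)):
                    chrom_of.setdefault(g, c)
        else:
            ids.append(set(map(str, value)))
    common = sorted(set.intersection(*ids))
    if chrom_of:
        chroms = [chrom_of.get(g, "NA") for g in common]
        tally = (
            pd.Series(chroms).value_counts().rename_axis("chrom").reset_index(name="n_genes")
        )
        tally["fraction"] = tally["n_genes"] / max(len(common), 1)
        tally = tally.sort_values(
            "chrom", key=lambda s: s.map(chrom_sort_key)
        ).reset_index(drop=True)
    else:
        tally = pd.DataFrame(columns=["chrom", "n_genes", "fraction"])
    return common, tally
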