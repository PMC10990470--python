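"""Genotype/haplotype containers, VCF I/O, site filters and track merging.

Coordinates are 1-based (VCF convention) throughout; BED output converts to
0-based half-open at the boundary.  Missing genotype dosages are encoded as
-1, never 0.  The per-SNP key used to align statistic tracks is the SNP ID
string ``"chrom:pos"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from sweepscan._errors import DataError, ValidationError

if TYPE_CHECKING:  # pragma: no cover - typing only
    from sweepscan.selection_stats import SiteStatTrack

log = logging.getLogger(__name__)

MISSING = -1

SITE_COLUMNS = ["chrom", "pos", "snp_id", "ref_allele", "alt_allele", "cm"]


def chrom_sort_key(chrom: str) -> tuple[int, int, str]:
    """Ordering key giving numeric chromosomes first, in numeric order."""
    c = str(chrom)
    if c.lower().startswith("chr"):
        c = c[3:]
    if c.isdigit():
        return (0, int(c), "")
    return (1, 0, c)


def make_site_table(
    chrom: Sequence[str],
    pos: Sequence[int],
    ref_allele: Sequence[str],
    alt_allele: Sequence[str],
    cm: Sequence[float] | None = None,
    multiallelic: Sequence[bool] | None = None,
) -> pd.DataFrame:
    """Build a validated site table with the ``chrom:pos`` SNP ID key.

    When no genetic map is available ``cm`` defaults to ``pos * 1e-6``
    (a flat 1 cM/Mb map); this is logged because iHH integration depends
    on it.
    """
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos, dtype=np.int64)
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "snp_id": [f"{c}:{p}" for c, p in zip(chrom, pos)],
            "ref_allele": np.asarray(ref_allele, dtype=object),
            "alt_allele": np.asarray(alt_allele, dtype=object),
        }
    )
    if cm is None:
        log.info(
            "no genetic map supplied; assuming a flat 1 cM/Mb map (cm = pos * 1e-6)"
        )
        df["cm"] = df["pos"].to_numpy(dtype=float) * 1e-6
    else:
        df["cm"] = np.asarray(cm, dtype=float)
    if multiallelic is not None:
        df["multiallelic"] = np.asarray(multiallelic, dtype=bool)
    else:
        df["multiallelic"] = False
    validate_site_table(df)
    return df


def validate_site_table(sites: pd.DataFrame) -> None:
    for col in SITE_COLUMNS:
        if col not in sites.columns:
            raise ValidationError(f"site table missing column {col!r}")
    for chrom, sub in sites.groupby("chrom", sort=False):
        p = sub["pos"].to_numpy()
        if len(p) > 1 and not np.all(np.diff(p) > 0):
            i = int(np.flatnonzero(np.diff(p) <= 0)[0])
            raise ValidationError(
                f"positions not strictly increasing on {chrom} near pos {p[i + 1]}"
            )
    if sites["snp_id"].duplicated().any():
        dup = sites.loc[sites["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise ValidationError(f"duplicate SNP ID {dup!r}")
    same = sites["ref_allele"] == sites["alt_allele"]
    if bool(same.any()):
        raise ValidationError(
            f"identical ref/alt alleles at {sites.loc[same, 'snp_id'].iloc[0]}"
        )


@dataclass(frozen=True)
class PopulationSpec:
    """A named sample group with a role in the two-population comparison."""

    name: str
    samples: tuple[str, ...]
    role: str = "target"  # "target" or "reference"

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValidationError(f"population {self.name!r} has no samples")
        if self.role not in ("target", "reference"):
            raise ValidationError(f"population role must be target|reference, got {self.role!r}")


@dataclass
class FilterReport:
    """Per-filter site removal bookkeeping from :func:`apply_site_filters`."""

    n_input: int
    n_multiallelic: int
    n_low_maf: int
    n_high_missing: int
    n_retained: int


@dataclass
class GenotypeMatrix:
    """Diploid alt-allele dosages (samples x sites) with site metadata.

    ``dosage`` entries are in {0, 1, 2} with missing encoded as -1.
    """

    sites: pd.DataFrame
    samples: list[str]
    dosage: np.ndarray
    pop_of: dict[str, str]
    filter_report: FilterReport | None = None

    def __post_init__(self) -> None:
        if self.dosage.shape != (len(self.samples), len(self.sites)):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} does not match "
                f"({len(self.samples)}, {len(self.sites)})"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def samples_in(self, population: str) -> list[str]:
        return [s for s in self.samples if self.pop_of.get(s) == population]

    def population_spec(self, population: str, role: str = "target") -> PopulationSpec:
        return PopulationSpec(population, tuple(self.samples_in(population)), role)

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sites=self.sites.loc[mask].reset_index(drop=True),
            samples=list(self.samples),
            dosage=self.dosage[:, mask],
            pop_of=dict(self.pop_of),
            filter_report=self.filter_report,
        )


@dataclass
class HaplotypeSet:
    """Phased binary haplotypes (2 x samples rows) with complete sites only."""

    sites: pd.DataFrame
    haplotypes: np.ndarray  # (2*n_samples, n_sites) uint8 in {0,1}
    sample_of_hap: list[str]
    pop_of: dict[str, str]

    def __post_init__(self) -> None:
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] % 2 != 0:
            raise ValidationError("haplotype matrix must have an even number of rows")
        if self.haplotypes.shape != (len(self.sample_of_hap), len(self.sites)):
            raise ValidationError("haplotype matrix shape mismatch")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def restrict_population(self, population: str) -> "HaplotypeSet":
        keep = np.array([self.pop_of.get(s) == population for s in self.sample_of_hap])
        if not keep.any():
            raise ValidationError(f"no haplotypes belong to population {population!r}")
        return HaplotypeSet(
            sites=self.sites,
            haplotypes=self.haplotypes[keep],
            sample_of_hap=[s for s, k in zip(self.sample_of_hap, keep) if k],
            pop_of=dict(self.pop_of),
        )

    def subset_sites(self, mask: np.ndarray) -> "HaplotypeSet":
        return HaplotypeSet(
            sites=self.sites.loc[mask].reset_index(drop=True),
            haplotypes=self.haplotypes[:, mask],
            sample_of_hap=list(self.sample_of_hap),
            pop_of=dict(self.pop_of),
        )

    def restrict_to_snp_ids(self, snp_ids: Iterable[str]) -> "HaplotypeSet":
        wanted = set(snp_ids)
        mask = self.sites["snp_id"].isin(wanted).to_numpy()
        return self.subset_sites(mask)


# ---------------------------------------------------------------------------
# readers


def read_population_file(path: str | Path) -> dict[str, str]:
    """Two-column whitespace-delimited table: sample, population."""
    pop_of: dict[str, str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValidationError(
                    f"{path}:{line_no}: expected 'sample population', got {line.strip()!r}"
                )
            pop_of[parts[0]] = parts[1]
    if not pop_of:
        raise ValidationError(f"population file {path} is empty")
    return pop_of


def read_genetic_map(path: str | Path) -> pd.DataFrame:
    """Three-column genetic map: chrom, pos (bp), cm."""
    df = pd.read_csv(
        path, sep=r"\s+", comment="#", header=None, names=["chrom", "pos", "cm"]
    )
    df["chrom"] = df["chrom"].astype(str)
    return df


def apply_genetic_map(sites: pd.DataFrame, gmap: pd.DataFrame) -> pd.DataFrame:
    """Interpolate cM positions onto the site table (linear, per chromosome)."""
    sites = sites.copy()
    cm = np.empty(len(sites), dtype=float)
    for chrom, sub in sites.groupby("chrom", sort=False):
        g = gmap[gmap["chrom"] == str(chrom)].sort_values("pos")
        if g.empty:
            raise ValidationError(f"genetic map has no entries for chromosome {chrom}")
        cm[sub.index] = np.interp(sub["pos"].to_numpy(), g["pos"], g["cm"])
    sites["cm"] = cm
    return sites


def _resolve_pop_of(pop_file: str | Path | Mapping[str, str]) -> dict[str, str]:
    if isinstance(pop_file, Mapping):
        return dict(pop_file)
    return read_population_file(pop_file)


def _open_vcf(path: str | Path, pop_of: dict[str, str]) -> tuple[VCF, list[str]]:
    vcf = VCF(str(path))
    missing = sorted(set(pop_of) - set(vcf.samples))
    if missing:
        raise ValidationError(
            f"samples in population file absent from VCF: {', '.join(missing)}"
        )
    keep = [s for s in vcf.samples if s in pop_of]
    if not keep:
        raise ValidationError("population file covers no VCF sample")
    vcf = VCF(str(path), samples=keep)
    return vcf, list(vcf.samples)


def _check_sorted(
    chrom: str, pos: int, prev: tuple[str | None, int], seen: set[str]
) -> tuple[str, int]:
    prev_chrom, prev_pos = prev
    if chrom != prev_chrom:
        if chrom in seen:
            raise DataError(f"unsorted VCF: chromosome {chrom} re-appears at {chrom}:{pos}")
        seen.add(chrom)
    elif pos < prev_pos:
        raise DataError(f"unsorted VCF: record {chrom}:{pos} follows {chrom}:{prev_pos}")
    return chrom, pos


def read_vcf(
    path: str | Path,
    pop_file: str | Path | Mapping[str, str],
    gmap: pd.DataFrame | None = None,
) -> GenotypeMatrix:
    """Read a sorted diploid VCF into a :class:`GenotypeMatrix`.

    Only samples listed in ``pop_file`` are retained (in VCF order).
    Multi-allelic records are kept but flagged in the site table; their
    dosage counts allele 1 only.
    """
    pop_of = _resolve_pop_of(pop_file)
    vcf, samples = _open_vcf(path, pop_of)
    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    multi: list[bool] = []
    rows: list[np.ndarray] = []
    prev: tuple[str | None, int] = (None, -1)
    seen: set[str] = set()
    for var in vcf:
        prev = _check_sorted(var.CHROM, var.POS, prev, seen)
        g = var.genotype.array()  # (n_samples, ploidy+1); last column = phased
        alleles = g[:, :-1]
        dosage = (alleles == 1).sum(axis=1).astype(np.int8)
        dosage[(alleles < 0).any(axis=1)] = MISSING
        rows.append(dosage)
        chroms.append(var.CHROM)
        positions.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0] if var.ALT else ".")
        multi.append(len(var.ALT) > 1)
    if not rows:
        raise DataError(f"VCF {path} contains no records")
    sites = make_site_table(chroms, positions, refs, alts, multiallelic=multi)
    if gmap is not None:
        sites = apply_genetic_map(sites, gmap)
    dosage = np.stack(rows, axis=1)
    return GenotypeMatrix(sites=sites, samples=samples, dosage=dosage, pop_of=pop_of)


def read_phased(
    path: str | Path,
    pop_file: str | Path | Mapping[str, str],
    gmap: pd.DataFrame | None = None,
) -> HaplotypeSet:
    """Read a phased VCF into a :class:`HaplotypeSet`.

    Sites with any unphased or missing call (or with more than two alleles)
    are dropped; the drop count is logged.  Haplotype rows 2i and 2i+1 hold
    the two phased alleles of sample i.
    """
    pop_of = _resolve_pop_of(pop_file)
    vcf, samples = _open_vcf(path, pop_of)
    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    cols: list[np.ndarray] = []
    n_dropped = 0
    prev: tuple[str | None, int] = (None, -1)
    seen: set[str] = set()
    for var in vcf:
        prev = _check_sorted(var.CHROM, var.POS, prev, seen)
        g = var.genotype.array()
        alleles = g[:, :-1]
        phased = g[:, -1].astype(bool)
        if (
            len(var.ALT) != 1
            or alleles.shape[1] != 2
            or (alleles < 0).any()
            or (alleles > 1).any()
            or not phased.all()
        ):
            n_dropped += 1
            continue
        cols.append(alleles.astype(np.uint8).reshape(-1))
        chroms.append(var.CHROM)
        positions.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
    if n_dropped:
        log.info("read_phased: dropped %d sites with unphased/missing/multi-allelic calls", n_dropped)
    if not cols:
        raise DataError(f"VCF {path} has no fully phased biallelic sites")
    sites = make_site_table(chroms, positions, refs, alts)
    if gmap is not None:
        sites = apply_genetic_map(sites, gmap)
    haplotypes = np.stack(cols, axis=1)
    sample_of_hap = [s for s in samples for _ in range(2)]
    return HaplotypeSet(
        sites=sites, haplotypes=haplotypes, sample_of_hap=sample_of_hap, pop_of=pop_of
    )


# ---------------------------------------------------------------------------
# writer


def write_vcf(data: GenotypeMatrix | HaplotypeSet, path: str | Path) -> Path:
    """Write a minimal deterministic VCF 4.2 file.

    :class:`HaplotypeSet` input is written phased (``a|b``);
    :class:`GenotypeMatrix` input is written unphased with dosage 1 as
    ``0/1`` and missing as ``./.``.
    """
    path = Path(path)
    sites = data.sites
    if isinstance(data, HaplotypeSet):
        sample_names = data.sample_of_hap[::2]
    else:
        sample_names = data.samples
    lines = ["##fileformat=VCFv4.2", "##source=sweepscan"]
    for chrom in dict.fromkeys(sites["chrom"]):
        length = int(sites.loc[sites["chrom"] == chrom, "pos"].max()) + 1
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_names)
    )
    gt_of_dosage = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    for j in range(len(sites)):
        row = sites.iloc[j]
        if isinstance(data, HaplotypeSet):
            col = data.haplotypes[:, j]
            gts = [f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(len(sample_names))]
        else:
            gts = [gt_of_dosage[int(d)] for d in data.dosage[:, j]]
        lines.append(
            f"{row['chrom']}\t{row['pos']}\t{row['snp_id']}\t{row['ref_allele']}\t"
            f"{row['alt_allele']}\t.\t.\t.\tGT\t" + "\t".join(gts)
        )
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# filters and frequencies


def apply_site_filters(
    gm: GenotypeMatrix,
    maf_min: float = 0.01,
    max_missing: float = 0.1,
    biallelic_only: bool = True,
) -> GenotypeMatrix:
    """Apply the standard site filters; thresholds are read strictly.

    A site is removed when its folded MAF (over non-missing genotypes,
    all samples pooled) is *below* ``maf_min``, when its missing-genotype
    rate *exceeds* ``max_missing``, or (by default) when it carries more
    than two alleles.  Per-filter removal counts are logged and attached
    to the returned matrix as ``filter_report``.
    """
    if gm.n_sites == 0:
        raise ValidationError("empty genotype matrix")
    dosage = gm.dosage
    missing = dosage == MISSING
    miss_rate = missing.mean(axis=0)
    n_called = (~missing).sum(axis=0)
    alt = np.where(missing, 0, dosage).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
    maf = np.fmin(p, 1.0 - p)
    fail_multi = (
        gm.sites["multiallelic"].to_numpy()
        if biallelic_only
        else np.zeros(gm.n_sites, dtype=bool)
    )
    fail_maf = maf < maf_min  # nan compares False: all-missing handled by miss filter
    fail_miss = miss_rate > max_missing
    keep = ~(fail_multi | fail_maf | fail_miss)
    report = FilterReport(
        n_input=gm.n_sites,
        n_multiallelic=int(fail_multi.sum()),
        n_low_maf=int(fail_maf.sum()),
        n_high_missing=int(fail_miss.sum()),
        n_retained=int(keep.sum()),
    )
    log.info(
        "site filters: %d input, %d multi-allelic, %d MAF<%g, %d missing>%g, %d retained",
        report.n_input,
        report.n_multiallelic,
        report.n_low_maf,
        maf_min,
        report.n_high_missing,
        max_missing,
        report.n_retained,
    )
    if not keep.any():
        raise DataError(
            "all sites removed by filters "
            f"(multi-allelic={report.n_multiallelic}, low-MAF={report.n_low_maf}, "
            f"high-missing={report.n_high_missing})"
        )
    out = gm.subset_sites(keep)
    out.filter_report = report
    return out


def allele_frequencies(
    gm: GenotypeMatrix, pop: PopulationSpec | str
) -> np.ndarray:
    """Per-site alt-allele frequency within one population.

    Frequencies are alt-dosage sums over twice the number of non-missing
    genotypes; sites fully missing in the population yield NaN.
    """
    if isinstance(pop, str):
        pop = gm.population_spec(pop)
    unknown = [s for s in pop.samples if s not in gm.samples]
    if unknown:
        raise ValidationError(f"population {pop.name!r} samples not in matrix: {unknown}")
    if not pop.samples:
        raise ValidationError(f"population {pop.name!r} is empty")
    idx = [gm.samples.index(s) for s in pop.samples]
    dos = gm.dosage[idx]
    missing = dos == MISSING
    n_called = (~missing).sum(axis=0)
    alt = np.where(missing, 0, dos).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
    return freq


def allele_counts(
    gm: GenotypeMatrix, pop: PopulationSpec | str
) -> np.ndarray:
    """Per-site (n_alleles, alt_count) pairs over non-missing genotypes."""
    if isinstance(pop, str):
        pop = gm.population_spec(pop)
    idx = [gm.samples.index(s) for s in pop.samples]
    dos = gm.dosage[idx]
    missing = dos == MISSING
    n_alleles = 2 * (~missing).sum(axis=0)
    alt = np.where(missing, 0, dos).sum(axis=0)
    return np.column_stack([n_alleles, alt]).astype(np.int64)


# ---------------------------------------------------------------------------
# track merging


def merge_by_snp_id(tracks: Sequence["SiteStatTrack"]) -> pd.DataFrame:
    """Join statistic tracks on the intersection of their SNP IDs.

    The result holds exactly the SNP IDs present in every track, in genome
    order (chromosomes naturally sorted, positions ascending), with one
    value column per track named after its statistic.
    """
    if len(tracks) < 2:
        raise ValidationError("merge_by_snp_id requires at least two tracks")
    common: set[str] | None = None
    for t in tracks:
        ids = set(map(str, t.snp_ids))
        common = ids if common is None else common & ids
    assert common is not None
    if not common:
        raise DataError("no SNP IDs shared by all tracks")
    ordered = sorted(common, key=_snp_id_sort_key)
    out = pd.DataFrame({"snp_id": ordered})
    out["chrom"] = [s.rsplit(":", 1)[0] for s in ordered]
    out["pos"] = [int(s.rsplit(":", 1)[1]) for s in ordered]
    names_seen: dict[str, int] = {}
    for t in tracks:
        name = t.stat_name
        if name in names_seen:
            names_seen[name] += 1
            name = f"{name}_{names_seen[t.stat_name]}"
        else:
            names_seen[name] = 1
        ser = pd.Series(np.asarray(t.values, dtype=float), index=list(map(str, t.snp_ids)))
        out[name] = ser.reindex(ordered).to_numpy()
    return out


def _snp_id_sort_key(snp_id: str) -> tuple[tuple[int, int, str], int]:
    chrom, pos = snp_id.rsplit(":", 1)
    return (chrom_sort_key(chrom), int(pos))
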