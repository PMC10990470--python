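"""End-to-end orchestration: filters -> statistics -> CSS -> clusters -> genes.

Stages run in a fixed order, abort with stage-named errors, and write
intermediate files exactly once with a provenance header carrying every
tunable, so a rerun with the same configuration reproduces byte-identical
outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from sweepscan._errors import SweepscanError
from sweepscan.ancestry import f3_trio_report
from sweepscan.config import RunConfig
from sweepscan.css_pipeline import (
    annotate_clusters,
    call_clusters,
    clusters_to_frame,
    css_from_tracks,
    read_genes,
    smooth_windows,
)
from sweepscan.genotype_io import (
    allele_counts,
    allele_frequencies,
    apply_site_filters,
    read_genetic_map,
    read_phased,
    read_population_file,
    read_vcf,
)
from sweepscan.selection_stats import (
    delta_saf,
    fst_weir_cockerham,
    standardize,
    xpehh,
)
from sweepscan.synthetic_data import (
    AdmixSimParams,
    SweepSimParams,
    simulate_admixture_trio,
    simulate_sweep_panel,
    synthetic_gene_grid,
)

log = logging.getLogger(__name__)


class StageError(SweepscanError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name: str):
    def wrap(func):
        def inner(*args, **kwargs):
            try:
                return func(*args, **kwargs)
            except SweepscanError as exc:
                raise StageError(f"[{name}] {exc}") from exc

        return inner

    return wrap


def _write_track_tsv(path: Path, header: str, frame: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        frame.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def run_full_scan(config: RunConfig) -> dict[str, Path]:
    """Run the full selection scan; returns the paths of all outputs."""
    config.validate_for_scan()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pop_of = read_population_file(config.pops)
    for role, name in (("target", config.target), ("reference", config.reference)):
        if name not in set(pop_of.values()):
            raise StageError(f"[inputs] {role} population {name!r} not in {config.pops}")
    gmap = read_genetic_map(config.genetic_map) if config.genetic_map else None

    log.info("stage 1/6: read + filter genotypes")
    gm = _stage("read_vcf")(read_vcf)(config.vcf, pop_of, gmap)
    gm = _stage("site_filters")(apply_site_filters)(
        gm, config.maf_min, config.max_missing, config.biallelic_only
    )
    log.info("stage 2/6: read phased haplotypes")
    haps = _stage("read_phased")(read_phased)(config.vcf, pop_of, gmap)
    haps = haps.restrict_to_snp_ids(gm.sites["snp_id"])

    log.info("stage 3/6: constituent statistics")
    snp_ids = gm.sites["snp_id"].to_numpy(dtype=object)
    counts_t = allele_counts(gm, config.target)
    counts_r = allele_counts(gm, config.reference)
    fst = _stage("fst")(fst_weir_cockerham)(counts_t, counts_r, snp_ids)
    freq_t = allele_frequencies(gm, config.target)
    freq_r = allele_frequencies(gm, config.reference)
    dsaf = _stage("dsaf")(delta_saf)(freq_t, freq_r, snp_ids)
    haps_t = haps.restrict_population(config.target)
    haps_r = haps.restrict_population(config.reference)
    xp = _stage("xpehh")(xpehh)(haps_t, haps_r, config.ehh_cutoff, config.max_gap_bp)

    log.info("stage 4/6: standardization")
    z_xp = _stage("standardize")(standardize)(xp)
    z_dsaf = _stage("standardize")(standardize)(dsaf)

    paths: dict[str, Path] = {}
    for name, raw, z in (
        ("fst", fst, None),
        ("xpehh", xp, z_xp),
        ("dsaf", dsaf, z_dsaf),
    ):
        frame = pd.DataFrame(
            {
                "snp_id": raw.snp_ids,
                "chrom": [s.rsplit(":", 1)[0] for s in raw.snp_ids],
                "pos": [int(s.rsplit(":", 1)[1]) for s in raw.snp_ids],
                "raw": raw.values,
            }
        )
        if z is not None:
            frame["z"] = z.values
        path = out_dir / f"track_{name}.tsv"
        _write_track_tsv(path, config.provenance_header(f"track {name}"), frame)
        paths[f"track_{name}"] = path

    log.info("stage 5/6: CSS combine + smooth + clusters")
    css = _stage("css_combine")(css_from_tracks)(
        [fst, z_xp, z_dsaf], config.variance_mode
    )
    css = _stage("smooth")(smooth_windows)(css, config.window_bp, config.smoothing)
    clusters = _stage("clusters")(call_clusters)(
        css,
        config.top_frac,
        config.flank_frac,
        config.min_flankers,
        config.flank_span_bp,
    )

    log.info("stage 6/6: gene annotation + outputs")
    if config.genes:
        genes = _stage("genes")(read_genes)(config.genes)
        clusters = _stage("annotate")(annotate_clusters)(
            clusters, genes, config.gene_flank_bp
        )

    css_path = out_dir / "css.tsv"
    _write_track_tsv(css_path, config.provenance_header("css"), css.to_frame())
    paths["css"] = css_path

    bed_path = out_dir / "clusters.bed"
    with open(bed_path, "w") as fh:
        for cl in clusters:  # BED is 0-based half-open
            fh.write(f"{cl.chrom}\t{cl.start - 1}\t{cl.end}\t{cl.label}\n")
    paths["clusters_bed"] = bed_path

    clusters_path = out_dir / "clusters.tsv"
    _write_track_tsv(
        clusters_path, config.provenance_header("clusters"), clusters_to_frame(clusters)
    )
    paths["clusters"] = clusters_path
    paths["out_dir"] = out_dir
    log.info("scan complete: %d clusters", len(clusters))
    return paths


# ---------------------------------------------------------------------------
# demo


def run_demo(
    seed: int,
    out_dir: str | Path,
    sweep: bool = True,
    sweep_params: SweepSimParams | None = None,
) -> tuple[str, dict[str, Path]]:
    """Simulate, scan, and compare the calls against the planted truth.

    Returns the human-readable report text and the output paths.  The
    report covers sweep recovery (hit/miss of the planted core within
    100 kb of a called cluster) and an f3 sign table for an admixed and a
    drift-only trio.
    """
    out_dir = Path(out_dir)
    sim_dir = out_dir / "sim"
    params = sweep_params or SweepSimParams()
    params.seed = seed
    if not sweep:
        params.sweep_freq_target = 0.0
    haps, truth, sim_paths = simulate_sweep_panel(params, sim_dir)
    assert sim_paths is not None
    genes = synthetic_gene_grid(params.chrom, params.chrom_length_bp)
    genes_path = sim_dir / "genes.bed"
    with open(genes_path, "w") as fh:
        for _, g in genes.iterrows():
            fh.write(f"{g['chrom']}\t{g['start'] - 1}\t{g['end']}\t{g['gene_id']}\n")

    config = RunConfig(
        vcf=str(sim_paths["vcf"]),
        pops=str(sim_paths["pops"]),
        genetic_map=str(sim_paths["map"]),
        genes=str(genes_path),
        target=params.target_name,
        reference=params.ref_name,
        out_dir=str(out_dir / "scan"),
        seed=seed,
    )
    paths = run_full_scan(config)

    clusters = pd.read_csv(paths["clusters"], sep="\t", comment="#")
    lines = ["sweepscan demo report", "====================", ""]
    lines.append(f"seed: {seed}")
    if sweep:
        lines.append(
            f"planted sweep: {truth.core_snp_id} "
            f"(realized core freq {truth.realized_core_freq[params.target_name]:.3f} target, "
            f"{truth.realized_core_freq[params.ref_name]:.3f} reference)"
        )
    else:
        lines.append("planted sweep: none (0 planted loci)")
    lines.append(f"clusters called: {len(clusters)}")
    hit = False
    if sweep and len(clusters):
        core = truth.core_pos_bp
        assert core is not None
        for _, cl in clusters.iterrows():
            if str(cl["chrom"]) == params.chrom and (
                cl["start"] - 100_000 <= core <= cl["end"] + 100_000
            ):
                hit = True
    if sweep:
        lines.append(f"sweep recovered (cluster within 100 kb of core): {'yes' if hit else 'no'}")
    for _, cl in clusters.iterrows():
        lines.append(
            f"  cluster {cl['chrom']}:{cl['start']}-{cl['end']} "
            f"members={cl['n_members']} support={cl['n_top1_support']} "
            f"genes={cl['genes'] if isinstance(cl['genes'], str) else ''}"
        )

    lines.append("")
    lines.append("f3 admixture tests (50k SNPs each)")
    admixed = simulate_admixture_trio(AdmixSimParams(seed=seed, alpha=0.5))
    drifted = simulate_admixture_trio(AdmixSimParams(seed=seed, alpha=None, f_c=0.3))
    for label, sim in (("admixed (alpha=0.5)", admixed), ("drift-only", drifted)):
        row = f3_trio_report(sim.genotypes, [("target", "refA", "refB")]).iloc[0]
        lines.append(
            f"  {label}: f3 = {row['f3_hat']:+.6f} +/- {row['se']:.6f} "
            f"(z = {row['z']:+.2f}) admixture_signal={bool(row['admixture_signal'])}"
        )
    report = "\n".join(lines) + "\n"
    report_path = out_dir / "report.txt"
    report_path.write_text(report)
    paths["report"] = report_path
    return report, paths


def run_demo_batch(
    seeds: list[int], out_dir: str | Path, sweep: bool = True
) -> tuple[float, tuple[float, float]]:
    """Recovery fraction over a seed batch with a 95% Wilson interval."""
    hits = 0
    out_dir = Path(out_dir)
    for seed in seeds:
        report, _ = run_demo(seed, out_dir / f"seed{seed}", sweep=sweep)
        if "sweep recovered (cluster within 100 kb of core): yes" in report:
            hits += 1
    n = len(seeds)
    frac = hits / n
    z = 1.959963984540054
    denom = 1 + z**2 / n
    center = (frac + z**2 / (2 * n)) / denom
    half = z * np.sqrt(frac * (1 - frac) / n + z**2 / (4 * n**2)) / denom
    return frac, (center - half, center + half)
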