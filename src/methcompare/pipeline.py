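"""End-to-end orchestration: simulate -> landscape -> segment -> allelic -> xci -> enrich.

A :class:`RunConfig` carries every threshold under the name of its role, with
defaults equal to the analysis' canonical values (5X CpG depth, >= 3 CpG
calls per read, 35% CGI CpG coverage, UMR meth.cutoff 0.5 / nCpG.cutoff 5,
DMV >= 5 kb, allelic gates 30-60% mean / > 90% full reads / delta < 40,
stringent >= 20 CpGs and > 350 bp, lenient >= 10 CpGs, escapee pCGI < 10%,
DE fold change > 3 and adjusted p < 0.01).  The config is serialized into
the output directory for provenance, and a fixed seed reproduces every
output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import allelic, enrichment, landscape, segmentation, simulate, xci
from . import io as mio

log = logging.getLogger("methcompare")

DEFAULT_THRESHOLDS = {
    "min_depth": 5,
    "min_read_cpgs": 3,
    "cgi_min_covered_fraction": 0.35,
    "promoter_ratio_lower": 0.35,
    "promoter_ratio_upper": 0.55,
    "promoter_gc_min": 55.0,
    "pmd_win_cpgs": 101,
    "pmd_intermediate_band": [0.3, 0.7],
    "pmd_frac_cutoff": 0.5,
    "umr_meth_cutoff": 0.5,
    "umr_n_cpg_cutoff": 5,
    "umr_smooth_k": 3,
    "dmv_min_size_bp": 5000,
    "allelic_window_bp": 50,
    "allelic_step_bp": 10,
    "allelic_mean_meth_range": [30.0, 60.0],
    "allelic_min_pct_full_reads": 90.0,
    "allelic_max_delta": 40.0,
    "allelic_min_reads": 5,
    "allelic_window_mean_source": "overlapping_reads",
    "allelic_max_gene_distance_bp": 50000,
    "escapee_max_pcgi_meth": 10.0,
    "de_min_fold_change": 3.0,
    "de_max_padj": 0.01,
}

ALL_STAGES = ["simulate", "landscape", "segment", "allelic", "xci", "enrich"]


@dataclass
class RunConfig:
    species: str = "A"
    outdir: str | None = None
    seed: int = 0
    chrx_name: str = "chrX"
    stages: list = field(default_factory=lambda: list(ALL_STAGES))
    simulate: dict = field(default_factory=dict)  # SimConfig overrides
    inputs: dict | None = None  # paths for a non-synthetic run
    thresholds: dict = field(default_factory=dict)

    def resolved_thresholds(self) -> dict:
        th = dict(DEFAULT_THRESHOLDS)
        th.update(self.thresholds)
        return th

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class SpeciesResult:
    """Everything one species run produces, for in-memory aggregation."""

    config: RunConfig
    data: simulate.SpeciesData | None
    cpg_table: pd.DataFrame
    report: dict
    cgi_classes: pd.DataFrame | None = None
    promoters: pd.DataFrame | None = None
    pmds: pd.DataFrame | None = None
    umrs: pd.DataFrame | None = None
    dmvs: pd.DataFrame | None = None
    dmv_genes: set = field(default_factory=set)
    dmr_calls: pd.DataFrame | None = None
    escapee_calls: pd.DataFrame | None = None
    enrichment_table: pd.DataFrame | None = None
    ortholog_map: pd.DataFrame | None = None


def _promoter_cgis(cgi_feats: pd.DataFrame, genes, chrom=None) -> pd.DataFrame:
    """Promoter CGIs with the gene whose TSS they cover."""
    proms = cgi_feats[cgi_feats["feature_class"] == "promoter"].reset_index(drop=True)
    gene_ids = []
    for _, r in proms.iterrows():
        hit = ""
        for g in genes:
            if g.chrom == r["chrom"] and r["start"] <= g.tss < r["end"]:
                hit = g.gene_id
                break
        gene_ids.append(hit)
    proms = proms.copy()
    proms["gene_id"] = gene_ids
    if chrom is not None:
        proms = proms[proms["chrom"] == chrom].reset_index(drop=True)
    return proms


def run_pipeline(config: RunConfig) -> SpeciesResult:
    """Run the configured stages for one species and assemble the report.

    With a ``simulate`` stage the synthetic generator provides all inputs;
    otherwise ``config.inputs`` must name the on-disk products (FASTA, GTF,
    CGI/TE/exclusion BEDs, coverage table, read-level calls, DE table).
    """
    th = config.resolved_thresholds()
    stages = list(config.stages)
    report: dict = {"species": config.species, "seed": config.seed, "stages": stages}
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(outdir / "config.yaml")

    t0 = time.time()
    if "simulate" in stages:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("species", config.species)
        sim_kwargs.setdefault("seed", config.seed)
        sim_kwargs.setdefault("chrx_name", config.chrx_name)
        cfg = simulate.SimConfig(**sim_kwargs)
        data = simulate.simulate_species(cfg)
        if outdir:
            simulate.write_species(data, outdir / "sim")
        genome = data.genome
        genes = data.genes
        cgis, tes, excl = data.cgis, data.tes, data.exclusions
        cov_raw = data.cov
        read_calls = mio.build_read_call_set(data.calls, min_cpgs=th["min_read_cpgs"])
        de_table = data.de_table
        ortho = data.ortholog_map()
    else:
        if not config.inputs:
            raise ValueError("non-synthetic run requires config.inputs")
        import pyfaidx

        paths = config.inputs
        fa = pyfaidx.Fasta(paths["fasta"])
        genome = {name: landscape._as_codes(str(fa[name][:])) for name in fa.keys()}
        bundle = mio.load_annotations(
            paths["gtf"],
            paths.get("cgis"),
            paths.get("tes"),
            paths.get("exclusions"),
            chrom_names=set(genome),
        )
        genes, cgis, tes, excl = bundle.genes, bundle.cgis, bundle.repeats, bundle.exclusions
        cov_raw = mio.read_cov_table(paths["cov"], min_depth=1, combine=False)
        read_calls = mio.read_readlevel_calls(paths["reads"], min_cpgs=th["min_read_cpgs"])
        de_table = pd.read_csv(paths["de"], sep="\t") if paths.get("de") else None
        ortho = pd.read_csv(paths["orthologs"], sep="\t") if paths.get("orthologs") else None
        germline_input = (
            set(pd.read_csv(paths["germline"], sep="\t")["gene_id"])
            if paths.get("germline")
            else None
        )
        data = None
    chrom_lengths = {c: len(landscape._as_codes(s)) for c, s in genome.items()}
    cpg_table = mio.depth_filter(cov_raw, th["min_depth"])
    report["n_cpgs_total"] = int(len(cov_raw))
    report["n_cpgs_depth_filtered"] = int(len(cpg_table))
    log.info("inputs ready (%.1fs): %d CpGs at >=%dX", time.time() - t0, len(cpg_table), th["min_depth"])

    res = SpeciesResult(config=config, data=data, cpg_table=cpg_table, report=report)
    res.ortholog_map = ortho
    cgi_feats = landscape.annotate_cgi_features(cgis, genes)

    if "landscape" in stages:
        t = time.time()
        report["global_mean_meth"] = round(landscape.global_mean_methylation(cpg_table), 3)
        autosomal = cpg_table[cpg_table["chrom"] != config.chrx_name]
        report["global_mean_meth_autosomes"] = round(landscape.global_mean_methylation(autosomal), 3)
        classes = landscape.classify_cgi_methylation(
            cgi_feats, cpg_table, genome, min_covered_fraction=th["cgi_min_covered_fraction"]
        )
        res.cgi_classes = classes
        props = landscape.cgi_class_proportions(classes)
        report["cgi_class_percent"] = {k: round(float(v), 3) for k, v in sorted(props.items())}
        proms = landscape.define_promoters(genes, genome)
        proms = landscape.classify_promoters(
            proms,
            th["promoter_ratio_lower"],
            th["promoter_ratio_upper"],
            gc_min=th["promoter_gc_min"],
        )
        res.promoters = proms
        report["promoter_class_counts"] = {
            k: int(v) for k, v in sorted(proms["promoter_class"].value_counts().items())
        }
        meta = landscape.gene_metaplot(genes, cpg_table, exclude_chroms={config.chrx_name})
        report["metaplot_minimum_bin"] = int(np.nanargmin(meta["profile"]))
        if outdir:
            classes.to_csv(outdir / "cgi_classes.tsv", sep="\t", index=False)
            proms.to_csv(outdir / "promoters.tsv", sep="\t", index=False)
        log.info("landscape done (%.1fs)", time.time() - t)

    if "segment" in stages:
        t = time.time()
        pmds = segmentation.detect_pmds(
            cpg_table,
            win_cpgs=th["pmd_win_cpgs"],
            intermediate_band=tuple(th["pmd_intermediate_band"]),
            frac_cutoff=th["pmd_frac_cutoff"],
        )
        umrs = segmentation.detect_umrs(
            cpg_table,
            pmds,
            meth_cutoff=th["umr_meth_cutoff"],
            n_cpg_cutoff=th["umr_n_cpg_cutoff"],
            smooth_k=th["umr_smooth_k"],
        )
        dmvs = segmentation.call_dmvs(umrs, min_size_bp=th["dmv_min_size_bp"])
        res.pmds, res.umrs, res.dmvs = pmds, umrs, dmvs
        res.dmv_genes = segmentation.dmv_gene_overlap(dmvs, genes)
        report["n_pmds"] = int(len(pmds))
        report["n_umrs"] = int(len(umrs))
        report["n_dmvs"] = int(len(dmvs))
        report["pmd_genome_fraction"] = round(segmentation.genome_fraction(pmds, chrom_lengths), 5)
        report["dmv_genome_fraction"] = round(segmentation.genome_fraction(dmvs, chrom_lengths), 5)
        report["dmv_genes"] = sorted(res.dmv_genes)
        if outdir:
            for name, df in (("pmds", pmds), ("umrs", umrs), ("dmvs", dmvs)):
                cols = [c for c in ("n_cpg", "mean_meth") if c in df.columns]
                mio.write_bed(df, outdir / f"{name}.bed", extra_cols=cols)
        log.info("segmentation done (%.1fs): %d UMRs, %d DMVs", time.time() - t, len(umrs), len(dmvs))

    if "allelic" in stages:
        t = time.time()
        calls = allelic.call_dmrs(
            read_calls,
            cpg_table,
            genes,
            exclusions=excl,
            chrx_name=config.chrx_name,
            window=th["allelic_window_bp"],
            step=th["allelic_step_bp"],
            min_reads=th["allelic_min_reads"],
            mean_range=tuple(th["allelic_mean_meth_range"]),
            min_pct_full=th["allelic_min_pct_full_reads"],
            max_delta=th["allelic_max_delta"],
            max_gene_distance_bp=th["allelic_max_gene_distance_bp"],
            mean_source=th["allelic_window_mean_source"],
        )
        res.dmr_calls = calls
        report["n_dmrs_stringent"] = int(calls["stringent"].sum())
        report["n_dmrs_lenient"] = int(len(calls))
        report["dmr_genes_stringent"] = sorted(
            set(calls.loc[calls["stringent"] & (calls["nearest_gene"] != ""), "nearest_gene"])
        )
        if outdir:
            calls.to_csv(outdir / "allelic_dmrs.tsv", sep="\t", index=False)
        log.info(
            "allelic done (%.1fs): %d stringent / %d lenient",
            time.time() - t,
            report["n_dmrs_stringent"],
            report["n_dmrs_lenient"],
        )

    if "xci" in stages:
        t = time.time()
        pcgis = _promoter_cgis(cgi_feats, genes)
        contrast = xci.x_vs_autosome_pcgi(pcgis, cpg_table, chrx_name=config.chrx_name, genome=genome)
        tiles = xci.x_vs_autosome_tiles(cpg_table, cgis, chrom_lengths, chrx_name=config.chrx_name)
        x_pcgis = pcgis[pcgis["chrom"] == config.chrx_name].reset_index(drop=True)
        esc = xci.call_escapees(x_pcgis, cpg_table, threshold=th["escapee_max_pcgi_meth"], genome=genome)
        res.escapee_calls = esc
        report["x_pcgi_median_meth"] = round(contrast["x_median"], 3)
        report["autosome_pcgi_median_meth"] = round(contrast["autosome_median"], 3)
        report["x_vs_autosome_pcgi_p"] = float(f"{contrast['p_value']:.3e}")
        report["x_tile_median_meth"] = round(tiles["x_median"], 3)
        report["autosome_tile_median_meth"] = round(tiles["autosome_median"], 3)
        report["escapee_genes"] = sorted(esc.loc[esc["is_escapee"], "gene_id"])
        if outdir:
            esc.to_csv(outdir / "escapees.tsv", sep="\t", index=False)
        log.info("xci done (%.1fs): %d escapees", time.time() - t, len(report["escapee_genes"]))

    if "enrich" in stages and de_table is not None:
        t = time.time()
        if res.promoters is None:
            proms = landscape.define_promoters(genes, genome)
            proms = landscape.classify_promoters(
                proms, th["promoter_ratio_lower"], th["promoter_ratio_upper"], th["promoter_gc_min"]
            )
        else:
            proms = res.promoters
        prom_meth = landscape.region_mean_meth(cpg_table, proms)
        cgrich = prom_meth[prom_meth["promoter_class"].isin(["ICP", "HCP"])]
        meth_cgrich_genes = set(cgrich.loc[cgrich["mean_meth"] > 50.0, "gene_id"])
        upregulated = enrichment.select_upregulated(
            de_table, min_fc=th["de_min_fold_change"], max_padj=th["de_max_padj"]
        )
        all_genes = {g.gene_id for g in genes}
        if data is not None:
            germ = set(data.truth.germline["gene_id"])
        elif germline_input is not None:
            germ = germline_input & all_genes
        else:
            raise ValueError("enrich stage needs a germline gene-set input")
        enr = enrichment.gg_dko_enrichment(
            germ,
            upregulated,
            {"all_genes": all_genes, "methylated_cgrich_promoters": meth_cgrich_genes},
        )
        res.enrichment_table = enr
        report["n_upregulated"] = len(upregulated)
        report["enrichment"] = {
            r["set_name"]: {"k": int(r["k"]), "K": int(r["K"]), "n": int(r["n"]), "N": int(r["N"]),
                             "p": float(f"{r['p']:.4e}") if np.isfinite(r["p"]) else None,
                             "padj": float(f"{r['padj']:.4e}") if np.isfinite(r["padj"]) else None}
            for _, r in enr.iterrows()
        }
        if outdir:
            enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        log.info("enrichment done (%.1fs)", time.time() - t)

    if outdir:
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, sort_keys=True, indent=2)
            fh.write("\n")
    return res


def cross_species_run(
    results: dict,
    ortholog_map: pd.DataFrame | None = None,
    min_species_dmr: int = 2,
    min_species_escapee: int = 3,
    outdir=None,
) -> dict:
    """Aggregate per-species runs: DMV conservation, DMR genes, escapees.

    ``results`` maps species name to :class:`SpeciesResult` (at least two).
    ``ortholog_map`` (gene_id -> ortholog over all species) defaults to the
    concatenation of the per-species maps.
    """
    if len(results) < 2:
        raise ValueError("cross-species aggregation needs at least 2 species")
    if ortholog_map is None:
        maps = [r.ortholog_map for r in results.values() if r.ortholog_map is not None]
        if not maps:
            raise ValueError("no ortholog map available")
        ortholog_map = pd.concat(maps, ignore_index=True).drop_duplicates()

    species = sorted(results)
    cons = pd.DataFrame(index=species, columns=species, dtype=float)
    for a in species:
        for b in species:
            cons.loc[a, b] = segmentation.conservation_percent(
                results[a].dmv_genes, results[b].dmv_genes, ortholog_map
            )
    dmr_calls = {s: r.dmr_calls for s, r in results.items() if r.dmr_calls is not None}
    dmr_table = (
        allelic.cross_species_dmr_genes(dmr_calls, ortholog_map, min_species=min_species_dmr)
        if dmr_calls
        else pd.DataFrame()
    )
    esc_calls = {s: r.escapee_calls for s, r in results.items() if r.escapee_calls is not None}
    esc_table = (
        xci.cross_species_escapees(esc_calls, ortholog_map, min_species=min_species_escapee)
        if esc_calls
        else pd.DataFrame()
    )
    out = {"dmv_conservation": cons, "dmr_genes": dmr_table, "escapees": esc_table}
    if outdir:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cons.to_csv(outdir / "dmv_conservation.tsv", sep="\t")
        dmr_table.to_csv(outdir / "cross_species_dmr_genes.tsv", sep="\t", index=False)
        esc_table.to_csv(outdir / "cross_species_escapees.tsv", sep="\t", index=False)
    return out
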