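"""Shared plumbing for the analysis drivers: load one simulated species."""

from pathlib import Path

import pandas as pd

from methcompare.pipeline import RunConfig, run_pipeline

ROOT = Path(__file__).resolve().parents[1]
BASE_SEED = 2026_000
SPECIES = ["A", "B", "C"]


def species_config(sp: str, stages) -> RunConfig:
    simdir = ROOT / "scratch" / "sim" / sp
    if not simdir.exists():
        raise SystemExit(f"{simdir} missing - run analysis/01_simulate.py first")
    return RunConfig(
        species=sp,
        seed=BASE_SEED + SPECIES.index(sp),
        stages=list(stages),
        inputs={
            "fasta": str(simdir / "genome.fa"),
            "gtf": str(simdir / "genes.gtf"),
            "cgis": str(simdir / "cgis.bed"),
            "tes": str(simdir / "tes.bed"),
            "exclusions": str(simdir / "exclusions.bed"),
            "cov": str(simdir / "methylation.cov"),
            "reads": str(simdir / "read_calls.tsv"),
            "de": str(simdir / "de_table.tsv"),
            "orthologs": str(simdir / "orthologs.tsv"),
            "germline": str(simdir / "germline_genes.tsv"),
        },
    )


def run_species(sp: str, stages):
    return run_pipeline(species_config(sp, stages))


def truth(sp: str, name: str) -> pd.DataFrame:
    return pd.read_csv(ROOT / "scratch" / "sim" / sp / "truth" / f"{name}.tsv", sep="\t")


def results_dir(name: str) -> Path:
    d = ROOT / "results" / name
    d.mkdir(parents=True, exist_ok=True)
    return d
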