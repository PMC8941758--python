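"""X-inactivation methylation contrasts and escapee prediction.

On the inactive X chromosome, promoter CpG islands of silenced (subject)
genes are methylated on one allele, yielding ~30% aggregate methylation,
while promoter CGIs of genes that escape X inactivation stay unmethylated
(< 10%).  The non-CGI X background is hypomethylated relative to autosomes.
These contrasts are quantified with two-sided rank-sum tests on per-region
means, and escapees are called from promoter-CGI methylation alone.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .landscape import _intervals_overlap_mask, region_mean_meth

ESCAPEE_MAX_METH = 10.0


def _ranksum(a, b) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) == 0 or len(b) == 0:
        return float("nan")
    return float(mannwhitneyu(a, b, alternative="two-sided").pvalue)


def pcgi_means(
    promoter_cgis: pd.DataFrame,
    cpg_table: pd.DataFrame,
    genome: dict | None = None,
    min_covered_fraction: float = 0.35,
) -> pd.DataFrame:
    """Per promoter-CGI mean methylation with the 35% CpG-coverage rule.

    When a ``genome`` is supplied, CGIs with fewer than
    ``min_covered_fraction`` of their sequence CpGs covered are dropped.
    """
    from .landscape import classify_cgi_methylation

    if genome is not None:
        out = classify_cgi_methylation(
            promoter_cgis, cpg_table, genome, min_covered_fraction=min_covered_fraction
        )
        return out[out["meth_class"] != "NA"].reset_index(drop=True)
    out = region_mean_meth(cpg_table, promoter_cgis)
    return out[out["n_cpg_covered"] > 0].reset_index(drop=True)


def x_vs_autosome_pcgi(
    promoter_cgis: pd.DataFrame,
    cpg_table: pd.DataFrame,
    chrx_name: str = "chrX",
    genome: dict | None = None,
) -> dict:
    """Promoter-CGI methylation on the X vs the autosomes (+ rank-sum p)."""
    means = pcgi_means(promoter_cgis, cpg_table, genome=genome)
    on_x = means["chrom"] == chrx_name
    x_vals = means.loc[on_x, "mean_meth"].to_numpy()
    a_vals = means.loc[~on_x, "mean_meth"].to_numpy()
    return {
        "x": x_vals,
        "autosome": a_vals,
        "p_value": _ranksum(x_vals, a_vals),
        "x_median": float(np.median(x_vals)) if len(x_vals) else float("nan"),
        "autosome_median": float(np.median(a_vals)) if len(a_vals) else float("nan"),
    }


def x_vs_autosome_tiles(
    cpg_table: pd.DataFrame,
    cgis: pd.DataFrame,
    chrom_lengths: dict,
    chrx_name: str = "chrX",
    tile_bp: int = 1000,
) -> dict:
    """Non-CGI background methylation in 1-kb tiles, X vs autosomes.

    Tiles are non-overlapping, fully contained in chromosome bounds, removed
    when they overlap a CGI by >= 1 bp, and contribute when they hold at
    least one covered CpG.
    """
    rows = []
    for chrom, L in chrom_lengths.items():
        starts = np.arange(0, L - tile_bp + 1, tile_bp)
        iv = cgis.loc[cgis["chrom"] == chrom, ["start", "end"]].to_numpy()
        keep = ~_intervals_overlap_mask(starts, starts + tile_bp, iv)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts[keep], "end": starts[keep] + tile_bp}))
    tiles = pd.concat(rows, ignore_index=True)
    means = region_mean_meth(cpg_table, tiles)
    means = means[means["n_cpg_covered"] >= 1]
    on_x = means["chrom"] == chrx_name
    x_vals = means.loc[on_x, "mean_meth"].to_numpy()
    a_vals = means.loc[~on_x, "mean_meth"].to_numpy()
    return {
        "x": x_vals,
        "autosome": a_vals,
        "p_value": _ranksum(x_vals, a_vals),
        "x_median": float(np.median(x_vals)) if len(x_vals) else float("nan"),
        "autosome_median": float(np.median(a_vals)) if len(a_vals) else float("nan"),
    }


def call_escapees(
    promoter_cgis_on_x: pd.DataFrame,
    cpg_table: pd.DataFrame,
    threshold: float = ESCAPEE_MAX_METH,
    genome: dict | None = None,
) -> pd.DataFrame:
    """Predict XCI escapees: X-linked genes whose promoter CGI is < 10% methylated.

    ``promoter_cgis_on_x`` needs chrom/start/end plus a ``gene_id`` column;
    ``is_escapee`` is strict (< threshold), so a pCGI at exactly the
    threshold is called subject to XCI.  The call depends only on X-linked
    data.
    """
    means = pcgi_means(promoter_cgis_on_x, cpg_table, genome=genome)
    out = means.copy()
    out["is_escapee"] = out["mean_meth"] < threshold
    return out


def cross_species_escapees(
    per_species_calls: dict,
    ortholog_map: pd.DataFrame,
    min_species: int = 3,
) -> pd.DataFrame:
    """Orthologs predicted to escape XCI in at least ``min_species`` species."""
    mapping = dict(zip(ortholog_map["gene_id"], ortholog_map["ortholog"]))
    rows = []
    for species, calls in per_species_calls.items():
        esc = calls[calls["is_escapee"]]
        for gid in esc["gene_id"]:
            og = mapping.get(gid)
            if og is not None:
                rows.append((og, species))
    if not rows:
        return pd.DataFrame(columns=["ortholog", "n_species", "species"])
    df = pd.DataFrame(rows, columns=["ortholog", "species"]).drop_duplicates()
    agg = df.groupby("ortholog").agg(
        n_species=("species", "nunique"), species=("species", lambda s: ",".join(sorted(s)))
    ).reset_index()
    agg = agg[agg["n_species"] >= min_species]
    return agg.sort_values(["n_species", "ortholog"], ascending=[False, True]).reset_index(drop=True)
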