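"""Read-level prediction of allelic (imprinted) differentially methylated regions.

Imprinted DMRs show ~50% aggregate methylation because one parental allele is
methylated and the other is not; at the single-read level this produces a
mixture of fully methylated and fully unmethylated molecules, unlike random
partial methylation where individual reads are mosaic.  The caller scans the
genome in 50-bp windows sliding by 10 bp and keeps windows whose

* mean CpG methylation lies between 30 and 60%,
* fraction of overlapping reads that are fully methylated or fully
  unmethylated exceeds 90%, and
* difference between the fully-methylated and fully-unmethylated read
  percentages is below 40,

then merges consecutive passing windows, removes the X chromosome (possible
X-inactivation) and regions overlapping an exclusion track (developmental
genes with variable allele-specific methylation), and applies the mode
thresholds: stringent = at least 20 CpGs and larger than 350 bp, lenient =
at least 10 CpGs with no size gate.

A read's fully-methylated/unmethylated status is judged over ALL of its CpG
calls (reads are pre-filtered to >= 3 calls), not only the calls inside the
window; a read overlaps a window iff at least one of its calls lies inside.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import ReadCallSet
from .landscape import _intervals_overlap_mask

DEFAULT_MEAN_RANGE = (30.0, 60.0)
DEFAULT_MIN_PCT_FULL = 90.0
DEFAULT_MAX_DELTA = 40.0
DEFAULT_MIN_READS = 5
STRINGENT_MIN_CPG = 20
STRINGENT_MIN_SIZE = 350
LENIENT_MIN_CPG = 10


def _window_starts_for_positions(pos: np.ndarray, window: int, step: int):
    """All step-aligned window starts whose [s, s+window) contains each pos.

    Returns (expanded positions index, window starts) with window/step rows
    per input position.
    """
    k_hi = pos // step  # last start <= pos
    n_per = window // step
    offsets = np.arange(n_per) * step
    starts = k_hi[:, None] * step - offsets[None, :]
    idx = np.repeat(np.arange(pos.size), n_per)
    starts = starts.ravel()
    keep = starts >= 0
    return idx[keep], starts[keep]


def window_scan(
    read_calls: ReadCallSet,
    cpg_table: pd.DataFrame,
    window: int = 50,
    step: int = 10,
    min_reads: int = DEFAULT_MIN_READS,
    mean_source: str = "overlapping_reads",
) -> pd.DataFrame:
    """Per-window read-composition statistics over the sliding-window scan.

    One row per (chrom, window start) with at least one overlapping read:
    ``n_reads``, ``pct_fully_m``, ``pct_fully_u``, ``pct_full``, ``delta``
    (|pct_fully_m - pct_fully_u|), ``mean_meth``, and ``low_reads`` flagging
    windows below ``min_reads``.

    ``mean_source`` picks the window methylation estimate:

    * ``"overlapping_reads"`` (default): fraction of methylated calls over
      ALL calls of the window's overlapping reads — the same read cohort the
      fully-methylated/unmethylated percentages are computed on, so all
      window gates see one consistent set of molecules;
    * ``"cpg_table"``: unweighted mean percent of the coverage-table CpGs
      inside the window;
    * ``"window_calls"``: methylated fraction of the read calls falling
      inside the window.
    """
    if window % step != 0:
        raise ValueError("window must be a multiple of step")
    calls = read_calls.calls
    reads = read_calls.reads
    if not len(calls):
        return pd.DataFrame(
            columns=[
                "chrom",
                "start",
                "end",
                "n_reads",
                "pct_fully_m",
                "pct_fully_u",
                "pct_full",
                "delta",
                "mean_meth",
                "low_reads",
            ]
        )
    call_keys = calls["read"].astype(str) + "\x00" + calls["chrom"].astype(str)
    read_codes, read_index = pd.factorize(call_keys)
    idx, starts = _window_starts_for_positions(calls["pos"].to_numpy(), window, step)
    pairs = pd.DataFrame(
        {
            "chrom": calls["chrom"].to_numpy()[idx],
            "win": starts,
            "rcode": read_codes[idx],
        }
    ).drop_duplicates()
    key_to_code = {k: i for i, k in enumerate(read_index)}
    status_codes = (reads["read"].astype(str) + "\x00" + reads["chrom"].astype(str)).map(key_to_code)
    status = reads.assign(rcode=status_codes).dropna(subset=["rcode"])
    status["rcode"] = status["rcode"].astype(int)
    pairs = pairs.merge(
        status[["rcode", "fully_m", "fully_u", "n_calls", "n_meth"]], on="rcode", how="left"
    )
    grp = pairs.groupby(["chrom", "win"], as_index=False).agg(
        n_reads=("rcode", "size"),
        n_fully_m=("fully_m", "sum"),
        n_fully_u=("fully_u", "sum"),
        n_read_calls=("n_calls", "sum"),
        n_read_meth=("n_meth", "sum"),
    )
    grp["pct_fully_m"] = 100.0 * grp["n_fully_m"] / grp["n_reads"]
    grp["pct_fully_u"] = 100.0 * grp["n_fully_u"] / grp["n_reads"]
    grp["pct_full"] = grp["pct_fully_m"] + grp["pct_fully_u"]
    grp["delta"] = (grp["pct_fully_m"] - grp["pct_fully_u"]).abs()

    if mean_source == "overlapping_reads":
        grp["mean_meth"] = 100.0 * grp["n_read_meth"] / grp["n_read_calls"]
        out = grp
    elif mean_source in {"cpg_table", "window_calls"}:
        if mean_source == "window_calls":
            midx, mstarts = _window_starts_for_positions(calls["pos"].to_numpy(), window, step)
            meth_src = pd.DataFrame(
                {
                    "chrom": calls["chrom"].to_numpy()[midx],
                    "win": mstarts,
                    "percent": 100.0 * calls["meth"].to_numpy()[midx],
                }
            )
        else:
            cidx, cstarts = _window_starts_for_positions(cpg_table["pos"].to_numpy(), window, step)
            meth_src = pd.DataFrame(
                {
                    "chrom": cpg_table["chrom"].to_numpy()[cidx],
                    "win": cstarts,
                    "percent": cpg_table["percent"].to_numpy()[cidx],
                }
            )
        meth = meth_src.groupby(["chrom", "win"], as_index=False)["percent"].mean()
        meth = meth.rename(columns={"percent": "mean_meth"})
        out = grp.merge(meth, on=["chrom", "win"], how="left")
    else:
        raise ValueError(f"unknown mean_source {mean_source!r}")
    out = out.rename(columns={"win": "start"})
    out["end"] = out["start"] + window
    out["low_reads"] = out["n_reads"] < min_reads
    cols = [
        "chrom",
        "start",
        "end",
        "n_reads",
        "pct_fully_m",
        "pct_fully_u",
        "pct_full",
        "delta",
        "mean_meth",
        "low_reads",
    ]
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)[cols]


def filter_windows(
    stats: pd.DataFrame,
    mean_range: tuple = DEFAULT_MEAN_RANGE,
    min_pct_full: float = DEFAULT_MIN_PCT_FULL,
    max_delta: float = DEFAULT_MAX_DELTA,
    min_reads: int = DEFAULT_MIN_READS,
) -> pd.DataFrame:
    """Windows passing the allelic-methylation gates.

    Pass iff ``mean_range[0] <= mean_meth <= mean_range[1]`` and
    ``pct_full > min_pct_full`` and ``delta < max_delta`` and
    ``n_reads >= min_reads``.
    """
    m = stats["mean_meth"]
    ok = (
        (m >= mean_range[0])
        & (m <= mean_range[1])
        & (stats["pct_full"] > min_pct_full)
        & (stats["delta"] < max_delta)
        & (stats["n_reads"] >= min_reads)
    )
    return stats[ok.fillna(False)].reset_index(drop=True)


def merge_windows(passing: pd.DataFrame, cpg_table: pd.DataFrame, step: int = 10) -> pd.DataFrame:
    """Union consecutive/overlapping passing windows into candidate regions.

    Two windows merge when they overlap or touch (bookended, the interval
    merge convention of the standard genome-arithmetic tools); this subsumes
    windows whose starts are exactly ``step`` apart, which are adjacent in
    the scan.  A merged region spans the union and counts the distinct
    covered CpGs and their mean methylation over its span.  Idempotent and
    order-independent.
    """
    rows = []
    for chrom, sub in passing.groupby("chrom"):
        sub = sub.sort_values("start")
        cur_s, cur_e = None, None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    merged = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    n_cpg = np.zeros(len(merged), dtype=np.int64)
    mean = np.full(len(merged), np.nan)
    for chrom, sub in cpg_table.groupby("chrom"):
        sel = merged.index[merged["chrom"] == chrom].to_numpy()
        if not len(sel):
            continue
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        pct = sub["percent"].to_numpy()
        csum = np.concatenate([[0.0], np.cumsum(pct)])
        lo = np.searchsorted(pos, merged.loc[sel, "start"].to_numpy())
        hi = np.searchsorted(pos, merged.loc[sel, "end"].to_numpy())
        n = hi - lo
        n_cpg[sel] = n
        with np.errstate(invalid="ignore"):
            mean[sel] = (csum[hi] - csum[lo]) / np.where(n > 0, n, np.nan)
    merged["n_cpg"] = n_cpg
    merged["size_bp"] = merged["end"] - merged["start"]
    merged["mean_meth"] = mean
    return merged


def apply_mode_filters(
    candidates: pd.DataFrame,
    mode: str,
    exclusions: pd.DataFrame | None = None,
    chrx_name: str = "chrX",
    chrom_names=None,
) -> pd.DataFrame:
    """Remove X-linked and excluded regions, then apply the mode thresholds.

    ``mode``: "stringent" (>= 20 CpGs and > 350 bp) or "lenient"
    (>= 10 CpGs, no size gate).  Stringent calls are a subset of lenient
    calls on identical input.
    """
    if mode not in {"stringent", "lenient"}:
        raise ValueError(f"unknown mode {mode!r}")
    if chrom_names is not None and chrx_name not in set(chrom_names):
        raise ValueError(f"X chromosome {chrx_name!r} not among known chromosomes")
    out = candidates[candidates["chrom"] != chrx_name]
    if exclusions is not None and len(exclusions):
        drop = np.zeros(len(out), dtype=bool)
        out = out.reset_index(drop=True)
        for chrom, sub in exclusions.groupby("chrom"):
            sel = out.index[out["chrom"] == chrom].to_numpy()
            if not len(sel):
                continue
            drop[sel] = _intervals_overlap_mask(
                out.loc[sel, "start"].to_numpy(),
                out.loc[sel, "end"].to_numpy(),
                sub[["start", "end"]].to_numpy(),
            )
        out = out[~drop]
    if mode == "stringent":
        out = out[(out["n_cpg"] >= STRINGENT_MIN_CPG) & (out["size_bp"] > STRINGENT_MIN_SIZE)]
    else:
        out = out[out["n_cpg"] >= LENIENT_MIN_CPG]
    return out.reset_index(drop=True)


def associate_genes(dmrs: pd.DataFrame, genes, max_distance_bp: int = 50_000) -> pd.DataFrame:
    """Annotate each DMR with its nearest gene body within ``max_distance_bp``.

    Distance is 0 for overlaps, otherwise the gap to the gene body; DMRs with
    no gene within range stay unassigned (empty gene, distance NaN).  Ties
    break towards the lexicographically smaller gene id for determinism.
    """
    gene_rows = [(g.gene_id, g.chrom, g.start, g.end) for g in genes]
    gdf = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end"])
    nearest, dist = [], []
    for _, r in dmrs.iterrows():
        sub = gdf[gdf["chrom"] == r["chrom"]]
        if not len(sub):
            nearest.append("")
            dist.append(np.nan)
            continue
        gap = np.maximum(sub["start"].to_numpy() - r["end"], 0) + np.maximum(
            r["start"] - sub["end"].to_numpy(), 0
        )
        order = np.lexsort((sub["gene_id"].to_numpy(), gap))
        best = order[0]
        if gap[best] <= max_distance_bp:
            nearest.append(sub["gene_id"].to_numpy()[best])
            dist.append(int(gap[best]))
        else:
            nearest.append("")
            dist.append(np.nan)
    out = dmrs.reset_index(drop=True).copy()
    out["nearest_gene"] = nearest
    out["distance_bp"] = dist
    return out


def call_dmrs(
    read_calls: ReadCallSet,
    cpg_table: pd.DataFrame,
    genes,
    exclusions: pd.DataFrame | None = None,
    chrx_name: str = "chrX",
    window: int = 50,
    step: int = 10,
    min_reads: int = DEFAULT_MIN_READS,
    mean_range: tuple = DEFAULT_MEAN_RANGE,
    min_pct_full: float = DEFAULT_MIN_PCT_FULL,
    max_delta: float = DEFAULT_MAX_DELTA,
    max_gene_distance_bp: int = 50_000,
    mean_source: str = "overlapping_reads",
) -> pd.DataFrame:
    """Full caller: scan, gate, merge, mode filters and gene association.

    Returns one row per candidate passing at least the lenient mode, with
    boolean ``stringent``/``lenient`` columns.
    """
    stats = window_scan(
        read_calls,
        cpg_table,
        window=window,
        step=step,
        min_reads=min_reads,
        mean_source=mean_source,
    )
    passing = filter_windows(
        stats,
        mean_range=mean_range,
        min_pct_full=min_pct_full,
        max_delta=max_delta,
        min_reads=min_reads,
    )
    merged = merge_windows(passing, cpg_table, step=step)
    lenient = apply_mode_filters(merged, "lenient", exclusions, chrx_name)
    stringent = apply_mode_filters(merged, "stringent", exclusions, chrx_name)
    key = lambda df: df["chrom"].astype(str) + ":" + df["start"].astype(str)
    lenient = lenient.copy()
    lenient["stringent"] = key(lenient).isin(set(key(stringent)))
    lenient["lenient"] = True
    return associate_genes(lenient, genes, max_distance_bp=max_gene_distance_bp)


def cross_species_dmr_genes(
    per_species_calls: dict,
    ortholog_map: pd.DataFrame,
    min_species: int = 2,
) -> pd.DataFrame:
    """Genes with predicted allelic DMRs in at least ``min_species`` species.

    ``per_species_calls`` maps species name to a calls table (from
    :func:`call_dmrs`); ``ortholog_map`` maps every species' gene ids into a
    common ortholog namespace.  Ranked by species count, then by the number
    of species with a stringent-mode call.
    """
    if not len(ortholog_map):
        warnings.warn("empty ortholog map; no cross-species genes")
        return pd.DataFrame(columns=["ortholog", "n_species", "n_stringent", "species"])
    mapping = dict(zip(ortholog_map["gene_id"], ortholog_map["ortholog"]))
    rows = []
    for species, calls in per_species_calls.items():
        with_gene = calls[calls["nearest_gene"] != ""]
        unmapped = set(with_gene["nearest_gene"]) - set(mapping)
        if unmapped:
            warnings.warn(f"{species}: {len(unmapped)} DMR gene(s) missing from ortholog map")
        for _, r in with_gene.iterrows():
            og = mapping.get(r["nearest_gene"])
            if og is None:
                continue
            rows.append((og, species, bool(r["stringent"])))
    if not rows:
        return pd.DataFrame(columns=["ortholog", "n_species", "n_stringent", "species"])
    df = pd.DataFrame(rows, columns=["ortholog", "species", "stringent"])
    agg = (
        df.groupby("ortholog")
        .agg(
            n_species=("species", "nunique"),
            n_stringent=("species", lambda s: df.loc[s.index].loc[lambda d: d["stringent"], "species"].nunique()),
            species=("species", lambda s: ",".join(sorted(set(s)))),
        )
        .reset_index()
    )
    agg = agg[agg["n_species"] >= min_species]
    return agg.sort_values(
        ["n_species", "n_stringent", "ortholog"], ascending=[False, False, True]
    ).reset_index(drop=True)
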