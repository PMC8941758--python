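"""Genome-scale CpG-density and methylation statistics.

CG observed/expected ratio windows, global methylation means, CGI feature
annotation and methylation classes, promoter definition and LCP/ICP/HCP
classification, gene metaplots, gene-body methylation and feature-stratified
CpG methylation distributions.

The CpG ratio follows the observed/expected convention
``(n_CpG * length) / (n_C * n_G)`` with N bases excluded from all counts and
a declared convention of ratio 0 when the denominator is 0.  All per-region
methylation means are unweighted across covered CpGs (depth-independent),
matching percent-based methylation extraction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import GeneModel

# CGI methylation class bounds (percent scale)
UNMETH_MAX = 10.0
LOW_MAX = 50.0


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------


def _as_codes(seq) -> np.ndarray:
    """Accept a string, pyfaidx sequence or uint8 code array (0=A..3=T, 4=N)."""
    if isinstance(seq, np.ndarray):
        return seq
    s = str(seq).upper()
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.size, 4, dtype=np.uint8)
    for base, code in (("A", 0), ("C", 1), ("G", 2), ("T", 3)):
        codes[arr == ord(base)] = code
    return codes


def cpg_ratio(seq) -> float:
    """CG observed/expected ratio of a sequence.

    ``(number of CpGs x number of bp) / (number of Cs x number of Gs)``;
    N bases are excluded from the counts and from the length; returns 0.0
    when the denominator is 0.  Raises on an empty sequence.
    """
    codes = _as_codes(seq)
    if codes.size == 0:
        raise ValueError("empty sequence")
    n_c = int((codes == 1).sum())
    n_g = int((codes == 2).sum())
    n_cpg = int(((codes[:-1] == 1) & (codes[1:] == 2)).sum()) if codes.size > 1 else 0
    length = int((codes != 4).sum())
    if n_c == 0 or n_g == 0:
        return 0.0
    return n_cpg * length / (n_c * n_g)


def gc_percent(seq) -> float:
    codes = _as_codes(seq)
    non_n = int((codes != 4).sum())
    if non_n == 0:
        return float("nan")
    return 100.0 * int(((codes == 1) | (codes == 2)).sum()) / non_n


def sliding_cg_ratio(genome: dict, window: int = 500, step: int | None = None) -> pd.DataFrame:
    """CG o/e ratio in sliding windows over every chromosome.

    ``genome`` maps chromosome name to sequence (string or code array).
    Windows with more than 50% N are dropped.  ``step`` defaults to
    ``window`` (a non-overlapping tiling).
    """
    if step is None:
        step = window
    rows = []
    for chrom, seq in genome.items():
        codes = _as_codes(seq)
        L = codes.size
        if L < window:
            continue
        is_cpg = np.zeros(L, dtype=np.int64)
        is_cpg[:-1] = (codes[:-1] == 1) & (codes[1:] == 2)

        def cum(x):
            return np.concatenate([[0], np.cumsum(x)])

        cc = cum((codes == 1).astype(np.int64))
        cg_ = cum((codes == 2).astype(np.int64))
        cn = cum((codes == 4).astype(np.int64))
        ccpg = cum(is_cpg)
        starts = np.arange(0, L - window + 1, step)
        ends = starts + window
        n_c = cc[ends] - cc[starts]
        n_g = cg_[ends] - cg_[starts]
        n_n = cn[ends] - cn[starts]
        n_cpg = ccpg[ends] - ccpg[starts]
        length = window - n_n
        denom = n_c * n_g
        ratio = np.where(denom > 0, n_cpg * length / np.maximum(denom, 1), 0.0)
        gc = np.where(length > 0, 100.0 * (n_c + n_g) / np.maximum(length, 1), np.nan)
        keep = n_n <= window / 2
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts[keep],
                    "end": ends[keep],
                    "n_cpg": n_cpg[keep],
                    "n_c": n_c[keep],
                    "n_g": n_g[keep],
                    "length_bp": length[keep],
                    "ratio": ratio[keep],
                    "gc_percent": gc[keep],
                }
            )
        )
    cols = ["chrom", "start", "end", "n_cpg", "n_c", "n_g", "length_bp", "ratio", "gc_percent"]
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=cols)


# ---------------------------------------------------------------------------
# interval arithmetic over the CpG table
# ---------------------------------------------------------------------------


def _merge_intervals(iv: np.ndarray) -> np.ndarray:
    """Union of possibly overlapping [start, end) intervals (n x 2)."""
    if len(iv) == 0:
        return np.empty((0, 2), dtype=np.int64)
    iv = np.asarray(iv, dtype=np.int64)
    iv = iv[np.argsort(iv[:, 0])]
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


def _in_intervals(pos: np.ndarray, intervals) -> np.ndarray:
    """Boolean mask: which positions fall in the union of [start, end)."""
    intervals = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    if len(intervals) == 0 or len(pos) == 0:
        return np.zeros(len(pos), dtype=bool)
    merged = _merge_intervals(intervals)
    idx = np.searchsorted(merged[:, 0], pos, side="right") - 1
    ok = idx >= 0
    res = np.zeros(len(pos), dtype=bool)
    res[ok] = pos[ok] < merged[idx[ok], 1]
    return res


def _intervals_overlap_mask(starts, ends, iv_list) -> np.ndarray:
    """For each query [start, end), whether it overlaps any interval."""
    if not len(iv_list):
        return np.zeros(len(starts), dtype=bool)
    merged = _merge_intervals(np.asarray(iv_list))
    # candidate: last interval starting before the query end
    idx = np.searchsorted(merged[:, 0], ends, side="left") - 1
    res = np.zeros(len(starts), dtype=bool)
    ok = idx >= 0
    res[ok] = merged[idx[ok], 1] > np.asarray(starts)[ok]
    return res


def region_mean_meth(cpg_table: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    """Per-region unweighted mean CpG methylation and covered-CpG count.

    ``regions`` needs chrom/start/end; the result adds ``n_cpg_covered`` and
    ``mean_meth`` (NaN when no covered CpG falls in the region).
    """
    regions = regions.reset_index(drop=True).copy()
    mean = np.full(len(regions), np.nan)
    n_cov = np.zeros(len(regions), dtype=np.int64)
    for chrom, sub in cpg_table.groupby("chrom"):
        sel = regions.index[regions["chrom"] == chrom].to_numpy()
        if not len(sel):
            continue
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        pct = sub["percent"].to_numpy()
        csum = np.concatenate([[0.0], np.cumsum(pct)])
        lo = np.searchsorted(pos, regions.loc[sel, "start"].to_numpy())
        hi = np.searchsorted(pos, regions.loc[sel, "end"].to_numpy())
        n = hi - lo
        with np.errstate(invalid="ignore"):
            m = (csum[hi] - csum[lo]) / np.where(n > 0, n, np.nan)
        mean[sel] = m
        n_cov[sel] = n
    regions["n_cpg_covered"] = n_cov
    regions["mean_meth"] = mean
    return regions


def global_mean_methylation(cpg_table: pd.DataFrame) -> float:
    """Unweighted mean of per-CpG percent methylation (depth-filtered input)."""
    if not len(cpg_table):
        raise ValueError("empty CpG table")
    return float(cpg_table["percent"].mean())


def methylation_by_cg_ratio(
    windows: pd.DataFrame, cpg_table: pd.DataFrame, ratio_bins
) -> pd.Series:
    """Median of window mean methylation per CG-ratio bin.

    Windows without a covered CpG do not contribute; empty bins yield NaN.
    """
    win = region_mean_meth(cpg_table, windows)
    win = win[win["n_cpg_covered"] >= 1]
    binned = pd.cut(win["ratio"], bins=ratio_bins)
    return win.groupby(binned, observed=False)["mean_meth"].median()


# ---------------------------------------------------------------------------
# CGI feature annotation and methylation classes
# ---------------------------------------------------------------------------


def annotate_cgi_features(cgis: pd.DataFrame, genes: list[GeneModel]) -> pd.DataFrame:
    """Classify CGIs by overlap precedence promoter(TSS) > CDS > intron > intergenic.

    Exon intervals stand in for coding sequence; introns are the within-body
    complement of a gene's exons.
    """
    tss_iv, cds_iv, intron_iv = {}, {}, {}
    for g in genes:
        tss_iv.setdefault(g.chrom, []).append((g.tss, g.tss + 1))
        exons = sorted({tuple(e) for t in (g.transcripts or [[g.body]]) for e in t})
        if not exons:
            exons = [g.body]
        for e in exons:
            cds_iv.setdefault(g.chrom, []).append(tuple(e))
        prev_end = None
        for s, e in exons:
            if prev_end is not None and s > prev_end:
                intron_iv.setdefault(g.chrom, []).append((prev_end, s))
            prev_end = e if prev_end is None else max(prev_end, e)
    out = cgis.reset_index(drop=True).copy()
    feature = np.full(len(out), "intergenic", dtype=object)
    for chrom, sel in out.groupby("chrom").groups.items():
        sel = np.asarray(sel)
        starts = out.loc[sel, "start"].to_numpy()
        ends = out.loc[sel, "end"].to_numpy()
        is_prom = _intervals_overlap_mask(starts, ends, tss_iv.get(chrom, []))
        is_cds = _intervals_overlap_mask(starts, ends, cds_iv.get(chrom, []))
        is_intron = _intervals_overlap_mask(starts, ends, intron_iv.get(chrom, []))
        feature[sel] = np.where(
            is_prom, "promoter", np.where(is_cds, "CDS", np.where(is_intron, "intron", "intergenic"))
        )
    out["feature_class"] = feature
    return out


def classify_cgi_methylation(
    cgis: pd.DataFrame,
    cpg_table: pd.DataFrame,
    genome: dict,
    min_covered_fraction: float = 0.35,
) -> pd.DataFrame:
    """Assign per-CGI methylation classes with a CpG-coverage gate.

    Classes on the unweighted mean over covered CpGs: unmethylated (< 10%),
    low (10-50%), high (> 50%); NA when fewer than ``min_covered_fraction``
    of the CGI's sequence CpGs are covered (or the CGI has no CpG at all).
    """
    out = region_mean_meth(cpg_table, cgis)
    total = np.zeros(len(out), dtype=np.int64)
    for i, r in out.iterrows():
        seq = _as_codes(genome[r["chrom"]])[int(r["start"]) : int(r["end"])]
        total[i] = int(((seq[:-1] == 1) & (seq[1:] == 2)).sum()) if seq.size > 1 else 0
    out["n_cpg_total"] = total
    out["covered_cpg_fraction"] = np.where(
        total > 0, out["n_cpg_covered"] / np.maximum(total, 1), 0.0
    )
    if (total == 0).any():
        warnings.warn(f"{int((total == 0).sum())} CGI(s) contain no CpG in sequence; class NA")
    cls = np.full(len(out), "NA", dtype=object)
    ok = (out["covered_cpg_fraction"].to_numpy() >= min_covered_fraction) & (total > 0)
    m = out["mean_meth"].to_numpy()
    cls[ok & (m < UNMETH_MAX)] = "unmethylated"
    cls[ok & (m >= UNMETH_MAX) & (m <= LOW_MAX)] = "low"
    cls[ok & (m > LOW_MAX)] = "high"
    out["meth_class"] = cls
    return out


def cgi_class_proportions(classified: pd.DataFrame) -> pd.Series:
    """Percent of non-NA CGIs per methylation class (sums to 100)."""
    counts = classified.loc[classified["meth_class"] != "NA", "meth_class"].value_counts()
    return 100.0 * counts / counts.sum()


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------


def promoter_window(tss: int, strand: str, upstream: int = 1000, downstream: int = 500):
    """Strand-oriented promoter interval ([TSS-1000, TSS+500) on plus)."""
    if strand == "+":
        return tss - upstream, tss + downstream
    return tss - downstream, tss + upstream


def define_promoters(
    genes: list[GeneModel],
    genome: dict,
    upstream: int = 1000,
    downstream: int = 500,
) -> pd.DataFrame:
    """One promoter per gene: the isoform TSS window with the highest CpG ratio.

    Candidate TSSs are the strand-oriented 5' ends of every transcript (plus
    the gene TSS).  Windows truncated at contig bounds are flagged.
    """
    rows = []
    for g in genes:
        tss_set = {g.tss}
        for exons in g.transcripts:
            t_start = min(e[0] for e in exons)
            t_end = max(e[1] for e in exons)
            tss_set.add(t_start if g.strand == "+" else t_end - 1)
        codes = _as_codes(genome[g.chrom])
        L = codes.size
        best = None
        for tss in sorted(tss_set):
            s, e = promoter_window(tss, g.strand, upstream, downstream)
            truncated = s < 0 or e > L
            s_c, e_c = max(s, 0), min(e, L)
            seq = codes[s_c:e_c]
            ratio = cpg_ratio(seq) if seq.size else 0.0
            gc = gc_percent(seq) if seq.size else float("nan")
            cand = (ratio, tss, s_c, e_c, gc, truncated)
            if best is None or cand[0] > best[0]:
                best = cand
        ratio, tss, s, e, gc, truncated = best
        rows.append((g.gene_id, g.name, g.chrom, s, e, g.strand, tss, ratio, gc, truncated))
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "name",
            "chrom",
            "start",
            "end",
            "strand",
            "tss",
            "cpg_ratio",
            "gc_percent",
            "truncated",
        ],
    )


def classify_promoters(
    promoters: pd.DataFrame, lower: float, upper: float, gc_min: float = 55.0
) -> pd.DataFrame:
    """LCP/ICP/HCP classes from species-specific CpG-ratio cutoffs.

    HCP: ratio > upper and GC% > gc_min; LCP: ratio < lower; everything else
    ICP.  Total: every promoter gets exactly one class.
    """
    if lower >= upper:
        raise ValueError(f"lower cutoff ({lower}) must be below upper cutoff ({upper})")
    out = promoters.copy()
    ratio = out["cpg_ratio"].to_numpy()
    gc = out["gc_percent"].to_numpy()
    cls = np.full(len(out), "ICP", dtype=object)
    cls[(ratio > upper) & (gc > gc_min)] = "HCP"
    cls[ratio < lower] = "LCP"
    out["promoter_class"] = cls
    return out


def suggest_promoter_cutoffs(ratios) -> dict:
    """Heuristic LCP/HCP cutoffs from antimodes of the promoter-ratio density.

    Fits a Gaussian KDE and proposes the outermost density minima as
    {lower, upper}.  Advisory only; classification always takes explicit
    cutoffs.
    """
    from scipy.stats import gaussian_kde

    r = np.asarray(ratios, dtype=float)
    r = r[np.isfinite(r)]
    kde = gaussian_kde(r)
    grid = np.linspace(r.min(), r.max(), 512)
    dens = kde(grid)
    minima = [
        float(grid[i])
        for i in range(1, len(grid) - 1)
        if dens[i] < dens[i - 1] and dens[i] <= dens[i + 1]
    ]
    if not minima:
        anti = float(np.median(r))
        return {"lower": anti * 0.8, "upper": anti}
    return {"lower": min(minima), "upper": max(minima)}


# ---------------------------------------------------------------------------
# metaplots and gene-body methylation
# ---------------------------------------------------------------------------


def gene_metaplot(
    genes: list[GeneModel],
    cpg_table: pd.DataFrame,
    n_body_bins: int = 20,
    flank_bins: int = 10,
    flank_bin_bp: int = 1000,
    exclude_chroms: set | None = None,
) -> dict:
    """Mean methylation profile over genes: 5' flank, scaled body, 3' flank.

    Per gene, each bin's value is the mean methylation of the CpGs it covers;
    the profile is the unweighted mean over genes of the per-gene bin values
    (a gene contributes nothing to a bin without covered CpGs).  Genes
    shorter than ``n_body_bins`` bp are skipped and counted.  ``exclude_chroms``
    typically holds the X chromosome (autosome-only convention).
    """
    n_bins = n_body_bins + 2 * flank_bins
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    n_skipped = 0
    by_chrom = {c: s.sort_values("pos") for c, s in cpg_table.groupby("chrom")}
    for g in genes:
        if exclude_chroms and g.chrom in exclude_chroms:
            continue
        if g.end - g.start < n_body_bins:
            n_skipped += 1
            continue
        if g.chrom not in by_chrom:
            continue
        pos = by_chrom[g.chrom]["pos"].to_numpy()
        pct = by_chrom[g.chrom]["percent"].to_numpy()
        edges = np.concatenate(
            [
                g.start - flank_bin_bp * np.arange(flank_bins, 0, -1),
                np.linspace(g.start, g.end, n_body_bins + 1),
                g.end + flank_bin_bp * np.arange(1, flank_bins + 1),
            ]
        )
        lo = np.searchsorted(pos, edges[:-1])
        hi = np.searchsorted(pos, edges[1:])
        csum = np.concatenate([[0.0], np.cumsum(pct)])
        n = hi - lo
        with np.errstate(invalid="ignore"):
            binmeans = (csum[hi] - csum[lo]) / np.where(n > 0, n, np.nan)
        if g.strand == "-":
            binmeans = binmeans[::-1]
        got = ~np.isnan(binmeans)
        sums[got] += binmeans[got]
        counts[got] += 1
    with np.errstate(invalid="ignore"):
        profile = sums / np.where(counts > 0, counts, np.nan)
    return {"profile": profile, "n_genes_per_bin": counts, "n_skipped": n_skipped}


def gene_body_methylation(genes: list[GeneModel], cpg_table: pd.DataFrame) -> pd.DataFrame:
    """Per-gene mean CpG methylation from +500 bp after the TSS to the gene end.

    Strand-oriented on the isoform-merged body; NaN when the region holds no
    covered CpG.
    """
    rows = []
    for g in genes:
        if g.strand == "+":
            s, e = g.tss + 500, g.end
        else:
            s, e = g.start, g.tss - 500 + 1
        rows.append((g.gene_id, g.chrom, max(s, g.start), min(e, g.end)))
    regions = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])
    regions = regions[regions["end"] > regions["start"]].reset_index(drop=True)
    res = region_mean_meth(cpg_table, regions)
    all_ids = pd.DataFrame({"gene_id": [g.gene_id for g in genes]})
    return all_ids.merge(res[["gene_id", "n_cpg_covered", "mean_meth"]], on="gene_id", how="left")


def feature_stratified_methylation(
    cpg_table: pd.DataFrame,
    promoters: pd.DataFrame,
    genes: list[GeneModel],
    tes: pd.DataFrame | None = None,
) -> dict:
    """Per-feature CpG methylation distributions.

    Each CpG is assigned one class by precedence promoter > exon > intron >
    intergenic; the transposable-element layer is independent (a CpG in a TE
    also appears in its positional class).
    """
    exon_iv, intron_iv = {}, {}
    for g in genes:
        exons = sorted({tuple(e) for t in (g.transcripts or [[g.body]]) for e in t})
        for e in exons:
            exon_iv.setdefault(g.chrom, []).append(tuple(e))
        prev = None
        for s, e in exons:
            if prev is not None and s > prev:
                intron_iv.setdefault(g.chrom, []).append((prev, s))
            prev = e if prev is None else max(prev, e)
    prom_iv = {
        chrom: list(zip(sub["start"], sub["end"]))
        for chrom, sub in promoters.groupby("chrom")
    }
    te_iv = {}
    if tes is not None:
        te_iv = {
            chrom: list(zip(sub["start"], sub["end"])) for chrom, sub in tes.groupby("chrom")
        }
    out = {"promoter": [], "exon": [], "intron": [], "intergenic": [], "TE": []}
    for chrom, sub in cpg_table.groupby("chrom"):
        pos = sub["pos"].to_numpy()
        pct = sub["percent"].to_numpy()
        in_prom = _in_intervals(pos, prom_iv.get(chrom, []))
        in_exon = _in_intervals(pos, exon_iv.get(chrom, []))
        in_intron = _in_intervals(pos, intron_iv.get(chrom, []))
        in_te = _in_intervals(pos, te_iv.get(chrom, []))
        out["promoter"].append(pct[in_prom])
        out["exon"].append(pct[in_exon & ~in_prom])
        out["intron"].append(pct[in_intron & ~in_prom & ~in_exon])
        out["intergenic"].append(pct[~(in_prom | in_exon | in_intron)])
        out["TE"].append(pct[in_te])
    return {k: (np.concatenate(v) if v else np.array([])) for k, v in out.items()}
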