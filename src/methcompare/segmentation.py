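"""Methylome segmentation: PMDs, UMRs, DMVs and cross-species conservation.

PMD (partially methylated domain) detection is a documented windowed
approximation, not a hidden-Markov segmentation: a CpG belongs to a PMD when
more than half of the CpGs in a surrounding window of fixed CpG count have
intermediate methylation, and flagged runs are merged.  UMRs (unmethylated
regions) are maximal runs of at least ``n_cpg_cutoff`` consecutive CpGs whose
smoothed methylation fraction stays below ``meth_cutoff`` (defaults 5 CpGs
and 0.5), computed outside PMDs.  DMVs (DNA methylation valleys) are UMRs
spanning at least 5 kb.  Methylation enters the segmentation math as
fractions in [0, 1]; tables carry percents and are converted explicitly.

Externally supplied PMD intervals (e.g. from another segmentation tool) can
be passed to the UMR caller in place of the built-in approximation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .landscape import _in_intervals, _merge_intervals


def detect_pmds(
    cpg_table: pd.DataFrame,
    win_cpgs: int = 101,
    intermediate_band: tuple = (0.3, 0.7),
    frac_cutoff: float = 0.5,
    merge_gap_bp: int = 0,
) -> pd.DataFrame:
    """Windowed intermediate-methylation PMD caller.

    A CpG-centred window of ``win_cpgs`` CpGs votes PMD when the fraction of
    its CpGs with methylation inside ``intermediate_band`` (fractions of 1)
    exceeds ``frac_cutoff``; maximal runs of voting CpGs become intervals
    snapped to their first/last CpG, merged across gaps up to
    ``merge_gap_bp``.
    """
    lo_band, hi_band = intermediate_band
    half = win_cpgs // 2
    rows = []
    for chrom, sub in cpg_table.groupby("chrom"):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        frac = sub["percent"].to_numpy() / 100.0
        if pos.size < win_cpgs:
            warnings.warn(f"{chrom}: fewer than {win_cpgs} CpGs; no PMD call")
            continue
        inter = ((frac > lo_band) & (frac < hi_band)).astype(np.int64)
        csum = np.concatenate([[0], np.cumsum(inter)])
        centers = np.arange(pos.size)
        w_lo = np.maximum(centers - half, 0)
        w_hi = np.minimum(centers + half + 1, pos.size)
        votes = (csum[w_hi] - csum[w_lo]) / (w_hi - w_lo) > frac_cutoff
        if not votes.any():
            continue
        breaks = np.nonzero(np.diff(votes.astype(np.int8)))[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [votes.size - 1]])
        for s_i, e_i in zip(starts, ends):
            if votes[s_i]:
                rows.append((chrom, int(pos[s_i]), int(pos[e_i]) + 1))
    pmds = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    if merge_gap_bp > 0 and len(pmds):
        merged_rows = []
        for chrom, sub in pmds.groupby("chrom"):
            iv = sub[["start", "end"]].to_numpy().copy()
            iv[:, 1] += merge_gap_bp
            merged = _merge_intervals(iv)
            merged[:, 1] -= merge_gap_bp
            for s, e in merged:
                merged_rows.append((chrom, int(s), int(e)))
        pmds = pd.DataFrame(merged_rows, columns=["chrom", "start", "end"])
    return pmds.sort_values(["chrom", "start"]).reset_index(drop=True)


def detect_umrs(
    cpg_table: pd.DataFrame,
    pmds: pd.DataFrame | None = None,
    meth_cutoff: float = 0.5,
    n_cpg_cutoff: int = 5,
    smooth_k: int = 3,
) -> pd.DataFrame:
    """Unmethylated regions: runs of low-methylation CpGs outside PMDs.

    CpG methylation fractions are smoothed with a centred running mean over
    ``smooth_k`` CpGs (truncated at chromosome ends); maximal runs of at
    least ``n_cpg_cutoff`` consecutive CpGs with smoothed fraction below
    ``meth_cutoff`` become UMRs spanning their first..last CpG.  CpGs inside
    ``pmds`` cannot belong to a UMR and break runs (a UMR never spans a
    masked region).
    """
    rows = []
    for chrom, sub in cpg_table.groupby("chrom"):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        frac = sub["percent"].to_numpy() / 100.0
        masked = np.zeros(pos.size, dtype=bool)
        if pmds is not None and len(pmds):
            iv = pmds.loc[pmds["chrom"] == chrom, ["start", "end"]].to_numpy()
            masked = _in_intervals(pos, iv)
        if pos.size == 0:
            continue
        half = smooth_k // 2
        csum = np.concatenate([[0.0], np.cumsum(frac)])
        idx = np.arange(pos.size)
        w_lo = np.maximum(idx - half, 0)
        w_hi = np.minimum(idx + half + 1, pos.size)
        # rounding guards the strict < cutoff against cumulative-sum float
        # error when a window mean ties the cutoff exactly
        smooth = np.round((csum[w_hi] - csum[w_lo]) / (w_hi - w_lo), 12)
        low = (smooth < meth_cutoff) & ~masked
        if not low.any():
            continue
        breaks = np.nonzero(np.diff(low.astype(np.int8)))[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [low.size - 1]])
        for s_i, e_i in zip(starts, ends):
            n = e_i - s_i + 1
            if low[s_i] and n >= n_cpg_cutoff:
                seg = slice(s_i, e_i + 1)
                rows.append(
                    (chrom, int(pos[s_i]), int(pos[e_i]) + 1, int(n), float(frac[seg].mean()))
                )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_cpg", "mean_meth"])


def call_dmvs(umrs: pd.DataFrame, min_size_bp: int = 5000) -> pd.DataFrame:
    """DNA methylation valleys: UMRs with size >= ``min_size_bp`` (inclusive)."""
    if not len(umrs):
        return umrs.copy()
    size = umrs["end"] - umrs["start"]
    return umrs[size >= min_size_bp].reset_index(drop=True)


def dmv_gene_overlap(dmvs: pd.DataFrame, genes) -> set:
    """Gene ids of genes overlapping any DMV by at least 1 bp."""
    out = set()
    by_chrom: dict[str, list] = {}
    for _, r in dmvs.iterrows():
        by_chrom.setdefault(r["chrom"], []).append((r["start"], r["end"]))
    for g in genes:
        for s, e in by_chrom.get(g.chrom, []):
            if g.start < e and s < g.end:
                out.add(g.gene_id)
                break
    return out


def conservation_percent(genes_a, genes_b, ortholog_map: pd.DataFrame | dict) -> float:
    """Shared-gene percentage of two gene sets in ortholog space: 100*n/min(x, y).

    Gene ids are mapped through ``ortholog_map`` (gene_id -> ortholog);
    unmapped genes are dropped.  Symmetric; equals 100 whenever one mapped
    set contains the other; NaN if either mapped set is empty.
    """
    if isinstance(ortholog_map, pd.DataFrame):
        mapping = dict(zip(ortholog_map["gene_id"], ortholog_map["ortholog"]))
    else:
        mapping = dict(ortholog_map)
    a = {mapping[g] for g in genes_a if g in mapping}
    b = {mapping[g] for g in genes_b if g in mapping}
    if not a or not b:
        return float("nan")
    return 100.0 * len(a & b) / min(len(a), len(b))


def genome_fraction(intervals: pd.DataFrame, chrom_lengths: dict) -> float:
    """Fraction of the genome covered by the (merged) intervals."""
    total = sum(chrom_lengths.values())
    if not total:
        return float("nan")
    covered = 0
    if len(intervals):
        for _, sub in intervals.groupby("chrom"):
            merged = _merge_intervals(sub[["start", "end"]].to_numpy())
            covered += int((merged[:, 1] - merged[:, 0]).sum())
    return covered / total
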