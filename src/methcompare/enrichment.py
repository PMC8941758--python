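"""Hypergeometric over-representation with Benjamini-Hochberg adjustment.

Generic gene-set enrichment: given a selection (e.g. genes upregulated after
DNA-methyltransferase inhibition), a target set (e.g. germline-gene
orthologs) and a background universe, the upper-tail hypergeometric p-value
P(X >= k) measures over-representation of the target among the selection.
Multiple sets are corrected with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class EnrichmentResult:
    set_name: str
    k: int  # hits: |selection & target|
    K: int  # target size within the background
    n: int  # selection size
    N: int  # background size
    fold: float  # (k/n) / (K/N)
    p: float  # upper-tail hypergeometric
    padj: float | None = None


def hypergeom_enrichment(selection, target, background, set_name: str = "") -> EnrichmentResult:
    """Upper-tail hypergeometric test of target over-representation.

    ``selection`` and ``target`` must be subsets of ``background``;
    p = P(X >= k) for X ~ Hypergeometric(N, K, n).
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    selection = set(selection)
    target = set(target)
    stray = (selection | target) - background
    if stray:
        raise ValueError(f"genes outside background: {sorted(stray)[:10]}")
    N, K, n = len(background), len(target), len(selection)
    k = len(selection & target)
    # sf(k-1) = P(X >= k); k = 0 gives p = 1 exactly
    p = float(hypergeom.sf(k - 1, N, K, n))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    fold = (k / n) / (K / N) if n > 0 and K > 0 else float("nan")
    return EnrichmentResult(set_name=set_name, k=k, K=K, n=n, N=N, fold=fold, p=p)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if len(p) == 0:
        return p
    if ((p <= 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_upregulated(
    de_table: pd.DataFrame, min_fc: float = 3.0, max_padj: float = 0.01
) -> set:
    """Upregulated genes from a differential-expression table.

    Strict gates: fold change > ``min_fc`` and adjusted p < ``max_padj``.
    The table needs columns ``gene``, ``fc`` and ``padj``.
    """
    missing = {"gene", "fc", "padj"} - set(de_table.columns)
    if missing:
        raise ValueError(f"DE table missing column(s): {sorted(missing)}")
    sel = de_table[(de_table["fc"] > min_fc) & (de_table["padj"] < max_padj)]
    return set(sel["gene"])


def gg_dko_enrichment(
    germline_genes,
    selection,
    backgrounds: dict,
) -> pd.DataFrame:
    """Enrichment of germline-gene orthologs in a selection, per background.

    ``backgrounds`` maps a background name (e.g. "all_genes",
    "methylated_cgrich_promoters") to its gene universe.  The germline set
    and the selection are intersected with each background before testing;
    BH adjustment is applied across the backgrounds.  Empty mapped sets
    yield a NaN row with a warning.
    """
    rows = []
    for name, bg in backgrounds.items():
        bg = set(bg)
        tgt = set(germline_genes) & bg
        sel = set(selection) & bg
        if not bg or not tgt:
            warnings.warn(f"{name}: empty background or no mapped germline genes")
            rows.append(EnrichmentResult(name, 0, len(tgt), len(sel), len(bg), float("nan"), float("nan")))
            continue
        rows.append(hypergeom_enrichment(sel, tgt, bg, set_name=name))
    df = pd.DataFrame([r.__dict__ for r in rows])
    ok = df["p"].notna()
    padj = np.full(len(df), np.nan)
    if ok.any():
        padj[ok.to_numpy()] = bh_adjust(df.loc[ok, "p"])
    df["padj"] = padj
    return df
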