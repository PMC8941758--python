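"""Readers/writers for the on-disk formats of the pipeline.

Formats handled: Bismark-style per-CpG coverage tables (``.cov`` dialect),
read-level CpG call tables (Bismark "CpG context" dialect), GTF gene
annotations and BED interval tracks.

Internal coordinates are 0-based half-open everywhere; conversion happens only
at the I/O boundary (``.cov`` and GTF are 1-based inclusive on disk, BED is
already 0-based half-open).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

COV_COLUMNS = ["chrom", "pos", "n_meth", "n_total", "percent"]


class ParseError(ValueError):
    """Malformed line in an input file; message names the line number."""


# ---------------------------------------------------------------------------
# per-CpG coverage tables
# ---------------------------------------------------------------------------


def _recompute_percent(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["percent"] = 100.0 * df["n_meth"] / df["n_total"]
    return df


def combine_strands(df: pd.DataFrame, genome=None) -> pd.DataFrame:
    """Collapse per-strand CpG records onto the plus-strand C.

    The minus-strand C of a CpG sits one base downstream of the plus-strand
    C; its calls are added to the record at position ``p``.  If ``genome``
    (a pyfaidx.Fasta-like mapping) is given, plus-strand Cs are identified
    from the sequence; otherwise records at adjacent positions (p, p+1) are
    paired greedily left to right, which is exact whenever both strands of a
    CpG are reported and no two CpGs abut ambiguously.

    Idempotent, and conserves the total call count.
    """
    out = []
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        n_meth = sub["n_meth"].to_numpy(dtype=np.int64)
        n_total = sub["n_total"].to_numpy(dtype=np.int64)
        if genome is not None:
            seq = str(genome[chrom][:]).upper()
            is_plus_c = np.array(
                [p < len(seq) and seq[p] == "C" for p in pos], dtype=bool
            )
            target = np.where(is_plus_c, pos, pos - 1)
        else:
            target = pos.copy()
            consumed_as_minus = np.zeros(len(pos), dtype=bool)
            for i in range(1, len(pos)):
                if (
                    pos[i] == pos[i - 1] + 1
                    and not consumed_as_minus[i - 1]
                    and target[i - 1] == pos[i - 1]
                ):
                    target[i] = pos[i - 1]
                    consumed_as_minus[i] = True
        merged = (
            pd.DataFrame({"pos": target, "n_meth": n_meth, "n_total": n_total})
            .groupby("pos", as_index=False)
            .sum()
        )
        merged.insert(0, "chrom", chrom)
        out.append(merged)
    res = pd.concat(out, ignore_index=True) if out else df.iloc[0:0][COV_COLUMNS[:4]]
    return _recompute_percent(res)[COV_COLUMNS]


def depth_filter(df: pd.DataFrame, min_depth: int) -> pd.DataFrame:
    """Drop CpGs with fewer than ``min_depth`` total calls (monotone)."""
    return df[df["n_total"] >= min_depth].reset_index(drop=True)


def read_cov_table(
    path,
    min_depth: int = 1,
    combine: bool = True,
    genome=None,
) -> pd.DataFrame:
    """Read a Bismark-dialect coverage file into a strand-combined CpG table.

    On-disk columns: chrom, start, end (1-based inclusive), percent
    methylation, count methylated, count unmethylated.  Lines starting with
    ``#`` are ignored.  Returns a DataFrame with columns
    ``chrom, pos (0-based), n_meth, n_total, percent``; percent is recomputed
    from the counts, records below ``min_depth`` are removed and duplicate
    records for one CpG are summed.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}: line {lineno}: expected 6 columns, got {len(parts)}")
            try:
                chrom = parts[0]
                start = int(parts[1])
                pct = float(parts[3])
                n_meth = int(parts[4])
                n_unmeth = int(parts[5])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            n_total = n_meth + n_unmeth
            if n_total > 0 and abs(pct - 100.0 * n_meth / n_total) > 0.5:
                warnings.warn(
                    f"{path}: line {lineno}: percent column inconsistent with "
                    f"counts; counts win"
                )
            rows.append((chrom, start - 1, n_meth, n_total))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "n_meth", "n_total"])
    df = df[df["n_total"] > 0]
    if combine:
        df = combine_strands(df, genome=genome)
    else:
        df = (
            df.groupby(["chrom", "pos"], as_index=False)[["n_meth", "n_total"]]
            .sum()
            .pipe(_recompute_percent)
        )
    df = depth_filter(df, min_depth)
    return df.reset_index(drop=True)[COV_COLUMNS]


def write_cov_table(df: pd.DataFrame, path) -> None:
    """Write a CpG table in the 1-based-inclusive coverage dialect."""
    with open(path, "w") as fh:
        fh.write("# coords: 1-based inclusive (chrom, start, end, percent, n_meth, n_unmeth)\n")
        for chrom, pos, n_meth, n_total, pct in df[COV_COLUMNS].itertuples(index=False):
            fh.write(
                f"{chrom}\t{pos + 1}\t{pos + 1}\t{pct:.6g}\t{int(n_meth)}\t{int(n_total - n_meth)}\n"
            )


# ---------------------------------------------------------------------------
# read-level CpG calls
# ---------------------------------------------------------------------------

_METH_SYMBOLS = {"Z": 1, "z": 0, "M": 1, "U": 0}


@dataclass
class ReadCallSet:
    """Per-read CpG calls plus a per-read summary.

    ``calls``: one row per CpG call — columns ``read, chrom, pos, meth``
    (pos 0-based, meth in {0,1}), sorted by (read, pos) and strictly
    increasing within a read.
    ``reads``: one row per kept read — columns
    ``read, chrom, n_calls, n_meth, start, end, fully_m, fully_u``.
    """

    calls: pd.DataFrame
    reads: pd.DataFrame

    def __len__(self) -> int:
        return len(self.reads)


def build_read_call_set(calls: pd.DataFrame, min_cpgs: int = 3) -> ReadCallSet:
    """Group call rows per read, drop reads with < ``min_cpgs`` calls."""
    calls = calls.drop_duplicates(["read", "chrom", "pos"]).sort_values(
        ["read", "chrom", "pos"]
    )
    n_chrom_per_read = calls.groupby("read")["chrom"].nunique()
    mixed = n_chrom_per_read[n_chrom_per_read > 1]
    if len(mixed):
        warnings.warn(
            f"{len(mixed)} read id(s) span multiple chromosomes; split per chromosome"
        )
    grp = calls.groupby(["read", "chrom"], sort=False)
    reads = grp.agg(
        n_calls=("meth", "size"),
        n_meth=("meth", "sum"),
        start=("pos", "min"),
        end=("pos", "max"),
    ).reset_index()
    reads = reads[reads["n_calls"] >= min_cpgs].reset_index(drop=True)
    reads["end"] = reads["end"] + 1
    reads["fully_m"] = reads["n_meth"] == reads["n_calls"]
    reads["fully_u"] = reads["n_meth"] == 0
    keep = pd.MultiIndex.from_frame(reads[["read", "chrom"]])
    calls = calls[
        pd.MultiIndex.from_frame(calls[["read", "chrom"]]).isin(keep)
    ].reset_index(drop=True)
    return ReadCallSet(calls=calls, reads=reads)


def read_readlevel_calls(
    path,
    min_cpgs: int = 3,
    genome=None,
    collapse_strand: bool = True,
) -> ReadCallSet:
    """Read a Bismark CpG-context dialect file of per-read CpG calls.

    On-disk columns: read id, methylation flag (+/-), chrom, 1-based
    position, call symbol (Z/z or M/U).  Positions are converted to 0-based
    and, when ``collapse_strand`` and a ``genome`` are given, minus-strand Cs
    (position with G preceded by C) are collapsed onto the plus-strand C one
    base upstream.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("Bismark"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ParseError(f"{path}: line {lineno}: expected 5 columns, got {len(parts)}")
            read_id, _flag, chrom, pos_s, sym = parts[:5]
            if sym not in _METH_SYMBOLS:
                raise ParseError(f"{path}: line {lineno}: unknown call symbol {sym!r}")
            try:
                pos = int(pos_s) - 1
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: bad position {pos_s!r}") from None
            rows.append((read_id, chrom, pos, _METH_SYMBOLS[sym]))
    calls = pd.DataFrame(rows, columns=["read", "chrom", "pos", "meth"])
    if collapse_strand and genome is not None and len(calls):
        for chrom, idx in calls.groupby("chrom").groups.items():
            if chrom not in genome:
                continue
            seq = str(genome[chrom][:]).upper()
            pos = calls.loc[idx, "pos"].to_numpy()
            minus = np.array(
                [p > 0 and p < len(seq) and seq[p] == "G" and seq[p - 1] == "C" for p in pos]
            )
            calls.loc[idx, "pos"] = np.where(minus, pos - 1, pos)
    return build_read_call_set(calls, min_cpgs=min_cpgs)


def write_readlevel_calls(calls: pd.DataFrame, path) -> None:
    """Write per-read CpG calls in the CpG-context dialect (1-based)."""
    with open(path, "w") as fh:
        fh.write("# coords: 1-based (read, flag, chrom, pos, Z=methylated/z=unmethylated)\n")
        for read, chrom, pos, meth in calls[["read", "chrom", "pos", "meth"]].itertuples(
            index=False
        ):
            flag = "+" if meth else "-"
            sym = "Z" if meth else "z"
            fh.write(f"{read}\t{flag}\t{chrom}\t{pos + 1}\t{sym}\n")


# ---------------------------------------------------------------------------
# gene models and interval annotations
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    gene_id: str
    name: str
    chrom: str
    strand: str
    tss: int
    transcripts: list = field(default_factory=list)  # list of exon-interval lists
    body: tuple = (0, 0)  # union of all isoforms, 0-based half-open

    @property
    def start(self) -> int:
        return self.body[0]

    @property
    def end(self) -> int:
        return self.body[1]


def genes_to_frame(genes: list[GeneModel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "name": [g.name for g in genes],
            "chrom": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "strand": [g.strand for g in genes],
            "tss": [g.tss for g in genes],
        }
    )


def read_gtf_genes(path) -> list[GeneModel]:
    """Load gene models from a GTF, merging all isoforms of one gene.

    The merged body is the union span of all transcripts; the TSS is the
    5'-most transcript start (strand-aware).  GTF is 1-based inclusive on
    disk; models are returned 0-based half-open.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )
    genes = []
    for g in db.features_of_type("gene"):
        gene_id = g.attributes.get("gene_id", [g.id])[0]
        name = g.attributes.get("gene_name", [gene_id])[0]
        start, end = g.start - 1, g.end
        transcripts = []
        for t in db.children(g, featuretype="transcript"):
            exons = [(e.start - 1, e.end) for e in db.children(t, featuretype="exon")]
            start = min(start, t.start - 1)
            end = max(end, t.end)
            transcripts.append(sorted(exons))
        tss = start if g.strand == "+" else end - 1
        genes.append(
            GeneModel(
                gene_id=gene_id,
                name=name,
                chrom=g.seqid,
                strand=g.strand,
                tss=tss,
                transcripts=transcripts,
                body=(start, end),
            )
        )
    return genes


def read_bed(path) -> pd.DataFrame:
    """Read a BED3+ file (0-based half-open) into chrom/start/end(/name)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >= 3 columns")
            try:
                rows.append(
                    (parts[0], int(parts[1]), int(parts[2]), parts[3] if len(parts) > 3 else ".")
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_bed(df: pd.DataFrame, path, extra_cols: list[str] | None = None) -> None:
    cols = ["chrom", "start", "end"] + (extra_cols or [])
    with open(path, "w") as fh:
        fh.write("# coords: 0-based half-open\n")
        df[cols].to_csv(fh, sep="\t", header=False, index=False)


@dataclass
class AnnotationBundle:
    genes: list[GeneModel]
    cgis: pd.DataFrame
    repeats: pd.DataFrame
    exclusions: pd.DataFrame

    @property
    def gene_frame(self) -> pd.DataFrame:
        return genes_to_frame(self.genes)


def load_annotations(
    genes,
    cgis,
    repeats=None,
    exclusions=None,
    chrom_names: set | None = None,
) -> AnnotationBundle:
    """Load GTF gene models plus CGI/repeat/exclusion BED tracks.

    ``chrom_names`` (e.g. from a genome index) restricts annotations to known
    chromosomes; records on unknown chromosomes are skipped with a warning.
    """
    gene_models = read_gtf_genes(genes)
    empty = pd.DataFrame(columns=["chrom", "start", "end", "name"])
    cgi_df = read_bed(cgis) if cgis is not None else empty.copy()
    rep_df = read_bed(repeats) if repeats is not None else empty.copy()
    exc_df = read_bed(exclusions) if exclusions is not None else empty.copy()
    if chrom_names is not None:
        known = set(chrom_names)
        kept_genes = [g for g in gene_models if g.chrom in known]
        if len(kept_genes) < len(gene_models):
            warnings.warn("gene annotations on unknown chromosomes skipped")
        gene_models = kept_genes

        def _restrict(df, label):
            bad = ~df["chrom"].isin(known)
            if bad.any():
                warnings.warn(f"{int(bad.sum())} {label} record(s) on unknown chromosomes skipped")
            return df[~bad].reset_index(drop=True)

        cgi_df = _restrict(cgi_df, "CGI")
        rep_df = _restrict(rep_df, "repeat")
        exc_df = _restrict(exc_df, "exclusion")
    return AnnotationBundle(genes=gene_models, cgis=cgi_df, repeats=rep_df, exclusions=exc_df)
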