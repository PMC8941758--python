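"""Synthetic genomes, methylomes and bisulfite read-level calls with truth labels.

The generator emulates the post-alignment products of a WGBS experiment on a
female fibroblast sample: a CpG-depleted genome background carrying CpG
islands and genes, a methylome with unmethylated promoter CGIs, methylated
gene bodies and transposons, >= 5 kb unmethylated valleys over developmental
genes, a partially methylated domain with disordered per-molecule methylation,
imprinted loci whose reads are a mixture of fully methylated and fully
unmethylated molecules, and an X chromosome whose inactivated promoter CGIs
average ~30% methylation (one allele methylated) over a hypomethylated
non-CGI background.

Every cell is modelled with two alleles.  Somatic random partial methylation
(the PMD regime) is modelled per sequenced molecule, not per allele, so that
an allelic caller's ability to discriminate the two situations is actually
testable.  Bisulfite conversion error is a per-call flip with probability
``epsilon``.  All randomness flows from one integer seed through
``numpy.random.default_rng``; outputs are byte-identical across runs for a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = 0, 1, 2, 3


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Study conditions for one simulated species.

    Lengths in bp, methylation levels as fractions in [0, 1], ``depth`` is the
    expected per-base read coverage (lambda of the Poisson placement).
    """

    species: str = "A"
    n_autosomes: int = 1
    autosome_len: int = 1_200_000
    x_len: int = 800_000
    chrx_name: str = "chrX"

    # feature layout (counts are genome totals, distributed over autosomes)
    n_imprinted: int = 10
    imprinted_cgi_len: int = 4000
    n_valleys: int = 3
    valley_len: int = 8000
    n_pmds: int = 1
    pmd_len: int = 80_000
    n_germline_genes: int = 8
    n_methylated_cgi_genes: int = 12
    n_ordinary_genes: int = 30
    n_lcp_genes: int = 10
    n_extra_cgis: int = 8
    n_te: int = 60
    te_len: int = 500
    gene_body_len: int = 4000
    promoter_cgi_len: int = 1000
    n_x_subject: int = 45
    n_x_escapee: int = 8

    # methylation regimes (two alleles per CpG)
    p_background: float = 0.8
    p_background_x: float = 0.6
    p_unmeth: float = 0.02
    p_low_cgi: float = 0.3
    p_imprinted_alleles: tuple = (1.0, 0.0)
    p_x_subject_alleles: tuple = (0.55, 0.05)
    pmd_read_level_range: tuple = (0.2, 0.8)

    # sequencing: a molecule contributes one contiguous string of CpG calls
    # over ``read_len`` bp; setting ``fragment_len >= 2 * read_len`` instead
    # models a paired-end insert observed over two ``read_len`` mate segments
    # sharing one read id
    depth: float = 12.0
    read_len: int = 100
    fragment_len: int = 100
    epsilon: float = 0.005

    seed: int = 0

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_autosomes)] + [self.chrx_name]


@dataclass
class Slot:
    kind: str
    chrom: str
    start: int
    end: int
    gene_id: str | None = None
    ortholog: str | None = None
    name: str | None = None
    strand: str = "+"
    tss: int = -1
    body: tuple | None = None  # merged gene body
    cgi: tuple | None = None  # promoter CGI interval
    body_cgi: tuple | None = None
    intron: tuple | None = None
    intron_cgi: tuple | None = None


@dataclass
class TruthSet:
    """Ground-truth labels of every implanted regime, for recovery tests."""

    imprinted: pd.DataFrame  # chrom,start,end,gene_id,ortholog,n_cpg,stringent_detectable
    valleys: pd.DataFrame  # chrom,start,end,gene_id,ortholog
    pmds: pd.DataFrame  # chrom,start,end
    escapees: pd.DataFrame  # gene_id,ortholog
    x_subject: pd.DataFrame  # gene_id,ortholog
    germline: pd.DataFrame  # gene_id,ortholog
    regimes: pd.DataFrame  # chrom,start,end,regime,p_allele1,p_allele2


# ---------------------------------------------------------------------------
# sequence synthesis
# ---------------------------------------------------------------------------


def _iid_sequence(rng, length, probs, cpg_keep=None):
    seq = rng.choice(4, size=length, p=np.asarray(probs, dtype=float)).astype(np.uint8)
    if cpg_keep is not None and length > 1:
        is_cpg_g = np.zeros(length, dtype=bool)
        is_cpg_g[1:] = (seq[:-1] == _C) & (seq[1:] == _G)
        idx = np.nonzero(is_cpg_g)[0]
        kill = idx[rng.random(idx.size) >= cpg_keep]
        seq[kill] = np.where(rng.random(kill.size) < 0.5, _A, _T).astype(np.uint8)
    return seq


def seq_to_str(seq: np.ndarray) -> str:
    return _BASES[seq].tobytes().decode("ascii")


def cpg_positions(seq: np.ndarray) -> np.ndarray:
    """0-based positions of the plus-strand C of each CpG."""
    return np.nonzero((seq[:-1] == _C) & (seq[1:] == _G))[0]


# background: CG-depleted (o/e ~ 0.25); CGIs: GC-rich, no depletion (o/e ~ 1);
# imprinted CGIs are "weak" islands (o/e ~ 0.8, GC 60%) like real germline
# DMRs; valleys carry mildly elevated density so boundaries resolve sharply
_BG_PROBS = (0.30, 0.20, 0.20, 0.30)
_BG_CPG_KEEP = 0.25
_CGI_PROBS = (0.175, 0.325, 0.325, 0.175)
_IMPRINTED_PROBS = (0.20, 0.30, 0.30, 0.20)
_IMPRINTED_CPG_KEEP = 0.8
_VALLEY_PROBS = (0.25, 0.25, 0.25, 0.25)
_VALLEY_CPG_KEEP = 0.5


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------


def _gene_slot(kind, chrom, start, length, cfg, strand, gene_id, ortholog, name):
    """A gene region: promoter CGI at the 5' end (when the kind has one),
    single-exon body covering the slot; mirrored for minus strand."""
    end = start + length
    s = Slot(kind, chrom, start, end, gene_id, ortholog, name, strand)
    has_cgi = kind in {
        "imprinted",
        "dev",
        "germline",
        "mcgi",
        "ordinary",
        "x_subject",
        "x_escapee",
    }
    cgi_len = cfg.imprinted_cgi_len if kind == "imprinted" else cfg.promoter_cgi_len
    if kind == "dev":
        # gene nested inside the valley, CGI around its TSS
        if strand == "+":
            s.body = (start + 1000, end - 1000)
            s.tss = s.body[0]
            s.cgi = (s.tss - 300, s.tss + 700)
        else:
            s.body = (start + 1000, end - 1000)
            s.tss = s.body[1] - 1
            s.cgi = (s.tss - 699, s.tss + 301)
        return s
    # the promoter CGI reaches 800 bp upstream of the TSS so the
    # [TSS-1000, TSS+500) window covers the island (CG- and GC-rich promoter);
    # the gene body starts at the TSS, as in real annotations
    tss_off = min(800, cgi_len - 1)
    if strand == "+":
        if has_cgi:
            s.cgi = (start, start + cgi_len)
            s.tss = start + tss_off
        else:
            s.tss = start
        s.body = (s.tss, end)
    else:
        if has_cgi:
            s.cgi = (end - cgi_len, end)
            s.tss = end - tss_off - 1
        else:
            s.tss = end - 1
        s.body = (start, s.tss + 1)
    return s


def _plan_layout(cfg: SimConfig, rng) -> list[Slot]:
    """Place non-overlapping feature slots on every chromosome.

    Gene indices are assigned in a fixed role order so the i-th gene plays the
    same role in every simulated species, defining the ortholog map by
    construction (ortholog id = OG<index>).
    """
    autosomes = cfg.chrom_names()[: cfg.n_autosomes]

    roles: list[tuple] = []
    dev_names = [f"HOXA{i + 1}" for i in range(cfg.n_valleys)]
    for i in range(cfg.n_imprinted):
        roles.append(("imprinted", None))
    for i in range(cfg.n_valleys):
        roles.append(("valley", dev_names[i]))
    for i in range(cfg.n_pmds):
        roles.append(("pmd", None))
    for i in range(cfg.n_germline_genes):
        roles.append(("germline", None))
    for i in range(cfg.n_methylated_cgi_genes):
        roles.append(("mcgi", None))
    for i in range(cfg.n_ordinary_genes):
        roles.append(("ordinary_bodycgi" if i < 4 else "ordinary", None))
    for i in range(cfg.n_lcp_genes):
        roles.append(("lcp_introncgi" if i < 2 else "lcp", None))
    for i in range(cfg.n_extra_cgis):
        roles.append(("cgi_high" if i % 2 == 0 else "cgi_low", None))
    for i in range(cfg.n_te):
        roles.append(("te", None))

    per_chrom: dict[str, list[tuple]] = {c: [] for c in autosomes}
    for j, role in enumerate(roles):
        per_chrom[autosomes[j % len(autosomes)]].append(role)

    x_roles = [("x_subject", None)] * cfg.n_x_subject + [("x_escapee", None)] * cfg.n_x_escapee
    per_chrom[cfg.chrx_name] = x_roles

    def slot_length(kind):
        if kind == "imprinted":
            return cfg.imprinted_cgi_len + cfg.gene_body_len
        if kind == "valley":
            return cfg.valley_len
        if kind == "pmd":
            return cfg.pmd_len
        if kind in {"germline", "mcgi", "ordinary", "ordinary_bodycgi", "x_subject", "x_escapee"}:
            return cfg.promoter_cgi_len + cfg.gene_body_len
        if kind in {"lcp", "lcp_introncgi"}:
            return cfg.gene_body_len
        if kind in {"cgi_high", "cgi_low"}:
            return cfg.promoter_cgi_len
        if kind == "te":
            return cfg.te_len
        raise ValueError(kind)

    gene_counter = 0
    slots: list[Slot] = []
    lengths_by_chrom = dict(
        [(c, cfg.autosome_len) for c in autosomes] + [(cfg.chrx_name, cfg.x_len)]
    )
    # fixed gene index order must not depend on placement shuffling
    for chrom in autosomes + [cfg.chrx_name]:
        chrom_roles = per_chrom[chrom]
        lens = [slot_length(k) for k, _ in chrom_roles]
        min_gap, head = 300, 1500
        needed = sum(lens) + min_gap * (len(lens) + 1) + head
        L = lengths_by_chrom[chrom]
        if needed > L:
            raise ValueError(
                f"{chrom}: requested features need {needed} bp but chromosome is {L} bp"
            )
        order = rng.permutation(len(chrom_roles))
        spare = L - needed
        extra = rng.multinomial(spare, np.full(len(lens) + 1, 1.0 / (len(lens) + 1)))
        pos = head + min_gap + extra[0]
        chrom_slots = [None] * len(chrom_roles)
        for slot_rank, role_idx in enumerate(order):
            kind, name = chrom_roles[role_idx]
            length = lens[role_idx]
            start = pos
            pos += length + min_gap + extra[slot_rank + 1]
            chrom_slots[role_idx] = (kind, name, start, length)
        for kind, name, start, length in chrom_slots:
            if kind in {"pmd", "te", "cgi_high", "cgi_low"}:
                slots.append(Slot(kind, chrom, start, start + length))
                continue
            gid = f"{cfg.species}_G{gene_counter:03d}"
            og = f"OG{gene_counter:03d}"
            gname = name if name is not None else og
            strand = "+" if rng.random() < 0.5 else "-"
            base_kind = {
                "valley": "dev",
                "ordinary_bodycgi": "ordinary",
                "lcp_introncgi": "lcp",
            }.get(kind, kind)
            s = _gene_slot(base_kind, chrom, start, length, cfg, strand, gid, og, gname)
            if kind == "ordinary_bodycgi":
                mid = (start + start + length) // 2
                s.body_cgi = (mid - 400, mid + 400)
            if kind == "lcp_introncgi":
                # two exons with an intronic CGI between them
                if strand == "+":
                    s.intron = (start + 500, start + length - 500)
                else:
                    s.intron = (start + 500, start + length - 500)
                imid = (s.intron[0] + s.intron[1]) // 2
                s.intron_cgi = (imid - 400, imid + 400)
            gene_counter += 1
            slots.append(s)
    return slots


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def simulate_genome(cfg: SimConfig, rng=None):
    """Synthesize chromosome sequences and the feature layout.

    Returns ``(genome, slots)`` where ``genome`` maps chromosome name to a
    uint8 base-code array.  CpG density is elevated inside CGI intervals
    (o/e ~ 1) over a CpG-depleted background (o/e ~ 0.25); valleys carry a
    mildly elevated density so their boundaries are well resolved by CpGs.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    slots = _plan_layout(cfg, rng)
    lengths = dict(
        [(c, cfg.autosome_len) for c in cfg.chrom_names()[: cfg.n_autosomes]]
        + [(cfg.chrx_name, cfg.x_len)]
    )
    genome = {
        chrom: _iid_sequence(rng, L, _BG_PROBS, cpg_keep=_BG_CPG_KEEP)
        for chrom, L in lengths.items()
    }
    for s in slots:
        seq = genome[s.chrom]
        if s.kind == "dev":
            seq[s.start : s.end] = _iid_sequence(
                rng, s.end - s.start, _VALLEY_PROBS, cpg_keep=_VALLEY_CPG_KEEP
            )
        for iv in (s.cgi, s.body_cgi, s.intron_cgi):
            if iv is not None:
                if s.kind == "imprinted":
                    seq[iv[0] : iv[1]] = _iid_sequence(
                        rng, iv[1] - iv[0], _IMPRINTED_PROBS, cpg_keep=_IMPRINTED_CPG_KEEP
                    )
                else:
                    seq[iv[0] : iv[1]] = _iid_sequence(rng, iv[1] - iv[0], _CGI_PROBS)
        if s.kind in {"cgi_high", "cgi_low"}:
            seq[s.start : s.end] = _iid_sequence(rng, s.end - s.start, _CGI_PROBS)
    return genome, slots


def slots_to_annotations(slots: list[Slot], cfg: SimConfig):
    """Derive gene models and CGI/TE/exclusion interval tables from a layout."""
    genes: list[mio.GeneModel] = []
    cgi_rows, te_rows, excl_rows = [], [], []
    for s in slots:
        if s.kind == "te":
            te_rows.append((s.chrom, s.start, s.end, "TE"))
            continue
        if s.kind in {"cgi_high", "cgi_low"}:
            cgi_rows.append((s.chrom, s.start, s.end, f"CGI_{s.kind}"))
            continue
        if s.kind == "pmd":
            continue
        # gene-bearing slot
        body, tss, cgi = s.body, s.tss, s.cgi
        if s.kind == "dev":
            excl_rows.append((s.chrom, s.start, s.end, s.name))
        if s.intron is not None:
            exons = [(body[0], s.intron[0]), (s.intron[1], body[1])]
        else:
            exons = [body]
        # germline/mcgi promoters are CG-rich in sequence but deliberately
        # absent from the CGI annotation track: annotated islands are mostly
        # unmethylated in real genomes, and these promoters model the
        # methylated CG-rich class found by promoter-ratio classification
        if cgi is not None and s.kind not in {"germline", "mcgi"}:
            cgi_rows.append((s.chrom, cgi[0], cgi[1], f"CGI_{s.gene_id}"))
        if s.body_cgi is not None:
            cgi_rows.append((s.chrom, s.body_cgi[0], s.body_cgi[1], f"CGI_body_{s.gene_id}"))
        if s.intron_cgi is not None:
            cgi_rows.append((s.chrom, s.intron_cgi[0], s.intron_cgi[1], f"CGI_intron_{s.gene_id}"))
        genes.append(
            mio.GeneModel(
                gene_id=s.gene_id,
                name=s.name,
                chrom=s.chrom,
                strand=s.strand,
                tss=tss,
                transcripts=[sorted(exons)],
                body=body,
            )
        )
    cols = ["chrom", "start", "end", "name"]
    cgis = pd.DataFrame(cgi_rows, columns=cols).sort_values(["chrom", "start"]).reset_index(drop=True)
    tes = pd.DataFrame(te_rows, columns=cols).sort_values(["chrom", "start"]).reset_index(drop=True)
    excl = pd.DataFrame(excl_rows, columns=cols).sort_values(["chrom", "start"]).reset_index(drop=True)
    return genes, cgis, tes, excl


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------


def simulate_methylome(genome: dict, slots: list[Slot], cfg: SimConfig):
    """Assign per-CpG, per-allele methylation probabilities from the layout.

    Returns ``(meth, truth)``: ``meth`` has columns
    ``chrom, pos, p_allele1, p_allele2, pmd`` (pmd rows get a per-read level
    at sequencing time instead of their allele probabilities), and ``truth``
    is the :class:`TruthSet` of implanted regimes.
    """
    regime_rows = []
    imp_rows, valley_rows, pmd_rows = [], [], []
    escapee_rows, subject_rows, germ_rows = [], [], []
    for s in slots:
        if s.kind == "imprinted":
            a1, a2 = cfg.p_imprinted_alleles
            regime_rows.append((s.chrom, s.cgi[0], s.cgi[1], "imprinted", a1, a2))
            imp_rows.append((s.chrom, s.cgi[0], s.cgi[1], s.gene_id, s.ortholog))
        elif s.kind == "dev":
            regime_rows.append((s.chrom, s.start, s.end, "valley", cfg.p_unmeth, cfg.p_unmeth))
            valley_rows.append((s.chrom, s.start, s.end, s.gene_id, s.ortholog))
        elif s.kind == "pmd":
            regime_rows.append((s.chrom, s.start, s.end, "pmd", np.nan, np.nan))
            pmd_rows.append((s.chrom, s.start, s.end))
        elif s.kind in {"ordinary"}:
            regime_rows.append((s.chrom, s.cgi[0], s.cgi[1], "pcgi_unmeth", cfg.p_unmeth, cfg.p_unmeth))
        elif s.kind in {"germline", "mcgi"}:
            # methylated CG-rich promoter: CGI stays at background level
            if s.kind == "germline":
                germ_rows.append((s.gene_id, s.ortholog))
        elif s.kind == "cgi_low":
            regime_rows.append((s.chrom, s.start, s.end, "cgi_low", cfg.p_low_cgi, cfg.p_low_cgi))
        elif s.kind == "x_subject":
            a1, a2 = cfg.p_x_subject_alleles
            regime_rows.append((s.chrom, s.cgi[0], s.cgi[1], "xci_pcgi", a1, a2))
            subject_rows.append((s.gene_id, s.ortholog))
        elif s.kind == "x_escapee":
            regime_rows.append((s.chrom, s.cgi[0], s.cgi[1], "escapee_pcgi", cfg.p_unmeth, cfg.p_unmeth))
            escapee_rows.append((s.gene_id, s.ortholog))

    regimes = pd.DataFrame(
        regime_rows, columns=["chrom", "start", "end", "regime", "p_allele1", "p_allele2"]
    )
    # valleys and imprinted loci must not overlap (distinct slots by design)
    for chrom, sub in regimes.groupby("chrom"):
        sub = sub.sort_values("start")
        if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping regime intervals on {chrom}")

    frames = []
    for chrom, seq in genome.items():
        pos = cpg_positions(seq)
        p_bg = cfg.p_background_x if chrom == cfg.chrx_name else cfg.p_background
        p1 = np.full(pos.size, p_bg)
        p2 = np.full(pos.size, p_bg)
        pmd = np.zeros(pos.size, dtype=bool)
        for _, r in regimes[regimes["chrom"] == chrom].iterrows():
            lo, hi = np.searchsorted(pos, [r["start"], r["end"]])
            if r["regime"] == "pmd":
                pmd[lo:hi] = True
            else:
                p1[lo:hi] = r["p_allele1"]
                p2[lo:hi] = r["p_allele2"]
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": pos, "p_allele1": p1, "p_allele2": p2, "pmd": pmd}
            )
        )
    meth = pd.concat(frames, ignore_index=True)

    imp = pd.DataFrame(imp_rows, columns=["chrom", "start", "end", "gene_id", "ortholog"])
    n_cpg = []
    for _, r in imp.iterrows():
        pos = cpg_positions(genome[r["chrom"]])
        lo, hi = np.searchsorted(pos, [r["start"], r["end"]])
        n_cpg.append(hi - lo)
    imp["n_cpg"] = n_cpg
    imp["stringent_detectable"] = imp["n_cpg"] >= 20

    truth = TruthSet(
        imprinted=imp,
        valleys=pd.DataFrame(valley_rows, columns=["chrom", "start", "end", "gene_id", "ortholog"]),
        pmds=pd.DataFrame(pmd_rows, columns=["chrom", "start", "end"]),
        escapees=pd.DataFrame(escapee_rows, columns=["gene_id", "ortholog"]),
        x_subject=pd.DataFrame(subject_rows, columns=["gene_id", "ortholog"]),
        germline=pd.DataFrame(germ_rows, columns=["gene_id", "ortholog"]),
        regimes=regimes,
    )
    return meth, truth


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------


def simulate_reads(
    meth: pd.DataFrame,
    chrom_lengths: dict,
    cfg: SimConfig,
    rng=None,
    min_calls_emit: int = 1,
):
    """Draw bisulfite molecules and their CpG calls from a methylome.

    Molecule placement is Poisson: ``n ~ Poisson(depth * L / (2 * read_len))``
    uniform fragment starts, each fragment of ``fragment_len`` bp observed
    over its two ``read_len`` mate segments (both mates carry the molecule's
    read id), so the expected per-CpG call depth is ``depth``.  Each molecule
    picks one of the two alleles with equal probability and calls each
    covered CpG methylated with that allele's probability.  Molecules inside
    the PMD regime instead draw a per-molecule methylation level uniform on
    ``pmd_read_level_range``.  Each call is flipped with probability
    ``epsilon`` (bisulfite conversion error).

    Returns ``(calls, cov)``; the coverage table is the exact aggregation of
    the emitted calls.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    frag = max(cfg.fragment_len, cfg.read_len)
    paired = frag >= 2 * cfg.read_len
    observed = 2 * cfg.read_len if paired else frag
    all_calls = []
    for chrom, L in chrom_lengths.items():
        sub = meth[meth["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        p_alleles = np.stack([sub["p_allele1"].to_numpy(), sub["p_allele2"].to_numpy()])
        pmd_mask = sub["pmd"].to_numpy()
        n_reads = int(rng.poisson(cfg.depth * L / observed))
        starts = rng.integers(0, max(L - frag, 0) + 1, size=n_reads)
        allele = rng.integers(0, 2, size=n_reads)
        u_pmd = rng.uniform(*cfg.pmd_read_level_range, size=n_reads)
        # covered CpGs: the observed segment(s) of the molecule
        mate1_len = cfg.read_len if paired else frag
        lo1 = np.searchsorted(pos, starts)
        hi1 = np.searchsorted(pos, starts + mate1_len)
        if paired:
            lo2 = np.searchsorted(pos, starts + frag - cfg.read_len)
            hi2 = np.searchsorted(pos, starts + frag)
        else:
            lo2 = hi1.copy()
            hi2 = hi1.copy()
        lo2 = np.maximum(lo2, hi1)
        c1 = hi1 - lo1
        c2 = hi2 - lo2
        counts = c1 + c2
        total = int(counts.sum())
        if total == 0:
            continue
        read_idx = np.repeat(np.arange(n_reads), counts)
        # positions within a molecule: first mate-1 CpGs, then mate-2 CpGs
        seg_counts = np.empty(2 * n_reads, dtype=np.int64)
        seg_counts[0::2] = c1
        seg_counts[1::2] = c2
        seg_lo = np.empty(2 * n_reads, dtype=np.int64)
        seg_lo[0::2] = lo1
        seg_lo[1::2] = lo2
        seg_offsets = np.cumsum(seg_counts) - seg_counts
        cpg_idx = (
            np.arange(total)
            - np.repeat(seg_offsets, seg_counts)
            + np.repeat(seg_lo, seg_counts)
        )
        p = p_alleles[allele[read_idx], cpg_idx]
        p = np.where(pmd_mask[cpg_idx], u_pmd[read_idx], p)
        meth_call = rng.random(total) < p
        meth_call ^= rng.random(total) < cfg.epsilon
        keep = np.repeat(counts, counts) >= min_calls_emit
        df = pd.DataFrame(
            {
                "read": pd.Series(read_idx[keep]).map(
                    lambda i, c=chrom: f"{cfg.species}_{c}_{i}"
                ),
                "chrom": chrom,
                "pos": pos[cpg_idx[keep]],
                "meth": meth_call[keep].astype(np.int8),
            }
        )
        all_calls.append(df)
    calls = (
        pd.concat(all_calls, ignore_index=True)
        if all_calls
        else pd.DataFrame(columns=["read", "chrom", "pos", "meth"])
    )
    cov = aggregate_calls(calls)
    return calls, cov


def aggregate_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Collapse read-level calls into a per-CpG coverage table."""
    if not len(calls):
        return pd.DataFrame(columns=mio.COV_COLUMNS)
    grp = calls.groupby(["chrom", "pos"], as_index=False).agg(
        n_meth=("meth", "sum"), n_total=("meth", "size")
    )
    grp["percent"] = 100.0 * grp["n_meth"] / grp["n_total"]
    return grp.sort_values(["chrom", "pos"]).reset_index(drop=True)[mio.COV_COLUMNS]


# ---------------------------------------------------------------------------
# expression table (consumed, not computed, by the pipeline)
# ---------------------------------------------------------------------------


def simulate_de_table(genes, truth: TruthSet, cfg: SimConfig, rng=None) -> pd.DataFrame:
    """Differential-expression results after methyltransferase inhibition.

    Germline genes (methylated CG-rich promoters) are strongly derepressed
    (fold change > 3, adjusted p < 0.01); a few ordinary genes are also
    upregulated so that enrichment of the germline set is non-trivial; all
    other genes are null.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    germ = set(truth.germline["gene_id"])
    rows = []
    ordinary_up = set()
    candidates = [
        g.gene_id for g in genes if g.gene_id not in germ and g.chrom != cfg.chrx_name
    ]
    if candidates:
        ordinary_up = set(rng.choice(candidates, size=min(4, len(candidates)), replace=False))
    for g in genes:
        if g.gene_id in germ or g.gene_id in ordinary_up:
            fc = float(rng.uniform(4.0, 20.0))
            padj = float(10 ** rng.uniform(-8, -3))
        else:
            fc = float(np.exp(rng.normal(0.0, 0.3)))
            padj = float(rng.uniform(0.02, 1.0))
        rows.append((g.gene_id, fc, padj))
    return pd.DataFrame(rows, columns=["gene", "fc", "padj"])


# ---------------------------------------------------------------------------
# whole-species driver
# ---------------------------------------------------------------------------


@dataclass
class SpeciesData:
    cfg: SimConfig
    genome: dict
    slots: list
    genes: list
    cgis: pd.DataFrame
    tes: pd.DataFrame
    exclusions: pd.DataFrame
    meth: pd.DataFrame
    truth: TruthSet
    calls: pd.DataFrame
    cov: pd.DataFrame
    de_table: pd.DataFrame

    @property
    def chrom_lengths(self) -> dict:
        return {c: len(s) for c, s in self.genome.items()}

    def ortholog_map(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "ortholog": [f"OG{g.gene_id.split('_G')[1]}" for g in self.genes],
            }
        )


def simulate_species(cfg: SimConfig) -> SpeciesData:
    """Run the full generator for one species under its study conditions."""
    rng = np.random.default_rng(cfg.seed)
    genome, slots = simulate_genome(cfg, rng)
    genes, cgis, tes, excl = slots_to_annotations(slots, cfg)
    meth, truth = simulate_methylome(genome, slots, cfg)
    calls, cov = simulate_reads(meth, {c: len(s) for c, s in genome.items()}, cfg, rng)
    de = simulate_de_table(genes, truth, cfg, rng)
    return SpeciesData(
        cfg=cfg,
        genome=genome,
        slots=slots,
        genes=genes,
        cgis=cgis,
        tes=tes,
        exclusions=excl,
        meth=meth,
        truth=truth,
        calls=calls,
        cov=cov,
        de_table=de,
    )


# ---------------------------------------------------------------------------
# on-disk emission
# ---------------------------------------------------------------------------


def write_fasta(genome: dict, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            s = seq_to_str(genome[chrom])
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_gtf(genes, path, source: str = "sim") -> None:
    """Emit gene/transcript/exon records (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("## coords: 1-based inclusive\n")
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.name}";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for ti, exons in enumerate(g.transcripts):
                tid = f"{g.gene_id}.t{ti + 1}"
                t_start = min(e[0] for e in exons)
                t_end = max(e[1] for e in exons)
                tattrs = attrs + f' transcript_id "{tid}";'
                fh.write(
                    f"{g.chrom}\t{source}\ttranscript\t{t_start + 1}\t{t_end}\t.\t{g.strand}\t.\t{tattrs}\n"
                )
                for e in exons:
                    fh.write(
                        f"{g.chrom}\t{source}\texon\t{e[0] + 1}\t{e[1]}\t.\t{g.strand}\t.\t{tattrs}\n"
                    )


def write_species(data: SpeciesData, outdir) -> dict:
    """Write every generator product to ``outdir``; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genome.fa",
        "gtf": outdir / "genes.gtf",
        "cgis": outdir / "cgis.bed",
        "tes": outdir / "tes.bed",
        "exclusions": outdir / "exclusions.bed",
        "cov": outdir / "methylation.cov",
        "reads": outdir / "read_calls.tsv",
        "de": outdir / "de_table.tsv",
        "orthologs": outdir / "orthologs.tsv",
        "germline": outdir / "germline_genes.tsv",
    }
    write_fasta(data.genome, paths["fasta"])
    write_gtf(data.genes, paths["gtf"])
    mio.write_bed(data.cgis, paths["cgis"], extra_cols=["name"])
    mio.write_bed(data.tes, paths["tes"], extra_cols=["name"])
    mio.write_bed(data.exclusions, paths["exclusions"], extra_cols=["name"])
    mio.write_cov_table(data.cov, paths["cov"])
    mio.write_readlevel_calls(data.calls, paths["reads"])
    data.de_table.to_csv(paths["de"], sep="\t", index=False)
    data.ortholog_map().to_csv(paths["orthologs"], sep="\t", index=False)
    # the germline gene set is an analysis input (like a published gene list),
    # not only a truth label
    data.truth.germline.to_csv(paths["germline"], sep="\t", index=False)
    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)
    for name in ("imprinted", "valleys", "pmds", "escapees", "x_subject", "germline", "regimes"):
        getattr(data.truth, name).to_csv(truth_dir / f"{name}.tsv", sep="\t", index=False)
        paths[f"truth_{name}"] = truth_dir / f"{name}.tsv"
    return paths
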