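"""CAGE CTSS clustering into tag clusters (TCs) and derived promoter metrics.

CTSSs (single-base 5'-end tag positions) are TPM-normalized per sample,
filtered at a minimum of 0.5 TPM in at least one sample, and neighboring
retained positions on the same chromosome and strand are merged into tag
clusters when they lie less than 20 bp apart.  Each TC gets a summit (the
position of maximum pooled TPM), per-sample tag counts/TPM, a gene
assignment (gene body or up to 2 kb upstream of the annotated TSS,
strand-aware), and feeds the alternative-promoter and full-length
(cap + polyA) statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .core_io import CTSS_COLUMNS, ExpressionMatrix, TranscriptModel, ValidationError


@dataclass
class TagCluster:
    """A CAGE tag cluster: a run of nearby CTSSs on one strand.

    ``start``/``end`` are 0-based half-open; ``summit`` is the 0-based
    position of the maximum pooled TPM; per-sample tag counts and TPM are
    dicts keyed by sample id.
    """

    tc_id: str
    chrom: str
    strand: str
    start: int
    end: int
    summit: int
    tags: dict[str, int] = field(default_factory=dict)
    tpm: dict[str, float] = field(default_factory=dict)
    assigned_gene: str | None = None

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def n_samples_detected(self) -> int:
        return sum(1 for v in self.tags.values() if v > 0)

    @property
    def total_tags(self) -> int:
        return sum(self.tags.values())


def tpm_normalize(ctss: pd.DataFrame) -> pd.DataFrame:
    """Add a ``tpm`` column: count / sample library total x 10^6.

    ``ctss`` may hold one or many samples (a ``sample_id`` column is
    required); each sample is normalized by its own tag total.
    """
    if ctss.empty:
        raise ValidationError("empty CTSS table")
    missing = set(CTSS_COLUMNS) - set(ctss.columns)
    if missing:
        raise ValidationError(f"CTSS table lacks columns {sorted(missing)}")
    totals = ctss.groupby("sample_id")["count"].transform("sum")
    if (totals <= 0).any():
        bad = sorted(set(ctss.loc[totals <= 0, "sample_id"]))
        raise ValidationError(f"zero tag total for samples {bad}")
    out = ctss.copy()
    out["tpm"] = out["count"] / totals * 1e6
    return out


def cluster_ctss(
    ctss: pd.DataFrame, min_tpm: float = 0.5, max_gap: int = 20
) -> list[TagCluster]:
    """Cluster pooled CTSSs into tag clusters.

    A CTSS position is retained iff its TPM reaches ``min_tpm`` in at least
    one sample.  Retained positions on the same chromosome and strand are
    sorted and joined while consecutive positional differences are strictly
    below ``max_gap`` (< 20 bp apart means a difference of at most 19).
    Summit = position of maximum pooled TPM, ties going to the 5'-most
    position.
    """
    if "tpm" not in ctss.columns:
        ctss = tpm_normalize(ctss)
    max_per_pos = ctss.groupby(["chrom", "strand", "pos"])["tpm"].transform("max")
    retained = ctss[max_per_pos >= min_tpm]
    if retained.empty:
        return []

    # assign a global cluster id to every retained position
    pos_tab = (
        retained.groupby(["chrom", "strand", "pos"])["tpm"]
        .sum()
        .rename("pooled_tpm")
        .reset_index()
        .sort_values(["chrom", "strand", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    same_group = (
        pos_tab[["chrom", "strand"]].eq(pos_tab[["chrom", "strand"]].shift()).all(axis=1)
    )
    gap_ok = pos_tab["pos"].diff() < max_gap
    pos_tab["cid"] = (~(same_group & gap_ok)).cumsum()

    # per-cluster extent and strand-aware summit (max pooled TPM, tie 5'-most)
    extent = pos_tab.groupby("cid").agg(
        chrom=("chrom", "first"), strand=("strand", "first"),
        pos_first=("pos", "min"), pos_last=("pos", "max"),
    )
    plus = pos_tab["strand"] == "+"
    summit_order = pd.concat(
        [
            pos_tab[plus].sort_values(
                ["cid", "pooled_tpm", "pos"], ascending=[True, False, True],
                kind="mergesort",
            ),
            pos_tab[~plus].sort_values(
                ["cid", "pooled_tpm", "pos"], ascending=[True, False, False],
                kind="mergesort",
            ),
        ]
    )
    extent["summit"] = summit_order.drop_duplicates("cid").set_index("cid")["pos"]

    # per-cluster per-sample tag counts and TPM
    key = pd.MultiIndex.from_frame(retained[["chrom", "strand", "pos"]])
    cid_of = pd.Series(
        pos_tab["cid"].to_numpy(),
        index=pd.MultiIndex.from_frame(pos_tab[["chrom", "strand", "pos"]]),
    )
    member = retained[["sample_id", "count", "tpm"]].copy()
    member["cid"] = cid_of.loc[key].to_numpy()
    per_sample = (
        member.groupby(["cid", "sample_id"])[["count", "tpm"]].sum().reset_index()
    )

    # split the flat (cid, sample) table into one slice per cluster
    ps_cid = per_sample["cid"].to_numpy()
    ps_sid = per_sample["sample_id"].to_numpy()
    ps_cnt = per_sample["count"].to_numpy()
    ps_tpm = per_sample["tpm"].to_numpy()
    bounds = np.flatnonzero(np.diff(ps_cid)) + 1
    lo_idx = np.concatenate([[0], bounds])
    hi_idx = np.concatenate([bounds, [len(ps_cid)]])

    clusters = []
    for (cid, row), lo, hi in zip(extent.iterrows(), lo_idx, hi_idx):
        clusters.append(
            TagCluster(
                tc_id=f"TC_{row.chrom}_{row.strand}_{int(row.pos_first)}",
                chrom=row.chrom,
                strand=row.strand,
                start=int(row.pos_first) - 1,  # positions are 1-based
                end=int(row.pos_last),
                summit=int(row.summit) - 1,
                tags=dict(zip(ps_sid[lo:hi], (int(v) for v in ps_cnt[lo:hi]))),
                tpm=dict(zip(ps_sid[lo:hi], (float(v) for v in ps_tpm[lo:hi]))),
            )
        )
    return clusters


# ---------------------------------------------------------------------------
# gene assignment and promoter statistics
# ---------------------------------------------------------------------------


def _gene_spans(annotation: Sequence[TranscriptModel]) -> pd.DataFrame:
    rows = {}
    for tx in annotation:
        if tx.strand not in ("+", "-"):
            raise ValidationError(f"unstranded transcript {tx.transcript_id}")
        rec = rows.get(tx.gene_id)
        if rec is None:
            rows[tx.gene_id] = [tx.chrom, tx.strand, tx.start, tx.end]
        else:
            if rec[1] != tx.strand:
                raise ValidationError(f"gene {tx.gene_id} has transcripts on both strands")
            rec[2] = min(rec[2], tx.start)
            rec[3] = max(rec[3], tx.end)
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["chrom", "strand", "start", "end"]
    )
    df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    return df


def assign_tc_to_genes(
    tcs: list[TagCluster],
    annotation: Sequence[TranscriptModel],
    upstream_bp: int = 2000,
) -> pd.DataFrame:
    """Assign each TC to a gene by summit position (mutates ``assigned_gene``).

    A TC is assignable to a gene iff it lies on the same strand and its
    summit falls within the gene span or within ``upstream_bp`` of the
    annotated TSS on the upstream side.  Ambiguous summits go to the gene
    with the nearest TSS.  Returns a per-gene table with TC counts and an
    ``alternative_promoter`` flag (> 1 assigned TC).
    """
    genes = _gene_spans(annotation)
    trees: dict[tuple[str, str], IntervalTree] = {}
    for gid, row in genes.iterrows():
        lo, hi = row["start"], row["end"]
        if row["strand"] == "+":
            lo -= upstream_bp
        else:
            hi += upstream_bp
        trees.setdefault((row["chrom"], row["strand"]), IntervalTree()).addi(
            lo, hi, gid
        )
    for tc in tcs:
        tree = trees.get((tc.chrom, tc.strand))
        tc.assigned_gene = None
        if tree is None:
            continue
        hits = tree.overlap(tc.summit, tc.summit + 1)
        if not hits:
            continue
        tc.assigned_gene = min(
            (abs(tc.summit - genes.at[h.data, "tss"]), h.data) for h in hits
        )[1]
    counts = pd.Series(
        [tc.assigned_gene for tc in tcs if tc.assigned_gene is not None]
    ).value_counts()
    table = pd.DataFrame({"n_tcs": counts})
    table["alternative_promoter"] = table["n_tcs"] > 1
    table.index.name = "gene_id"
    return table


def _dominant_tc(gene_tcs: list[TagCluster]) -> TagCluster:
    """Highest pooled tag count; ties broken by the 5'-most summit."""

    def key(tc: TagCluster):
        five_prime = tc.summit if tc.strand == "+" else -tc.summit
        return (-tc.total_tags, five_prime)

    return min(gene_tcs, key=key)


def alternative_promoter_ratio(
    tcs: list[TagCluster], sample_ids: Iterable[str]
) -> pd.Series:
    """Per sample: tags in non-dominant TCs / tags in all gene-assigned TCs.

    The dominant TC of a gene is the one with the highest pooled tag count
    (ties to the 5'-most summit); every other assigned TC is an alternative
    promoter.  Samples with no gene-assigned tags score 0 with a warning.
    """
    by_gene: dict[str, list[TagCluster]] = {}
    for tc in tcs:
        if tc.assigned_gene is not None:
            by_gene.setdefault(tc.assigned_gene, []).append(tc)
    sample_ids = list(sample_ids)
    alt = dict.fromkeys(sample_ids, 0.0)
    total = dict.fromkeys(sample_ids, 0.0)
    for gene_tcs in by_gene.values():
        dom = _dominant_tc(gene_tcs)
        for tc in gene_tcs:
            for sid, n in tc.tags.items():
                if sid not in total:
                    continue
                total[sid] += n
                if tc is not dom:
                    alt[sid] += n
    ratios = {}
    for sid in sample_ids:
        if total[sid] == 0:
            warnings.warn(f"sample {sid}: no gene-assigned TC tags", stacklevel=2)
            ratios[sid] = 0.0
        else:
            ratios[sid] = alt[sid] / total[sid]
    return pd.Series(ratios, name="alternative_promoter_ratio")


def full_length_frequency(
    tcs: list[TagCluster],
    matrix: ExpressionMatrix,
    gene_class: str | Sequence[str] = ("lnc_intergenic", "lnc_antisense"),
    detect_rpkm: float = 0.1,
) -> pd.Series:
    """Per sample: fraction of RNA-seq-detected genes of a class with TC support.

    RNA-seq detection (RPKM above ``detect_rpkm``) stands for polyA
    evidence; an assigned TC with at least one tag in the same sample stands
    for 5'-cap evidence.  Samples with no detected gene of the class are
    reported as NaN.
    """
    if isinstance(gene_class, str):
        gene_class = (gene_class,)
    class_genes = set(matrix.genes_of_class(*gene_class))
    capped: dict[str, set[str]] = {}
    for tc in tcs:
        if tc.assigned_gene in class_genes:
            for sid, n in tc.tags.items():
                if n > 0:
                    capped.setdefault(sid, set()).add(tc.assigned_gene)
    rpkm_df = matrix.rpkm.loc[sorted(class_genes)]
    out = {}
    for sid in matrix.sample_ids:
        detected = set(rpkm_df.index[(rpkm_df[sid] > detect_rpkm).to_numpy()])
        if not detected:
            out[sid] = np.nan
            continue
        out[sid] = len(detected & capped.get(sid, set())) / len(detected)
    return pd.Series(out, name="full_length_frequency")


# ---------------------------------------------------------------------------
# TSS profile and genomic-region distribution
# ---------------------------------------------------------------------------


def tss_profile(
    tcs: list[TagCluster],
    annotation: Sequence[TranscriptModel],
    window: int = 1000,
    bin_size: int = 10,
) -> pd.Series:
    """Histogram of strand-oriented TC summit distances to the nearest TSS.

    Distance is negative upstream of the annotated TSS and positive
    downstream, regardless of strand.  Summits farther than ``window`` from
    every same-strand TSS are omitted.
    """
    if not tcs:
        return pd.Series(dtype=int)
    tss_by_key: dict[tuple[str, str], np.ndarray] = {}
    genes = _gene_spans(annotation)
    for (chrom, strand), sub in genes.groupby(["chrom", "strand"]):
        tss_by_key[(chrom, strand)] = np.sort(sub["tss"].to_numpy())
    edges = np.arange(-window, window + bin_size, bin_size)
    counts = np.zeros(len(edges) - 1, dtype=int)
    for tc in tcs:
        sites = tss_by_key.get((tc.chrom, tc.strand))
        if sites is None or len(sites) == 0:
            continue
        i = np.searchsorted(sites, tc.summit)
        cands = sites[max(0, i - 1) : i + 1]
        nearest = cands[np.argmin(np.abs(cands - tc.summit))]
        d = tc.summit - nearest if tc.strand == "+" else nearest - tc.summit
        if -window <= d < window:
            counts[(d + window) // bin_size] += 1
    centers = edges[:-1] + bin_size / 2
    return pd.Series(counts, index=centers, name="n_tcs")


_REGION_PRECEDENCE = ("5UTR", "3UTR", "CDS", "intron", "intergenic")


def _feature_trees(annotation: Sequence[TranscriptModel]):
    trees = {
        name: {} for name in ("5UTR", "3UTR", "CDS", "exon", "gene")
    }
    has_subfeatures = False

    def add(name, chrom, a, b):
        trees[name].setdefault(chrom, IntervalTree()).addi(a, b)

    for tx in annotation:
        add("gene", tx.chrom, tx.start, tx.end)
        for a, b in tx.exons:
            add("exon", tx.chrom, a, b)
        for a, b in tx.utr5:
            has_subfeatures = True
            add("5UTR", tx.chrom, a, b)
        for a, b in tx.utr3:
            add("3UTR", tx.chrom, a, b)
        for a, b in tx.cds:
            add("CDS", tx.chrom, a, b)
    return trees, has_subfeatures


def _classify_position(trees, chrom: str, pos: int, with_sub: bool) -> str:
    def hit(name):
        tree = trees[name].get(chrom)
        return tree is not None and bool(tree.overlap(pos, pos + 1))

    if with_sub:
        for name in ("5UTR", "3UTR", "CDS"):
            if hit(name):
                return name
        if hit("gene"):
            # anything genic outside UTR/CDS (incl. noncoding exons) counts as intron
            return "intron"
        return "intergenic"
    if hit("exon"):
        return "exon"
    if hit("gene"):
        return "intron"
    return "intergenic"


def genomic_region_distribution(
    positions: Iterable[tuple[str, int]],
    annotation: Sequence[TranscriptModel],
    control_positions: Iterable[tuple[str, int]] | None = None,
) -> tuple[pd.Series, dict | None]:
    """Classify positions into genomic regions; optionally test 5'UTR enrichment.

    ``positions`` are (chrom, 0-based position) pairs (e.g. TC summits);
    precedence is 5UTR > 3UTR > CDS > intron > intergenic.  When the
    annotation lacks UTR/CDS sub-features, classification falls back to
    {exon, intron, intergenic} with a warning.  With ``control_positions``
    (e.g. RNA-seq read positions) a two-sided Fisher's exact test on 5'UTR
    membership (CAGE vs control) is returned as a dict.
    """
    trees, with_sub = _feature_trees(annotation)
    if not with_sub:
        warnings.warn(
            "annotation lacks UTR/CDS sub-features; classifying to "
            "{exon, intron, intergenic}",
            stacklevel=2,
        )
    labels = [
        _classify_position(trees, chrom, pos, with_sub) for chrom, pos in positions
    ]
    cats = _REGION_PRECEDENCE if with_sub else ("exon", "intron", "intergenic")
    counts = pd.Series(labels).value_counts().reindex(cats, fill_value=0)
    fractions = counts / counts.sum() if counts.sum() else counts.astype(float)
    test = None
    if control_positions is not None and with_sub:
        ctrl = [
            _classify_position(trees, chrom, pos, with_sub)
            for chrom, pos in control_positions
        ]
        a_in = int((counts["5UTR"]))
        a_out = int(counts.sum() - a_in)
        c_in = sum(1 for x in ctrl if x == "5UTR")
        c_out = len(ctrl) - c_in
        odds, p = stats.fisher_exact([[a_in, a_out], [c_in, c_out]], alternative="two-sided")
        test = {"table": [[a_in, a_out], [c_in, c_out]], "odds_ratio": odds, "p_value": p}
    return fractions, test


def tcs_to_bed(tcs: list[TagCluster], path) -> None:
    """Export TCs as BED6+ (extra columns: width, summit, n_samples, gene)."""
    with open(path, "w") as fh:
        for tc in sorted(tcs, key=lambda t: (t.chrom, t.start, t.strand)):
            fh.write(
                "\t".join(
                    [
                        tc.chrom,
                        str(tc.start),
                        str(tc.end),
                        tc.tc_id,
                        str(tc.total_tags),
                        tc.strand,
                        str(tc.width),
                        str(tc.summit),
                        str(tc.n_samples_detected),
                        tc.assigned_gene or ".",
                    ]
                )
                + "\n"
            )
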