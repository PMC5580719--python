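"""Classify assembled transcripts into lncRNA classes or reject them.

A transcript is kept as a lncRNA only if it is multi-exonic, at least 200 nt
of spliced length, has no open reading frame of 100 codons or more, and does
not overlap a known mRNA exon on the same strand.  Surviving transcripts are
split into intergenic and antisense classes by exon-level opposite-strand
overlap with known mRNAs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .core_io import TranscriptModel, ValidationError

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the lncRNA filter chain.

    min_length
        Minimum spliced length in nt (default 200, the conventional lncRNA
        size cut-off).
    min_exons
        Minimum exon count (default 2: multi-exonic transcripts only).
    max_orf_codons
        Transcripts whose longest ORF reaches this many codons are rejected
        as putatively coding (default 100).
    same_strand_cds_overlap_reject
        Reject transcripts whose exons overlap a known mRNA exon on the same
        strand (default on).
    """

    min_length: int = 200
    min_exons: int = 2
    max_orf_codons: int = 100
    same_strand_cds_overlap_reject: bool = True

    def __post_init__(self) -> None:
        if self.min_length < 1 or self.min_exons < 1:
            raise ValidationError("min_length and min_exons must be >= 1")


def longest_orf(sequence: str) -> int:
    """Length in codons of the longest ATG..stop ORF over the 3 forward frames.

    The count includes the ATG but not the stop codon; an ATG with no
    downstream in-frame stop contributes nothing (open-ended ORFs are not
    counted).  Returns 0 when no ORF terminates.
    """
    seq = sequence.upper()
    if not seq:
        warnings.warn("longest_orf called on empty sequence", stacklevel=2)
        return 0
    if set(seq) - set("ACGTN"):
        raise ValidationError("sequence contains characters outside ACGTN")
    best = 0
    for frame in range(3):
        start: int | None = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                if start is not None:
                    best = max(best, (i - start) // 3)
                    start = None
            elif start is None and codon == "ATG":
                start = i
    return best


def _exon_trees(
    transcripts: Iterable[TranscriptModel],
) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for tx in transcripts:
        tree = trees.setdefault((tx.chrom, tx.strand), IntervalTree())
        for (a, b) in tx.exons:
            tree.addi(a, b)
    return trees


def _overlaps(tree_map, chrom: str, strand: str, exons) -> bool:
    tree = tree_map.get((chrom, strand))
    if tree is None:
        return False
    return any(tree.overlap(a, b) for a, b in exons)


def classify_transcripts(
    transcripts: Sequence[TranscriptModel],
    sequences: Mapping[str, str],
    known_mrnas: Sequence[TranscriptModel],
    config: FilterConfig = FilterConfig(),
) -> dict[str, str]:
    """Assign a class label to every candidate transcript.

    Parameters
    ----------
    transcripts
        Candidate transcripts (assembled models).
    sequences
        Spliced transcript sequence per transcript id; required for each
        candidate.
    known_mrnas
        Reference mRNA transcript models; used for same-strand rejection and
        antisense classification.  Candidates whose transcript id matches a
        known mRNA id pass through with class ``mRNA``.

    Returns
    -------
    dict mapping transcript id to one of ``mRNA``, ``lnc_intergenic``,
    ``lnc_antisense``, ``rejected``.  The result does not depend on input
    order.
    """
    mrna_ids = {tx.transcript_id for tx in known_mrnas}
    missing = [
        tx.transcript_id
        for tx in transcripts
        if tx.transcript_id not in mrna_ids and tx.transcript_id not in sequences
    ]
    if missing:
        raise ValidationError(f"no sequence for transcripts: {sorted(missing)[:10]}")

    sense = _exon_trees(known_mrnas)
    flip = {"+": "-", "-": "+"}

    labels: dict[str, str] = {}
    for tx in transcripts:
        if tx.transcript_id in mrna_ids:
            labels[tx.transcript_id] = "mRNA"
            continue
        if tx.length < config.min_length or tx.n_exons < config.min_exons:
            labels[tx.transcript_id] = "rejected"
            continue
        if longest_orf(sequences[tx.transcript_id]) >= config.max_orf_codons:
            labels[tx.transcript_id] = "rejected"
            continue
        if config.same_strand_cds_overlap_reject and _overlaps(
            sense, tx.chrom, tx.strand, tx.exons
        ):
            labels[tx.transcript_id] = "rejected"
            continue
        if _overlaps(sense, tx.chrom, flip[tx.strand], tx.exons):
            labels[tx.transcript_id] = "lnc_antisense"
        else:
            labels[tx.transcript_id] = "lnc_intergenic"
    return labels


def classification_report(labels: Mapping[str, str]):
    """Tabulate counts per class label (TSV-ready DataFrame)."""
    import pandas as pd

    counts = pd.Series(labels).value_counts().rename_axis("class_label")
    return counts.to_frame("n_transcripts")
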