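"""Readers/writers for the external formats the pipeline touches, plus the shared data model.

Coordinate conventions
----------------------
All interval arithmetic is internally 0-based half-open.  GTF is read and
written in its native 1-based closed convention; BED is 0-based half-open.
CTSS positions are single 1-based genomic bases (the 5' end of a CAGE read),
stored in FANTOM-style single-base BED6 where a CTSS at 1-based position ``p``
occupies the interval ``[p-1, p)`` and the score column carries the tag count.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

REGIONS = ("PFC", "PCC", "TC", "PC", "OC", "CA1", "DG", "CB")
AGES = (1, 4, 10, 20)
SEXES = ("F", "M")

#: brain-region super-groups used for exclusive-expression analysis
REGION_GROUPS = {
    "PFC": "neocortex",
    "PCC": "neocortex",
    "TC": "neocortex",
    "PC": "neocortex",
    "OC": "neocortex",
    "CA1": "hippocampus",
    "DG": "hippocampus",
    "CB": "CB",
}

CLASS_LABELS = ("mRNA", "lnc_intergenic", "lnc_antisense", "rejected")


class ParseError(ValueError):
    """A file could not be parsed (malformed line, missing attribute)."""


class ValidationError(ValueError):
    """Parsed data violate a model invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleMetadata:
    """One brain sample: region x age (years) x sex cell of the design."""

    sample_id: str
    region: str
    age: int
    sex: str

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValidationError(f"unknown region {self.region!r}")
        if self.age not in AGES:
            raise ValidationError(f"unknown age group {self.age!r}")
        if self.sex not in SEXES:
            raise ValidationError(f"unknown sex {self.sex!r}")


@dataclass
class TranscriptModel:
    """An exon-structured transcript on a fixed strand.

    ``exons`` are 0-based half-open intervals, sorted and non-overlapping.
    ``cds``/``utr5``/``utr3`` carry optional sub-features (genomic intervals,
    same convention) used for promoter-context classification.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    class_label: str | None = None
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"transcript {self.transcript_id}: bad strand {self.strand!r}"
            )
        exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b) in exons:
            if b <= a:
                raise ValidationError(
                    f"transcript {self.transcript_id}: empty exon [{a},{b})"
                )
        for (_, b1), (a2, _) in zip(exons, exons[1:]):
            if a2 < b1:
                raise ValidationError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )
        self.exons = exons
        if self.class_label is not None and self.class_label not in CLASS_LABELS:
            raise ValidationError(
                f"transcript {self.transcript_id}: unknown class {self.class_label!r}"
            )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def length(self) -> int:
        """Spliced (exonic) length in nt."""
        return sum(b - a for a, b in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def tss(self) -> int:
        """0-based position of the 5' end (strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1


class ExpressionMatrix:
    """Gene x sample read counts bound to sample metadata and gene annotation.

    Parameters
    ----------
    counts : DataFrame
        Non-negative integer counts, index gene ids, columns sample ids.
    samples : DataFrame
        Indexed by sample id with columns ``region``, ``age``, ``sex``.
    gene_info : DataFrame
        Indexed by gene id with columns ``length`` (exonic nt) and
        ``class_label``.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        samples: pd.DataFrame,
        gene_info: pd.DataFrame,
    ) -> None:
        counts = counts.copy()
        if counts.index.has_duplicates or counts.columns.has_duplicates:
            raise ValidationError("duplicate gene or sample ids")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("counts must be integers")
            counts = counts.round().astype(np.int64)
            arr = counts.to_numpy()
        if (arr < 0).any():
            raise ValidationError("counts must be non-negative")
        missing = counts.columns.difference(samples.index)
        if len(missing):
            raise ValidationError(
                f"samples missing metadata: {sorted(missing)}"
            )
        missing_g = counts.index.difference(gene_info.index)
        if len(missing_g):
            raise ValidationError(f"genes missing annotation: {sorted(missing_g)[:5]}")
        self.counts = counts
        self.samples = samples.loc[counts.columns].copy()
        self.samples["age"] = self.samples["age"].astype(int)
        self.gene_info = gene_info.loc[counts.index].copy()
        if (self.gene_info["length"] <= 0).any():
            raise ValidationError("gene lengths must be positive")
        lib = counts.sum(axis=0)
        if (lib <= 0).any():
            bad = list(lib.index[lib <= 0])
            raise ValidationError(f"zero library size for samples {bad}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @cached_property
    def rpkm(self) -> pd.DataFrame:
        """Reads per kilobase of exonic length per million mapped reads."""
        lib = self.library_sizes.to_numpy(dtype=float)
        length = self.gene_info["length"].to_numpy(dtype=float)
        vals = (
            self.counts.to_numpy(dtype=float)
            / (length[:, None] / 1e3)
            / (lib[None, :] / 1e6)
        )
        return pd.DataFrame(vals, index=self.gene_ids, columns=self.sample_ids)

    def log_rpkm(self) -> pd.DataFrame:
        """log2(RPKM + 1), the scale used for correlation/PCA/testing."""
        return np.log2(self.rpkm + 1.0)

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        gene_ids = pd.Index(gene_ids)
        return ExpressionMatrix(
            self.counts.loc[gene_ids], self.samples, self.gene_info.loc[gene_ids]
        )

    def genes_of_class(self, *labels: str) -> pd.Index:
        mask = self.gene_info["class_label"].isin(labels)
        return self.gene_ids[mask.to_numpy()]

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ExpressionMatrix({self.counts.shape[0]} genes x "
            f"{self.counts.shape[1]} samples)"
        )


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')

_FEATURE_SLOT = {
    "exon": "exons",
    "CDS": "cds",
    "five_prime_utr": "utr5",
    "three_prime_utr": "utr3",
}


def read_gtf(path) -> list[TranscriptModel]:
    """Parse transcript models from a GTF file.

    Exon (and optional CDS/UTR) features are grouped by ``transcript_id``.
    GTF 1-based closed coordinates are converted to 0-based half-open.
    """
    slots: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = parts
            slot = _FEATURE_SLOT.get(feature)
            if slot is None:
                continue
            attr = dict(_ATTR_RE.findall(attrs))
            if "gene_id" not in attr or "transcript_id" not in attr:
                raise ParseError(
                    f"{path}:{lineno}: missing gene_id/transcript_id attribute"
                )
            tid = attr["transcript_id"]
            iv = (int(start) - 1, int(end))  # GTF 1-based closed -> half-open
            rec = slots.get(tid)
            if rec is None:
                rec = slots[tid] = {
                    "gene_id": attr["gene_id"],
                    "chrom": chrom,
                    "strand": strand,
                    "class_label": attr.get("class_label"),
                    "exons": [],
                    "cds": [],
                    "utr5": [],
                    "utr3": [],
                }
                order.append(tid)
            else:
                if rec["strand"] != strand:
                    raise ValidationError(
                        f"{path}:{lineno}: transcript {tid} has features on "
                        "mixed strands"
                    )
                if rec["chrom"] != chrom:
                    raise ValidationError(
                        f"{path}:{lineno}: transcript {tid} spans chromosomes"
                    )
            rec[slot].append(iv)
    models = []
    for tid in order:
        rec = slots[tid]
        if not rec["exons"]:
            raise ValidationError(f"transcript {tid} has no exon features")
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=rec["gene_id"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=rec["exons"],
                class_label=rec["class_label"],
                cds=sorted(rec["cds"]),
                utr5=sorted(rec["utr5"]),
                utr3=sorted(rec["utr3"]),
            )
        )
    return models


def write_gtf(transcripts: Iterable[TranscriptModel], path) -> None:
    """Write transcript models as GTF (1-based closed coordinates)."""
    feature_of = {"exons": "exon", "cds": "CDS", "utr5": "five_prime_utr",
                  "utr3": "three_prime_utr"}
    with open(path, "w") as fh:
        for tx in transcripts:
            attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
            if tx.class_label is not None:
                attrs += f' class_label "{tx.class_label}";'
            for slot, feature in feature_of.items():
                for (a, b) in getattr(tx, "exons" if slot == "exons" else slot):
                    fh.write(
                        "\t".join(
                            [tx.chrom, "lncbrain", feature, str(a + 1), str(b),
                             ".", tx.strand, ".", attrs]
                        )
                        + "\n"
                    )


# ---------------------------------------------------------------------------
# CTSS BED6
# ---------------------------------------------------------------------------

CTSS_COLUMNS = ["chrom", "strand", "pos", "sample_id", "count"]


def read_ctss_bed(path, sample_id: str) -> pd.DataFrame:
    """Read one sample's CTSS table from single-base BED6.

    Returns a DataFrame with columns ``chrom, strand, pos, sample_id, count``
    where ``pos`` is the 1-based TSS base and ``count`` the tag count.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: expected BED6")
            chrom, start, end, _name, score, strand = parts[:6]
            start, end = int(start), int(end)
            if end != start + 1:
                raise ParseError(
                    f"{path}:{lineno}: CTSS interval must be single-base "
                    f"(got [{start},{end}))"
                )
            count = int(score)
            if count < 0:
                raise ValidationError(f"{path}:{lineno}: negative tag count")
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
            rows.append((chrom, strand, start + 1, sample_id, count))
    df = pd.DataFrame(rows, columns=CTSS_COLUMNS)
    if df.duplicated(["chrom", "strand", "pos", "sample_id"]).any():
        raise ValidationError(
            f"{path}: duplicate CTSS rows for the same (chrom, strand, pos)"
        )
    return df


def write_ctss_bed(ctss: pd.DataFrame, path) -> None:
    """Write a single sample's CTSS records as single-base BED6."""
    with open(path, "w") as fh:
        df = ctss.sort_values(["chrom", "pos", "strand"])
        for row in df.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos - 1}\t{row.pos}\t.\t{row.count}\t{row.strand}\n"
            )


# ---------------------------------------------------------------------------
# expression / metadata TSV
# ---------------------------------------------------------------------------


def read_sample_metadata(path) -> pd.DataFrame:
    """Read a sample metadata TSV (sample_id, region, age, sex)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "region": str, "sex": str})
    required = {"sample_id", "region", "age", "sex"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: metadata needs columns {sorted(required)}")
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate sample ids")
    for row in df.itertuples(index=False):
        SampleMetadata(row.sample_id, row.region, int(row.age), row.sex)  # validates
    return df.set_index("sample_id")


def read_expression_tsv(path, metadata_path) -> ExpressionMatrix:
    """Read a gene x sample count TSV plus the metadata TSV binding its columns.

    The count table's first column holds gene ids; the optional special
    columns ``length`` and ``class_label`` carry gene annotation and are not
    treated as samples.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    gene_cols = [c for c in ("length", "class_label") if c in df.columns]
    gene_info = df[gene_cols].copy() if gene_cols else pd.DataFrame(index=df.index)
    if "length" not in gene_info:
        raise ParseError(f"{path}: expected a 'length' column with exonic lengths")
    if "class_label" not in gene_info:
        gene_info["class_label"] = "mRNA"
    counts = df.drop(columns=gene_cols)
    arr = counts.to_numpy()
    if not np.allclose(arr, np.round(arr)) or (arr < 0).any():
        raise ValidationError(f"{path}: counts must be non-negative integers")
    samples = read_sample_metadata(metadata_path)
    missing = counts.columns.difference(samples.index)
    if len(missing):
        raise ValidationError(
            f"{path}: samples absent from metadata: {sorted(missing)}"
        )
    return ExpressionMatrix(counts.astype(np.int64), samples, gene_info)


def write_expression_tsv(matrix: ExpressionMatrix, counts_path, metadata_path) -> None:
    out = matrix.gene_info[["length", "class_label"]].join(matrix.counts)
    out.index.name = "gene_id"
    out.to_csv(counts_path, sep="\t")
    meta = matrix.samples.copy()
    meta.index.name = "sample_id"
    meta.to_csv(metadata_path, sep="\t")


# ---------------------------------------------------------------------------
# GMT / FASTA
# ---------------------------------------------------------------------------


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene sets from GMT (name <tab> description <tab> genes...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT needs >= 3 columns")
            name = parts[0]
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set {name!r}")
            sets[name] = {g for g in parts[2:] if g}
    return sets


def read_fasta(path) -> dict[str, str]:
    """Read sequences keyed by record id."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def full_design(prefix: str = "S") -> pd.DataFrame:
    """The complete 8 regions x 4 ages x 2 sexes = 64-sample design."""
    rows = []
    for region in REGIONS:
        for age in AGES:
            for sex in SEXES:
                rows.append((f"{prefix}_{region}_{age}yr_{sex}", region, age, sex))
    return pd.DataFrame(
        rows, columns=["sample_id", "region", "age", "sex"]
    ).set_index("sample_id")
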