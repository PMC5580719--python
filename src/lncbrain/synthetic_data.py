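"""Synthetic study generator with known ground truth.

Emulates the structure of an 8-region x 4-age x 2-sex macaque brain survey:
negative-binomial RNA-seq counts around class-specific baselines (lncRNAs
lower-expressed, shorter, and lower-GC than mRNAs), planted region-, age-,
and sex-by-age-driven co-expression modules, planted sex-biased genes, and
CAGE tag pileups concentrated at true TSSs with alternative promoters and
uniform background noise.  One seed determines every emitted byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    AGES,
    CTSS_COLUMNS,
    REGIONS,
    SEXES,
    ExpressionMatrix,
    TranscriptModel,
    ValidationError,
    full_design,
)
from .transcript_filter import longest_orf

_NONSTOP_CODONS = None


@dataclass(frozen=True)
class PlantedModule:
    """A planted co-expression module.

    ``factor`` is one of ``region``, ``age``, ``sex_age``; ``level`` the
    driving level (a region name, an age in years, or a ``(sex, age)``
    pair); ``log2_effect`` the planted log2 fold change in samples at that
    level (may be negative); ``gene_class`` selects the gene pool.
    """

    name: str
    n_genes: int
    factor: str
    level: object
    log2_effect: float = 2.0
    gene_class: str = "lnc"

    def __post_init__(self) -> None:
        if self.factor not in ("region", "age", "sex_age"):
            raise ValidationError(f"unknown module factor {self.factor!r}")
        if self.n_genes < 0 or not np.isfinite(self.log2_effect):
            raise ValidationError("module gene count/effect invalid")


def default_planted_modules() -> list[PlantedModule]:
    """Planted structure mirroring the study's module classes.

    Region-driven (spatiotemporal) modules in cerebellum and hippocampal
    CA1, an age-driven (tempo-spatial) early module, a sex-by-age
    (sex-temporal) module, plus two mRNA modules — one of which is *down*
    at age 1 so that negative lncRNA-mRNA co-expression pairs exist.
    """
    return [
        PlantedModule("lnc_CB", 40, "region", "CB", 2.0, "lnc"),
        PlantedModule("lnc_CA1", 40, "region", "CA1", 2.0, "lnc"),
        PlantedModule("lnc_age1", 40, "age", 1, 2.0, "lnc"),
        PlantedModule("lnc_F4", 30, "sex_age", ("F", 4), 2.0, "lnc"),
        PlantedModule("mrna_CB", 60, "region", "CB", 2.0, "mrna"),
        PlantedModule("mrna_age1_down", 60, "age", 1, -2.0, "mrna"),
    ]


@dataclass(frozen=True)
class CageConfig:
    """CAGE tag simulation parameters.

    tags_per_sample
        Gene-derived plus background tags per sample library.
    tss_sd
        Gaussian jitter (bp, discretized) of tag 5' ends around the true
        TSS; 1 bp keeps most tag clusters at most a few nt wide.
    alt_promoter_fraction
        Fraction of genes given a second (internal) promoter.
    alt_usage
        Fraction of a gene's tags emitted from the alternative promoter.
    background_fraction
        Fraction of tags scattered uniformly over the chromosomes.
    """

    tags_per_sample: int = 50_000
    tss_sd: float = 1.0
    alt_promoter_fraction: float = 0.3
    alt_usage: float = 0.3
    background_fraction: float = 0.05


@dataclass(frozen=True)
class SimulationConfig:
    n_mrna: int = 800
    n_lncrna: int = 200
    n_decoys: int = 0
    regions: tuple = REGIONS
    ages: tuple = AGES
    sexes: tuple = SEXES
    planted_modules: tuple = field(default_factory=lambda: tuple(default_planted_modules()))
    n_sex_biased: int = 30
    sex_bias_log2_effect: float = 1.0
    nb_dispersion: float = 0.05
    mrna_log_mean: float = np.log(150.0)
    mrna_log_sd: float = 1.0
    lnc_log_mean: float = np.log(30.0)
    lnc_log_sd: float = 1.0
    antisense_fraction: float = 0.13
    orf_codons: int = 200
    cage: CageConfig = field(default_factory=CageConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        for n in (self.n_mrna, self.n_lncrna, self.n_decoys, self.n_sex_biased):
            if n < 0:
                raise ValidationError("gene counts must be >= 0")
        if not (0 <= self.antisense_fraction <= 1):
            raise ValidationError("antisense fraction must lie in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValidationError("dispersion must be >= 0")


@dataclass
class GroundTruth:
    """Planted truth emitted alongside the synthetic data."""

    module_of: pd.Series  # gene -> module name ("" = background)
    sex_biased: dict[str, str]  # gene -> direction
    tss_of: dict[str, list[tuple[str, str, int, float]]]  # gene -> (chrom, strand, 1-based pos, usage)
    class_of: dict[str, str]


# ---------------------------------------------------------------------------
# sequences and transcript models
# ---------------------------------------------------------------------------


def _nonstop_codons() -> list[str]:
    global _NONSTOP_CODONS
    if _NONSTOP_CODONS is None:
        stops = {"TAA", "TAG", "TGA"}
        _NONSTOP_CODONS = [
            a + b + c
            for a in "ACGT"
            for b in "ACGT"
            for c in "ACGT"
            if a + b + c not in stops
        ]
    return _NONSTOP_CODONS


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


def _orf_seq(rng: np.random.Generator, n_codons: int) -> str:
    codons = rng.choice(_nonstop_codons(), size=n_codons - 1)
    stop = rng.choice(["TAA", "TAG", "TGA"])
    return "ATG" + "".join(codons) + stop


def _noncoding_seq(rng: np.random.Generator, length: int, gc: float,
                   max_orf: int = 100) -> str:
    """Random sequence guaranteed to have no ORF of ``max_orf`` codons."""
    for _ in range(100):
        seq = _random_seq(rng, length, gc)
        if longest_orf(seq) < max_orf:
            return seq
    # fall back: break every frame with stops at regular spacing
    seq = list(_random_seq(rng, length, gc))
    stride = (max_orf - 2) * 3
    for frame in range(3):
        for i in range(frame, length - 3, stride):
            seq[i : i + 3] = "TAA"
    return "".join(seq[:length])


def _split_exons(
    rng: np.random.Generator, tx_len: int, n_exons: int, locus_start: int
) -> list[tuple[int, int]]:
    """Partition a transcript into exons separated by random introns."""
    if n_exons == 1:
        return [(locus_start, locus_start + tx_len)]
    cuts = np.sort(rng.choice(np.arange(1, tx_len), size=n_exons - 1, replace=False))
    lens = np.diff(np.concatenate([[0], cuts, [tx_len]]))
    exons = []
    pos = locus_start
    for i, L in enumerate(lens):
        exons.append((pos, pos + int(L)))
        pos += int(L)
        if i < len(lens) - 1:
            pos += int(rng.integers(200, 1000))
    return exons


def _tx_interval_to_genomic(
    exons: list[tuple[int, int]], strand: str, t0: int, t1: int
) -> list[tuple[int, int]]:
    """Map a transcript-coordinate interval to genomic intervals."""
    ordered = exons if strand == "+" else exons[::-1]
    out = []
    off = 0
    for a, b in ordered:
        L = b - a
        lo, hi = max(t0, off), min(t1, off + L)
        if lo < hi:
            if strand == "+":
                out.append((a + lo - off, a + hi - off))
            else:
                out.append((b - (hi - off), b - (lo - off)))
        off += L
    return sorted(out)


def simulate_transcripts(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[TranscriptModel], dict[str, str], dict[str, str]]:
    """Generate transcript models and spliced sequences.

    Returns ``(transcripts, sequences, true_class)``.  mRNAs carry a planted
    ORF of ``config.orf_codons`` codons; lncRNAs have no ORF of 100+ codons,
    are stochastically shorter and lower-GC, and a configurable fraction is
    placed antisense (opposite strand, exon-overlapping) to an mRNA.
    Decoys (if requested) violate one lncRNA filter each: too short,
    mono-exonic, or coding.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    transcripts: list[TranscriptModel] = []
    sequences: dict[str, str] = {}
    true_class: dict[str, str] = {}
    cursor: dict[str, int] = {}
    chrom_names = [f"chr{i + 1}" for i in range(4)]

    def place(chrom_idx: int, span: int) -> tuple[str, int]:
        chrom = chrom_names[chrom_idx % len(chrom_names)]
        start = cursor.get(chrom, 10_000)
        cursor[chrom] = start + span + int(rng.integers(3000, 8000))
        return chrom, start

    mrnas: list[TranscriptModel] = []
    for i in range(config.n_mrna):
        gid = f"MRNA_{i + 1:05d}"
        utr5 = int(rng.integers(100, 300))
        utr3 = int(rng.integers(200, 500))
        orf = _orf_seq(rng, config.orf_codons)
        seq = (
            _noncoding_seq(rng, utr5, 0.5, config.orf_codons)
            + orf
            + _noncoding_seq(rng, utr3, 0.5, config.orf_codons)
        )
        tx_len = len(seq)
        n_exons = int(rng.integers(2, 7))
        strand = "+" if rng.random() < 0.5 else "-"
        chrom, start = place(i, tx_len + 6 * 1000)
        exons = _split_exons(rng, tx_len, n_exons, start)
        cds_t = (utr5, utr5 + len(orf))
        tx = TranscriptModel(
            transcript_id=gid + ".1",
            gene_id=gid,
            chrom=chrom,
            strand=strand,
            exons=exons,
            class_label="mRNA",
            cds=_tx_interval_to_genomic(exons, strand, *cds_t),
            utr5=_tx_interval_to_genomic(exons, strand, 0, utr5),
            utr3=_tx_interval_to_genomic(exons, strand, cds_t[1], tx_len),
        )
        mrnas.append(tx)
        sequences[tx.transcript_id] = seq
        true_class[tx.transcript_id] = "mRNA"
    transcripts.extend(mrnas)

    n_antisense = int(round(config.antisense_fraction * config.n_lncrna))
    flip = {"+": "-", "-": "+"}
    for i in range(config.n_lncrna):
        gid = f"LNC_{i + 1:05d}"
        tx_len = int(np.clip(rng.lognormal(np.log(700), 0.4), 250, 3000))
        seq = _noncoding_seq(rng, tx_len, 0.40)
        n_exons = int(rng.integers(2, 5))
        antisense = i < n_antisense and mrnas
        if antisense:
            host = mrnas[int(rng.integers(len(mrnas)))]
            ha, hb = host.exons[0]
            # first lnc exon starts inside the host exon: overlap guaranteed
            start = ha + int(rng.integers(0, max(1, (hb - ha) // 2)))
            strand = flip[host.strand]
            chrom = host.chrom
        else:
            chrom, start = place(config.n_mrna + i, tx_len + 4 * 800)
            strand = "+" if rng.random() < 0.5 else "-"
        exons = _split_exons(rng, tx_len, n_exons, start)
        tx = TranscriptModel(
            transcript_id=gid + ".1",
            gene_id=gid,
            chrom=chrom,
            strand=strand,
            exons=exons,
            class_label="lnc_antisense" if antisense else "lnc_intergenic",
        )
        transcripts.append(tx)
        sequences[tx.transcript_id] = seq
        true_class[tx.transcript_id] = tx.class_label

    decoy_kinds = ("short", "mono_exonic", "coding")
    for i in range(config.n_decoys):
        gid = f"DECOY_{i + 1:05d}"
        kind = decoy_kinds[i % len(decoy_kinds)]
        if kind == "short":
            tx_len, n_exons = int(rng.integers(80, 199)), 2
            seq = _noncoding_seq(rng, tx_len, 0.45)
        elif kind == "mono_exonic":
            tx_len, n_exons = int(rng.integers(300, 900)), 1
            seq = _noncoding_seq(rng, tx_len, 0.45)
        else:
            orf = _orf_seq(rng, 150)
            seq = _noncoding_seq(rng, 100, 0.45) + orf + _noncoding_seq(rng, 100, 0.45)
            tx_len, n_exons = len(seq), 2
        chrom, start = place(
            config.n_mrna + config.n_lncrna + i, tx_len + 2 * 800
        )
        strand = "+" if rng.random() < 0.5 else "-"
        exons = _split_exons(rng, tx_len, n_exons, start)
        tx = TranscriptModel(
            transcript_id=gid + ".1", gene_id=gid, chrom=chrom,
            strand=strand, exons=exons,
        )
        transcripts.append(tx)
        sequences[tx.transcript_id] = seq
        true_class[tx.transcript_id] = "rejected"
    return transcripts, sequences, true_class


# ---------------------------------------------------------------------------
# counts and CAGE tags
# ---------------------------------------------------------------------------


def _assign_module_genes(config: SimulationConfig) -> tuple[pd.Series, dict[str, str]]:
    """Deterministically allot disjoint gene blocks to planted structure."""
    lnc_ids = [f"LNC_{i + 1:05d}" for i in range(config.n_lncrna)]
    mrna_ids = [f"MRNA_{i + 1:05d}" for i in range(config.n_mrna)]
    module_of = {}
    ptr = {"lnc": 0, "mrna": 0}
    pools = {"lnc": lnc_ids, "mrna": mrna_ids}
    for mod in config.planted_modules:
        pool = pools[mod.gene_class]
        lo = ptr[mod.gene_class]
        hi = lo + mod.n_genes
        if hi > len(pool):
            raise ValidationError(
                f"not enough {mod.gene_class} genes for module {mod.name}"
            )
        for gid in pool[lo:hi]:
            module_of[gid] = mod.name
        ptr[mod.gene_class] = hi
    # sex-biased genes drawn from the remaining lncRNA pool
    sex_biased: dict[str, str] = {}
    remaining = lnc_ids[ptr["lnc"] :]
    if config.n_sex_biased > len(remaining):
        raise ValidationError("not enough background lncRNAs for sex-biased genes")
    for j, gid in enumerate(remaining[: config.n_sex_biased]):
        sex_biased[gid] = "female-biased" if j % 2 == 0 else "male-biased"
    series = pd.Series(
        {g: module_of.get(g, "") for g in lnc_ids + mrna_ids}, name="module"
    )
    return series, sex_biased


def _effect_matrix(
    config: SimulationConfig,
    samples: pd.DataFrame,
    module_of: pd.Series,
    sex_biased: dict[str, str],
) -> np.ndarray:
    """Per-gene, per-sample log2 multiplier from planted effects."""
    genes = module_of.index
    log2_eff = np.zeros((len(genes), len(samples)))
    mod_by_name = {m.name: m for m in config.planted_modules}
    region = samples["region"].to_numpy()
    age = samples["age"].to_numpy()
    sex = samples["sex"].to_numpy()
    for gi, gid in enumerate(genes):
        name = module_of[gid]
        if name:
            mod = mod_by_name[name]
            if mod.factor == "region":
                mask = region == mod.level
            elif mod.factor == "age":
                mask = age == mod.level
            else:
                mask = (sex == mod.level[0]) & (age == mod.level[1])
            log2_eff[gi, mask] += mod.log2_effect
        direction = sex_biased.get(gid)
        if direction == "female-biased":
            log2_eff[gi, sex == "F"] += config.sex_bias_log2_effect
        elif direction == "male-biased":
            log2_eff[gi, sex == "M"] += config.sex_bias_log2_effect
    return log2_eff


def _nb_sample(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float
) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def _simulate_cage(
    rng: np.random.Generator,
    config: SimulationConfig,
    counts: pd.DataFrame,
    tss_of: dict[str, list[tuple[str, str, int, float]]],
    chrom_len: dict[str, int],
) -> dict[str, pd.DataFrame]:
    cg = config.cage
    ctss: dict[str, pd.DataFrame] = {}
    chroms = sorted(chrom_len)
    chrom_sizes = np.array([chrom_len[c] for c in chroms])

    # flatten (gene, promoter) pairs once: arrays over promoters
    p_chrom, p_strand, p_pos, p_weight, p_gene = [], [], [], [], []
    gene_index = {g: i for i, g in enumerate(counts.index)}
    for gid, promoters in tss_of.items():
        for chrom, strand, pos, w in promoters:
            p_chrom.append(chrom)
            p_strand.append(strand)
            p_pos.append(pos)
            p_weight.append(w)
            p_gene.append(gene_index[gid])
    p_chrom = np.array(p_chrom)
    p_strand = np.array(p_strand)
    p_pos = np.array(p_pos, dtype=np.int64)
    p_weight = np.array(p_weight, dtype=float)
    p_gene = np.array(p_gene, dtype=np.int64)

    for sid in counts.columns:
        expr = counts[sid].to_numpy(dtype=float)
        n_bg = int(round(cg.tags_per_sample * cg.background_fraction))
        n_gene_tags = cg.tags_per_sample - n_bg
        parts = []
        probs = expr[p_gene] * p_weight
        if probs.sum() > 0 and n_gene_tags > 0:
            alloc = rng.multinomial(n_gene_tags, probs / probs.sum())
            reps = np.repeat(np.arange(len(alloc)), alloc)
            jitter = np.rint(rng.normal(0.0, cg.tss_sd, size=len(reps))).astype(np.int64)
            parts.append(
                pd.DataFrame(
                    {
                        "chrom": p_chrom[reps],
                        "strand": p_strand[reps],
                        "pos": np.maximum(1, p_pos[reps] + jitter),
                    }
                )
            )
        if n_bg > 0:
            ci = rng.integers(0, len(chroms), size=n_bg)
            parts.append(
                pd.DataFrame(
                    {
                        "chrom": np.array(chroms)[ci],
                        "strand": np.where(rng.random(n_bg) < 0.5, "+", "-"),
                        "pos": 1 + rng.integers(0, chrom_sizes[ci]),
                    }
                )
            )
        tags = pd.concat(parts, ignore_index=True)
        tally = (
            tags.groupby(["chrom", "strand", "pos"], sort=True)
            .size()
            .rename("count")
            .reset_index()
        )
        tally["sample_id"] = sid
        ctss[sid] = tally[CTSS_COLUMNS]
    return ctss


def simulate_study(
    config: SimulationConfig = SimulationConfig(),
) -> tuple[list[TranscriptModel], ExpressionMatrix, dict[str, pd.DataFrame], GroundTruth]:
    """Generate the full synthetic study.

    Returns ``(annotation, expression, ctss_by_sample, truth)``.  Counts are
    negative binomial around class-specific log-normal baselines times the
    planted factor effects; CAGE tags pile up at true TSSs (with planted
    alternative promoters) plus uniform background.  The same config (and
    seed) always reproduces identical output.
    """
    rng = np.random.default_rng(config.seed)
    samples = full_design()
    samples = samples[
        samples["region"].isin(config.regions)
        & samples["age"].isin(config.ages)
        & samples["sex"].isin(config.sexes)
    ]
    if len(samples) < 2:
        raise ValidationError("degenerate design: need >= 2 samples")

    transcripts, _sequences, true_class = simulate_transcripts(config, rng)
    scored = [tx for tx in transcripts if not tx.gene_id.startswith("DECOY")]
    gene_ids = [tx.gene_id for tx in scored]
    lengths = pd.Series({tx.gene_id: tx.length for tx in scored})
    classes = pd.Series({tx.gene_id: tx.class_label for tx in scored})

    module_of, sex_biased = _assign_module_genes(config)
    module_of = module_of.loc[gene_ids]

    is_lnc = classes.str.startswith("lnc")
    base = np.where(
        is_lnc.to_numpy(),
        rng.lognormal(config.lnc_log_mean, config.lnc_log_sd, size=len(gene_ids)),
        rng.lognormal(config.mrna_log_mean, config.mrna_log_sd, size=len(gene_ids)),
    )
    log2_eff = _effect_matrix(config, samples, module_of, sex_biased)
    lib_factor = rng.lognormal(0.0, 0.1, size=len(samples))
    mu = base[:, None] * (2.0 ** log2_eff) * lib_factor[None, :]
    counts = pd.DataFrame(
        _nb_sample(rng, mu, config.nb_dispersion),
        index=gene_ids,
        columns=samples.index,
    )
    gene_info = pd.DataFrame(
        {"length": lengths.loc[gene_ids], "class_label": classes.loc[gene_ids]}
    )
    matrix = ExpressionMatrix(counts, samples, gene_info)

    # true TSSs: annotated 5' end, plus an internal alternative promoter for
    # a deterministic fraction of genes
    tss_of: dict[str, list[tuple[str, str, int, float]]] = {}
    n_alt = int(round(config.cage.alt_promoter_fraction * len(scored)))
    for k, tx in enumerate(scored):
        main = (tx.chrom, tx.strand, tx.tss + 1, 1.0 - config.cage.alt_usage)
        promoters = [main]
        if k < n_alt:
            span = tx.end - tx.start
            offset = int(0.3 * span + rng.integers(0, max(1, int(0.3 * span))))
            alt_pos = (
                tx.start + offset if tx.strand == "+" else tx.end - 1 - offset
            )
            promoters.append(
                (tx.chrom, tx.strand, alt_pos + 1, config.cage.alt_usage)
            )
        else:
            promoters = [(tx.chrom, tx.strand, tx.tss + 1, 1.0)]
        tss_of[tx.gene_id] = promoters

    chrom_len = {}
    for tx in transcripts:
        chrom_len[tx.chrom] = max(chrom_len.get(tx.chrom, 0), tx.end + 10_000)
    ctss = _simulate_cage(rng, config, counts, tss_of, chrom_len)

    truth = GroundTruth(
        module_of=module_of,
        sex_biased=sex_biased,
        tss_of=tss_of,
        class_of=true_class,
    )
    return transcripts, matrix, ctss, truth


def null_config(
    n_genes: int = 2000, seed: int = 0, dispersion: float = 0.05
) -> SimulationConfig:
    """A null study: no planted modules or sex effects, exchangeable genes."""
    return SimulationConfig(
        n_mrna=n_genes // 2,
        n_lncrna=n_genes - n_genes // 2,
        planted_modules=(),
        n_sex_biased=0,
        nb_dispersion=dispersion,
        seed=seed,
    )


def write_study(outdir, config: SimulationConfig = SimulationConfig()) -> dict:
    """Simulate and write every artifact in the formats the readers accept.

    Emits annotation GTF, transcript FASTA, count + metadata TSVs, one CTSS
    BED per sample, and a ground-truth TSV.  Returns the path map.
    """
    import os

    from . import core_io

    os.makedirs(outdir, exist_ok=True)
    rng_sim = simulate_study(config)
    transcripts, matrix, ctss, truth = rng_sim
    # sequences are regenerated deterministically from the same seed
    _, sequences, _ = simulate_transcripts(config)
    paths = {
        "gtf": os.path.join(outdir, "annotation.gtf"),
        "fasta": os.path.join(outdir, "transcripts.fa"),
        "counts": os.path.join(outdir, "counts.tsv"),
        "metadata": os.path.join(outdir, "samples.tsv"),
        "truth": os.path.join(outdir, "ground_truth.tsv"),
        "ctss_dir": os.path.join(outdir, "ctss"),
    }
    core_io.write_gtf(transcripts, paths["gtf"])
    core_io.write_fasta(sequences, paths["fasta"])
    core_io.write_expression_tsv(matrix, paths["counts"], paths["metadata"])
    os.makedirs(paths["ctss_dir"], exist_ok=True)
    for sid, df in ctss.items():
        core_io.write_ctss_bed(df, os.path.join(paths["ctss_dir"], f"{sid}.ctss.bed"))
    truth_df = pd.DataFrame(
        {
            "module": truth.module_of,
            "sex_biased": pd.Series(truth.sex_biased).reindex(truth.module_of.index, fill_value=""),
        }
    )
    truth_df.index.name = "gene_id"
    truth_df.to_csv(paths["truth"], sep="\t")
    return paths
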