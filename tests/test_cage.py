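"""CTSS clustering (vs brute-force oracle), gene assignment, promoter metrics."""

import numpy as np
import pandas as pd
import pytest

from lncbrain.cage import (
    TagCluster,
    alternative_promoter_ratio,
    assign_tc_to_genes,
    cluster_ctss,
    full_length_frequency,
    genomic_region_distribution,
    tpm_normalize,
    tss_profile,
)
from lncbrain.core_io import ExpressionMatrix, TranscriptModel, ValidationError


def _ctss(rows):
    """rows: (chrom, strand, pos, sample_id, count, tpm)."""
    return pd.DataFrame(
        rows, columns=["chrom", "strand", "pos", "sample_id", "count", "tpm"]
    )


def brute_force_clusters(positions, max_gap=20):
    """O(n^2) merge: repeatedly join any two runs closer than max_gap."""
    runs = [[p] for p in sorted(positions)]
    changed = True
    while changed:
        changed = False
        for i in range(len(runs) - 1):
            if min(abs(a - b) for a in runs[i] for b in runs[i + 1]) < max_gap:
                runs[i] = runs[i] + runs.pop(i + 1)
                changed = True
                break
    return sorted((min(r), max(r)) for r in runs)


class TestTpmNormalize:
    def test_formula(self):
        df = _ctss([("chr1", "+", 10, "s1", 5, None)]).drop(columns="tpm")
        df = pd.concat(
            [df, pd.DataFrame([("chr1", "+", 99, "s1", 9995)],
                              columns=["chrom", "strand", "pos", "sample_id", "count"])],
            ignore_index=True,
        )
        out = tpm_normalize(df)
        assert out.loc[0, "tpm"] == pytest.approx(500.0)  # 5 / 10000 * 1e6

    def test_scale_invariance(self):
        rows = [("chr1", "+", p, "s1", c) for p, c in [(5, 4), (9, 6), (50, 10)]]
        df = pd.DataFrame(rows, columns=["chrom", "strand", "pos", "sample_id", "count"])
        doubled = df.assign(count=df["count"] * 2)
        np.testing.assert_allclose(
            tpm_normalize(df)["tpm"], tpm_normalize(doubled)["tpm"]
        )

    def test_exact_threshold_value(self):
        # 1 tag in a 2e6-tag library is exactly 0.5 TPM
        rows = [("chr1", "+", 1, "s1", 1), ("chr1", "+", 9999, "s1", 2_000_000 - 1)]
        df = pd.DataFrame(rows, columns=["chrom", "strand", "pos", "sample_id", "count"])
        out = tpm_normalize(df)
        assert out.loc[0, "tpm"] == pytest.approx(0.5)

    def test_empty_table_is_an_error(self):
        with pytest.raises(ValidationError):
            tpm_normalize(_ctss([]))


class TestClusterCtss:
    def test_gap_merging_example(self):
        df = _ctss(
            [("chr1", "+", p, "s1", 1, 1.0) for p in (100, 110, 135)]
        )
        tcs = cluster_ctss(df)
        spans = sorted((tc.start + 1, tc.end) for tc in tcs)
        assert spans == [(100, 110), (135, 135)]
        widths = sorted(tc.width for tc in tcs)
        assert widths == [1, 11]

    def test_boundary_distance_convention(self):
        # 19 apart -> one cluster; 20 apart -> two
        near = cluster_ctss(_ctss([("chr1", "+", 100, "s1", 1, 1.0),
                                   ("chr1", "+", 119, "s1", 1, 1.0)]))
        far = cluster_ctss(_ctss([("chr1", "+", 100, "s1", 1, 1.0),
                                  ("chr1", "+", 120, "s1", 1, 1.0)]))
        assert len(near) == 1 and near[0].width == 20
        assert len(far) == 2

    def test_low_tpm_position_dropped_before_clustering(self):
        df = _ctss(
            [
                ("chr1", "+", 100, "s1", 1, 0.4),
                ("chr1", "+", 105, "s1", 1, 0.6),
            ]
        )
        tcs = cluster_ctss(df, min_tpm=0.5)
        assert len(tcs) == 1
        assert tcs[0].start + 1 == 105

    def test_retained_if_any_sample_reaches_threshold(self):
        df = _ctss(
            [
                ("chr1", "+", 100, "s1", 1, 0.2),
                ("chr1", "+", 100, "s2", 3, 0.7),
            ]
        )
        (tc,) = cluster_ctss(df, min_tpm=0.5)
        assert tc.tags == {"s1": 1, "s2": 3}
        assert tc.n_samples_detected == 2

    def test_summit_is_max_pooled_tpm_tie_five_prime(self):
        df = _ctss(
            [
                ("chr1", "+", 100, "s1", 2, 2.0),
                ("chr1", "+", 104, "s1", 2, 2.0),
                ("chr1", "-", 200, "s1", 2, 2.0),
                ("chr1", "-", 204, "s1", 2, 2.0),
            ]
        )
        tcs = {tc.strand: tc for tc in cluster_ctss(df)}
        assert tcs["+"].summit + 1 == 100  # 5'-most on + is the left end
        assert tcs["-"].summit + 1 == 204  # 5'-most on - is the right end

    def test_strand_separation(self):
        df = _ctss([("chr1", "+", 100, "s1", 1, 1.0),
                    ("chr1", "-", 101, "s1", 1, 1.0)])
        assert len(cluster_ctss(df)) == 2

    @pytest.mark.parametrize("case_seed", range(25))
    def test_matches_brute_force_oracle(self, case_seed):
        rng = np.random.default_rng(1000 + case_seed)
        n = int(rng.integers(1, 51))
        positions = sorted(set(rng.integers(1, 400, size=n).tolist()))
        df = _ctss([("chr1", "+", p, "s1", 1, 1.0) for p in positions])
        tcs = cluster_ctss(df)
        spans = sorted((tc.start + 1, tc.end) for tc in tcs)
        assert spans == brute_force_clusters(positions)

    def test_order_invariance_and_pooling_equivalence(self):
        rng = np.random.default_rng(7)
        rows = []
        for sid in ("s1", "s2"):
            for p in rng.integers(1, 300, size=30):
                rows.append(("chr1", "+", int(p), sid, 1, 1.0))
        df = _ctss(rows).drop_duplicates(["chrom", "strand", "pos", "sample_id"])
        shuffled = df.sample(frac=1.0, random_state=0)
        a = cluster_ctss(df)
        b = cluster_ctss(shuffled)
        assert [(t.start, t.end, t.summit) for t in a] == [
            (t.start, t.end, t.summit) for t in b
        ]

    def test_tag_conservation(self, planted_study):
        _, _, ctss, _ = planted_study
        sample = "S_PFC_1yr_F"
        df = tpm_normalize(ctss[sample])
        tcs = cluster_ctss(df)
        clustered = sum(tc.tags.get(sample, 0) for tc in tcs)
        assert clustered <= df["count"].sum()


def _gene(gid, chrom, strand, start, end):
    return TranscriptModel(f"{gid}.1", gid, chrom, strand, [(start, end)])


def _tc(chrom, strand, summit, tags, start=None, end=None, tc_id=None):
    start = summit if start is None else start
    end = summit + 1 if end is None else end
    return TagCluster(
        tc_id=tc_id or f"TC_{chrom}_{strand}_{summit}",
        chrom=chrom, strand=strand, start=start, end=end, summit=summit,
        tags=tags, tpm={k: float(v) for k, v in tags.items()},
    )


class TestAssignment:
    def test_upstream_window_and_gene_body(self):
        gene = _gene("G1", "chr1", "+", 10_000, 15_000)
        tcs = [
            _tc("chr1", "+", 8500, {"s1": 5}),    # 1.5 kb upstream -> assigned
            _tc("chr1", "+", 7000, {"s1": 5}),    # 3 kb upstream -> intergenic
            _tc("chr1", "+", 12_000, {"s1": 5}),  # gene body -> assigned
            _tc("chr1", "-", 12_000, {"s1": 5}),  # wrong strand -> unassigned
        ]
        table = assign_tc_to_genes(tcs, [gene])
        assert tcs[0].assigned_gene == "G1"
        assert tcs[1].assigned_gene is None
        assert tcs[2].assigned_gene == "G1"
        assert tcs[3].assigned_gene is None
        assert table.loc["G1", "n_tcs"] == 2
        assert bool(table.loc["G1", "alternative_promoter"])

    def test_minus_strand_upstream_is_rightward(self):
        gene = _gene("G1", "chr1", "-", 10_000, 15_000)
        up = _tc("chr1", "-", 16_500, {"s1": 1})
        far = _tc("chr1", "-", 17_500, {"s1": 1})
        assign_tc_to_genes([up, far], [gene])
        assert up.assigned_gene == "G1"
        assert far.assigned_gene is None

    def test_ambiguous_summit_goes_to_nearest_tss(self):
        g1 = _gene("G1", "chr1", "+", 10_000, 20_000)
        g2 = _gene("G2", "chr1", "+", 18_000, 30_000)
        tc = _tc("chr1", "+", 18_500, {"s1": 1})  # inside both spans
        assign_tc_to_genes([tc], [g1, g2])
        assert tc.assigned_gene == "G2"  # 500 bp from G2's TSS vs 8500 from G1's


class TestAlternativePromoterRatio:
    def test_stated_example(self):
        g1 = _gene("G1", "chr1", "+", 1000, 2000)
        g2 = _gene("G2", "chr1", "+", 50_000, 60_000)
        tcs = [
            _tc("chr1", "+", 1000, {"s1": 10}),
            _tc("chr1", "+", 1500, {"s1": 5}),
            _tc("chr1", "+", 50_000, {"s1": 20}),
        ]
        assign_tc_to_genes(tcs, [g1, g2])
        ratio = alternative_promoter_ratio(tcs, ["s1"])
        assert ratio["s1"] == pytest.approx(5 / 35)

    def test_single_tc_genes_give_zero(self):
        g = _gene("G1", "chr1", "+", 1000, 2000)
        tcs = [_tc("chr1", "+", 1000, {"s1": 10})]
        assign_tc_to_genes(tcs, [g])
        assert alternative_promoter_ratio(tcs, ["s1"])["s1"] == 0.0

    def test_tie_broken_to_five_prime_dominant(self):
        g = _gene("G1", "chr1", "+", 1000, 3000)
        tcs = [
            _tc("chr1", "+", 1000, {"s1": 10}),
            _tc("chr1", "+", 2000, {"s1": 10}),
        ]
        assign_tc_to_genes(tcs, [g])
        # dominant is the 5'-most (summit 1000); its 10 reads are not alternative
        assert alternative_promoter_ratio(tcs, ["s1"])["s1"] == pytest.approx(0.5)

    def test_no_assigned_tags_warns_and_scores_zero(self):
        tcs = [_tc("chr1", "+", 100, {"s1": 3})]  # never assigned
        with pytest.warns(UserWarning):
            ratio = alternative_promoter_ratio(tcs, ["s1"])
        assert ratio["s1"] == 0.0


class TestFullLengthFrequency:
    def _matrix(self, rpkm_values):
        samples = pd.DataFrame(
            {"region": ["PFC"], "age": [1], "sex": ["F"]}, index=["s1"]
        )
        counts = pd.DataFrame({"s1": rpkm_values}, index=[f"L{i}" for i in range(4)])
        gi = pd.DataFrame(
            {"length": 1000, "class_label": "lnc_intergenic"}, index=counts.index
        )
        return ExpressionMatrix(counts, samples, gi)

    def test_fraction_of_detected_with_cap_evidence(self):
        mat = self._matrix([100, 100, 100, 100])  # all four detected
        tcs = []
        for i in range(3):  # three of four have an assigned TC with a tag
            tc = _tc("chr1", "+", 100 + i, {"s1": 2})
            tc.assigned_gene = f"L{i}"
            tcs.append(tc)
        flf = full_length_frequency(tcs, mat)
        assert flf["s1"] == pytest.approx(0.75)

    def test_all_and_none(self):
        mat = self._matrix([100, 100, 100, 100])
        tcs = []
        for i in range(4):
            tc = _tc("chr1", "+", 100 + i, {"s1": 1})
            tc.assigned_gene = f"L{i}"
            tcs.append(tc)
        assert full_length_frequency(tcs, mat)["s1"] == 1.0
        assert full_length_frequency([], mat)["s1"] == 0.0


class TestTssProfile:
    def test_all_summits_at_tss_land_in_center_bin(self):
        genes = [_gene(f"G{i}", "chr1", "+", 10_000 * (i + 1), 10_000 * (i + 1) + 500)
                 for i in range(5)]
        tcs = [_tc("chr1", "+", 10_000 * (i + 1), {"s1": 1}) for i in range(5)]
        prof = tss_profile(tcs, genes, window=1000, bin_size=10)
        assert prof.sum() == 5
        assert prof.loc[5.0] == 5  # bin [0, 10) holds distance 0

    def test_minus_strand_orientation(self):
        gene = _gene("G1", "chr1", "-", 10_000, 15_000)  # TSS at 14_999
        tc = _tc("chr1", "-", 15_049, {"s1": 1})  # 50 bp greater-coordinate
        prof = tss_profile([tc], [gene], window=1000, bin_size=10)
        assert prof.loc[-45.0] == 1  # distance -50 -> bin [-50, -40)

    def test_empty_input_gives_empty_profile(self):
        assert tss_profile([], [], window=100).empty


class TestGenomicRegionDistribution:
    @pytest.fixture()
    def annotated_gene(self):
        # +-strand gene [1000, 2000): 5'UTR [1000,1200), CDS [1200,1700),
        # 3'UTR [1700,2000), all in one exon
        return TranscriptModel(
            "T1", "G1", "chr1", "+", [(1000, 2000)],
            cds=[(1200, 1700)], utr5=[(1000, 1200)], utr3=[(1700, 2000)],
        )

    def test_precedence_classification(self, annotated_gene):
        positions = [
            ("chr1", 1100),  # 5UTR
            ("chr1", 1400),  # CDS
            ("chr1", 1800),  # 3UTR
            ("chr1", 5000),  # intergenic
        ]
        frac, _ = genomic_region_distribution(positions, [annotated_gene])
        assert frac["5UTR"] == pytest.approx(0.25)
        assert frac["CDS"] == pytest.approx(0.25)
        assert frac["3UTR"] == pytest.approx(0.25)
        assert frac["intergenic"] == pytest.approx(0.25)
        assert frac.sum() == pytest.approx(1.0)

    def test_intronic_position(self):
        gene = TranscriptModel(
            "T1", "G1", "chr1", "+", [(1000, 1200), (1800, 2000)],
            cds=[(1000, 1200), (1800, 2000)], utr5=[], utr3=[],
        )
        frac, _ = genomic_region_distribution([("chr1", 1500)], [gene])
        assert frac["intron"] == pytest.approx(1.0)

    def test_fisher_enrichment_matches_hypergeometric_oracle(self, annotated_gene):
        from scipy import stats

        cage = [("chr1", 1100)] * 90 + [("chr1", 5000)] * 10
        ctrl = [("chr1", 1100)] * 10 + [("chr1", 5000)] * 90
        _, test = genomic_region_distribution(cage, [annotated_gene], ctrl)
        assert test["p_value"] < 1e-10
        # hypergeometric enumeration: sum P(a) over tables no more likely
        # than the observed one, margins fixed at (100, 100) x (100, 100)
        a_obs, N, K, n = 90, 200, 100, 100
        pmf = stats.hypergeom.pmf(np.arange(0, 101), N, K, n)
        oracle = pmf[pmf <= pmf[a_obs] * (1 + 1e-9)].sum()
        assert test["p_value"] == pytest.approx(oracle, rel=1e-9)

    def test_missing_subfeatures_falls_back_with_warning(self):
        gene = _gene("G1", "chr1", "+", 1000, 2000)
        with pytest.warns(UserWarning, match="sub-features"):
            frac, test = genomic_region_distribution([("chr1", 1100)], [gene])
        assert frac["exon"] == pytest.approx(1.0)
        assert test is None
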