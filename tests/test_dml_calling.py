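import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import radml as r
from radml import dml_calling as dml
from radml import genomic_data as gd

from oracles import exact_rank_sum_p, naive_bh


def _detp(fail_counts, n_samples=10, thresh=0.05):
    """Detection-p frame with the given number of failing samples per probe."""
    rows = {}
    for i, k in enumerate(fail_counts):
        row = np.full(n_samples, 0.001)
        row[:k] = thresh * 10
        rows[f"p{i}"] = row
    return pd.DataFrame(rows).T


class TestDetectionFilters:
    def test_probe_filter_strict_at_half(self):
        detp = _detp([6, 5, 0])
        kept = dml.filter_probes_by_detection(detp)
        assert kept == ["p1", "p2"]  # 6/10 removed; exactly half retained

    def test_sample_filter_keeps_well_detected(self):
        # sample 0: 80% of loci well detected -> kept; sample 1: 50% -> removed
        detp = pd.DataFrame(
            {"s0": [1e-7] * 8 + [1e-3] * 2, "s1": [1e-7] * 5 + [1e-3] * 5},
            index=[f"p{i}" for i in range(10)],
        )
        assert dml.filter_samples_by_detection(detp) == ["s0"]

    def test_empty_matrix_rejected(self):
        with pytest.raises(gd.ValidationError):
            dml.filter_samples_by_detection(pd.DataFrame())


class TestWilcoxon:
    def test_exact_most_extreme_split(self):
        _, p = dml.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], exact=True)
        assert p == pytest.approx(0.1)  # 2 of the 20 rank assignments

    def test_identical_groups_not_significant(self):
        _, p = dml.wilcoxon_rank_sum([1, 2, 3, 4], [1, 2, 3, 4])
        assert p >= 0.99

    def test_empty_group_after_nan_removal(self):
        with pytest.raises(gd.ValidationError):
            dml.wilcoxon_rank_sum([np.nan, np.nan], [1.0, 2.0])

    def test_normal_approximation_tracks_permutation_oracle(self, rng):
        """Normal approximation p within 0.03 of enumeration on 6 vs 6.

        Heavily tied data at this size make the rank-sum support too
        coarse for any normal approximation; such pooled sizes
        auto-select the exact path, checked separately below.
        """
        worst = 0.0
        for _ in range(200):
            x = rng.integers(0, 1000, size=6).astype(float)
            y = rng.integers(0, 1000, size=6).astype(float)
            _, p = dml.wilcoxon_rank_sum(x, y, exact=False)
            worst = max(worst, abs(p - exact_rank_sum_p(x, y)))
        assert worst < 0.03

    def test_small_samples_auto_select_exact_path(self, rng):
        """Heavily tied small samples are routed to exact enumeration."""
        for _ in range(50):
            x = rng.integers(0, 4, size=6).astype(float)
            y = rng.integers(0, 4, size=6).astype(float)
            _, p_auto = dml.wilcoxon_rank_sum(x, y)
            assert p_auto == pytest.approx(exact_rank_sum_p(x, y))

    def test_exact_path_handles_ties(self):
        x, y = [1.0, 1.0, 2.0], [2.0, 3.0, 3.0]
        _, p = dml.wilcoxon_rank_sum(x, y, exact=True)
        assert 0.0 < p <= 1.0
        assert p == pytest.approx(exact_rank_sum_p(x, y))


class TestBhFdr:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(dml.bh_fdr([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])
        np.testing.assert_allclose(dml.bh_fdr([0.04]), [0.04])

    def test_rejects_out_of_range(self):
        with pytest.raises(gd.ValidationError):
            dml.bh_fdr([0.5, 1.5])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_matches_naive_oracle_and_dominates_p(self, pvals):
        q = dml.bh_fdr(pvals)
        np.testing.assert_allclose(q, naive_bh(pvals), atol=1e-12)
        assert np.all(q >= np.asarray(pvals) - 1e-12)


class TestCallRadml:
    def test_threshold_edges(self, tiny_beta):
        beta, meta = tiny_beta
        records = {rec.probe_id: rec for rec in dml.call_radml(beta, meta)}
        up = records["cg_up"]
        assert up.delta_beta == pytest.approx(0.12)
        assert up.direction == "hyper" and up.is_radml
        dn = records["cg_dn"]
        assert dn.direction == "hypo" and dn.is_radml
        assert not records["cg_null"].is_radml
        small = records["cg_small"]
        assert small.delta_beta == pytest.approx(0.09)
        assert not small.is_radml  # below the effect threshold

    def test_delta_threshold_is_inclusive(self):
        # dyadic values so delta == threshold exactly in binary floats;
        # groups completely separated so the probe is clearly significant
        a = np.array([0.625, 0.640625, 0.65625, 0.671875, 0.6875])
        b = a - 0.125
        beta = r.BetaMatrix(pd.DataFrame(
            [np.r_[a, b]], index=["p"], columns=[f"s{i}" for i in range(10)]))
        meta = [r.SampleMeta(f"s{i}", "A" if i < 5 else "B", 50.0)
                for i in range(10)]
        (rec,) = dml.call_radml(beta, meta, delta_thresh=0.125, fdr_thresh=0.05)
        assert rec.delta_beta == 0.125
        assert rec.q_value < 0.05
        assert rec.is_radml  # "at least" keeps the boundary case

    def test_subthreshold_delta_never_called(self, rng):
        # highly significant but |delta| = 0.09 < 0.10
        a = np.tile(np.linspace(0.50, 0.52, 12), (1, 1))
        b = a - 0.09
        values = np.hstack([a, b])
        beta = r.BetaMatrix(pd.DataFrame(
            values, index=["p"], columns=[f"s{i}" for i in range(24)]))
        meta = [r.SampleMeta(f"s{i}", "A" if i < 12 else "B", 50.0)
                for i in range(24)]
        (rec,) = dml.call_radml(beta, meta)
        assert rec.q_value < 1e-3 and not rec.is_radml

    def test_single_group_rejected(self, tiny_beta):
        beta, meta = tiny_beta
        mono = [r.SampleMeta(m.sample_id, "A", m.age) for m in meta]
        with pytest.raises(gd.ValidationError):
            dml.call_radml(beta, mono)


def _gene(gid, chrom, start, end, biotype, strand="+"):
    return gd.GeneModel(gid, gid, chrom, start, end, strand, biotype)


class TestClassification:
    GENES = [
        _gene("CODING", "chr1", 1000, 2000, "protein_coding"),
        _gene("LNC", "chr1", 1800, 3000, "lncRNA"),
        _gene("LNC2", "chr2", 100, 500, "lincRNA"),
    ]

    @pytest.mark.parametrize(
        "probe,expected",
        [
            # manifest assignment wins regardless of position
            (gd.ProbeRecord("a", "chr1", 5000, "+", (("X", "protein_coding"),)),
             "protein_coding"),
            # inside lncRNA only
            (gd.ProbeRecord("b", "chr1", 2500, "+"), "ncRNA"),
            # overlapping both coding and lncRNA: the coding rule precedes
            (gd.ProbeRecord("c", "chr1", 1900, "+"), "protein_coding"),
            (gd.ProbeRecord("d", "chr1", 5000, "+"), "intergenic"),
            # chromosome absent from annotation
            (gd.ProbeRecord("e", "chrZ", 5000, "+"), "intergenic"),
        ],
    )
    def test_precedence_cascade(self, probe, expected):
        assert dml.classify_probe_region(probe, self.GENES) == expected

    def test_classify_many_agrees_with_single(self):
        probes = [
            gd.ProbeRecord(f"p{i}", "chr1", pos, "+")
            for i, pos in enumerate([500, 1500, 2500, 1900, 9000])
        ]
        classifier = dml.RegionClassifier(self.GENES)
        many = classifier.classify_many(probes)
        for p in probes:
            assert many[p.probe_id] == classifier.classify(p)


class TestCascade:
    def test_fixture_reproduces_stage_counts(self, fixture_run):
        counts = fixture_run["cascade"]
        assert counts["total_radml"] == 396
        assert counts["removed_manifest_coding"] == 276
        assert counts["uncharacterized_after_manifest"] == 120
        assert counts["removed_annotation_coding"] == 24
        assert counts["noncoding_survivors"] == 96

    def test_conservation_invariants(self, fixture_run):
        c = fixture_run["cascade"]
        assert (c["total_radml"] - c["removed_manifest_coding"]
                - c["removed_annotation_coding"] == c["noncoding_survivors"])
        assert c["intergenic"] + c["ncRNA"] == c["noncoding_survivors"]
        assert c["hypo"] + c["hyper"] == c["noncoding_survivors"]
        # each survivor carries exactly one region class
        assert all(s.region_class in ("intergenic", "ncRNA")
                   for s in fixture_run["survivors"])

    def test_empty_input_gives_zero_counts(self):
        survivors, counts = dml.noncoding_filter_cascade([], [], [])
        assert survivors == [] and (counts == 0).all()
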