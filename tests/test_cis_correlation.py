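import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import radml as r
from radml import cis_correlation as cc
from radml import dml_calling as dml
from radml import expression_de as de
from radml import genomic_data as gd

from oracles import brute_force_cis_pairs, midrank_spearman


def _gene(gid, chrom, start, end, strand="+", biotype="protein_coding"):
    return gd.GeneModel(gid, gid, chrom, start, end, strand, biotype)


def _probe(pid, chrom, pos):
    return gd.ProbeRecord(pid, chrom, pos, "+")


class TestEnumeration:
    def test_signed_distance_follows_genome_axis(self):
        probe = _probe("cg1", "chr17", 100_000)
        genes = [
            _gene("RIGHT", "chr17", 103_300, 108_000),          # TSS 3.3 kb right
            _gene("LEFT", "chr17", 50_000, 93_301, strand="-"),  # TSS 6.7 kb left
        ]
        pairs = {p.gene_id: p for p in cc.enumerate_cis_pairs([probe], genes)}
        assert pairs["RIGHT"].distance_kb == pytest.approx(3.3)
        assert pairs["LEFT"].distance_kb == pytest.approx(-6.7)

    def test_window_boundary_inclusive(self):
        probe = _probe("cg1", "chr1", 2_000_000)
        genes = [
            _gene("AT", "chr1", 3_000_000, 3_001_000),     # exactly 1 Mb
            _gene("BEYOND", "chr1", 3_000_001, 3_002_000),  # 1 Mb + 1
            _gene("OTHER", "chr2", 2_000_100, 2_001_100),   # wrong chromosome
        ]
        found = {p.gene_id for p in cc.enumerate_cis_pairs([probe], genes)}
        assert found == {"AT"}

    def test_matches_brute_force_scan(self, rng):
        probes = [_probe(f"cg{i}", f"chr{rng.integers(1, 3)}",
                         int(rng.integers(0, 5_000_000))) for i in range(40)]
        genes = [
            _gene(f"g{i}", f"chr{rng.integers(1, 3)}",
                  s := int(rng.integers(0, 5_000_000)), s + 2_000,
                  strand=str(rng.choice(["+", "-"])))
            for i in range(80)
        ]
        ours = {(p.probe_id, p.gene_id)
                for p in cc.enumerate_cis_pairs(probes, genes)}
        assert ours == brute_force_cis_pairs(probes, genes, 1_000_000)


class TestSpearman:
    def test_perfect_antitone(self):
        rho, _ = cc.spearman([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        rho, _ = cc.spearman([1, 2, 3, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(0.8)  # 1 - 6*2 / (4*15)

    def test_midranks_match_brute_force_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 25))
            x = rng.integers(0, 5, size=n).astype(float)  # heavy ties
            y = rng.integers(0, 5, size=n).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            rho, _ = cc.spearman(x, y)
            assert rho == pytest.approx(midrank_spearman(x, y), abs=1e-12)

    def test_constant_vector_gives_nan(self):
        rho, p = cc.spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(rho) and math.isnan(p)

    def test_too_few_observations(self):
        with pytest.raises(gd.ValidationError):
            cc.spearman([1, 2, 3], [3, 2, 1])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.integers(-50, 50), min_size=6, max_size=20, unique=True))
    def test_invariant_under_monotone_transforms(self, x):
        # integer support keeps exp() strictly monotone in float arithmetic
        x = np.asarray(x, dtype=float)
        rng = np.random.default_rng(7)
        y = rng.normal(size=len(x))
        base, _ = cc.spearman(x, y)
        for fn in (np.exp, lambda v: 3 * v + 1,
                   lambda v: np.argsort(np.argsort(v)).astype(float)):
            rho, _ = cc.spearman(fn(x), y)
            assert rho == pytest.approx(base, abs=1e-9)


class TestCorrelatePairs:
    def test_fixture_significant_pair_bookkeeping(self, fixture_run):
        sig = fixture_run["significant"]
        assert len(sig) == 39
        assert len({p.probe_id for p in sig}) == 23
        assert len({p.gene_id for p in sig}) == 36
        assert sum(p.rho > 0 for p in sig) == 25

    def test_constant_gene_dropped_not_zero(self):
        samples = [f"s{i}" for i in range(10)]
        beta = r.BetaMatrix(pd.DataFrame(
            [np.linspace(0.2, 0.8, 10)], index=["cg1"], columns=samples))
        logcpm = pd.DataFrame(
            [np.full(10, 3.0), np.linspace(1, 5, 10)],
            index=["FLAT", "RISES"], columns=samples)
        pairs = [cc.CpgGenePair("cg1", "FLAT", 10.0),
                 cc.CpgGenePair("cg1", "RISES", 20.0),
                 cc.CpgGenePair("cg1", "MISSING", 30.0)]
        out = cc.correlate_pairs(pairs, beta, logcpm)
        assert [p.gene_id for p in out] == ["RISES"]
        assert out[0].rho == pytest.approx(1.0)

    def test_null_cohort_yields_no_significant_pairs(self, rng):
        samples = [f"s{i}" for i in range(30)]
        beta = r.BetaMatrix(pd.DataFrame(
            rng.uniform(0.1, 0.9, size=(20, 30)),
            index=[f"cg{i}" for i in range(20)], columns=samples))
        logcpm = pd.DataFrame(
            rng.normal(5, 1, size=(20, 30)),
            index=[f"g{i}" for i in range(20)], columns=samples)
        pairs = [cc.CpgGenePair(f"cg{i}", f"g{j}", 0.0)
                 for i in range(20) for j in range(20)]
        out = cc.correlate_pairs(pairs, beta, logcpm)
        assert len(cc.significant_pairs(out)) / len(out) < 0.01


class TestDirectionConsistency:
    def test_fixture_has_exactly_one_discordant_probe(self, fixture_run):
        res = cc.direction_consistency(fixture_run["survivors"],
                                       fixture_run["validation_radmls"])
        assert res.n_available == 59
        assert res.n_discordant == 1

    def test_identical_cohorts_fully_concordant(self, fixture_run):
        surv = fixture_run["survivors"]
        res = cc.direction_consistency(surv, surv)
        assert res.n_available == len(surv) and res.n_discordant == 0

    def test_disjoint_probe_sets(self, fixture_run):
        res = cc.direction_consistency(fixture_run["survivors"], [])
        assert res.n_available == 0


class TestReplication:
    def test_fixture_replication_counts(self, fixture_run):
        rep = fixture_run["replicated"]
        assert sum(p.replicated != "untestable" for p in rep) == 28
        assert sum(p.replicated == "yes" for p in rep) == 20
        assert sum(p.replicated == "no" for p in rep) == 8

    def test_self_replication(self, fixture_run):
        disc = fixture_run["discovery"]
        rep = cc.replicate_pairs(fixture_run["significant"], disc.beta,
                                 de.log_cpm(disc.counts))
        testable = [p for p in rep if p.replicated != "untestable"]
        assert testable and all(p.replicated == "yes" for p in testable)

    def test_sign_flip_blocks_replication(self):
        samples = [f"s{i}" for i in range(12)]
        x = np.linspace(0.2, 0.8, 12)
        beta = r.BetaMatrix(pd.DataFrame([x], index=["cg1"], columns=samples))
        logcpm = pd.DataFrame([x[::-1] * 10], index=["g1"], columns=samples)
        pair = cc.CpgGenePair("cg1", "g1", 5.0, rho=0.9, p_value=1e-6,
                              q_value=1e-5, n_samples=12)
        (out,) = cc.replicate_pairs([pair], beta, logcpm)
        assert out.rho_validation == pytest.approx(-1.0)
        assert out.q_validation < 0.05 and out.replicated == "no"
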