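"""Differential methylation testing, reversal, density, and overlaps."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spaceomics.io import FormatError, GeneSetDB
from spaceomics.methylation import (
    MethSiteTable,
    ProfileDef,
    classify_profile,
    deg_meth_overlap,
    density_expression_correlation,
    diff_methylation,
    drach_check,
    filter_coverage,
    pathway_meth_density,
    read_meth_sites,
    reversal_analysis,
    write_meth_sites,
)


def _table(cov, mod, kmers=None, genes=None):
    cov = pd.DataFrame(cov)
    mod = pd.DataFrame(mod)
    n = len(cov)
    sites = pd.DataFrame(
        {
            "transcript_id": [f"T{i}" for i in range(n)],
            "gene_id": genes or [f"GN{i}" for i in range(n)],
            "position": range(n),
            "kmer": kmers or ["GGACT"] * n,
            "region": ["exon"] * n,
        },
        index=pd.Index([f"S{i}" for i in range(n)], name="site_id"),
    )
    cov.index = mod.index = sites.index
    return MethSiteTable(sites=sites, coverage=cov, mod=mod)


class TestTableValidation:
    def test_mod_exceeding_coverage_rejected(self):
        with pytest.raises(FormatError, match="mod_reads > coverage"):
            _table({"a": [10]}, {"a": [11]})

    def test_roundtrip(self, tmp_path):
        t = _table({"a": [10, 20], "b": [5, 8]}, {"a": [3, 4], "b": [1, 2]})
        write_meth_sites(t, tmp_path / "m.tsv")
        back = read_meth_sites(tmp_path / "m.tsv")
        pd.testing.assert_frame_equal(back.coverage, t.coverage)
        pd.testing.assert_frame_equal(back.mod, t.mod)
        pd.testing.assert_frame_equal(back.sites, t.sites)


class TestFilterCoverage:
    def test_per_sample_rule(self):
        t = _table({"a": [25, 25], "b": [19, 20]}, {"a": [0, 0], "b": [0, 0]})
        kept = filter_coverage(t, min_cov=20)
        assert kept.site_ids == ["S1"]  # (25, 19) fails the per-sample rule

    def test_exactly_at_threshold_retained(self):
        t = _table({"a": [20], "b": [20]}, {"a": [1], "b": [1]})
        assert filter_coverage(t, min_cov=20).site_ids == ["S0"]

    def test_min_cov_one_is_identity_on_positive(self):
        t = _table({"a": [3, 7]}, {"a": [1, 2]})
        assert filter_coverage(t, min_cov=1).site_ids == t.site_ids

    def test_sample_subset(self):
        t = _table({"a": [25], "b": [5]}, {"a": [0], "b": [0]})
        assert filter_coverage(t, min_cov=20, samples=["a"]).site_ids == ["S0"]
        assert filter_coverage(t, min_cov=20, samples=["a", "b"]).site_ids == []


class TestDrach:
    def test_canonical_motif(self):
        assert drach_check("GGACT") is True

    def test_r_position_violation(self):
        assert drach_check("GCACT") is False

    def test_t_u_equivalence(self):
        assert drach_check("GGACU") == drach_check("GGACT")
        assert drach_check("UGACU") is True

    @pytest.mark.parametrize("bad", ["GGAC", "GGACTT", "GGNCT"])
    def test_malformed_kmer_rejected(self, bad):
        with pytest.raises(ValueError):
            drach_check(bad)


class TestDiffMethylation:
    def test_identical_groups_null(self):
        t = _table(
            {"a": [50], "b": [50], "c": [50], "d": [50]},
            {"a": [10], "b": [10], "c": [10], "d": [10]},
        )
        rec = diff_methylation(t, ["a", "b"], ["c", "d"])
        assert rec.loc[0, "meth_diff"] == 0.0
        assert rec.loc[0, "direction"] == "ns"

    def test_pooled_p_equals_hypergeometric_oracle(self):
        # 30 mod / 20 unmod vs 10 mod / 40 unmod
        t = _table({"t": [50], "r": [50]}, {"t": [30], "r": [10]})
        rec = diff_methylation(t, ["t"], ["r"], engine="pooled")
        assert rec.loc[0, "meth_diff"] == pytest.approx(40.0)
        # independent oracle: sum hypergeometric pmf over tables as or less
        # probable than the observed one
        M, n, N, k = 100, 40, 50, 30
        rv = stats.hypergeom(M, n, N)
        p_obs = rv.pmf(k)
        oracle = sum(
            rv.pmf(x) for x in range(max(0, N - 60), min(n, N) + 1)
            if rv.pmf(x) <= p_obs * (1 + 1e-9)
        )
        assert rec.loc[0, "p"] == pytest.approx(oracle, abs=1e-10)

    def test_q_at_least_p(self):
        rng = np.random.default_rng(5)
        n = 40
        cov = {s: rng.integers(20, 60, n) for s in "abcd"}
        mod = {s: rng.binomial(cov[s], 0.2) for s in "abcd"}
        t = _table(cov, mod)
        rec = diff_methylation(t, ["a", "b"], ["c", "d"])
        assert (rec["q"] >= rec["p"] - 1e-12).all()

    def test_logistic_engine_detects_large_shift(self):
        t = _table(
            {s: [100] for s in "abcd"},
            {"a": [60], "b": [55], "c": [10], "d": [12]},
        )
        rec = diff_methylation(t, ["a", "b"], ["c", "d"], engine="logistic")
        assert rec.loc[0, "p"] < 1e-6
        assert rec.loc[0, "direction"] == "hyper"

    def test_empty_group_rejected(self):
        t = _table({"a": [10]}, {"a": [1]})
        with pytest.raises(FormatError, match="nonempty"):
            diff_methylation(t, [], ["a"])

    def test_profile_groups_must_not_overlap(self):
        with pytest.raises(FormatError, match="both groups"):
            ProfileDef("X", ("R+1",), ("R+1", "L-3"))


class TestClassify:
    def test_sign_partition(self):
        rec = pd.DataFrame(
            {
                "site_id": ["S0", "S1", "S2"],
                "meth_diff": [15.0, -9.0, 3.0],
                "significant": [True, True, False],
            }
        )
        hyper, hypo = classify_profile(rec)
        assert hyper == {"S0"} and hypo == {"S1"}
        assert hyper.isdisjoint(hypo)

    def test_all_ns_empty(self):
        rec = pd.DataFrame(
            {"site_id": ["S0"], "meth_diff": [5.0], "significant": [False]}
        )
        assert classify_profile(rec) == (set(), set())


class TestReversal:
    def _rec(self, rows):
        return pd.DataFrame(
            rows, columns=["site_id", "gene_id", "meth_diff", "significant"]
        )

    def test_rule_application(self):
        flight = self._rec([("S0", "GA", 30.0, True), ("S1", "GB", 25.0, True)])
        recovery = {
            "R+45": self._rec(
                [("S0", "GA", -30.0, True), ("S1", "GB", -10.0, False)]
            )
        }
        rep = reversal_analysis(flight, recovery)
        assert rep.reversed_hyper["R+45"] == {"S0"}
        assert rep.genes_hyper["R+45"] == {"GA"}

    def test_ns_recovery_not_reported(self):
        flight = self._rec([("S0", "GA", 30.0, True)])
        recovery = {"R+45": self._rec([("S0", "GA", -30.0, False)])}
        rep = reversal_analysis(flight, recovery)
        assert rep.reversed_hyper["R+45"] == set()

    def test_hypo_symmetry(self):
        flight = self._rec([("S0", "GA", -30.0, True)])
        recovery = {"R+45": self._rec([("S0", "GA", +20.0, True)])}
        rep = reversal_analysis(flight, recovery)
        assert rep.reversed_hypo["R+45"] == {"S0"}
        assert rep.reversed_hyper["R+45"] == set()

    def test_missing_profile_rejected(self):
        with pytest.raises(FormatError):
            reversal_analysis(self._rec([("S0", "GA", 1.0, True)]), {})


class TestDensity:
    def _db(self, **sets):
        return GeneSetDB(
            sets={k: frozenset(v) for k, v in sets.items()},
            descriptions={k: "" for k in sets},
        )

    def _sig(self, pairs):
        return pd.DataFrame(
            {
                "site_id": [f"S{i}" for i in range(len(pairs))],
                "gene_id": [g for g, in pairs],
            }
        )

    def test_zero_sites(self):
        dens, _ = pathway_meth_density(
            self._sig([]), self._db(P={"G1", "G2"}), {"G1", "G2"}
        )
        assert dens["P"] == 0.0

    def test_arithmetic(self):
        sig = pd.DataFrame(
            {
                "site_id": [f"S{i}" for i in range(9)],
                "gene_id": ["G1"] * 5 + ["G2"] * 4,
            }
        )
        dens, _ = pathway_meth_density(
            sig, self._db(P={"G1", "G2"}), {"G1", "G2"}
        )
        assert dens["P"] == pytest.approx(4.5)

    def test_undetected_gene_changes_nothing(self):
        sig = pd.DataFrame({"site_id": ["S0"], "gene_id": ["G1"]})
        base, _ = pathway_meth_density(
            sig, self._db(P={"G1", "G2"}), {"G1", "G2"}
        )
        padded, _ = pathway_meth_density(
            sig, self._db(P={"G1", "G2", "UNDETECTED"}), {"G1", "G2"}
        )
        assert padded["P"] == base["P"]

    def test_disjoint_pathway_skipped(self):
        dens, skipped = pathway_meth_density(
            self._sig([]), self._db(P={"GX"}), {"G1"}
        )
        assert skipped == ["P"] and dens == {}


class TestDensityExpressionCorrelation:
    def test_identical_vectors_correlate_perfectly(self):
        d = {"P1": 0.5, "P2": 1.0, "P3": 2.0, "P4": 3.5}
        out = density_expression_correlation(d, dict(d))
        assert out["pearson_r"] == pytest.approx(1.0)
        assert out["spearman_rho"] == pytest.approx(1.0)

    def test_constant_vector_reported_na(self):
        d = {"P1": 1.0, "P2": 1.0, "P3": 1.0}
        s = {"P1": 0.1, "P2": 0.4, "P3": 0.9}
        out = density_expression_correlation(d, s)
        assert np.isnan(out["pearson_r"])

    def test_reversed_ranks_flip_spearman(self):
        d = {"P1": 1.0, "P2": 2.0, "P3": 3.0}
        s = {"P1": 9.0, "P2": 5.0, "P3": 1.0}
        out = density_expression_correlation(d, s)
        assert out["spearman_rho"] == pytest.approx(-1.0)

    def test_too_few_pathways_rejected(self):
        with pytest.raises(FormatError, match=">=3"):
            density_expression_correlation({"P1": 1.0}, {"P1": 2.0})


class TestOverlap:
    def test_disjoint(self):
        assert deg_meth_overlap({"A"}, {"B"})["n_overlap"] == 0

    def test_intersection(self):
        rep = deg_meth_overlap({"A", "B", "C"}, {"B", "C", "D"})
        assert rep["overlap"] == {"B", "C"}
        assert rep["only_meth"] == {"A"}
        assert rep["only_deg"] == {"D"}

    def test_bound(self):
        rep = deg_meth_overlap({"A", "B"}, {"A", "B", "C", "D"})
        assert rep["n_overlap"] <= min(rep["n_meth"], rep["n_deg"])
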