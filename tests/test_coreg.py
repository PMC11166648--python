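"""Normalization, z-scoring, trajectories, co-regulation, concordance, DE."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spaceomics._stats import bh_adjust
from spaceomics.coreg import (
    average_quantifiers,
    concordance,
    coregulation_test,
    genes_detected,
    normalize_library_size,
    pathway_trajectory,
    simple_de,
    zscore,
)
from spaceomics.io import CountMatrix, FormatError, GeneSetDB
from spaceomics.simulate import (
    SimTruth,
    random_geneset_db,
    simulate_counts,
    simulate_dual_quantifier,
)


def _cm(arr, genes=None, samples=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"G{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return CountMatrix(pd.DataFrame(arr, index=genes, columns=samples))


class TestNormalize:
    def test_proportional_scaling(self):
        m = normalize_library_size(_cm([[10], [30], [60]]), scale=1e6)
        np.testing.assert_allclose(m.values[:, 0], [1e5, 3e5, 6e5])

    def test_already_at_scale_unchanged(self):
        m = normalize_library_size(_cm([[1], [1], [2]]), scale=4)
        np.testing.assert_allclose(m.values[:, 0], [1, 1, 2])

    def test_zero_column_names_sample(self):
        with pytest.raises(FormatError, match="s1"):
            normalize_library_size(_cm([[1, 0], [2, 0]]))


class TestAverageQuantifiers:
    def test_identical_inputs(self, tiny_counts):
        avg, dropped = average_quantifiers(tiny_counts, tiny_counts)
        assert dropped == []
        assert np.array_equal(avg.values, tiny_counts.values)

    def test_mean_of_two_values(self):
        a, b = _cm([[2.0]]), _cm([[4.0]])
        avg, _ = average_quantifiers(a, b)
        assert avg.values[0, 0] == 3.0

    def test_unshared_gene_excluded_and_listed(self):
        a = _cm([[1.0], [2.0]], genes=["G1", "G2"])
        b = _cm([[1.0]], genes=["G1"])
        avg, dropped = average_quantifiers(a, b)
        assert avg.gene_ids == ["G1"]
        assert dropped == ["G2"]

    def test_sample_mismatch_rejected(self):
        a = _cm([[1.0]], samples=["s1"])
        b = _cm([[1.0]], samples=["sX"])
        with pytest.raises(FormatError, match="sample ids differ"):
            average_quantifiers(a, b)


class TestZscore:
    def test_constant_gene_set_aside(self):
        z = zscore(_cm([[5, 5, 5], [1, 2, 3]]))
        assert z.constant_genes == {"G0"}
        assert z.gene_ids == ["G1"]

    def test_two_point_symmetry_sample_sd(self):
        # sample SD (n-1) convention: a two-sample gene maps to -/+ 1/sqrt(2)
        z = zscore(_cm([[2, 8]]), log_transform=False)
        np.testing.assert_allclose(
            z.z.loc["G0"].to_numpy(), [-np.sqrt(0.5), np.sqrt(0.5)]
        )

    def test_row_moments_are_exact(self, rng):
        m = _cm(rng.gamma(2, 30, size=(40, 9)))
        z = zscore(normalize_library_size(m))
        assert np.allclose(z.z.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(z.z.std(axis=1, ddof=1), 1, atol=1e-9)

    def test_single_sample_rejected(self):
        with pytest.raises(FormatError, match="single-sample"):
            zscore(_cm([[1.0], [2.0]]))


class TestTrajectory:
    def test_singleton_pathway_equals_gene_series(self, design, metas):
        counts, _ = simulate_counts(
            40, random_geneset_db(2, 4), design, seed=1
        )
        z = zscore(normalize_library_size(counts))
        gene = z.gene_ids[0]
        traj = pathway_trajectory(z, {gene}, metas, pathway="solo")
        for day, med in zip(traj.time_days, traj.median_z):
            cols = [m.sample_id for m in metas if m.time_days == day]
            assert med == pytest.approx(float(np.median(z.z.loc[gene, cols])))

    def test_odd_count_median(self, metas):
        # 3 member genes, 1 subject: median of (0.1, 0.5, 0.9) is 0.5
        one = [m for m in metas if m.subject_id == "C001"]
        days = sorted(m.time_days for m in one)
        zvals = pd.DataFrame(
            {m.sample_id: [0.1, 0.5, 0.9] for m in one},
            index=["G1", "G2", "G3"],
        )
        from spaceomics.coreg import ZMatrix

        traj = pathway_trajectory(
            ZMatrix(z=zvals), {"G1", "G2", "G3"}, one, pathway="p"
        )
        assert traj.median_z == [0.5] * len(days)
        assert traj.n_values == [3] * len(days)
        assert traj.time_days == days  # ordered by signed day

    def test_empty_intersection_rejected(self, design, metas):
        counts, _ = simulate_counts(
            40, random_geneset_db(2, 4), design, seed=1
        )
        z = zscore(normalize_library_size(counts))
        with pytest.raises(FormatError, match="not detected"):
            pathway_trajectory(z, {"ABSENT"}, metas, pathway="gone")


@pytest.fixture(scope="module")
def z28(design):
    counts, _ = simulate_counts(200, random_geneset_db(5, 10), design, seed=42)
    return zscore(normalize_library_size(counts))


class TestCoregulationTest:

    def test_all_gene_set_scores_near_zero(self, z28):
        # rows are centered, so the all-gene member mean is ~0 per sample
        db = GeneSetDB(
            sets={"ALL": frozenset(z28.gene_ids)}, descriptions={"ALL": ""}
        )
        results, _ = coregulation_test(
            z28, db, n_perm=100, min_size=1, max_size=10_000, seed=0
        )
        n = len(z28.sample_ids)
        assert results[0].score < 0.01 * n

    def test_singleton_score_is_sd_constant(self, z28):
        # sum of squared z over samples = n-1 under the sample-SD convention
        g = z28.gene_ids[0]
        db = GeneSetDB(sets={"ONE": frozenset({g})}, descriptions={"ONE": ""})
        results, _ = coregulation_test(
            z28, db, n_perm=100, min_size=1, max_size=10, seed=0
        )
        assert results[0].score == pytest.approx(len(z28.sample_ids) - 1)

    def test_p_respects_permutation_floor(self, z28):
        db = random_geneset_db(5, 10)
        results, _ = coregulation_test(z28, db, n_perm=100, min_size=2, seed=0)
        assert all(r.p >= 1 / 101 for r in results)
        assert all(r.padj >= r.p for r in results)

    def test_size_window_skips_and_reports(self, z28):
        db = GeneSetDB(
            sets={
                "BIG": frozenset(z28.gene_ids),
                "OK": frozenset(z28.gene_ids[:10]),
            },
            descriptions={"BIG": "", "OK": ""},
        )
        results, skipped = coregulation_test(
            z28, db, n_perm=100, min_size=5, max_size=50, seed=0
        )
        assert skipped == ["BIG"]
        assert [r.pathway for r in results] == ["OK"]

    def test_n_perm_floor_enforced(self, z28):
        with pytest.raises(ValueError, match="n_perm"):
            coregulation_test(z28, random_geneset_db(2, 5), n_perm=10)


class TestConcordance:
    def _dge(self, sig, universe):
        return pd.DataFrame(
            {
                "gene": universe,
                "log2fc": np.linspace(-1, 1, len(universe)),
                "p": [0.001 if g in sig else 0.5 for g in universe],
                "padj": [0.01 if g in sig else 0.9 for g in universe],
            }
        )

    def test_self_comparison_is_perfect(self, tiny_counts):
        d = self._dge({"G1"}, ["G1", "G2", "G3"])
        res = concordance(tiny_counts, tiny_counts, d, d)
        assert res.median_r == 1.0
        assert (res.categories != "only_A").all()
        assert (res.categories != "only_B").all()

    def test_consensus_is_set_intersection(self, tiny_counts):
        universe = ["G1", "G2", "G3"]
        res = concordance(
            tiny_counts, tiny_counts,
            self._dge({"G1", "G2"}, universe),
            self._dge({"G2", "G3"}, universe),
        )
        assert res.consensus_degs == {"G2"}
        assert set(res.categories[res.categories == "only_A"].index) == {"G1"}
        assert set(res.categories[res.categories == "only_B"].index) == {"G3"}

    def test_categories_partition_universe(self, tiny_counts):
        universe = ["G1", "G2", "G3"]
        res = concordance(
            tiny_counts, tiny_counts,
            self._dge({"G1"}, universe), self._dge({"G3"}, universe),
        )
        assert sorted(res.categories.index) == universe
        assert set(res.categories.unique()) <= {
            "both", "only_A", "only_B", "neither"
        }

    def test_homolog_redistribution_lowers_r(self, design):
        counts, _ = simulate_counts(
            300, random_geneset_db(3, 10), design, seed=13
        )
        groups = [set(counts.gene_ids[i: i + 5]) for i in (0, 5, 10, 15)]
        d = self._dge(set(), counts.gene_ids)
        a1, b1 = simulate_dual_quantifier(counts, [], seed=1)
        a2, b2 = simulate_dual_quantifier(counts, groups, seed=1)
        r_without = concordance(a1, b1, d, d).median_r
        r_with = concordance(a2, b2, d, d).median_r
        assert r_with < r_without


class TestGenesDetected:
    def test_strict_threshold(self):
        m = _cm([[10.0], [11.0], [0.0]])
        assert genes_detected(m, min_alignments=10).iloc[0] == 1

    def test_all_zero(self):
        assert genes_detected(_cm([[0.0], [0.0]])).iloc[0] == 0

    def test_zero_threshold_counts_any_positive(self):
        m = _cm([[0.5], [0.0]])
        assert genes_detected(m, min_alignments=0).iloc[0] == 1


class TestSimpleDe:
    def test_identical_groups_zero_log2fc(self, design):
        counts, _ = simulate_counts(
            50, random_geneset_db(2, 5), design, seed=21
        )
        dup = CountMatrix(
            pd.DataFrame(
                np.tile(counts.values[:, :2], 2),
                index=counts.gene_ids,
                columns=["a1", "a2", "b1", "b2"],
            )
        )
        table = simple_de(dup, ["a1", "a2"], ["b1", "b2"])
        assert np.allclose(table["log2fc"], 0)
        assert (table["padj"] >= table["p"] - 1e-12).all()

    def test_planted_effects_recovered_in_consensus(self, design):
        # moderate-noise study: 40 genes shifted 2 log2-units at return,
        # return draws vs one pre-flight draw, 4 vs 4 samples
        db = random_geneset_db(2, 5)
        de_genes = {f"BG{i:05d}": 2.0 for i in range(40)}
        counts, truth = simulate_counts(
            500, db, design, effects=SimTruth(de_genes=de_genes),
            dispersion=30.0, seed=99,
        )
        test = [s for s in counts.sample_ids if s.endswith("_R+1")]
        ref = [s for s in counts.sample_ids if s.endswith("_L-3")]
        a, b = simulate_dual_quantifier(counts, [], seed=1, noise_sd=0.01)
        dge_a = simple_de(a, test, ref, source="A")
        dge_b = simple_de(b, test, ref, source="B")
        res = concordance(a, b, dge_a, dge_b, alpha=0.05)
        sens = len(res.consensus_degs & set(de_genes)) / len(de_genes)
        assert sens >= 0.8

    def test_small_group_rejected(self, tiny_counts):
        with pytest.raises(FormatError, match=">=2"):
            simple_de(tiny_counts, ["s1"], ["s2", "s2b"])


class TestBenjaminiHochberg:
    @staticmethod
    def _oracle(p):
        # literal step-up: q_(i) = min_{j >= i} p_(j) * n / j, capped at 1
        p = np.asarray(p, float)
        n = len(p)
        order = np.argsort(p)
        q = np.empty(n)
        running = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * n / rank)
            q[i] = running
        return q

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1, max_size=20,
        )
    )
    def test_matches_step_up_oracle(self, pvals):
        np.testing.assert_allclose(
            bh_adjust(np.array(pvals)), self._oracle(pvals), atol=1e-12
        )
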