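"""F-measure agreement, repeated-clustering stability, subsample consensus."""

import numpy as np
import pytest

import cytorisk as ck
from cytorisk.clustering import cluster_fixed_k
from cytorisk.embedding import embed
from cytorisk.io import CellTable, ValidationError
from cytorisk.stability import (
    cluster_stability,
    f_measure,
    patient_category_f,
    subsample_consensus,
)


def brute_force_f(ref, test):
    """Exhaustive best-match confusion-matrix oracle."""
    ref, test = np.asarray(ref), np.asarray(test)
    out = {}
    for r in np.unique(ref):
        best = 0.0
        in_r = ref == r
        for t in np.unique(test):
            in_t = test == t
            tp = np.sum(in_r & in_t)
            p = tp / in_t.sum()
            rc = tp / in_r.sum()
            f = 2 * p * rc / (p + rc) if (p + rc) > 0 else 0.0
            best = max(best, f)
        out[r] = best
    return out


class TestFMeasure:
    def test_identical_partitions(self, rng):
        labels = rng.integers(0, 4, size=50)
        fm = f_measure(labels, labels)
        assert np.all(fm["F"] == 1.0)
        assert np.all(fm["precision"] == 1.0)

    def test_even_split_formula(self):
        ref = np.zeros(8, dtype=int)
        test = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        fm = f_measure(ref, test)
        assert fm.loc[0, "precision"] == 1.0
        assert fm.loc[0, "recall"] == 0.5
        assert fm.loc[0, "F"] == pytest.approx(2 / 3)

    def test_matches_brute_force_on_random_partitions(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 12))
            ref = rng.integers(0, 3, size=n)
            test = rng.integers(0, 4, size=n)
            fm = f_measure(ref, test)
            oracle = brute_force_f(ref, test)
            for r, f in oracle.items():
                assert fm.loc[r, "F"] == pytest.approx(f, abs=1e-12)

    def test_label_renaming_invariance(self, rng):
        ref = rng.integers(0, 3, size=40)
        test = rng.integers(0, 3, size=40)
        f1 = f_measure(ref, test)["F"].to_numpy()
        f2 = f_measure(ref + 10, (test * 7 + 3))["F"].to_numpy()
        np.testing.assert_allclose(np.sort(f1), np.sort(f2))

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            f_measure([1, 2], [1, 2, 3])


class TestClusterStability:
    def _blob_embedding(self, rng, centers=(0.0, 4.0, 8.0), n=200):
        vals = np.vstack([rng.normal(c, 0.3, size=(n, 3)) for c in centers])
        t = CellTable(vals, ["a", "b", "c"], np.repeat("P", len(vals)))
        return embed(t, method="none")

    def test_well_separated_blobs_are_stable(self, rng):
        e = self._blob_embedding(rng)
        ref = cluster_fixed_k(e, 3, seed=1)
        rep = cluster_stability(e, 3, ref, n_runs=8, seed=5)
        assert np.all(rep.mean_f > 0.9)
        assert np.all(rep.stable)
        # the reference run contributes F = 1
        assert np.all(rep.per_run[0] == 1.0)

    def test_overclustering_is_unstable(self, rng):
        # one homogeneous cloud forced into 12 clusters: arbitrary splits
        # do not reproduce across seeds and agreement drops sharply
        vals = rng.normal(size=(2000, 3))
        t = CellTable(vals, ["a", "b", "c"], np.repeat("P", 2000))
        e = embed(t, method="none")
        ref = cluster_fixed_k(e, 12, seed=1)
        rep = cluster_stability(e, 12, ref, n_runs=6, seed=2)
        assert (~rep.stable).sum() >= 1
        assert rep.mean_f.mean() < 0.8  # far from the perfect-agreement regime

    def test_equal_seeds_give_mean_f_one(self, rng):
        e = self._blob_embedding(rng, n=100)
        ref = cluster_fixed_k(e, 3, seed=9)
        rep = cluster_stability(
            e, 3, ref, n_runs=4, replicate_seeds=[9, 9, 9]
        )
        assert np.all(rep.mean_f == 1.0)

    def test_n_runs_validation(self, rng):
        e = self._blob_embedding(rng, n=30)
        ref = cluster_fixed_k(e, 3, seed=0)
        with pytest.raises(ValidationError):
            cluster_stability(e, 3, ref, n_runs=1)


class TestPatientCategoryF:
    def test_identical(self):
        cats = ["NP-high", "PP-high", "neither"] * 4
        assert patient_category_f(cats, cats) == 1.0

    def test_one_patient_moved_matches_hand_computation(self):
        ref = ["NP-high"] * 8 + ["PP-high"] * 7 + ["neither"] * 13
        test = list(ref)
        test[0] = "neither"  # one NP-high patient recategorised
        # NP: P=1, R=7/8 -> F=14/15; PP: F=1; neither: P=13/14, R=1 -> F=26/27
        expect = np.mean([14 / 15, 1.0, 26 / 27])
        assert patient_category_f(ref, test) == pytest.approx(expect, abs=1e-12)

    def test_degenerate_all_neither(self):
        ref = ["NP-high"] * 5 + ["neither"] * 5
        test = ["neither"] * 10
        # NP fully missed -> 0; neither: P=0.5, R=1 -> 2/3
        assert patient_category_f(ref, test) == pytest.approx(np.mean([0, 2 / 3]))

    def test_unknown_category(self):
        with pytest.raises(ValidationError, match="unknown"):
            patient_category_f(["NP-high"], ["high-risk"])


class TestSubsampleConsensus:
    def test_planted_phenotype_reaches_majority_support(self, small_planted):
        tables, manifest, _ = small_planted
        cfg = ck.RunConfig(
            embedding_method="none", k_range=(4, 10), seed=21, subsample_depth=150
        )
        cons = subsample_consensus(tables, manifest, cfg, n_subsamples=4)
        assert len(cons.run_reports) >= 2
        assert cons.consensus is not None
        # at least one phenotype recurs in >= half of the runs
        assert (cons.consensus.support >= 0.5).any()
        # patient categorisation agrees between runs more than chance
        off_diag = cons.patient_category_f.to_numpy()[
            ~np.eye(len(cons.patient_category_f), dtype=bool)
        ]
        assert off_diag.mean() > 0.5

    def test_requires_two_runs(self, small_planted):
        tables, manifest, _ = small_planted
        cfg = ck.RunConfig(embedding_method="none", seed=0)
        with pytest.raises(ValidationError):
            subsample_consensus(tables, manifest, cfg, n_subsamples=1)
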