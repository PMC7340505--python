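"""Marker enrichment labels, RMSD similarity, consensus grouping."""

import numpy as np
import pandas as pd
import pytest

from cytorisk.io import CellTable, ValidationError
from cytorisk.mem import (
    MEMLabel,
    consensus_phenotypes,
    mem_rmsd_similarity,
    mem_scores,
)


def _table(values, markers=None):
    values = np.asarray(values, dtype=float)
    markers = markers or [f"m{i}" for i in range(values.shape[1])]
    return CellTable(values, markers, np.repeat("P", values.shape[0]))


def _label(name, scores, markers=None):
    markers = markers or [f"m{i}" for i in range(len(scores))]
    return MEMLabel(cluster_id=name, scores=pd.Series(scores, index=markers))


class TestMemScores:
    def test_identical_distribution_scores_zero(self, rng):
        # cluster 2 is an exact copy of cluster 1's cells: identical
        # empirical medians and IQRs, plus a third cluster that differs
        base = rng.normal(1.0, 0.5, size=(100, 3))
        distinct = rng.normal(4.0, 0.5, size=(200, 3))
        t = _table(np.vstack([base, base, distinct]))
        labels = np.array([1] * 100 + [2] * 100 + [3] * 200)
        out = mem_scores(t, labels)
        np.testing.assert_allclose(out[1].scores, out[2].scores, atol=1e-9)

    def test_run_maximum_maps_to_ten(self, rng):
        a = rng.normal(0.0, 0.5, size=(150, 4))
        b = rng.normal(0.0, 0.5, size=(150, 4))
        b[:, 2] += 6.0  # dominant enrichment
        t = _table(np.vstack([a, b]))
        out = mem_scores(t, np.repeat([1, 2], 150))
        all_scores = np.concatenate([l.scores.to_numpy() for l in out.values()])
        assert np.max(np.abs(all_scores)) == pytest.approx(10.0, abs=1e-9)
        assert out[2].scores["m2"] == pytest.approx(10.0, abs=1e-9)
        assert out[1].scores["m2"] < -8  # reciprocal contrast, near-maximal

    def test_two_cluster_toy_matches_formula(self):
        # cluster: median 3, IQR 1; reference: median 1, IQR 1
        # raw = |3-1| + 1/1 - 1 = 2, positive sign
        c = np.array([2.5, 3.0, 3.5, 3.0])
        r = np.array([0.5, 1.0, 1.5, 1.0])
        t = _table(np.concatenate([c, r])[:, None], ["f"])
        labels = np.array([1] * 4 + [2] * 4)
        out = mem_scores(t, labels)
        # raw values: cluster1 = +2, cluster2 = -2 (symmetric); both map to ±10
        assert out[1].scores["f"] == pytest.approx(10.0)
        assert out[2].scores["f"] == pytest.approx(-10.0)
        assert out[1].medians["f"] == pytest.approx(3.0)
        assert out[1].iqrs["f"] == pytest.approx(0.25)

    def test_sign_follows_median_difference(self, rng):
        a = rng.normal(0.0, 1.0, size=(200, 2))
        b = rng.normal([3.0, -3.0], 1.0, size=(200, 2))
        out = mem_scores(_table(np.vstack([a, b])), np.repeat([1, 2], 200))
        assert out[2].scores["m0"] > 0
        assert out[2].scores["m1"] < 0

    def test_cell_permutation_invariance(self, rng):
        vals = rng.normal(size=(300, 3))
        labels = rng.integers(1, 4, size=300)
        out1 = mem_scores(_table(vals), labels)
        perm = rng.permutation(300)
        out2 = mem_scores(_table(vals[perm]), labels[perm])
        for c in out1:
            np.testing.assert_allclose(out1[c].scores, out2[c].scores, atol=1e-12)

    def test_zero_iqr_floored_with_warning(self):
        t = _table(np.array([[1.0], [1.0], [1.0], [5.0], [6.0], [7.0]]), ["f"])
        with pytest.warns(UserWarning, match="IQR"):
            out = mem_scores(t, np.repeat([1, 2], 3))
        assert np.isfinite(out[1].scores["f"])


class TestRmsdSimilarity:
    def test_identical_labels_score_100(self):
        a = _label("a", [3.0, -2.0, 7.0])
        assert mem_rmsd_similarity(a, a) == 100.0

    def test_maximally_opposed_score_0(self):
        a = _label("a", [10.0] * 5)
        b = _label("b", [-10.0] * 5)
        assert mem_rmsd_similarity(a, b) == 0.0

    def test_matches_formula_and_symmetry(self, rng):
        sa = rng.uniform(-10, 10, size=8)
        sb = rng.uniform(-10, 10, size=8)
        a, b = _label("a", sa), _label("b", sb)
        rmsd = np.sqrt(np.mean((sa - sb) ** 2))
        expect = np.clip(100 * (1 - rmsd / 20), 0, 100)
        assert mem_rmsd_similarity(a, b) == pytest.approx(expect, abs=1e-12)
        assert mem_rmsd_similarity(a, b) == mem_rmsd_similarity(b, a)

    def test_marker_mismatch(self):
        a = _label("a", [1.0, 2.0], ["x", "y"])
        b = _label("b", [1.0, 2.0], ["x", "z"])
        with pytest.raises(ValidationError, match="marker"):
            mem_rmsd_similarity(a, b)


class TestConsensus:
    def test_identical_labels_form_one_full_support_group(self):
        labels = {f"run{i}/c1": _label(i, [5.0, -3.0, 1.0]) for i in range(10)}
        run_of = {k: i for i, k in enumerate(labels)}
        cons = consensus_phenotypes(labels, run_of)
        assert cons.groups.nunique() == 1
        assert cons.support.iloc[0] == 1.0
        assert cons.unstable_groups == []
        assert np.all(np.diag(cons.similarity) == 100.0)

    def test_outlier_phenotype_flagged_unstable(self):
        labels = {f"run{i}/c1": _label(i, [5.0, -3.0, 1.0]) for i in range(9)}
        labels["run9/odd"] = _label("odd", [-8.0, 9.0, -9.0])
        run_of = {k: k.split("/")[0] for k in labels}
        cons = consensus_phenotypes(labels, run_of)
        odd_group = int(cons.groups["run9/odd"])
        assert cons.support.loc[odd_group] == pytest.approx(0.1)
        assert odd_group in cons.unstable_groups

    def test_two_planted_phenotypes_recovered(self, rng):
        labels = {}
        run_of = {}
        for i in range(6):
            labels[f"run{i}/np"] = _label(
                "np", np.array([8.0, -6.0, 2.0]) + rng.normal(0, 0.3, 3)
            )
            labels[f"run{i}/pp"] = _label(
                "pp", np.array([-7.0, 8.0, -1.0]) + rng.normal(0, 0.3, 3)
            )
            run_of[f"run{i}/np"] = i
            run_of[f"run{i}/pp"] = i
        cons = consensus_phenotypes(labels, run_of)
        assert cons.groups.nunique() == 2
        np_groups = {int(cons.groups[f"run{i}/np"]) for i in range(6)}
        pp_groups = {int(cons.groups[f"run{i}/pp"]) for i in range(6)}
        assert len(np_groups) == 1 and len(pp_groups) == 1 and np_groups != pp_groups
        assert all(cons.support == 1.0)
        # group profile medians reflect the planted signatures
        g_np = np_groups.pop()
        assert cons.group_profiles[g_np].loc["m0", "median"] > 5

    def test_single_run_warns(self):
        labels = {"run0/c1": _label("a", [1.0, 2.0])}
        with pytest.warns(UserWarning, match="single run"):
            cons = consensus_phenotypes(labels, {"run0/c1": 0})
        assert cons.groups.nunique() == 1
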