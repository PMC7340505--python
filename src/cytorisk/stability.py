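"""Statistical validation of clustering results.

Two kinds of robustness are measured.  Cluster stability repeats the
(stochastic) SOM clustering on the same embedding with fresh seeds and
scores each original cluster by its F-measure against the best-matching
cluster of every replicate; clusters with mean F <= 0.5 over the runs are
unstable.  Subsampling consensus re-runs the entire pipeline on fresh
with-replacement samples of cells and asks whether prognostic phenotypes
(as MEM labels) recur in at least half the runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clustering import ClusterResult, cluster_fixed_k
from .embedding import Embedding
from .io import CellTable, CohortManifest, ValidationError
from .mem import MEMLabel, PhenotypeConsensus, consensus_phenotypes

__all__ = [
    "f_measure",
    "FMeasureReport",
    "cluster_stability",
    "patient_category_f",
    "subsample_consensus",
    "SubsampleConsensus",
]

PATIENT_CATEGORIES = ("NP-high", "PP-high", "neither")


def f_measure(
    reference_labels: Sequence, test_labels: Sequence
) -> pd.DataFrame:
    """Best-match precision/recall/F per reference cluster.

    Each reference cluster is matched to the test cluster maximising
    F = 2PR/(P+R), where TP are cells in both clusters, FP cells in the
    matched test cluster only, FN cells in the reference cluster only.
    F is 0 when P + R = 0.  Invariant to relabeling on either side.
    """
    ref = np.asarray(reference_labels)
    test = np.asarray(test_labels)
    if ref.shape != test.shape:
        raise ValidationError("reference and test labels must align")
    ref_ids, ref_inv = np.unique(ref, return_inverse=True)
    test_ids, test_inv = np.unique(test, return_inverse=True)
    # confusion matrix via flat bincount
    conf = np.bincount(
        ref_inv * len(test_ids) + test_inv, minlength=len(ref_ids) * len(test_ids)
    ).reshape(len(ref_ids), len(test_ids)).astype(float)
    ref_sizes = conf.sum(axis=1)
    test_sizes = conf.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = conf / test_sizes[None, :]
        recall = conf / ref_sizes[:, None]
        f = 2 * precision * recall / (precision + recall)
    f = np.nan_to_num(f)
    best = np.argmax(f, axis=1)
    rows = []
    for i, r in enumerate(ref_ids):
        j = best[i]
        rows.append(
            {
                "cluster": r,
                "precision": precision[i, j],
                "recall": recall[i, j],
                "F": f[i, j],
                "matched": test_ids[j],
            }
        )
    return pd.DataFrame(rows).set_index("cluster")


@dataclass
class FMeasureReport:
    """Per-cluster F-measures across replicate clusterings."""

    per_run: pd.DataFrame  # rows: reference clusters, columns: run index
    stability_threshold: float = 0.5

    @property
    def mean_f(self) -> pd.Series:
        return self.per_run.mean(axis=1).rename("mean_F")

    @property
    def stable(self) -> pd.Series:
        return (self.mean_f > self.stability_threshold).rename("stable")


def cluster_stability(
    embedding: Embedding,
    k: int,
    reference: ClusterResult,
    n_runs: int = 100,
    seed: int = 0,
    som_shape: tuple[int, int] = (10, 10),
    stability_threshold: float = 0.5,
    replicate_seeds: Sequence[int] | None = None,
) -> FMeasureReport:
    """Repeat the clustering ``n_runs - 1`` times with fresh seeds.

    The reference clustering counts as run 1 (contributing F = 1 for every
    cluster); each replicate contributes the best-match F per reference
    cluster.  A cluster is stable when its mean F over all runs exceeds
    ``stability_threshold``.  ``replicate_seeds`` fixes the replicate seeds
    explicitly (e.g. all equal to the reference seed, which must reproduce
    the reference labels exactly).
    """
    if n_runs < 2:
        raise ValidationError("n_runs must be >= 2")
    if reference.labels.shape[0] != embedding.n_cells:
        raise ValidationError("reference labels must align with the embedding")
    if replicate_seeds is not None and len(replicate_seeds) != n_runs - 1:
        raise ValidationError("need n_runs - 1 replicate seeds")
    rng = np.random.default_rng(seed)
    ref_ids = np.unique(reference.labels)
    cols = {0: pd.Series(1.0, index=ref_ids)}  # reference vs itself
    for run in range(1, n_runs):
        rep_seed = (
            int(replicate_seeds[run - 1])
            if replicate_seeds is not None
            else int(rng.integers(0, 2**31 - 1))
        )
        rep = cluster_fixed_k(embedding, k, seed=rep_seed, som_shape=som_shape)
        fm = f_measure(reference.labels, rep.labels)
        cols[run] = fm["F"].reindex(ref_ids).fillna(0.0)
    per_run = pd.DataFrame(cols)
    per_run.index.name = "cluster"
    return FMeasureReport(per_run=per_run, stability_threshold=stability_threshold)


def patient_category_f(
    reference_categories: Sequence[str], test_categories: Sequence[str]
) -> float:
    """Mean F over the three patient categories, reference as truth.

    Categories: 'NP-high', 'PP-high', 'neither'.  A category absent from
    both classifications is skipped; one that is present in the reference
    but fully missed scores 0.
    """
    ref = np.asarray(reference_categories)
    test = np.asarray(test_categories)
    if ref.shape != test.shape:
        raise ValidationError("category vectors must align")
    unknown = (set(ref) | set(test)) - set(PATIENT_CATEGORIES)
    if unknown:
        raise ValidationError(f"unknown categories: {sorted(unknown)}")
    fs = []
    for cat in PATIENT_CATEGORIES:
        in_ref = ref == cat
        in_test = test == cat
        if not in_ref.any() and not in_test.any():
            continue
        tp = float((in_ref & in_test).sum())
        p = tp / in_test.sum() if in_test.any() else 0.0
        r = tp / in_ref.sum() if in_ref.any() else 0.0
        fs.append(2 * p * r / (p + r) if (p + r) > 0 else 0.0)
    return float(np.mean(fs)) if fs else 0.0


@dataclass
class SubsampleConsensus:
    """Pooled results of repeated full-pipeline subsampling runs."""

    consensus: PhenotypeConsensus | None
    run_reports: dict[int, "object"]  # run index -> RiskStratificationResults
    labels: dict[str, MEMLabel]
    run_of: dict[str, int]
    patient_category_f: pd.DataFrame | None  # pairwise mean-F between runs
    failed_runs: list[int] = field(default_factory=list)


def subsample_consensus(
    cohort_tables: Mapping[str, CellTable],
    cohort: CohortManifest,
    config,
    n_subsamples: int = 10,
    linkage_threshold: float = 15.0,
    min_support: float = 0.5,
) -> SubsampleConsensus:
    """Run the full pipeline on repeated with-replacement cell subsamples.

    Each run draws a fresh equal-depth sample per patient (with
    replacement), embeds, auto-selects k, clusters, tests prognosis and
    computes MEM labels for its stable prognostic clusters; phenotypes
    recurring in >= ``min_support`` of the runs are the consensus.  Failed
    runs are logged and excluded; consensus proceeds when >= 2 runs remain.
    """
    from .model import RiskStratification  # local import to avoid a cycle

    if n_subsamples < 2:
        raise ValidationError("n_subsamples must be >= 2")
    rng = np.random.default_rng(config.seed)
    run_reports: dict[int, object] = {}
    labels: dict[str, MEMLabel] = {}
    run_of: dict[str, int] = {}
    categories: dict[int, pd.Series] = {}
    failed: list[int] = []
    for run in range(n_subsamples):
        run_seed = int(rng.integers(0, 2**31 - 1))
        try:
            model = RiskStratification(
                cohort_tables, cohort, config=config, seed=run_seed,
                with_replacement=run > 0,
            )
            res = model.fit()
        except Exception as exc:  # noqa: BLE001 - a failed run is excluded
            warnings.warn(f"subsample run {run} failed: {exc}")
            failed.append(run)
            continue
        run_reports[run] = res
        categories[run] = res.patient_categories()
        stable = set(res.stability.per_run.index[res.stability.stable]) if res.stability is not None else None
        for c in res.prognostic_report.prognostic_clusters():
            if stable is not None and c not in stable:
                continue
            name = f"run{run}/cluster{c}"
            labels[name] = res.mem_labels[c]
            run_of[name] = run

    consensus = None
    if len(run_reports) >= 2 and len(labels) >= 1:
        consensus = consensus_phenotypes(
            labels, run_of, linkage_threshold=linkage_threshold, min_support=min_support
        )
        # support is measured against the runs that completed
        n_done = len(run_reports)
        sup = {}
        for g, members in consensus.groups.groupby(consensus.groups).groups.items():
            member_runs = {run_of[m] for m in members}
            sup[int(g)] = len(member_runs) / n_done
        consensus.support = pd.Series(sup, name="support").sort_index()

    pcf = None
    if len(categories) >= 2:
        runs = sorted(categories)
        pids = categories[runs[0]].index
        mat = np.full((len(runs), len(runs)), np.nan)
        for i, a in enumerate(runs):
            for j, b in enumerate(runs):
                mat[i, j] = patient_category_f(
                    categories[a].reindex(pids).to_numpy(),
                    categories[b].reindex(pids).to_numpy(),
                )
        pcf = pd.DataFrame(mat, index=runs, columns=runs)

    return SubsampleConsensus(
        consensus=consensus,
        run_reports=run_reports,
        labels=labels,
        run_of=run_of,
        patient_category_f=pcf,
        failed_runs=failed,
    )
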