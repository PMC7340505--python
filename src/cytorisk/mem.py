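"""Marker enrichment labels and phenotype consensus.

Marker enrichment modeling (MEM) summarises what makes a cell population
distinct from the remaining cells: for cluster c and marker f the raw
enrichment is

    raw = |Med_c - Med_ref| + IQR_ref / IQR_c - 1,   clamped below at 0,

signed by (Med_c - Med_ref), where the reference population is every cell
NOT in c.  Raw values are then scaled so the largest magnitude across all
clusters and markers in the run maps to 10, giving signed scores on the
-10..+10 scale (+10 = specifically enriched, -10 = specifically excluded).

Phenotype similarity between two labels is derived from the RMSD of their
score vectors, mapped to a 0-100 scale; hierarchical grouping of labels
pooled over repeated runs yields consensus phenotypes with a support
fraction (phenotypes seen in fewer than half the runs are flagged
unstable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .clustering import ClusterResult
from .io import CellTable, ValidationError

__all__ = [
    "MEMLabel",
    "PhenotypeConsensus",
    "mem_scores",
    "mem_rmsd_similarity",
    "consensus_phenotypes",
]

IQR_EPS = 1e-8
MAX_SCORE = 10.0


@dataclass
class MEMLabel:
    """Signed per-marker enrichment scores for one cluster."""

    cluster_id: int | str
    scores: pd.Series  # marker -> score on [-10, 10]
    medians: pd.Series | None = None
    iqrs: pd.Series | None = None
    marker_classes: Mapping[str, str] | None = None  # e.g. P (protein) / S (signaling)

    @property
    def markers(self) -> list[str]:
        return list(self.scores.index)

    def text(self, threshold: float = 0.5) -> str:
        """Compact '▲marker+5 ▼marker-3' style rendering."""
        parts = []
        for m, s in self.scores.sort_values(ascending=False).items():
            if abs(s) < threshold:
                continue
            arrow = "▲" if s > 0 else "▼"
            cls = f"({self.marker_classes[m]})" if self.marker_classes else ""
            parts.append(f"{arrow}{m}{cls}{s:+.0f}")
        return " ".join(parts) if parts else "(no enriched markers)"


def _median_iqr(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    q1, med, q3 = np.percentile(X, [25, 50, 75], axis=0)
    return med, q3 - q1


def mem_scores(
    table: CellTable,
    clusters: ClusterResult | np.ndarray,
    markers: Sequence[str] | None = None,
    marker_classes: Mapping[str, str] | None = None,
) -> dict[int, MEMLabel]:
    """MEM labels for every occupied cluster, scaled to the ±10 scale.

    The run maximum |raw| maps to exactly ±10; a cluster distributed
    identically to its reference scores 0 on every marker.  Zero reference
    or cluster IQRs are floored at a small epsilon.
    """
    labels = clusters.labels if isinstance(clusters, ClusterResult) else np.asarray(clusters)
    if labels.shape[0] != table.n_cells:
        raise ValidationError("cluster labels must align with the table")
    markers = list(markers) if markers is not None else list(table.marker_names)
    X = table.marker_matrix(markers)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValidationError("need at least 2 clusters for MEM")

    raw = {}
    meds = {}
    iqrs = {}
    floored = False
    for c in uniq:
        in_c = labels == c
        med_c, iqr_c = _median_iqr(X[in_c])
        med_r, iqr_r = _median_iqr(X[~in_c])
        if np.any(iqr_c <= 0) or np.any(iqr_r <= 0):
            floored = True
        iqr_c = np.maximum(iqr_c, IQR_EPS)
        iqr_r = np.maximum(iqr_r, IQR_EPS)
        diff = med_c - med_r
        mag = np.abs(diff) + iqr_r / iqr_c - 1.0
        mag = np.maximum(mag, 0.0)
        raw[c] = np.sign(diff) * mag
        meds[c] = med_c
        iqrs[c] = iqr_c
    if floored:
        warnings.warn("zero IQR encountered; floored at epsilon")

    max_abs = max(np.max(np.abs(v)) for v in raw.values())
    scale = MAX_SCORE / max_abs if max_abs > 0 else 0.0
    out = {}
    for c in uniq:
        out[int(c)] = MEMLabel(
            cluster_id=int(c),
            scores=pd.Series(raw[c] * scale, index=markers),
            medians=pd.Series(meds[c], index=markers),
            iqrs=pd.Series(iqrs[c], index=markers),
            marker_classes=marker_classes,
        )
    return out


def mem_rmsd_similarity(a: MEMLabel | pd.Series, b: MEMLabel | pd.Series) -> float:
    """Similarity (0-100) between two MEM labels from score RMSD.

    RMSD = sqrt(mean_f (a_f - b_f)^2); similarity = 100 * (1 - RMSD / 20),
    clamped to [0, 100] (20 is the largest possible per-marker difference on
    the ±10 scale).  Identical labels score 100; maximally opposed labels
    (all +10 vs all -10) score 0.
    """
    sa = a.scores if isinstance(a, MEMLabel) else a
    sb = b.scores if isinstance(b, MEMLabel) else b
    if list(sa.index) != list(sb.index):
        raise ValidationError("MEM labels must share the same ordered marker set")
    rmsd = float(np.sqrt(np.mean((sa.to_numpy() - sb.to_numpy()) ** 2)))
    return float(np.clip(100.0 * (1.0 - rmsd / (2 * MAX_SCORE)), 0.0, 100.0))


@dataclass
class PhenotypeConsensus:
    """Consensus grouping of MEM labels pooled from repeated runs."""

    similarity: pd.DataFrame  # pairwise 0-100, diagonal 100
    groups: pd.Series  # label name -> group id
    group_profiles: dict[int, pd.DataFrame]  # group -> median/SD score table
    support: pd.Series  # group -> fraction of runs represented
    min_support: float = 0.5

    @property
    def unstable_groups(self) -> list[int]:
        return [int(g) for g in self.support.index[self.support < self.min_support]]


def consensus_phenotypes(
    labels: Mapping[str, MEMLabel],
    run_of: Mapping[str, int | str],
    linkage_threshold: float = 15.0,
    min_support: float = 0.5,
) -> PhenotypeConsensus:
    """Group phenotypes from multiple runs and score their support.

    ``labels`` maps a unique label name (e.g. ``"run3/cluster7"``) to its
    MEM label; ``run_of`` maps the same names to their run identifier.
    Labels are grouped by average-linkage hierarchical clustering of the
    dissimilarity 100 - similarity, cut at ``linkage_threshold`` (default
    15, i.e. replicate groups with similarity >= 85 merge).  A group's
    support is the fraction of runs contributing at least one label;
    support below ``min_support`` marks the phenotype unstable.
    """
    names = list(labels)
    if not names:
        raise ValidationError("no labels supplied")
    runs = sorted({str(run_of[n]) for n in names})
    n_runs = len(runs)
    if n_runs < 2:
        warnings.warn("consensus over a single run: identity grouping")

    n = len(names)
    sim = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            s = mem_rmsd_similarity(labels[names[i]], labels[names[j]])
            sim[i, j] = sim[j, i] = s
    sim_df = pd.DataFrame(sim, index=names, columns=names)

    if n == 1:
        grp = np.array([1])
    else:
        dissim = squareform(100.0 - sim, checks=False)
        Z = linkage(dissim, method="average")
        grp = fcluster(Z, t=linkage_threshold, criterion="distance")
    groups = pd.Series(grp, index=names, name="group")

    profiles: dict[int, pd.DataFrame] = {}
    support = {}
    for g in np.unique(grp):
        members = [names[i] for i in range(n) if grp[i] == g]
        scores = pd.DataFrame({m: labels[m].scores for m in members})
        profiles[int(g)] = pd.DataFrame(
            {"median": scores.median(axis=1), "sd": scores.std(axis=1, ddof=0)}
        )
        member_runs = {str(run_of[m]) for m in members}
        support[int(g)] = len(member_runs) / n_runs
    support = pd.Series(support, name="support").sort_index()
    return PhenotypeConsensus(
        similarity=sim_df,
        groups=groups,
        group_profiles=profiles,
        support=support,
        min_support=min_support,
    )
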