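"""Model/results interface tying the pipeline stages together.

:class:`RiskStratification` is built from per-patient cell tables plus a
cohort manifest; ``fit()`` executes the full unsupervised workflow — equal
per-patient subsampling, optional 2-D embedding, SOM metaclustering with
automated cluster-number selection, per-cluster abundance computation,
IQR-cut Cox testing against the censored outcome, and marker-enrichment
labelling — and returns a :class:`RiskStratificationResults` carrying the
estimates, per-cluster uncertainties and a ``summary()`` table.  Stability
re-clustering, subsampling consensus, the two-marker gate distillation and
plotting hang off the results object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import gating as _gating
from .clustering import (
    ClusterNumberSearch,
    ClusterResult,
    cluster_fixed_k,
    select_cluster_number,
)
from .embedding import Embedding, embed
from .io import (
    PROGNOSTIC_CODES,
    CellTable,
    CohortManifest,
    CytoriskError,
    RunConfig,
    ValidationError,
    write_annotated_events,
)
from .mem import MEMLabel, mem_scores
from .preprocess import equal_subsample
from .prognosis import (
    PrognosticReport,
    abundance_table,
    assign_high_low,
    cut_point,
    diversity_association,
    kaplan_meier,
    prognostic_report,
)
from .stability import FMeasureReport, cluster_stability

__all__ = ["RiskStratification", "RiskStratificationResults"]


class RiskStratification:
    """Unsupervised survival stratification of a cytometry cohort.

    Parameters
    ----------
    cohort_tables : mapping of patient_id -> CellTable, or a pooled CellTable
        Per-patient event tables on the arcsinh scale (preprocessing —
        transform, positive-identification filter, lineage gating — is the
        caller's responsibility; see :mod:`cytorisk.preprocess`).  A single
        pooled table is used as-is, without subsampling.
    cohort : CohortManifest
        Outcome records for every patient present in the tables.
    config : RunConfig, optional
        Pipeline settings; defaults follow the reference workflow.
    seed : int, optional
        Overrides ``config.seed`` for this run.
    with_replacement : bool
        Sample cells with replacement (repeat/stability runs) instead of
        without (primary run).
    """

    def __init__(
        self,
        cohort_tables: Mapping[str, CellTable] | CellTable,
        cohort: CohortManifest,
        config: RunConfig | None = None,
        seed: int | None = None,
        with_replacement: bool = False,
    ) -> None:
        self.config = config if config is not None else RunConfig()
        self.seed = int(seed) if seed is not None else self.config.seed
        self.cohort = cohort
        self.with_replacement = with_replacement
        if isinstance(cohort_tables, CellTable):
            self.cohort_tables = None
            self.pooled = cohort_tables
        else:
            self.cohort_tables = dict(cohort_tables)
            self.pooled = None
            missing = [
                p for p in self.cohort_tables if p not in cohort.data.index
            ]
            if missing:
                raise ValidationError(
                    f"patients without manifest records: {sorted(missing)}"
                )

    def fit(self) -> "RiskStratificationResults":
        cfg = self.config
        if self.pooled is not None:
            pooled = self.pooled
        else:
            pooled = equal_subsample(
                self.cohort_tables,
                depth=cfg.subsample_depth,
                seed=self.seed,
                with_replacement=self.with_replacement,
            )
        markers = (
            list(cfg.markers_for_clustering)
            if cfg.markers_for_clustering
            else list(pooled.marker_names)
        )
        emb = embed(
            pooled,
            markers=markers,
            method=cfg.embedding_method,
            params=cfg.embedding_params,
            seed=self.seed,
        )
        search = select_cluster_number(
            emb,
            pooled,
            markers,
            k_range=cfg.k_range,
            elbow_tol=cfg.elbow_tol,
            seed=self.seed,
            som_shape=cfg.som_shape,
        )
        clusters = cluster_fixed_k(
            emb, search.k_opt, seed=self.seed, som_shape=cfg.som_shape
        )
        abund = abundance_table(clusters, pooled.patient_ids)
        report = prognostic_report(
            abund,
            self.cohort,
            endpoint=cfg.endpoint,
            alpha=cfg.alpha,
            cut_rule=cfg.cut_rule,
        )
        mem = mem_scores(pooled, clusters, markers=markers)
        return RiskStratificationResults(
            model=self,
            pooled=pooled,
            embedding=emb,
            k_search=search,
            clusters=clusters,
            abundance=abund,
            prognostic_report=report,
            mem_labels=mem,
            markers=markers,
        )


@dataclass
class RiskStratificationResults:
    """Fitted pipeline state: clusters, survival statistics and labels."""

    model: RiskStratification
    pooled: CellTable
    embedding: Embedding
    k_search: ClusterNumberSearch
    clusters: ClusterResult
    abundance: pd.DataFrame
    prognostic_report: PrognosticReport
    mem_labels: dict[int, MEMLabel]
    markers: list[str]
    stability: FMeasureReport | None = None

    # -- basic accessors ---------------------------------------------------

    @property
    def k_opt(self) -> int:
        return self.k_search.k_opt

    @property
    def survival_table(self) -> pd.DataFrame:
        return self.prognostic_report.table

    def negative_clusters(self) -> list[int]:
        return self.prognostic_report.prognostic_clusters("negative")

    def positive_clusters(self) -> list[int]:
        return self.prognostic_report.prognostic_clusters("positive")

    # -- derived quantities ------------------------------------------------

    def compute_stability(
        self, n_runs: int | None = None, seed: int | None = None
    ) -> FMeasureReport:
        """Repeat the clustering with fresh seeds and score mean F per cluster."""
        n = n_runs if n_runs is not None else self.model.config.n_stability_runs
        self.stability = cluster_stability(
            self.embedding,
            self.k_opt,
            self.clusters,
            n_runs=n,
            seed=seed if seed is not None else self.model.seed,
            som_shape=self.model.config.som_shape,
        )
        return self.stability

    def pooled_group_abundance(self) -> pd.DataFrame:
        """Per-patient total NP and PP abundance (percent), summed over
        the respective prognostic clusters."""
        neg = self.negative_clusters()
        pos = self.positive_clusters()
        return pd.DataFrame(
            {
                "NP_pct": self.abundance[neg].sum(axis=1) if neg else 0.0,
                "PP_pct": self.abundance[pos].sum(axis=1) if pos else 0.0,
            },
            index=self.abundance.index,
        )

    def patient_categories(self) -> pd.Series:
        """'NP-high' / 'PP-high' / 'neither' per patient.

        A patient is NP-high when their summed negative-prognostic
        abundance exceeds the cohort IQR cut of that total, PP-high
        analogously; patients above both cuts (not expected, but possible)
        fall to 'neither'.
        """
        totals = self.pooled_group_abundance()
        rule = self.model.config.cut_rule
        np_high = np.zeros(len(totals), dtype=bool)
        pp_high = np.zeros(len(totals), dtype=bool)
        if self.negative_clusters() and totals["NP_pct"].nunique() > 1:
            cut = cut_point(totals["NP_pct"], rule=rule)
            np_high = assign_high_low(totals["NP_pct"], cut) == "high"
        if self.positive_clusters() and totals["PP_pct"].nunique() > 1:
            cut = cut_point(totals["PP_pct"], rule=rule)
            pp_high = assign_high_low(totals["PP_pct"], cut) == "high"
        cats = np.where(
            np_high & pp_high,
            "neither",
            np.where(np_high, "NP-high", np.where(pp_high, "PP-high", "neither")),
        )
        return pd.Series(cats, index=totals.index, name="category")

    def pooled_mem_labels(self) -> dict[str, MEMLabel]:
        """MEM labels of the pooled NP and PP cell groups vs all other cells."""
        neg, pos = self.negative_clusters(), self.positive_clusters()
        if not neg or not pos:
            raise CytoriskError(
                "need at least one negative- and one positive-prognostic cluster"
            )
        grp = np.where(
            np.isin(self.clusters.labels, neg),
            1,
            np.where(np.isin(self.clusters.labels, pos), 2, 3),
        )
        labels = mem_scores(self.pooled, grp, markers=self.markers)
        return {"NP": labels[1], "PP": labels[2]}

    def derive_gate(
        self,
        np_threshold: float | None = None,
        pp_threshold: float | None = None,
    ) -> _gating.GateModel:
        """Two-marker gate from the pooled NP/PP enrichment labels.

        Default positivity thresholds are the midpoint between the gated
        marker's median inside the prognostic group and its median in the
        remaining cells — a user-reviewable stand-in for a manually drawn
        box.
        """
        labels = self.pooled_mem_labels()
        m_np, m_pp = _gating.derive_gate_markers(labels["NP"], labels["PP"])

        def _midpoint(marker: str, group_clusters: list[int]) -> float:
            col = self.pooled.values[:, self.pooled.marker_index(marker)]
            in_g = np.isin(self.clusters.labels, group_clusters)
            return float((np.median(col[in_g]) + np.median(col[~in_g])) / 2.0)

        if np_threshold is None:
            np_threshold = _midpoint(m_np, self.negative_clusters())
        if pp_threshold is None:
            pp_threshold = _midpoint(m_pp, self.positive_clusters())
        return _gating.GateModel(
            marker_np=m_np,
            marker_pp=m_pp,
            np_threshold=np_threshold,
            pp_threshold=pp_threshold,
        )

    def diversity(self, min_abundance: float = 1.0) -> tuple[float, float]:
        """Spearman rho and p of cluster-count diversity vs survival time."""
        times, _ = self.model.cohort.survival(self.model.config.endpoint)
        t = times.loc[self.abundance.index]
        return diversity_association(self.abundance, t, min_abundance=min_abundance)

    def km_curves(self, cluster: int) -> dict[str, pd.DataFrame]:
        """Kaplan-Meier curves for the high/low split of one cluster."""
        grp = self.prognostic_report.groups[int(cluster)]
        times, events = self.model.cohort.survival(self.model.config.endpoint)
        pids = grp.index
        return kaplan_meier(
            times.loc[pids].to_numpy(), events.loc[pids].to_numpy(), grp.to_numpy()
        )

    def annotated_table(self) -> CellTable:
        """Pooled cells with per-cell cluster and prognostic annotations.

        Prognostic status is the -1/0/+1 encoding of the cell's cluster
        direction (negative/NS/positive).
        """
        direction = self.survival_table["direction"]
        code = direction.map(PROGNOSTIC_CODES).reindex(
            range(1, self.clusters.k + 1), fill_value=0
        )
        prog = code.to_numpy()[self.clusters.labels - 1]
        return self.pooled.with_annotations(
            cluster=self.clusters.labels, prognostic=prog
        )

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        """Human-readable per-cluster survival summary."""
        cfg = self.model.config
        t = self.survival_table
        n_prog = int((t["direction"] != "NS").sum())
        lines = [
            "Cytometry risk stratification results",
            "=" * 72,
            f"Patients: {self.abundance.shape[0]}    Pooled cells: {self.pooled.n_cells}"
            f"    Markers: {len(self.markers)}",
            f"Embedding: {self.embedding.method}    Endpoint: {cfg.endpoint.upper()}"
            f"    alpha: {cfg.alpha}",
            f"Cluster number search: k in [{self.k_search.k_range[0]}, "
            f"{self.k_search.k_range[-1]}] -> k_opt = {self.k_opt}",
            f"Prognostic clusters: {n_prog} "
            f"(negative: {self.negative_clusters()}, positive: {self.positive_clusters()})",
            "-" * 72,
        ]
        show = t.copy()
        for c in ("cut", "HR", "ci_low", "ci_high"):
            show[c] = show[c].map(lambda v: f"{v:.3g}" if np.isfinite(v) else "-")
        show["p"] = show["p"].map(lambda v: f"{v:.4f}" if np.isfinite(v) else "-")
        if self.stability is not None:
            show["mean_F"] = self.stability.mean_f.round(3)
            show["stable"] = self.stability.stable
        lines.append(show.to_string())
        lines.append("-" * 72)
        return "\n".join(lines)

    def save(self, out_dir, write_events: bool = True) -> None:
        """Write the run's tables (and annotated events) under ``out_dir``."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.abundance.to_csv(out / "abundance.csv")
        self.survival_table.to_csv(out / "survival_statistics.csv")
        self.k_search.to_csv(out / "cluster_number_search.csv")
        pd.DataFrame({c: l.scores for c, l in self.mem_labels.items()}).to_csv(
            out / "mem_scores.csv"
        )
        with open(out / "mem_labels.txt", "w") as fh:
            for c, l in sorted(self.mem_labels.items()):
                fh.write(f"cluster {c}: {l.text()}\n")
        self.patient_categories().to_csv(out / "patient_categories.csv")
        if self.stability is not None:
            pd.concat([self.stability.mean_f, self.stability.stable], axis=1).to_csv(
                out / "cluster_stability.csv"
            )
        if write_events:
            try:
                write_annotated_events(
                    self.annotated_table(), out / "annotated_events.csv"
                )
            except CytoriskError as exc:  # pragma: no cover - defensive
                warnings.warn(f"could not write annotated events: {exc}")

    def plot(self, out_dir=None):
        """Standard plot bundle; see :mod:`cytorisk.plotting`."""
        from . import plotting

        return plotting.run_report_figures(self, out_dir=out_dir)
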