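"""Outcome-guided testing of cluster abundance.

For every cluster, each patient's abundance (percent of that patient's
pooled cells falling in the cluster) is computed, the cohort is split into
"high" and "low" groups at a statistical cut point — by default the
interquartile range (Q3 - Q1) of the abundance distribution — and a
univariate Cox proportional-hazards model compares the two groups.  A
cluster is called negative-prognostic when p < alpha with hazard ratio > 1
(high abundance, shorter survival) and positive-prognostic when p < alpha
with HR < 1.  Continuous multivariate modelling and Kaplan-Meier estimation
run through lifelines; the per-cluster tests apply no multiplicity
correction (each cluster is reported at its nominal p), with an optional
FDR column available on request.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import proportional_hazard_test
from scipy import stats

from .clustering import ClusterResult
from .io import CohortManifest, CytoriskError, ValidationError

__all__ = [
    "abundance_table",
    "iqr_cut_point",
    "cut_point",
    "assign_high_low",
    "cox_univariate",
    "classify_prognostic",
    "kaplan_meier",
    "cox_multivariate",
    "diversity_association",
    "prognostic_report",
    "PrognosticReport",
    "HazardModel",
]

DIRECTIONS = ("negative", "positive", "NS")


class FitError(CytoriskError):
    pass


def abundance_table(clusters: ClusterResult, patient_ids: np.ndarray) -> pd.DataFrame:
    """Per-patient per-cluster abundance in percent of that patient's cells.

    Rows are patients, columns cluster ids 1..k; every row sums to 100.
    """
    patient_ids = np.asarray(patient_ids)
    if patient_ids.shape[0] != clusters.labels.shape[0]:
        raise ValidationError("patient_ids must align with cluster labels")
    df = pd.DataFrame({"patient": patient_ids, "cluster": clusters.labels})
    counts = df.groupby(["patient", "cluster"], sort=True).size().unstack(fill_value=0)
    counts = counts.reindex(columns=range(1, clusters.k + 1), fill_value=0)
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValidationError("patient with zero pooled cells")
    out = counts.div(totals, axis=0) * 100.0
    out.index = out.index.astype(str)
    out.index.name = "patient_id"
    out.columns.name = "cluster"
    return out


def iqr_cut_point(
    abundances: Sequence[float], quantile_method: str = "linear"
) -> float:
    """Abundance cut point = Q3 - Q1 (the IQR width itself).

    The worked convention: an abundance distribution with quartiles 0.67%
    and 3.36% yields a cut point of 2.69%; patients at or below the cut are
    "low", above it "high".
    """
    a = np.asarray(abundances, dtype=float)
    if a.size < 4:
        raise ValidationError("need >= 4 patients for an IQR cut point")
    q1, q3 = np.quantile(a, [0.25, 0.75], method=quantile_method)
    return float(q3 - q1)


def cut_point(
    abundances: Sequence[float],
    rule: str = "iqr",
    quantile_method: str = "linear",
) -> float:
    """Cut point under the chosen rule: 'iqr' (default), 'tertile', 'quartile'.

    The tertile/quartile rules place the cut at the upper tertile/quartile of
    the abundance distribution (high = top third / top quarter).
    """
    a = np.asarray(abundances, dtype=float)
    if rule == "iqr":
        return iqr_cut_point(a, quantile_method)
    if rule == "tertile":
        return float(np.quantile(a, 2.0 / 3.0, method=quantile_method))
    if rule == "quartile":
        return float(np.quantile(a, 0.75, method=quantile_method))
    raise ValidationError(f"unknown cut rule {rule!r}")


def assign_high_low(abundances: Sequence[float], cut: float) -> np.ndarray:
    """'high' iff abundance > cut, 'low' iff <= cut (boundary is low)."""
    if cut < 0:
        raise ValidationError("cut must be nonnegative")
    a = np.asarray(abundances, dtype=float)
    return np.where(a > cut, "high", "low")


def _fit_cox(df: pd.DataFrame, duration_col: str, event_col: str) -> CoxPHFitter:
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col=duration_col, event_col=event_col)
    return cph


def cox_univariate(
    groups: Sequence[str],
    times: Sequence[float],
    events: Sequence[int],
) -> tuple[float, tuple[float, float], float]:
    """Cox PH fit with a single binary covariate (high = 1 vs low = 0).

    Returns (HR, (ci_low, ci_high), p) with Wald 95% interval and Wald p.
    Ties in event times are handled by lifelines' Efron approximation.
    """
    groups = np.asarray(groups)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if not (groups.shape == times.shape == events.shape):
        raise ValidationError("groups, times and events must align")
    if events.sum() == 0:
        raise FitError("no observed events; hazard ratio undefined")
    high = (groups == "high").astype(float)
    if high.sum() == 0 or high.sum() == len(high):
        raise FitError("both groups must be nonempty")
    df = pd.DataFrame({"T": times, "E": events, "high": high})
    cph = _fit_cox(df, "T", "E")
    s = cph.summary.loc["high"]
    p = float(s["p"])
    if float(s["se(coef)"]) > 10:
        # monotone likelihood (complete separation between the groups): the
        # Wald statistic degenerates.  Take the p-value from the
        # likelihood-ratio test and report a ridge-stabilised HR/CI
        # (a small L2 penalty keeps the estimate finite).
        p = float(cph.log_likelihood_ratio_test().p_value)
        ridge = CoxPHFitter(penalizer=0.1, l1_ratio=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ridge.fit(df, duration_col="T", event_col="E")
        s = ridge.summary.loc["high"]
    return (
        float(s["exp(coef)"]),
        (float(s["exp(coef) lower 95%"]), float(s["exp(coef) upper 95%"])),
        p,
    )


def classify_prognostic(hr: float, p: float, alpha: float = 0.05) -> str:
    """'negative' (HR>1, p<alpha), 'positive' (HR<1, p<alpha) or 'NS'."""
    if hr <= 0 or not np.isfinite(hr):
        raise ValidationError("HR must be positive and finite")
    if p < alpha and hr > 1:
        return "negative"
    if p < alpha and hr < 1:
        return "positive"
    return "NS"


def kaplan_meier(
    times: Sequence[float],
    events: Sequence[int],
    groups: Sequence[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Product-limit survival estimate per group.

    Returns ``{group: DataFrame(time, survival, censored)}``; censored
    subjects contribute risk-set time only.  Empty groups are omitted with a
    warning.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = (
        np.asarray(groups) if groups is not None else np.repeat("all", len(times))
    )
    if not (times.shape == events.shape == groups.shape):
        raise ValidationError("times, events and groups must align")
    out: dict[str, pd.DataFrame] = {}
    for g in pd.unique(groups):
        mask = groups == g
        if mask.sum() == 0:
            warnings.warn(f"group {g!r} is empty; omitted")
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        sf = kmf.survival_function_
        df = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
        censor_times = np.sort(times[mask][events[mask] == 0])
        out[str(g)] = df
        df.attrs["censor_times"] = censor_times
    return out


@dataclass
class HazardModel:
    """Fitted multivariate Cox proportional-hazards model.

    Per covariate x: coefficient b_x (log-hazard units), hazard ratio
    exp(b_x), Wald 95% CI and p.  When requested, ``ph_check`` carries
    Schoenfeld-residual proportional-hazards p-values per covariate.
    """

    summary: pd.DataFrame
    ph_check: pd.Series | None = None
    dropped: list[str] = field(default_factory=list)
    fitter: CoxPHFitter | None = None

    @property
    def hazard_ratios(self) -> pd.Series:
        return self.summary["HR"]


def cox_multivariate(
    data: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: Sequence[str] | None = None,
    check_ph: bool = False,
) -> HazardModel:
    """Multivariate Cox PH model on continuous and binary covariates.

    The hazard for patient i is h0(t) * exp(sum_x b_x * x_i); exp(b_x) is
    the hazard ratio per unit of covariate x (per percent, for cluster
    abundances).  Constant (all-equal) covariates are dropped with a
    warning; exactly collinear covariates raise a singular-fit error naming
    the offending pair.
    """
    covariates = (
        list(covariates)
        if covariates is not None
        else [c for c in data.columns if c not in (duration_col, event_col)]
    )
    missing = [c for c in covariates if c not in data.columns]
    if missing:
        raise ValidationError(f"missing covariate column(s): {missing}")
    if data[covariates].isna().any().any():
        raise ValidationError("missing covariate values among included patients")

    X = data[covariates]
    kept = []
    dropped = []
    for c in covariates:
        if X[c].nunique() <= 1:
            warnings.warn(f"covariate {c!r} is constant; excluded from the model")
            dropped.append(c)
        else:
            kept.append(c)
    if not kept:
        raise FitError("no non-constant covariates to fit")
    corr = X[kept].corr().abs()
    for i, a in enumerate(kept):
        for b in kept[i + 1 :]:
            if corr.loc[a, b] > 1 - 1e-10:
                raise FitError(f"collinear covariates: {a!r} and {b!r}")

    df = data[[duration_col, event_col, *kept]]
    cph = _fit_cox(df, duration_col, event_col)
    s = cph.summary
    out = pd.DataFrame(
        {
            "coef": s["coef"],
            "HR": s["exp(coef)"],
            "ci_low": s["exp(coef) lower 95%"],
            "ci_high": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )
    ph = None
    if check_ph:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = proportional_hazard_test(cph, df, time_transform="rank")
        ph = res.summary["p"]
        ph.index = [ix[0] if isinstance(ix, tuple) else ix for ix in ph.index]
    return HazardModel(summary=out, ph_check=ph, dropped=dropped, fitter=cph)


def diversity_association(
    abundance: pd.DataFrame,
    times: Sequence[float],
    events: Sequence[int] | None = None,
    min_abundance: float = 1.0,
) -> tuple[float, float]:
    """Spearman correlation of intra-tumor diversity with survival time.

    Diversity = number of clusters present in a patient at
    > ``min_abundance`` percent.  All patients (censored included) enter the
    rank correlation.  Returns (rho, p); (nan, nan) when counts are constant.
    """
    if len(abundance) < 5:
        raise ValidationError("need >= 5 patients")
    counts = (abundance > min_abundance).sum(axis=1).to_numpy()
    times = np.asarray(times, dtype=float)
    if counts.shape[0] != times.shape[0]:
        raise ValidationError("abundance rows must align with times")
    if np.all(counts == counts[0]):
        warnings.warn("diversity counts constant across patients; rho undefined")
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(counts, times)
    return float(rho), float(p)


@dataclass
class PrognosticReport:
    """Per-cluster survival statistics table plus patient group assignments.

    ``table`` columns: cut, HR, ci_low, ci_high, p, direction, n_high,
    n_low.  ``groups`` maps cluster id -> Series of 'high'/'low' per
    patient.
    """

    table: pd.DataFrame
    groups: dict[int, pd.Series]
    endpoint: str = "os"
    alpha: float = 0.05

    def prognostic_clusters(self, direction: str | None = None) -> list[int]:
        t = self.table
        mask = t["direction"] != "NS"
        if direction is not None:
            mask = t["direction"] == direction
        return [int(c) for c in t.index[mask]]


def prognostic_report(
    abundance: pd.DataFrame,
    cohort: CohortManifest,
    endpoint: str = "os",
    alpha: float = 0.05,
    cut_rule: str = "iqr",
) -> PrognosticReport:
    """Cut, stratify and Cox-test every cluster's abundance.

    Clusters whose cut point leaves one group empty, or whose Cox fit fails,
    are reported NS rather than aborting the run.
    """
    times, events = cohort.survival(endpoint)
    patients = [p for p in abundance.index if p in times.index]
    if len(patients) < len(abundance.index):
        missing = sorted(set(abundance.index) - set(patients))
        raise ValidationError(f"patients missing from manifest: {missing}")
    t = times.loc[patients].to_numpy()
    e = events.loc[patients].to_numpy()

    rows = []
    groups: dict[int, pd.Series] = {}
    for c in abundance.columns:
        a = abundance[c].loc[patients].to_numpy()
        cut = cut_point(a, rule=cut_rule)
        grp = assign_high_low(a, cut)
        groups[int(c)] = pd.Series(grp, index=patients, name=f"cluster_{c}")
        n_high = int((grp == "high").sum())
        n_low = len(grp) - n_high
        hr, ci, p = np.nan, (np.nan, np.nan), np.nan
        direction = "NS"
        if 0 < n_high < len(grp):
            try:
                hr, ci, p = cox_univariate(grp, t, e)
                direction = classify_prognostic(hr, p, alpha)
            except (FitError, Exception) as exc:  # noqa: BLE001 - NS on any fit failure
                if isinstance(exc, ValidationError):
                    raise
                warnings.warn(f"cluster {c}: Cox fit failed ({exc}); reported NS")
        else:
            warnings.warn(f"cluster {c}: degenerate cut (one group empty); NS")
        rows.append(
            {
                "cluster": int(c),
                "cut": cut,
                "HR": hr,
                "ci_low": ci[0],
                "ci_high": ci[1],
                "p": p,
                "direction": direction,
                "n_high": n_high,
                "n_low": n_low,
            }
        )
    table = pd.DataFrame(rows).set_index("cluster")
    return PrognosticReport(table=table, groups=groups, endpoint=endpoint, alpha=alpha)
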