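"""Distill prognostic phenotypes into a transparent two-marker gate.

From the pooled MEM labels of the negative-prognostic (NP) and
positive-prognostic (PP) cells, the single most NP-discriminating and the
single most PP-discriminating marker are chosen.  Cells are then classed by
two rectangular gates on that biaxial plane — NP-like = marker_np positive
AND marker_pp negative, PP-like = marker_pp positive — and patients are
stratified by their gated-cell fractions with the same IQR cut-point rule
used for cluster abundances.  The result is a decision rule simple enough
to apply on low-dimensional platforms (conventional flow cytometry, IHC).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CellTable, CohortManifest, CytoriskError, ValidationError
from .mem import MEMLabel
from .prognosis import (
    assign_high_low,
    classify_prognostic,
    cox_univariate,
    cut_point,
    kaplan_meier,
)

__all__ = ["GateModel", "derive_gate_markers", "gate_fractions", "stratify_by_gate"]


class NoDiscriminantError(CytoriskError):
    pass


@dataclass
class GateModel:
    """Two-marker rectangular gate rule.

    NP-like cells: ``marker_np`` strictly above its threshold AND
    ``marker_pp`` at or below its threshold.  PP-like cells: ``marker_pp``
    strictly above its threshold.  ``np_cut``/``pp_cut`` are per-patient
    fraction cut points (percent) for the high/low patient split.
    """

    marker_np: str
    marker_pp: str
    np_threshold: float
    pp_threshold: float
    np_cut: float | None = None
    pp_cut: float | None = None

    def __post_init__(self) -> None:
        if self.marker_np == self.marker_pp:
            raise ValidationError("gate markers must be distinct")
        if not (np.isfinite(self.np_threshold) and np.isfinite(self.pp_threshold)):
            raise ValidationError("gate thresholds must be finite")


def derive_gate_markers(
    np_label: MEMLabel | pd.Series, pp_label: MEMLabel | pd.Series
) -> tuple[str, str]:
    """Pick the most discriminating marker for each prognostic group.

    marker_np maximises (NP score - PP score); marker_pp maximises the
    reverse contrast.  Ties break on the larger absolute own-group score,
    then lexicographically.
    """
    a = np_label.scores if isinstance(np_label, MEMLabel) else np_label
    b = pp_label.scores if isinstance(pp_label, MEMLabel) else pp_label
    if list(a.index) != list(b.index):
        raise ValidationError("labels must share the same ordered marker set")
    contrast = a - b
    if np.allclose(contrast.to_numpy(), 0.0):
        raise NoDiscriminantError("labels are identical; no discriminating marker")

    def _pick(c: pd.Series, own: pd.Series) -> str:
        order = pd.DataFrame({"c": c, "own": own.abs()})
        order = order.sort_values(
            by=["c", "own"], ascending=[False, False], kind="mergesort"
        )
        top = order[
            (order["c"] == order["c"].iloc[0]) & (order["own"] == order["own"].iloc[0])
        ]
        return sorted(top.index)[0]

    marker_np = _pick(contrast, a)
    marker_pp = _pick(-contrast, b)
    return marker_np, marker_pp


def gate_fractions(table: CellTable, model: GateModel) -> pd.DataFrame:
    """Per-patient percentages of NP-like and PP-like gated cells.

    Gate membership uses strict inequalities: a cell sitting exactly on a
    threshold is outside the positive gate.
    """
    x_np = table.values[:, table.marker_index(model.marker_np)]
    x_pp = table.values[:, table.marker_index(model.marker_pp)]
    np_like = (x_np > model.np_threshold) & ~(x_pp > model.pp_threshold)
    pp_like = x_pp > model.pp_threshold
    df = pd.DataFrame(
        {
            "patient_id": table.patient_ids.astype(str),
            "np_like": np_like,
            "pp_like": pp_like,
        }
    )
    out = df.groupby("patient_id").mean() * 100.0
    return out.rename(columns={"np_like": "np_like_pct", "pp_like": "pp_like_pct"})


def stratify_by_gate(
    fractions: pd.DataFrame,
    cohort: CohortManifest,
    endpoint: str = "os",
    cut_rule: str = "iqr",
    alpha: float = 0.05,
) -> dict:
    """Class patients by gated fractions and compare the two high groups.

    Patients are NP-like-high when their NP-like fraction exceeds the
    cohort's cut point (same rule as cluster abundances), PP-like-high
    analogously, otherwise 'neither'.  Patients above both cuts are
    assigned 'neither' with a warning.  A univariate Cox model compares
    NP-like-high against PP-like-high.
    """
    pids = [p for p in fractions.index if p in cohort.data.index]
    if len(pids) < len(fractions.index):
        raise ValidationError("gated patients missing from the manifest")
    np_cut = cut_point(fractions.loc[pids, "np_like_pct"], rule=cut_rule)
    pp_cut = cut_point(fractions.loc[pids, "pp_like_pct"], rule=cut_rule)
    np_high = assign_high_low(fractions.loc[pids, "np_like_pct"], np_cut) == "high"
    pp_high = assign_high_low(fractions.loc[pids, "pp_like_pct"], pp_cut) == "high"
    dual = np_high & pp_high
    if dual.any():
        warnings.warn(
            f"{int(dual.sum())} patient(s) above both cuts; assigned 'neither'"
        )
    classes = np.where(
        dual, "neither", np.where(np_high, "NP-high", np.where(pp_high, "PP-high", "neither"))
    )
    classes = pd.Series(classes, index=pids, name="gate_class")

    times, events = cohort.survival(endpoint)
    mask = classes.isin(("NP-high", "PP-high"))
    result = {
        "classes": classes,
        "np_cut": np_cut,
        "pp_cut": pp_cut,
        "HR": np.nan,
        "ci95": (np.nan, np.nan),
        "p": np.nan,
        "direction": "NS",
        "km": None,
    }
    if (classes == "NP-high").sum() == 0 or (classes == "PP-high").sum() == 0:
        warnings.warn("one gated high group is empty; stratification NS")
        return result
    sel = classes.index[mask]
    grp = np.where(classes.loc[sel] == "NP-high", "high", "low")
    t = times.loc[sel].to_numpy()
    e = events.loc[sel].to_numpy()
    try:
        hr, ci, p = cox_univariate(grp, t, e)
    except CytoriskError as exc:
        warnings.warn(f"gate stratification Cox fit failed: {exc}")
        return result
    result.update(
        HR=hr, ci95=ci, p=p, direction=classify_prognostic(hr, p, alpha=alpha)
    )
    result["km"] = kaplan_meier(t, e, np.where(grp == "high", "NP-high", "PP-high"))
    return result
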