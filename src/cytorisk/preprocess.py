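"""Pre-embedding transforms and filters.

Order of operations in a standard run: arcsinh transform (cofactor 5),
positive-identification filter (raw signal above 10 on at least one stained
channel), threshold gating to exclude non-tumor lineages (e.g. CD45+ immune
and CD31+ endothelial cells), then equal per-patient subsampling so every
patient contributes the same number of cells to the pooled analysis.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io import CellTable, CytoriskError, ValidationError

__all__ = [
    "GateRule",
    "arcsinh_transform",
    "positive_identification_filter",
    "apply_gates",
    "equal_subsample",
]


class SamplingError(CytoriskError):
    pass


@dataclass(frozen=True)
class GateRule:
    """One-dimensional threshold gate on a single marker.

    Cells are kept when their (transformed-scale) intensity is strictly on
    ``keep_side`` of ``threshold``.  A rule list is a conjunction: a cell
    passes only if it satisfies every rule.
    """

    marker: str
    threshold: float
    keep_side: str = "below"  # {above, below}

    def __post_init__(self) -> None:
        if self.keep_side not in ("above", "below"):
            raise ValidationError("keep_side must be 'above' or 'below'")
        if not np.isfinite(self.threshold):
            raise ValidationError("gate threshold must be finite")


def arcsinh_transform(raw_values: np.ndarray, cofactor: float = 5.0) -> np.ndarray:
    """Variance-stabilising transform y = asinh(x / cofactor).

    Cofactor 5 is the mass-cytometry convention.  Monotone and odd, so the
    rank order within every channel is preserved and zero maps to zero.
    """
    if cofactor <= 0:
        raise ValidationError("cofactor must be positive")
    return np.arcsinh(np.asarray(raw_values, dtype=float) / cofactor)


def positive_identification_filter(
    table: CellTable,
    channel_subset: Sequence[str],
    threshold: float = 10.0,
    scale: str = "raw",
    cofactor: float = 5.0,
) -> CellTable:
    """Keep cells with signal above ``threshold`` on >=1 stained channel.

    ``threshold`` is on the raw scale by default (10 raw counts); when the
    table already holds arcsinh values, pass ``scale='transformed'`` to have
    the equivalent asinh(threshold / cofactor) applied instead.
    """
    if not channel_subset:
        raise ValidationError("channel_subset must not be empty")
    cut = threshold if scale == "raw" else float(np.arcsinh(threshold / cofactor))
    if scale == "transformed":
        pass
    elif scale != "raw":
        raise ValidationError("scale must be 'raw' or 'transformed'")
    sub = table.marker_matrix(channel_subset)
    keep = (sub > cut).any(axis=1)
    return table.select(keep)


def apply_gates(table: CellTable, rules: Sequence[GateRule]) -> CellTable:
    """Apply a conjunction of 1-D threshold gates (order-independent)."""
    keep = np.ones(table.n_cells, dtype=bool)
    for rule in rules:
        col = table.values[:, table.marker_index(rule.marker)]
        keep &= col > rule.threshold if rule.keep_side == "above" else col < rule.threshold
    return table.select(keep)


def _patient_rng(seed: int, patient_id: str) -> np.random.Generator:
    # per-patient substream: adding/removing a patient leaves the others'
    # draws untouched
    return np.random.default_rng([seed, zlib.crc32(str(patient_id).encode())])


def equal_subsample(
    cohort_tables: Mapping[str, CellTable],
    depth: int | None = None,
    seed: int = 0,
    with_replacement: bool = False,
) -> CellTable:
    """Pool an equal random sample of cells from every patient.

    Even sampling prevents the patients with the most collected cells from
    dominating the pooled embedding and clustering.  ``depth`` defaults to
    the smallest per-patient cell count.  Repeat (stability) runs sample
    with replacement; the primary run samples without.
    """
    if not cohort_tables:
        raise SamplingError("no patient tables supplied")
    counts = {pid: t.n_cells for pid, t in cohort_tables.items()}
    if depth is None:
        depth = min(counts.values())
    if depth < 1:
        raise SamplingError("depth must be >= 1")
    if not with_replacement:
        short = {p: n for p, n in counts.items() if n < depth}
        if short:
            raise SamplingError(
                f"depth {depth} exceeds available cells without replacement: {short}"
            )
    picks = []
    for pid, t in cohort_tables.items():
        rng = _patient_rng(seed, pid)
        idx = rng.choice(t.n_cells, size=depth, replace=with_replacement)
        sub = t.select(np.sort(idx)) if not with_replacement else t.select(idx)
        if not np.all(sub.patient_ids == pid):
            sub = CellTable(
                sub.values, sub.marker_names, np.repeat(pid, depth), sub.annotations
            )
        picks.append(sub)
    return CellTable.concat(picks)
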