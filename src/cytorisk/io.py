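"""Core data containers and event/manifest I/O.

Cytometry events live in a :class:`CellTable`: a cells x markers matrix of
(typically arcsinh-transformed) intensities plus a per-cell patient identifier
and optional per-cell annotation columns (cluster label, prognostic status).
Clinical outcomes live in a :class:`CohortManifest` with one row per patient.

Events are read and written either as plain CSV (header row of marker names,
one cell per row) or as FCS 3.1 list-mode files with single-precision float
data.  The FCS codec implemented here is deliberately minimal: it reads the
TEXT segment of any FCS 3.0/3.1 file with ``$DATATYPE F`` (or ``D``) and
list-mode data, and writes standard-conforming FCS 3.1 files; keywords other
than the channel descriptions are not preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CellTable",
    "CohortManifest",
    "RunConfig",
    "read_events",
    "write_events",
    "write_annotated_events",
    "load_cohort",
    "read_fcs",
    "write_fcs",
]

#: numeric encoding of per-cell prognostic status in annotation columns and
#: exported event files (FCS channels are numeric).
PROGNOSTIC_CODES = {"negative": -1, "NS": 0, "positive": 1}


class CytoriskError(Exception):
    """Base class for all package errors."""


class ValidationError(CytoriskError):
    """Input violates a documented contract."""


class EmptyInputError(CytoriskError):
    """A file or table contained no cells."""


@dataclass
class CellTable:
    """Per-cell marker intensities for one patient or a pooled cohort.

    Parameters
    ----------
    values : ndarray, shape (n_cells, n_markers)
        Marker intensities.  The pipeline works on the arcsinh scale but the
        container itself is scale-agnostic.
    marker_names : sequence of str
        Unique channel labels, one per column.
    patient_ids : ndarray of str, shape (n_cells,)
        Patient identifier per cell.
    annotations : DataFrame, optional
        Per-cell columns such as ``cluster`` or ``prognostic``; row-aligned
        with ``values``.
    """

    values: np.ndarray
    marker_names: list[str]
    patient_ids: np.ndarray
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D cells x markers matrix")
        self.marker_names = list(self.marker_names)
        if len(set(self.marker_names)) != len(self.marker_names):
            raise ValidationError("marker_names must be unique")
        if self.values.shape[1] != len(self.marker_names):
            raise ValidationError(
                f"{self.values.shape[1]} columns but "
                f"{len(self.marker_names)} marker names"
            )
        self.patient_ids = np.asarray(self.patient_ids)
        if self.patient_ids.shape[0] != self.values.shape[0]:
            raise ValidationError("patient_ids must align with rows of values")
        if self.annotations is not None:
            if len(self.annotations) != self.values.shape[0]:
                raise ValidationError("annotations must align 1:1 with cells")
            self.annotations = self.annotations.reset_index(drop=True)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def marker_index(self, marker: str) -> int:
        try:
            return self.marker_names.index(marker)
        except ValueError:
            raise ValidationError(f"unknown marker {marker!r}") from None

    def marker_matrix(self, markers: Sequence[str]) -> np.ndarray:
        """Submatrix of the named markers, in the given order."""
        idx = [self.marker_index(m) for m in markers]
        return self.values[:, idx]

    def select(self, mask: np.ndarray) -> "CellTable":
        """Row subset; never alters intensity values."""
        ann = self.annotations.loc[np.asarray(mask)] if self.annotations is not None else None
        return CellTable(
            self.values[mask], self.marker_names, self.patient_ids[mask], ann
        )

    def with_annotations(self, **columns: np.ndarray) -> "CellTable":
        ann = (
            self.annotations.copy()
            if self.annotations is not None
            else pd.DataFrame(index=range(self.n_cells))
        )
        for name, col in columns.items():
            col = np.asarray(col)
            if col.shape[0] != self.n_cells:
                raise ValidationError(f"annotation {name!r} misaligned with cells")
            ann[name] = col
        return CellTable(self.values, self.marker_names, self.patient_ids, ann)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.marker_names)
        df.insert(0, "patient_id", self.patient_ids)
        if self.annotations is not None:
            for c in self.annotations.columns:
                df[c] = self.annotations[c].to_numpy()
        return df

    @staticmethod
    def concat(tables: Sequence["CellTable"]) -> "CellTable":
        if not tables:
            raise EmptyInputError("no tables to concatenate")
        markers = tables[0].marker_names
        for t in tables[1:]:
            if t.marker_names != markers:
                raise ValidationError("tables have different marker panels")
        anns = [t.annotations for t in tables]
        ann = (
            pd.concat(anns, ignore_index=True)
            if all(a is not None for a in anns)
            else None
        )
        return CellTable(
            np.vstack([t.values for t in tables]),
            markers,
            np.concatenate([t.patient_ids for t in tables]),
            ann,
        )


@dataclass
class CohortManifest:
    """Per-patient clinical outcomes.

    ``data`` holds one row per patient indexed by ``patient_id`` with columns
    ``os_time`` (days), ``os_event`` (1 = death observed, 0 = censored) and,
    when available, ``pfs_time``/``pfs_event`` plus arbitrary covariates
    (Age, MGMT, EOR, TMZ, XRT ...).
    """

    data: pd.DataFrame

    REQUIRED = ("os_time", "os_event")

    def __post_init__(self) -> None:
        df = self.data
        if "patient_id" in df.columns:
            df = df.set_index(df["patient_id"].astype(str)).drop(columns="patient_id")
        df.index = df.index.astype(str)
        if df.index.duplicated().any():
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate patient_id(s): {dupes}")
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValidationError(f"manifest missing required column {col!r}")
        for col in ("os_time", "pfs_time"):
            if col in df.columns and (df[col].dropna() < 0).any():
                raise ValidationError(f"negative values in {col}")
        for col in ("os_event", "pfs_event"):
            if col in df.columns:
                bad = ~df[col].dropna().isin((0, 1))
                if bad.any():
                    raise ValidationError(f"{col} must be 0/1")
        self.data = df

    @property
    def patient_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def has_pfs(self) -> bool:
        return {"pfs_time", "pfs_event"}.issubset(self.data.columns)

    def survival(self, endpoint: str = "os") -> tuple[pd.Series, pd.Series]:
        """(time, event) vectors for endpoint 'os' or 'pfs'."""
        if endpoint not in ("os", "pfs"):
            raise ValidationError("endpoint must be 'os' or 'pfs'")
        if endpoint == "pfs" and not self.has_pfs:
            raise ValidationError("cohort has no PFS columns")
        return self.data[f"{endpoint}_time"], self.data[f"{endpoint}_event"]

    def covariates(self, names: Sequence[str]) -> pd.DataFrame:
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise ValidationError(f"missing covariate column(s): {missing}")
        return self.data[list(names)]


@dataclass
class RunConfig:
    """Tunable parameters for one full stratification run.

    Defaults follow the pipeline's reference settings: cluster-number search
    over k = 5..50, significance level 0.05, 100 stability re-clusterings and
    10 repeated cell subsamplings.
    """

    embedding_method: str = "tsne"  # {tsne, umap, none}
    markers_for_clustering: list[str] | None = None
    k_range: tuple[int, int] = (5, 50)
    seed: int = 38
    subsample_depth: int | None = None  # None -> min per-patient count
    alpha: float = 0.05
    n_stability_runs: int = 100
    n_subsample_runs: int = 10
    cofactor: float = 5.0
    elbow_tol: float = 0.01
    som_shape: tuple[int, int] = (10, 10)
    endpoint: str = "os"
    cut_rule: str = "iqr"  # {iqr, tertile, quartile}
    embedding_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.embedding_method not in ("tsne", "umap", "none"):
            raise ValidationError(f"unsupported embedding {self.embedding_method!r}")
        lo, hi = self.k_range
        if lo < 2 or hi < lo:
            raise ValidationError("k_range must satisfy 2 <= lo <= hi")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.subsample_depth is not None and self.subsample_depth < 1:
            raise ValidationError("subsample_depth must be >= 1")


# ---------------------------------------------------------------------------
# CSV events
# ---------------------------------------------------------------------------


def read_events(
    path: str | Path,
    format: str = "auto",
    patient_id: str | None = None,
) -> CellTable:
    """Read one patient's events from a CSV or FCS file.

    CSV dialect: header row of marker names, one cell per row.  A
    ``patient_id`` column, when present, is used; otherwise the patient
    identifier defaults to the file stem or the explicit ``patient_id``.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read events: no such file {path}")
    if format == "auto":
        format = "fcs" if path.suffix.lower() == ".fcs" else "csv"
    if format == "fcs":
        values, markers = read_fcs(path)
        df = pd.DataFrame(values, columns=markers)
    elif format == "csv":
        df = pd.read_csv(path)
    else:
        raise ValidationError(f"unknown event format {format!r}")
    if df.empty:
        raise EmptyInputError(f"{path} contains no cells")

    pid_col = None
    if "patient_id" in df.columns:
        pid_col = df.pop("patient_id").astype(str).to_numpy()
    pid = pid_col if pid_col is not None else np.repeat(
        patient_id if patient_id is not None else path.stem, len(df)
    )
    ann_cols = [c for c in ("cluster", "prognostic") if c in df.columns]
    ann = df[ann_cols].copy() if ann_cols else None
    df = df.drop(columns=ann_cols)
    return CellTable(df.to_numpy(dtype=float), list(df.columns), pid, ann)


def write_events(table: CellTable, path: str | Path, format: str = "auto") -> Path:
    """Write a CellTable (values + patient ids + any annotations)."""
    path = Path(path)
    if format == "auto":
        format = "fcs" if path.suffix.lower() == ".fcs" else "csv"
    if format == "csv":
        table.to_frame().to_csv(path, index=False)
    elif format == "fcs":
        names = list(table.marker_names)
        data = table.values
        if table.annotations is not None:
            for c in table.annotations.columns:
                names.append(str(c))
                data = np.column_stack(
                    [data, table.annotations[c].to_numpy(dtype=float)]
                )
        write_fcs(path, data, names)
    else:
        raise ValidationError(f"unknown event format {format!r}")
    return path


def write_annotated_events(
    table: CellTable, path: str | Path, format: str = "auto"
) -> Path:
    """Write events with their ``cluster`` and ``prognostic`` annotations.

    Mirrors the pipeline's final output: the original channels plus two
    appended numeric columns.  Prognostic status uses the -1/0/+1 encoding
    of :data:`PROGNOSTIC_CODES`.
    """
    if table.annotations is None or not {"cluster", "prognostic"}.issubset(
        table.annotations.columns
    ):
        raise ValidationError(
            "table must carry 'cluster' and 'prognostic' annotations"
        )
    return write_events(table, path, format=format)


def load_cohort(manifest_path: str | Path) -> CohortManifest:
    """Load a cohort manifest (CSV, one row per patient)."""
    path = Path(manifest_path)
    if not path.exists():
        raise IOError(f"cannot read manifest: no such file {path}")
    df = pd.read_csv(path)
    if "patient_id" not in df.columns:
        raise ValidationError("manifest must have a patient_id column")
    return CohortManifest(df)


# ---------------------------------------------------------------------------
# Minimal FCS 3.1 codec (float list-mode data)
# ---------------------------------------------------------------------------

_DELIM = "/"


def read_fcs(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read an FCS 3.0/3.1 list-mode file with float or double data.

    Returns ``(events, channel_names)`` where ``events`` has one row per
    event.  Channel names prefer ``$PnS`` (stain) over ``$PnN`` (short name).
    """
    raw = Path(path).read_bytes()
    if len(raw) < 58:
        raise IOError(f"{path}: not an FCS file (truncated header)")
    version = raw[:6].decode("ascii", "replace")
    if not version.startswith("FCS"):
        raise IOError(f"{path}: not an FCS file (version {version!r})")
    text_start = int(raw[10:18])
    text_end = int(raw[18:26])
    text = raw[text_start : text_end + 1].decode("utf-8", "replace")
    delim = text[0]
    fields = text.strip(delim).split(delim)
    kw = {fields[i].strip().upper(): fields[i + 1] for i in range(0, len(fields) - 1, 2)}

    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    dtype_code = kw["$DATATYPE"].strip().upper()
    if dtype_code not in ("F", "D"):
        raise IOError(f"{path}: unsupported $DATATYPE {dtype_code!r} (need F or D)")
    byteord = kw.get("$BYTEORD", "1,2,3,4").strip()
    little = byteord.startswith("1")
    base = "<" if little else ">"
    np_dtype = np.dtype(base + ("f4" if dtype_code == "F" else "f8"))

    data_start = int(kw.get("$BEGINDATA", 0) or 0)
    data_end = int(kw.get("$ENDDATA", 0) or 0)
    if data_start == 0:
        data_start = int(raw[26:34])
        data_end = int(raw[34:42])
    buf = raw[data_start : data_end + 1]
    events = np.frombuffer(buf, dtype=np_dtype, count=n_par * n_tot)
    events = events.reshape(n_tot, n_par).astype(float)

    names = []
    for i in range(1, n_par + 1):
        names.append(kw.get(f"$P{i}S") or kw.get(f"$P{i}N") or f"P{i}")
    return events, names


def write_fcs(path: str | Path, events: np.ndarray, channel_names: Sequence[str]) -> Path:
    """Write events as a minimal FCS 3.1 file (float32, list mode)."""
    events = np.asarray(events, dtype=np.float32)
    if events.ndim != 2:
        raise ValidationError("events must be 2-D")
    n_tot, n_par = events.shape
    if n_par != len(channel_names):
        raise ValidationError("channel_names must match event columns")

    data = events.astype("<f4").tobytes()
    kw: dict[str, str] = {
        "$DATATYPE": "F",
        "$MODE": "L",
        "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
        "$NEXTDATA": "0",
    }
    for i, name in enumerate(channel_names, start=1):
        kw[f"$P{i}N"] = str(name).replace(_DELIM, "_")
        kw[f"$P{i}S"] = str(name).replace(_DELIM, "_")
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        finite = events[:, i - 1][np.isfinite(events[:, i - 1])]
        rng = float(finite.max()) + 1 if finite.size else 1.0
        kw[f"$P{i}R"] = str(int(np.ceil(max(rng, 1.0))))

    def render_text(begin_data: int, end_data: int) -> bytes:
        items = dict(kw)
        items["$BEGINDATA"] = str(begin_data)
        items["$ENDDATA"] = str(end_data)
        items["$BEGINANALYSIS"] = "0"
        items["$ENDANALYSIS"] = "0"
        items["$BEGINSTEXT"] = "0"
        items["$ENDSTEXT"] = "0"
        parts = [_DELIM]
        for k, v in items.items():
            parts.append(f"{k}{_DELIM}{v}{_DELIM}")
        return "".join(parts).encode("ascii")

    header_len = 58
    text_start = header_len
    # iterate because the data offsets appear inside TEXT and change its length
    begin_data = end_data = 0
    for _ in range(8):
        text = render_text(begin_data, end_data)
        new_begin = text_start + len(text)
        new_end = new_begin + len(data) - 1
        if (new_begin, new_end) == (begin_data, end_data):
            break
        begin_data, end_data = new_begin, new_end
    text = render_text(begin_data, end_data)
    text_end = text_start + len(text) - 1

    def off(x: int) -> bytes:
        s = str(x)
        if len(s) > 8:
            s = "0"  # too large for header slot; TEXT keywords carry the value
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + off(text_start) + off(text_end)
    if end_data <= 99_999_999:
        header += off(begin_data) + off(end_data)
    else:
        header += off(0) + off(0)
    header += off(0) + off(0)  # analysis segment
    assert len(header) == header_len, len(header)

    Path(path).write_bytes(header + text + data)
    return Path(path)
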