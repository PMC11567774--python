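"""Read/write cohort tables, matrices and time series as TSV.

Every writer emits deterministic byte streams: fixed column ordering
(canonicalized by parcel label), fixed 9-significant-digit float format.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from parcelmark.core import (
    SUBCORTICAL_LABELS,
    Connectome,
    ParcellatedSample,
    RestingTimeseries,
    parcel_labels,
)

FLOAT_FMT = "%.9g"
MEASURE_FILES = ("area", "thickness", "myelin", "subcortical")
META_COLUMNS = ("group", "batch", "sex", "age", "n_types", "etiv", "global_area")


def save_cohort(
    samples: list[ParcellatedSample],
    out_dir: str | os.PathLike,
    timeseries: list[RestingTimeseries] | None = None,
) -> Path:
    """Write a cohort as ``metadata.tsv`` plus one wide TSV per measure.

    Time series, when given, go to ``timeseries/<subject_id>.tsv``
    (parcels x timepoints).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ids = [s.subject_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject_id in cohort")
    meta = pd.DataFrame(
        {
            "group": [s.group for s in samples],
            "batch": [s.batch for s in samples],
            "sex": [s.sex for s in samples],
            "age": [s.age for s in samples],
            "n_types": [s.n_types for s in samples],
            "etiv": [s.etiv for s in samples],
            "global_area": [s.global_area for s in samples],
        },
        index=pd.Index(ids, name="subject_id"),
    )
    meta.to_csv(out / "metadata.tsv", sep="\t", float_format=FLOAT_FMT)
    n_parcels = samples[0].area.size
    cols = {
        "area": parcel_labels(n_parcels),
        "thickness": parcel_labels(n_parcels),
        "myelin": parcel_labels(n_parcels),
        "subcortical": list(SUBCORTICAL_LABELS[: samples[0].subcortical.size]),
    }
    for measure in MEASURE_FILES:
        tab = pd.DataFrame(
            np.vstack([getattr(s, measure) for s in samples]),
            index=pd.Index(ids, name="subject_id"),
            columns=cols[measure],
        )
        tab.to_csv(out / f"{measure}.tsv", sep="\t", float_format=FLOAT_FMT)
    if timeseries:
        ts_dir = out / "timeseries"
        ts_dir.mkdir(exist_ok=True)
        for ts in timeseries:
            pd.DataFrame(ts.data).to_csv(
                ts_dir / f"{ts.subject_id}.tsv",
                sep="\t", float_format=FLOAT_FMT, header=False, index=False,
            )
    return out


def _read_table(path: Path, index_col: str = "subject_id") -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"missing cohort table: {path}")
    tab = pd.read_csv(path, sep="\t", index_col=0)
    if tab.index.duplicated().any():
        dupes = tab.index[tab.index.duplicated()].tolist()
        raise ValueError(f"duplicate subject_id in {path.name}: {dupes}")
    return tab


def _require_numeric(tab: pd.DataFrame, name: str) -> pd.DataFrame:
    for col in tab.columns:
        coerced = pd.to_numeric(tab[col], errors="coerce")
        if coerced.isna().any():
            row = tab.index[coerced.isna()][0]
            raise ValueError(f"non-numeric cell in {name} at row {row!r}, column {col!r}")
        tab[col] = coerced
    return tab


def load_cohort(
    dir_path: str | os.PathLike,
    load_timeseries: bool = False,
) -> tuple[list[ParcellatedSample], list[RestingTimeseries]]:
    """Load a cohort directory written by :func:`save_cohort`.

    Round-trips losslessly to ~1e-9 relative precision. Measure tables
    must contain exactly the subjects listed in ``metadata.tsv``; a
    missing subject is a hard error naming that subject.
    """
    d = Path(dir_path)
    meta = _read_table(d / "metadata.tsv")
    measures: dict[str, pd.DataFrame] = {}
    for measure in MEASURE_FILES:
        tab = _require_numeric(_read_table(d / f"{measure}.tsv"), f"{measure}.tsv")
        missing = set(meta.index) - set(tab.index)
        if missing:
            raise ValueError(
                f"subject {sorted(missing)[0]!r} missing from {measure}.tsv"
            )
        # canonical order: metadata row order; parcel tables label-sorted,
        # subcortical tables in registry order
        if measure == "subcortical":
            known = [c for c in SUBCORTICAL_LABELS if c in tab.columns]
            cols = known + sorted(set(tab.columns) - set(known))
        else:
            cols = sorted(tab.columns)
        measures[measure] = tab.loc[meta.index, cols]
    samples = []
    for sid in meta.index:
        row = meta.loc[sid]
        samples.append(
            ParcellatedSample(
                subject_id=str(sid),
                group=str(row["group"]),
                batch=int(row["batch"]),
                sex=str(row["sex"]),
                age=float(row["age"]),
                n_types=int(row["n_types"]),
                area=measures["area"].loc[sid].to_numpy(),
                thickness=measures["thickness"].loc[sid].to_numpy(),
                myelin=measures["myelin"].loc[sid].to_numpy(),
                subcortical=measures["subcortical"].loc[sid].to_numpy(),
                etiv=float(row["etiv"]),
                global_area=float(row["global_area"]),
            )
        )
    timeseries: list[RestingTimeseries] = []
    if load_timeseries:
        ts_dir = d / "timeseries"
        if ts_dir.exists():
            for sid in meta.index:
                f = ts_dir / f"{sid}.tsv"
                if f.exists():
                    data = pd.read_csv(f, sep="\t", header=None).to_numpy()
                    timeseries.append(RestingTimeseries(subject_id=str(sid), data=data))
    return samples, timeseries


def save_matrix(
    matrix: np.ndarray | Connectome,
    path: str | os.PathLike,
    labels: list[str] | None = None,
) -> Path:
    """Write a (feature or connectome) matrix as labeled TSV.

    Square matrices must be symmetric within 1e-8 and are stored in
    full with the label set as both header row and index column.
    """
    if isinstance(matrix, Connectome):
        labels = labels or matrix.parcel_labels
        matrix = matrix.weights
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("matrix must be 2-D")
    square = m.shape[0] == m.shape[1]
    if square and not np.allclose(m, m.T, atol=1e-8):
        raise ValueError("square matrix is asymmetric beyond 1e-8; refusing to write")
    if labels is None:
        labels = [f"V{i + 1:03d}" for i in range(m.shape[1])]
    idx = labels if square else [f"R{i + 1:03d}" for i in range(m.shape[0])]
    pd.DataFrame(m, index=idx, columns=labels).to_csv(
        path, sep="\t", float_format=FLOAT_FMT
    )
    return Path(path)


def load_matrix(path: str | os.PathLike) -> tuple[np.ndarray, list[str]]:
    """Load a matrix written by :func:`save_matrix`; returns (values, labels)."""
    tab = pd.read_csv(path, sep="\t", index_col=0)
    tab = _require_numeric(tab, Path(path).name)
    return tab.to_numpy(), [str(c) for c in tab.columns]
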