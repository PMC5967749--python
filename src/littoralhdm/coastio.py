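"""Data model and I/O for ordered coastline presence/absence point datasets.

The analysis operates on a 1-D chain of shore points (the study unit is a
point every ~10 m of coastline), each carrying environmental predictors
(sea-surface temperature, wave heights, slope class, geology, substrate
type) and one binary presence/absence column per littoral habitat.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

#: canonical predictor column names, in the order models use them
PREDICTOR_COLUMNS = ("sst_avg", "wh_avg", "wh_min", "slope_class", "geology", "substrate")
COORD_COLUMNS = ("x", "y")
REQUIRED_COLUMNS = COORD_COLUMNS + PREDICTOR_COLUMNS

#: habitat short codes used by the study database legend
DEFAULT_HABITAT_CODES = ("Riv", "Lby", "Tro", "Neo", "Hph", "Cme")

SLOPE_CLASSES = (1, 2, 3, 4, 5)
GEOLOGY_LEVELS = ("metamorphic", "mineral", "plutonic", "sedimentary", "artificial")
SUBSTRATE_LEVELS = ("natural", "artificial")


class ValidationError(ValueError):
    """Raised when a loaded table violates the dataset contract."""


class CoastPoint(NamedTuple):
    """One coastline point: position, predictors, habitat indicators."""

    index: int
    x: float
    y: float
    sst_avg: float
    wh_avg: float
    wh_min: float
    slope_class: int
    geology: str
    substrate: str
    habitats: dict


@dataclass
class CoastlineDataset:
    """An ordered chain of coastline points with predictors and habitat layers.

    Parameters
    ----------
    df
        One row per point, positional order = chain order. Must contain
        ``x, y, sst_avg, wh_avg, wh_min, slope_class, geology, substrate``
        plus one 0/1 column per entry of `habitat_codes`.
    habitat_codes
        Names of the habitat indicator columns present in `df`.
    """

    df: pd.DataFrame
    habitat_codes: tuple = field(default=())

    def __post_init__(self) -> None:
        self.habitat_codes = tuple(self.habitat_codes)
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"missing required columns: {missing}")
        for code in self.habitat_codes:
            if code not in self.df.columns:
                raise ValidationError(f"missing habitat column: {code!r}")
        self.df = self.df.reset_index(drop=True)
        bad_slope = ~self.df["slope_class"].isin(SLOPE_CLASSES)
        if bad_slope.any():
            rows = self.df.index[bad_slope][:5].tolist()
            raise ValidationError(f"slope_class outside 1..5 at rows {rows}")
        for code in self.habitat_codes:
            col = self.df[code]
            bad = ~col.isin((0, 1))
            if bad.any():
                row = int(self.df.index[bad][0])
                raise ValidationError(
                    f"habitat {code!r} has non-binary value {col.iloc[row]!r} at row {row}"
                )
            self.df[code] = col.astype(np.int8)

    @property
    def n(self) -> int:
        return len(self.df)

    def point(self, i: int) -> CoastPoint:
        r = self.df.iloc[i]
        return CoastPoint(
            index=i, x=float(r["x"]), y=float(r["y"]),
            sst_avg=float(r["sst_avg"]), wh_avg=float(r["wh_avg"]), wh_min=float(r["wh_min"]),
            slope_class=int(r["slope_class"]), geology=str(r["geology"]),
            substrate=str(r["substrate"]),
            habitats={c: int(r[c]) for c in self.habitat_codes},
        )

    def habitat(self, code: str) -> np.ndarray:
        """Binary presence/absence vector for one habitat."""
        if code not in self.habitat_codes:
            raise KeyError(f"unknown habitat code {code!r}; have {self.habitat_codes}")
        return self.df[code].to_numpy(dtype=np.int8)

    def prevalence(self, code: str) -> float:
        """Fraction of points where the habitat is present (F in study tables)."""
        return float(self.habitat(code).mean())

    def chain_violations(self, factor: float = 5.0) -> np.ndarray:
        """Indices i where the step i -> i+1 exceeds `factor` x median step.

        A proper coastline ordering is a spatial chain: consecutive points
        are near-neighbours. Large steps flag rows that are out of order.
        """
        xy = self.df[["x", "y"]].to_numpy(float)
        if len(xy) < 3:
            return np.empty(0, dtype=int)
        d = np.hypot(*(np.diff(xy, axis=0).T))
        med = np.median(d)
        if med == 0:
            return np.flatnonzero(d > 0)
        return np.flatnonzero(d > factor * med)


def _read_table(path, fmt: str | None) -> pd.DataFrame:
    path = Path(path)
    if fmt is None:
        fmt = "xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv"
    if fmt == "xlsx":
        return pd.read_excel(path)
    return pd.read_csv(path)


def read_dataset(
    path,
    habitat_codes: Sequence[str] | None = None,
    column_map: Mapping[str, str] | None = None,
    fmt: str | None = None,
) -> CoastlineDataset:
    """Load a coastline table (CSV or XLSX) into a validated dataset.

    Parameters
    ----------
    path
        Input file, one row per coastline point, in file order.
    habitat_codes
        Habitat indicator columns to load. Default: whichever of the
        study codes (Riv, Lby, Tro, Neo, Hph, Cme) are present; lists
        shorter than six are accepted. Explicitly requested codes must
        exist in the file.
    column_map
        Mapping canonical name -> file column name for any non-default
        column naming.
    fmt
        "csv" or "xlsx"; inferred from the suffix when omitted.

    Rows with any missing predictor or coordinate are dropped (the count
    is logged). Habitat cells must be 0/1.
    """
    raw = _read_table(path, fmt)
    if raw.empty:
        raise ValidationError(f"{path}: file is empty")
    colmap = dict(column_map or {})
    rename = {v: k for k, v in colmap.items() if v in raw.columns}
    raw = raw.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")

    if habitat_codes is None:
        codes = tuple(c for c in DEFAULT_HABITAT_CODES if c in raw.columns)
    else:
        codes = tuple(habitat_codes)
        absent = [c for c in codes if c not in raw.columns]
        if absent:
            raise ValidationError(f"{path}: missing habitat columns {absent}")

    keep = list(REQUIRED_COLUMNS) + list(codes)
    df = raw[keep].copy()
    complete = df[list(REQUIRED_COLUMNS)].notna().all(axis=1) & df[list(codes)].notna().all(axis=1)
    n_drop = int((~complete).sum())
    if n_drop:
        logger.info("dropped %d rows with missing values", n_drop)
        df = df[complete]
    if df.empty:
        raise ValidationError(f"{path}: no complete rows after dropping missing values")
    for c in ("x", "y", "sst_avg", "wh_avg", "wh_min"):
        df[c] = pd.to_numeric(df[c])
    df["slope_class"] = pd.to_numeric(df["slope_class"], downcast="integer").astype(int)
    for code in codes:
        vals = pd.to_numeric(df[code], errors="coerce")
        ok = vals.isin((0, 1))
        if not ok.all():
            row = int(np.flatnonzero(~ok.to_numpy())[0])
            raise ValidationError(
                f"{path}: habitat {code!r} non-binary value {df[code].iloc[row]!r} at row {row}"
            )
        df[code] = vals.astype(np.int8)
    return CoastlineDataset(df.reset_index(drop=True), codes)


def write_dataset(dataset: CoastlineDataset, path) -> None:
    """Write a dataset back to CSV in canonical column order."""
    cols = list(REQUIRED_COLUMNS) + list(dataset.habitat_codes)
    dataset.df[cols].to_csv(path, index=False)


def order_chain(dataset: CoastlineDataset) -> CoastlineDataset:
    """Reorder rows as a nearest-neighbour chain from the northernmost point.

    Guards against arbitrarily ordered input tables: starting from the
    point with maximum y, each step moves to the nearest not-yet-visited
    point. Duplicate coordinates are tie-broken by original row order
    (a warning is emitted). Idempotent on an already-ordered chain.
    """
    df = dataset.df
    n = len(df)
    if n <= 1:
        return CoastlineDataset(df.copy(), dataset.habitat_codes)
    xy = df[["x", "y"]].to_numpy(float)
    if len(np.unique(xy, axis=0)) < n:
        warnings.warn("duplicate coordinates; ties broken by original row order")
    # start at max y; ties -> smallest original row index
    start = int(np.flatnonzero(xy[:, 1] == xy[:, 1].max())[0])
    tree = cKDTree(xy)
    visited = np.zeros(n, dtype=bool)
    order = np.empty(n, dtype=int)
    order[0] = start
    visited[start] = True
    cur = start
    for step in range(1, n):
        k = 2
        nxt = -1
        while nxt < 0:
            k = min(k * 2, n)
            _, idx = tree.query(xy[cur], k=k)
            idx = np.atleast_1d(idx)
            for j in idx:
                if not visited[j]:
                    nxt = int(j)
                    break
            if k >= n and nxt < 0:  # pragma: no cover - all visited guard
                raise RuntimeError("chain construction exhausted candidates")
        order[step] = nxt
        visited[nxt] = True
        cur = nxt
    out = df.iloc[order].reset_index(drop=True)
    return CoastlineDataset(out, dataset.habitat_codes)


RESULT_COLUMNS = (
    "habitat", "strategy", "case", "fraction", "n_train", "F_train",
    "D2", "AUC", "threshold", "sensitivity", "specificity", "status",
)


def write_results(rows: Iterable, path) -> pd.DataFrame:
    """Write scenario result rows to CSV (4-decimal numbers).

    `rows` may be ScenarioResult-like objects (anything exposing
    `.to_row()`), plain dicts, or a DataFrame. Returns the frame written.
    """
    if isinstance(rows, pd.DataFrame):
        recs = rows.to_dict("records")
    else:
        recs = [r.to_row() if hasattr(r, "to_row") else dict(r) for r in rows]
    if not recs:
        raise ValueError("no result rows to write")
    out = pd.DataFrame(recs)
    for c in RESULT_COLUMNS:
        if c not in out.columns:
            out[c] = np.nan
    out = out[list(RESULT_COLUMNS)]
    out.to_csv(path, index=False, float_format="%.4f")
    return out
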