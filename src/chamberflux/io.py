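"""CSV ingestion and output for the chamber-flux pipeline.

Input tables are long-format RFC-4180 CSV (UTF-8, '.' decimal).  A closure
table holds one row per analyzer sample; rows are grouped into
:class:`ClosureSeries` by (plot, campaign, filter count) with a new closure
starting whenever the within-group time stamp resets (analyzer exports are
concatenated closures).  Output tables carry their units in leading
``#``-comment lines and encode missing values as empty fields.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig

logger = logging.getLogger("chamberflux")

#: canonical closure-table columns; pressure is optional
CLOSURE_COLUMNS = [
    "plot_id", "transect_id", "campaign", "filter_count",
    "t", "co2_wet", "h2o", "ppfd_in", "ppfd_out", "tair",
]
OPTIONAL_CLOSURE_COLUMNS = ["pressure"]

#: filter counts of the shading sequence used in the field protocol
PROTOCOL_FILTER_COUNTS = (0, 1, 2, 3, 4, 5, 6, 7, 9, 11)


class FormatError(ValueError):
    """Raised when an input table violates the column/units contract."""


@dataclass
class ClosureSeries:
    """One 60-s chamber closure for one plot x filter level.

    Vectors are ordered by time; ``t`` is seconds since chamber closing
    (0-based).  ``dead_band`` seconds are discarded while the headspace
    mixes and the following ``fit_window`` seconds are used for fitting.
    """

    plot_id: str
    transect_id: str
    campaign: str
    filter_count: int
    closure_index: int
    t: np.ndarray
    co2_wet: np.ndarray
    h2o: np.ndarray
    tair: np.ndarray
    ppfd_in: np.ndarray
    ppfd_out: np.ndarray
    pressure: float | None = None
    dead_band: float = 20.0
    fit_window: float = 40.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for name in ("co2_wet", "h2o", "tair", "ppfd_in", "ppfd_out"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if len(self.t) and not np.all(np.diff(self.t) > 0):
            raise ValueError(
                f"closure {self.key()}: time must be strictly increasing")

    def key(self) -> tuple:
        return (self.plot_id, self.campaign, self.filter_count,
                self.closure_index)

    @property
    def span(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) else 0.0

    def fit_mask(self) -> np.ndarray:
        """Samples inside [t0+dead_band, t0+dead_band+fit_window).

        The half-open window yields exactly 40 samples at 1 Hz for the
        field protocol (20 s dead band, 40 s used).
        """
        rel = self.t - self.t[0]
        return (rel >= self.dead_band) & (rel < self.dead_band + self.fit_window)


def _rename_from_map(df: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    if config.header_map:
        inverse = {v: k for k, v in config.header_map.items()}
        df = df.rename(columns=inverse)
    return df


def read_closure_table(path: str | Path, config: RunConfig | None = None,
                       ) -> list[ClosureSeries]:
    """Read a long-format closure CSV into a list of ClosureSeries.

    Grouping is a partition: every accepted row belongs to exactly one
    series.  Rows with non-finite required values are dropped and counted;
    a series whose time stamps are not strictly increasing (after reset
    splitting) is rejected with a diagnostic.
    """
    config = config or RunConfig()
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        logger.warning("empty closure table: %s", path)
        return []
    df = _rename_from_map(df, config)
    missing = [c for c in CLOSURE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    if df.empty:
        logger.warning("closure table has headers but no rows: %s", path)
        return []

    numeric = ["t", "co2_wet", "h2o", "ppfd_in", "ppfd_out", "tair"]
    bad = ~np.isfinite(df[numeric]).all(axis=1)
    if bad.any():
        logger.warning("dropping %d malformed row(s) in %s", int(bad.sum()), path)
        df = df[~bad]

    series: list[ClosureSeries] = []
    n_rejected = 0
    group_cols = ["plot_id", "campaign", "filter_count"]
    for _, g in df.groupby(group_cols, sort=True):
        # split concatenated closures where t resets below its predecessor;
        # a tied time stamp is left in place and rejected as non-monotone
        t = g["t"].to_numpy(dtype=float)
        starts = np.flatnonzero(np.r_[True, np.diff(t) < 0])
        bounds = list(starts) + [len(t)]
        for idx, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
            chunk = g.iloc[a:b]
            try:
                series.append(_series_from_chunk(chunk, idx, config))
            except ValueError as exc:
                n_rejected += 1
                logger.warning("rejected closure: %s", exc)
    if n_rejected:
        logger.warning("%d closure(s) rejected in %s", n_rejected, path)
    logger.info("read %d closure(s) from %s", len(series), path)
    return series


def _series_from_chunk(chunk: pd.DataFrame, idx: int,
                       config: RunConfig) -> ClosureSeries:
    first = chunk.iloc[0]
    pressure = None
    if "pressure" in chunk.columns and np.isfinite(first.get("pressure", np.nan)):
        pressure = float(first["pressure"])
    t = chunk["t"].to_numpy(dtype=float)
    return ClosureSeries(
        plot_id=str(first["plot_id"]),
        transect_id=str(first["transect_id"]),
        campaign=str(first["campaign"]),
        filter_count=int(first["filter_count"]),
        closure_index=idx,
        t=t - t[0],
        co2_wet=chunk["co2_wet"].to_numpy(),
        h2o=chunk["h2o"].to_numpy(),
        tair=chunk["tair"].to_numpy(),
        ppfd_in=chunk["ppfd_in"].to_numpy(),
        ppfd_out=chunk["ppfd_out"].to_numpy(),
        pressure=pressure,
        dead_band=config.dead_band,
        fit_window=config.fit_window,
    )


def write_table(df: pd.DataFrame, path: str | Path,
                units: dict[str, str] | None = None) -> None:
    """Write a result table as CSV with unit header comment lines.

    Column order is the DataFrame's order (deterministic); missing values
    are written as empty fields.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if units:
            for col in df.columns:
                if col in units:
                    fh.write(f"# {col}: {units[col]}\n")
        df.to_csv(fh, index=False, na_rep="")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a table written by :func:`write_table` (skips ``#`` comments)."""
    return pd.read_csv(path, comment="#")


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path,
                  units: dict[str, dict[str, str]] | None = None) -> list[Path]:
    """Write a set of named stage outputs under ``out_dir``.

    Returns the written paths (``<name>.csv`` per table).
    """
    out_dir = Path(out_dir)
    paths = []
    for name in sorted(tables):
        p = out_dir / f"{name}.csv"
        write_table(tables[name], p, (units or {}).get(name))
        paths.append(p)
    return paths


def closures_to_frame(series: list[ClosureSeries]) -> pd.DataFrame:
    """Flatten ClosureSeries back to the long-format closure table."""
    frames = []
    for s in series:
        frames.append(pd.DataFrame({
            "plot_id": s.plot_id, "transect_id": s.transect_id,
            "campaign": s.campaign, "filter_count": s.filter_count,
            "t": s.t, "co2_wet": s.co2_wet, "h2o": s.h2o,
            "ppfd_in": s.ppfd_in, "ppfd_out": s.ppfd_out, "tair": s.tair,
        }))
    if not frames:
        return pd.DataFrame(columns=CLOSURE_COLUMNS)
    return pd.concat(frames, ignore_index=True)
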