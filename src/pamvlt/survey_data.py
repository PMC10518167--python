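"""Survey geometry, domain types, forward-distance binning and file I/O.

Coordinate convention
---------------------
All geometry is ship-relative.  Forward distance is signed: positive ahead
of the ship, negative aft, zero at the ship/array reference point (the
towed-array layback is folded into the reference point, not modelled
separately).  The forward axis is divided into equally spaced bins; bin 1
is the farthest-ahead bin, at the maximum distance at which the towed
array detects whales, and indices increase toward and past the ship.
Because the ship moves at a constant speed, each distance bin also
represents a fixed unit of time (``bin_duration``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, InputError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "SurveyConfig",
    "VisualSighting",
    "AcousticEvent",
    "ClickRecord",
    "build_bin_grid",
    "bin_click_train",
    "radial_distance",
    "read_sightings",
    "read_events",
    "read_histories",
    "read_clicks",
    "write_sightings",
    "write_events",
    "write_histories",
    "write_clicks",
    "read_survey",
    "write_survey",
    "load_config",
    "save_config",
]


@dataclass(frozen=True)
class SurveyConfig:
    """Static configuration of a dual-platform survey.

    Parameters
    ----------
    truncation_perp_visual
        Perpendicular truncation distance W for the visual platform (m).
    truncation_perp_acoustic
        Perpendicular truncation distance for the acoustic platform (m).
    max_forward_ahead
        Farthest forward distance (m) ahead of the ship at which the towed
        array detects whales; the upper edge of bin 1.
    max_forward_behind
        Distance (m) aft of the ship covered by the grid (>= 0).
    bin_width
        Width of each forward-distance bin (m).
    ship_speed
        Ship speed (m/s), assumed constant.
    """

    truncation_perp_visual: float
    truncation_perp_acoustic: float
    max_forward_ahead: float
    max_forward_behind: float
    bin_width: float
    ship_speed: float

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ConfigurationError("bin_width must be > 0")
        if self.ship_speed <= 0:
            raise ConfigurationError("ship_speed must be > 0")
        if self.max_forward_behind < 0:
            raise ConfigurationError("max_forward_behind must be >= 0")
        if self.truncation_perp_visual <= 0 or self.truncation_perp_acoustic <= 0:
            raise ConfigurationError("perpendicular truncations must be > 0")
        if self.n_bins < 2:
            raise ConfigurationError(
                "grid must contain at least 2 bins; widen the forward span "
                "or narrow bin_width"
            )

    @property
    def bin_duration(self) -> float:
        """Time (s) the ship takes to traverse one bin."""
        return self.bin_width / self.ship_speed

    @property
    def n_bins(self) -> int:
        """Number of forward-distance bins J (ceil of span / width)."""
        span = self.max_forward_ahead + self.max_forward_behind
        return math.ceil(span / self.bin_width)


@dataclass
class VisualSighting:
    """One surface detection of a whale group by a visual team."""

    sighting_id: str
    team: int
    perp_distance: float
    group_size: int = 1
    duplicate_id: str | None = None
    covariates: Mapping[str, object] | None = None

    def __post_init__(self) -> None:
        if self.team not in (1, 2):
            raise InputError(f"team must be 1 or 2, got {self.team}")
        if self.perp_distance < 0:
            raise InputError("perp_distance must be >= 0")
        if self.group_size < 1:
            raise InputError("group_size must be >= 1")


@dataclass
class AcousticEvent:
    """One localized click train with a binary capture history over bins.

    ``history[j]`` is 1 when the whale was detected clicking in bin j+1 and
    0 otherwise; ``radial[j]`` is the radial distance from the array to the
    whale when it occupies bin j+1, computed from the localized
    perpendicular distance and the bin midpoint.
    """

    event_id: str
    perp_distance: float
    history: np.ndarray
    radial: np.ndarray
    fully_annotated: bool = True

    def __post_init__(self) -> None:
        self.history = np.asarray(self.history, dtype=int)
        self.radial = np.asarray(self.radial, dtype=float)
        if self.perp_distance < 0:
            raise InputError("perp_distance must be >= 0")
        if self.history.ndim != 1 or self.radial.shape != self.history.shape:
            raise InputError("history and radial must be 1-D and equal length")
        if not np.isin(self.history, (0, 1)).all():
            raise InputError("history entries must be 0 or 1")
        if self.history.sum() < 1:
            raise InputError("an observed event must have at least one detection")

    @classmethod
    def from_perp(
        cls,
        event_id: str,
        perp_distance: float,
        history: Sequence[int],
        config: SurveyConfig,
        fully_annotated: bool = True,
    ) -> "AcousticEvent":
        """Build an event, deriving the radial vector from the bin grid."""
        mids = build_bin_grid(config)
        radial = radial_distance(perp_distance, mids)
        return cls(event_id, perp_distance, np.asarray(history), radial,
                   fully_annotated)


@dataclass(frozen=True)
class ClickRecord:
    """One detected click, time-stamped, with signed forward distance."""

    event_id: str
    time: float
    forward_distance: float


def build_bin_grid(config: SurveyConfig) -> np.ndarray:
    """Return signed forward-distance midpoints of the J bins.

    Bin 1 sits at the top of the grid (upper edge at ``max_forward_ahead``)
    and indices increase toward and past the ship, so the returned array is
    strictly decreasing.  When the span is not an exact multiple of
    ``bin_width`` the final (aft-most) bin is a full-width bin extending
    past ``-max_forward_behind`` (ceil rounding).
    """
    j = np.arange(1, config.n_bins + 1)
    return config.max_forward_ahead - (j - 0.5) * config.bin_width


def radial_distance(perp: float | np.ndarray, forward_midpoint: float | np.ndarray):
    """Euclidean radial distance from perpendicular and forward offsets.

    Symmetric in the sign of ``forward_midpoint`` (bins aft of the ship
    are as far away as their mirror image ahead).
    """
    perp = np.asarray(perp, dtype=float)
    if np.any(perp < 0):
        raise InputError("perpendicular distance must be >= 0")
    out = np.hypot(perp, np.asarray(forward_midpoint, dtype=float))
    return float(out) if out.ndim == 0 else out


def bin_click_train(
    clicks: Sequence[ClickRecord], config: SurveyConfig
) -> np.ndarray:
    """Collapse a click train to a binary capture history over the bin grid.

    Each click's forward distance at its own time is reconstructed from the
    forward distance of the first recorded click and the constant ship
    speed; bin j receives a 1 when at least one click falls in it.  Clicks
    that convert to positions outside the grid are dropped with a logged
    count.  A click exactly on a bin boundary is assigned to the earlier
    (farther-ahead) bin.
    """
    if len(clicks) == 0:
        raise InputError("click train is empty")
    times = np.array([c.time for c in clicks], dtype=float)
    if np.any(np.diff(times) < 0):
        raise InputError("click times within an event must be non-decreasing")
    t0 = times[0]
    f0 = clicks[0].forward_distance
    # the whale is treated as horizontally stationary; the ship advances
    forward = f0 - config.ship_speed * (times - t0)

    a, w, j_max = config.max_forward_ahead, config.bin_width, config.n_bins
    idx = np.ceil((a - forward) / w).astype(int)
    idx[forward == a] = 1  # top edge of the grid belongs to bin 1
    inside = (idx >= 1) & (idx <= j_max)
    n_dropped = int((~inside).sum())
    if n_dropped:
        logger.warning("bin_click_train: %d click(s) outside the grid dropped",
                       n_dropped)
    history = np.zeros(j_max, dtype=int)
    history[idx[inside] - 1] = 1
    return history


# ---------------------------------------------------------------------------
# File I/O.  CSV, UTF-8, header row.  Unknown columns are preserved.
# ---------------------------------------------------------------------------

_SIGHTING_COLS = ["sighting_id", "team", "perp_distance_m", "group_size",
                  "duplicate_id"]
_EVENT_COLS = ["event_id", "perp_distance_m", "fully_annotated"]
_CLICK_COLS = ["event_id", "time_s", "forward_distance_m"]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    for c in cols:
        if c not in df.columns:
            raise SchemaError(f"{what}: missing mandatory column '{c}'")


def read_sightings(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sighting_id": str, "duplicate_id": str})
    _require_columns(df, _SIGHTING_COLS, "sightings")
    if df["sighting_id"].duplicated().any():
        raise ValidationError("sightings: duplicated sighting_id values")
    if not df["team"].isin([1, 2]).all():
        raise ValidationError("sightings: team must be 1 or 2")
    return df


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"event_id": str})
    _require_columns(df, _EVENT_COLS, "events")
    if df["event_id"].duplicated().any():
        raise ValidationError("events: duplicated event_id rows")
    return df


def read_histories(path: str | Path) -> pd.DataFrame:
    """Read wide-format capture histories (event_id, bin_1 ... bin_J)."""
    df = pd.read_csv(path, dtype={"event_id": str})
    _require_columns(df, ["event_id", "bin_1"], "histories")
    bin_cols = [c for c in df.columns if c.startswith("bin_")]
    vals = df[bin_cols].to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValidationError("histories: bin entries must be 0 or 1")
    return df


def read_clicks(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"event_id": str})
    _require_columns(df, _CLICK_COLS, "clicks")
    return df


def write_sightings(df: pd.DataFrame, path: str | Path) -> None:
    _require_columns(df, _SIGHTING_COLS, "sightings")
    df.to_csv(path, index=False)


def write_events(df: pd.DataFrame, path: str | Path) -> None:
    _require_columns(df, _EVENT_COLS, "events")
    df.to_csv(path, index=False)


def write_histories(df: pd.DataFrame, path: str | Path) -> None:
    _require_columns(df, ["event_id", "bin_1"], "histories")
    df.to_csv(path, index=False)


def write_clicks(df: pd.DataFrame, path: str | Path) -> None:
    _require_columns(df, _CLICK_COLS, "clicks")
    df.to_csv(path, index=False)


def read_survey(directory: str | Path) -> dict[str, pd.DataFrame]:
    """Read a survey bundle directory into a name -> table mapping.

    Looks for ``sightings.csv``, ``events.csv``, ``histories.csv`` and
    ``clicks.csv``; only files that exist are loaded.
    """
    directory = Path(directory)
    readers = {
        "sightings": read_sightings,
        "events": read_events,
        "histories": read_histories,
        "clicks": read_clicks,
    }
    out: dict[str, pd.DataFrame] = {}
    for name, reader in readers.items():
        p = directory / f"{name}.csv"
        if p.exists():
            out[name] = reader(p)
    if not out:
        raise InputError(f"no survey tables found in {directory}")
    return out


def write_survey(tables: Mapping[str, pd.DataFrame], directory: str | Path) -> None:
    """Write a name -> table mapping as a survey bundle directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    writers = {
        "sightings": write_sightings,
        "events": write_events,
        "histories": write_histories,
        "clicks": write_clicks,
    }
    for name, df in tables.items():
        if name not in writers:
            raise InputError(f"unknown survey table '{name}'")
        writers[name](df, directory / f"{name}.csv")


_CONFIG_FIELDS = [
    "truncation_perp_visual",
    "truncation_perp_acoustic",
    "max_forward_ahead",
    "max_forward_behind",
    "bin_width",
    "ship_speed",
]


def load_config(path: str | Path) -> SurveyConfig:
    """Load a SurveyConfig from a YAML file mirroring its field names."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    missing = [f for f in _CONFIG_FIELDS if f not in raw]
    if missing:
        raise SchemaError(f"config: missing field(s) {missing}")
    return SurveyConfig(**{f: float(raw[f]) for f in _CONFIG_FIELDS})


def save_config(config: SurveyConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({f: getattr(config, f) for f in _CONFIG_FIELDS}, fh)


def events_from_tables(
    events: pd.DataFrame, histories: pd.DataFrame, config: SurveyConfig
) -> list[AcousticEvent]:
    """Join an events table with a wide histories table into AcousticEvents."""
    bin_cols = [c for c in histories.columns if c.startswith("bin_")]
    if len(bin_cols) != config.n_bins:
        raise ValidationError(
            f"histories have {len(bin_cols)} bins but config defines "
            f"{config.n_bins}"
        )
    hmap = {r["event_id"]: r[bin_cols].to_numpy(dtype=int)
            for _, r in histories.iterrows()}
    out = []
    for _, row in events.iterrows():
        eid = row["event_id"]
        if eid not in hmap:
            raise ValidationError(f"event {eid} has no capture history")
        out.append(
            AcousticEvent.from_perp(
                eid, float(row["perp_distance_m"]), hmap[eid], config,
                fully_annotated=bool(row["fully_annotated"]),
            )
        )
    return out
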