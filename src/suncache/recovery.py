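"""Cache-fate analysis: PRE24/A24 classification by solar-arc symmetry,
azimuthal accuracy, the equality-of-proportions test and theft summaries.

A recovered cache is compared against two reference solar azimuths computed
at the burrow: ``theta_a``, the azimuth 24 h after caching, and ``theta_b``,
its North-South mirror (the same position on the opposite half of the solar
arc).  Whichever is circularly closer to the azimuth at the recovery instant
decides the category (A24 on ties).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError
from .solar import GeoPoint, mirrored_azimuth, solar_position

__all__ = [
    "CacheFate",
    "RecoveryClassification",
    "ProportionTestResult",
    "circular_dist_deg",
    "classify_recovery",
    "proportion_test",
    "theft_summary",
    "read_events_csv",
    "classification_table",
]

OUTCOMES = ("recovered_by_cacher", "stolen", "intact")


@dataclass(frozen=True)
class CacheFate:
    cache_id: str
    cache_time: datetime
    cache_loc: GeoPoint
    burrow_loc: GeoPoint
    outcome: str
    event_time: Optional[datetime] = None
    group_size: Optional[int] = None
    group_id: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise InvalidInputError(f"unknown outcome {self.outcome!r}")
        if self.outcome == "intact" and self.event_time is not None:
            raise InvalidInputError("intact cache cannot have an event time")
        if self.event_time is not None and self.event_time <= self.cache_time:
            raise InvalidInputError(
                f"cache {self.cache_id}: event_time must follow cache_time"
            )


@dataclass(frozen=True)
class RecoveryClassification:
    cache_id: str
    theta_a_deg: float  # solar azimuth 24 h after caching
    theta_b_deg: float  # North-South mirror of theta_a
    az_recovery_deg: float
    az_cache_deg: float
    category: str  # "A24" | "PRE24"
    az_error_deg: float  # min over {cache azimuth, its mirror}
    dist_to_cache_az_deg: float
    dist_to_mirror_az_deg: float
    elevation_at_cache_deg: float
    elevation_at_recovery_deg: float


@dataclass(frozen=True)
class ProportionTestResult:
    k: int
    n: int
    p0: float
    chi2: float
    p: float
    continuity: bool


def circular_dist_deg(a: float, b: float) -> float:
    """Shortest angular distance between two azimuths, degrees in [0, 180]."""
    d = abs((a - b) % 360.0)
    return min(d, 360.0 - d)


def classify_recovery(fate: CacheFate) -> RecoveryClassification:
    """Classify one recovered cache as A24 or PRE24.

    All azimuths are computed at the burrow centre.  Recoveries with the sun
    below the horizon cannot be referenced to the solar arc and raise
    :class:`InvalidInputError`.
    """
    if fate.outcome != "recovered_by_cacher" or fate.event_time is None:
        raise InvalidInputError(
            f"cache {fate.cache_id}: classification needs a recovered cache with event time"
        )
    loc = fate.burrow_loc
    sun_cache = solar_position(fate.cache_time, loc)
    sun_rec = solar_position(fate.event_time, loc)
    if sun_rec.elevation_deg < 0:
        raise InvalidInputError(
            f"cache {fate.cache_id}: recovery at night (sun below horizon); unclassifiable"
        )
    theta_a = solar_position(fate.cache_time + timedelta(hours=24), loc).azimuth_deg
    theta_b = mirrored_azimuth(theta_a)
    d_a = circular_dist_deg(sun_rec.azimuth_deg, theta_a)
    d_b = circular_dist_deg(sun_rec.azimuth_deg, theta_b)
    category = "A24" if d_a <= d_b else "PRE24"  # tie -> A24
    d_cache = circular_dist_deg(sun_rec.azimuth_deg, sun_cache.azimuth_deg)
    d_mirror = circular_dist_deg(sun_rec.azimuth_deg, mirrored_azimuth(sun_cache.azimuth_deg))
    return RecoveryClassification(
        cache_id=fate.cache_id,
        theta_a_deg=theta_a,
        theta_b_deg=theta_b,
        az_recovery_deg=sun_rec.azimuth_deg,
        az_cache_deg=sun_cache.azimuth_deg,
        category=category,
        az_error_deg=min(d_cache, d_mirror),
        dist_to_cache_az_deg=d_cache,
        dist_to_mirror_az_deg=d_mirror,
        elevation_at_cache_deg=sun_cache.elevation_deg,
        elevation_at_recovery_deg=sun_rec.elevation_deg,
    )


def proportion_test(k: int, n: int, p0: float = 0.5,
                    continuity: bool = True) -> ProportionTestResult:
    """One-sample equality-of-proportions chi-squared test.

    With Yates continuity correction:
    ``chi2 = (max(0, |k - n p0| - 1/2))^2 / (n p0 (1 - p0))``,
    referred to a chi-squared distribution with 1 df.
    """
    if n < 1 or k < 0 or k > n:
        raise InvalidInputError(f"invalid counts k={k}, n={n}")
    if not 0 < p0 < 1:
        raise InvalidInputError(f"p0 must be in (0, 1), got {p0}")
    dev = abs(k - n * p0)
    if continuity:
        dev = max(0.0, dev - 0.5)
    chi2 = dev * dev / (n * p0 * (1.0 - p0))
    p = float(stats.chi2.sf(chi2, df=1))
    return ProportionTestResult(k=k, n=n, p0=p0, chi2=chi2, p=p, continuity=continuity)


def theft_summary(fates: Iterable[CacheFate]) -> dict:
    """Theft/recovery summary over monitored caches.

    Proportions are over all monitored caches (stolen) and over stolen /
    recovered caches with known event times (within-24 h rates); recovery
    time statistics cover caches recovered by the cacher.
    """
    fates = list(fates)
    if not fates:
        raise InvalidInputError("no cache fates supplied")
    n = len(fates)
    stolen = [f for f in fates if f.outcome == "stolen"]
    recovered = [f for f in fates if f.outcome == "recovered_by_cacher"]

    def _lag_h(f: CacheFate) -> float:
        return (f.event_time - f.cache_time).total_seconds() / 3600.0

    stolen_lags = [_lag_h(f) for f in stolen if f.event_time is not None]
    rec_lags = [_lag_h(f) for f in recovered if f.event_time is not None]
    out = {
        "n_monitored": n,
        "n_stolen": len(stolen),
        "n_recovered": len(recovered),
        "n_intact": sum(f.outcome == "intact" for f in fates),
        "prop_stolen": len(stolen) / n,
        "prop_stolen_within_24h": (
            sum(l <= 24.0 for l in stolen_lags) / len(stolen_lags) if stolen_lags else None
        ),
        "n_stolen_within_24h": sum(l <= 24.0 for l in stolen_lags),
        "prop_recovered_within_24h": (
            sum(l <= 24.0 for l in rec_lags) / len(rec_lags) if rec_lags else None
        ),
        "n_recovered_within_24h": sum(l <= 24.0 for l in rec_lags),
        "mean_recovery_h": float(np.mean(rec_lags)) if rec_lags else None,
        "sd_recovery_h": float(np.std(rec_lags, ddof=1)) if len(rec_lags) > 1 else None,
    }
    return out


# ---------------------------------------------------------------------------
# I/O

EVENTS_COLUMNS = [
    "cache_id", "group_id", "subject_id", "cache_time_utc",
    "cache_lat", "cache_lon", "burrow_lat", "burrow_lon",
    "outcome", "event_time_utc", "group_size",
]


def read_events_csv(path) -> list[CacheFate]:
    df = pd.read_csv(path, dtype={"cache_id": str, "group_id": str, "subject_id": str})
    missing = [c for c in EVENTS_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"events CSV missing columns: {missing}")
    fates = []
    for idx, r in df.iterrows():
        try:
            cache_t = pd.Timestamp(r["cache_time_utc"], tz="UTC").to_pydatetime()
            event_t = None
            if pd.notna(r["event_time_utc"]) and str(r["event_time_utc"]).strip():
                event_t = pd.Timestamp(r["event_time_utc"], tz="UTC").to_pydatetime()
            fates.append(
                CacheFate(
                    cache_id=str(r["cache_id"]),
                    group_id=str(r["group_id"]),
                    subject_id=str(r["subject_id"]),
                    cache_time=cache_t,
                    cache_loc=GeoPoint(float(r["cache_lat"]), float(r["cache_lon"])),
                    burrow_loc=GeoPoint(float(r["burrow_lat"]), float(r["burrow_lon"])),
                    outcome=str(r["outcome"]),
                    event_time=event_t,
                    group_size=int(r["group_size"]) if pd.notna(r["group_size"]) else None,
                )
            )
        except (ValueError, InvalidInputError) as exc:
            raise InvalidInputError(f"events CSV row {idx + 2}: {exc}") from exc
    return fates


def classification_table(fates: Iterable[CacheFate]) -> pd.DataFrame:
    """Classify every recoverable cache; unclassifiable ones are recorded
    with a reason instead of failing the batch."""
    rows = []
    for f in fates:
        if f.outcome != "recovered_by_cacher" or f.event_time is None:
            continue
        base = {
            "cache_id": f.cache_id,
            "group_id": f.group_id,
            "subject_id": f.subject_id,
            "group_size": f.group_size,
            "recovery_lag_h": (f.event_time - f.cache_time).total_seconds() / 3600.0,
        }
        try:
            c = classify_recovery(f)
        except InvalidInputError as exc:
            rows.append({**base, "category": "unclassifiable", "reason": str(exc)})
            continue
        rows.append({
            **base,
            "category": c.category,
            "theta_a_deg": c.theta_a_deg,
            "theta_b_deg": c.theta_b_deg,
            "az_cache_deg": c.az_cache_deg,
            "az_recovery_deg": c.az_recovery_deg,
            "az_error_deg": c.az_error_deg,
            "dist_to_cache_az_deg": c.dist_to_cache_az_deg,
            "dist_to_mirror_az_deg": c.dist_to_mirror_az_deg,
            "elevation_at_cache_deg": c.elevation_at_cache_deg,
            "elevation_at_recovery_deg": c.elevation_at_recovery_deg,
            "reason": "",
        })
    return pd.DataFrame(rows)
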