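"""Seeded synthetic-data generator.

Produces fix and cache-event tables with the statistical structure the
analysis pipeline assumes: near-straight provisioning-to-cache tracks whose
bearings sit at a bimodal mixture of offsets from the solar azimuth,
observation sessions at the four daylight-division time points, theft
hazard increasing with group size, and recoveries timed near either the
+24 h solar position or its North-South mirror.  Every latent draw is
recorded in a truth dictionary so estimator output can be scored against
the generating process.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field, replace
from datetime import date as _date
from datetime import datetime, timedelta, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidComparisonError, InvalidConfigError
from .solar import GeoPoint, STUDY_SITE, mirrored_azimuth, observation_periods, solar_position
from .tracks import inverse_local_xy, local_xy

__all__ = ["SynthConfig", "generate", "truth_compare", "azimuth_crossing_time"]

_HALF_PI = math.pi / 2


@dataclass(frozen=True)
class MixtureTruth:
    lam: float = 0.45  # weight of the left-of-sun component (calibration choice)
    mu1: float = -1.01
    mu2: float = 0.59
    sigma1: float = 0.35  # calibration choice; field study reports SEs, not SDs
    sigma2: float = 0.40


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 0
    site_lat: float = STUDY_SITE.lat_deg
    site_lon: float = STUDY_SITE.lon_deg
    start_date: str = "2014-04-01"
    end_date: str = "2014-07-31"
    n_groups: int = 5
    n_subjects: int = 9  # allocated round-robin across groups
    group_size_range: tuple = (3, 36)
    days_per_subject: int = 3
    sessions_per_day: int = 4
    tracks_per_session: int = 5
    mixture: MixtureTruth = field(default_factory=MixtureTruth)
    p_toward_sun: float = 0.5
    straightness_target: float = 0.89
    straightness_sd: float = 0.15
    gps_sd_m: float = 1.5
    track_length_range_m: tuple = (8.0, 30.0)
    start_cluster_sd_m: float = 12.0
    start_outlier_prob: float = 0.1
    start_outlier_range_m: tuple = (40.0, 90.0)
    burrow_spacing_m: float = 400.0
    theft_base_hazard_per_h: float = 0.02
    theft_hazard_per_individual_per_h: float = 0.0025
    audience_prob: float = 0.6  # fraction of the group present at any event
    monitoring_days: float = 5.0
    p_pre24_intercept: float = 0.0
    p_pre24_slope: float = 0.08  # per individual above the mid group size
    recovery_jitter_min: float = 30.0
    walking_speed_m_s: float = 0.5

    @property
    def site(self) -> GeoPoint:
        return GeoPoint(self.site_lat, self.site_lon)

    def validate(self) -> None:
        if not 0 < self.straightness_target <= 1:
            raise InvalidConfigError("straightness_target must be in (0, 1]")
        for p in (self.p_toward_sun, self.start_outlier_prob):
            if not 0 <= p <= 1:
                raise InvalidConfigError(f"probability {p} outside [0, 1]")
        if self.mixture.sigma1 <= 0 or self.mixture.sigma2 <= 0:
            raise InvalidConfigError("mixture sigmas must be > 0")
        if not 0 < self.mixture.lam < 1:
            raise InvalidConfigError("mixture lambda must be in (0, 1)")
        if self.gps_sd_m < 0 or self.straightness_sd < 0:
            raise InvalidConfigError("noise scales must be >= 0")
        y0 = _date.fromisoformat(self.start_date).year
        y1 = _date.fromisoformat(self.end_date).year
        if not (1950 <= y0 and y1 <= 2050):
            raise InvalidConfigError("dates outside ephemeris validity (1950-2050)")
        if _date.fromisoformat(self.end_date) < _date.fromisoformat(self.start_date):
            raise InvalidConfigError("end_date before start_date")

    def noise_free(self) -> "SynthConfig":
        """Copy of this config with every noise source switched off."""
        return replace(
            self,
            gps_sd_m=0.0,
            straightness_target=1.0,
            straightness_sd=0.0,
            recovery_jitter_min=0.0,
        )

    def run_id(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# helpers


def _truncated_normal(rng, mu, sigma, lo, hi):
    for _ in range(10000):
        v = rng.normal(mu, sigma)
        if lo <= v <= hi:
            return v
    return min(max(mu, lo), hi)


def _straightness_params(target, sd):
    """Beta(a, b) on (0, 1] matching the requested mean/SD (left-skewed
    toward 1 for means near 1, like observed straightness indices)."""
    var = sd * sd
    max_var = target * (1 - target)
    if var >= max_var:
        var = 0.9 * max_var
    k = target * (1 - target) / var - 1
    return target * k, (1 - target) * k


def _zigzag_amplitude(step, n_mid, s):
    """Lateral amplitude for alternating +/-A interior offsets so the
    zigzag path is 1/s times the straight-line distance."""
    if s >= 1.0 or n_mid == 0:
        return 0.0
    d = step * (n_mid + 1)
    target = d / s

    def path(a):
        return 2 * math.hypot(step, a) + (n_mid - 1) * math.hypot(step, 2 * a)

    lo, hi = 0.0, 10.0 * d
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if path(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def azimuth_crossing_time(target_az_deg: float, t0: datetime, t1: datetime,
                          loc: GeoPoint, tol_s: float = 0.5) -> datetime | None:
    """First instant in (t0, t1) when the solar azimuth equals ``target``.

    Scans a coarse grid for a sign change of the wrapped azimuth difference,
    then bisects.  Returns None when no crossing exists in the window.
    """

    def diff(t):
        d = (solar_position(t, loc).azimuth_deg - target_az_deg + 180.0) % 360.0 - 180.0
        return d

    step = timedelta(minutes=10)
    t_prev, d_prev = t0, diff(t0)
    t = t0 + step
    while t_prev < t1:
        t_cur = min(t, t1)
        d_cur = diff(t_cur)
        if d_prev == 0.0:
            return t_prev
        if d_prev * d_cur < 0 and abs(d_cur - d_prev) < 180.0:  # genuine crossing
            lo, hi, d_lo = t_prev, t_cur, d_prev
            while (hi - lo).total_seconds() > tol_s:
                mid = lo + (hi - lo) / 2
                d_mid = diff(mid)
                if d_lo * d_mid <= 0:
                    hi = mid
                else:
                    lo, d_lo = mid, d_mid
            return lo + (hi - lo) / 2
        t_prev, d_prev = t_cur, d_cur
        t += step
    return None


# ---------------------------------------------------------------------------
# generation


def generate(config: SynthConfig, out_dir=None):
    """Generate fix and event tables plus the latent-truth record.

    Returns ``(fixes_df, events_df, truth)``; when ``out_dir`` is given the
    three artefacts are also written as ``fixes.csv``, ``events.csv`` and
    ``truth.json`` (byte-identical for identical configs).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    site = config.site
    mix = config.mixture
    d0 = _date.fromisoformat(config.start_date)
    d1 = _date.fromisoformat(config.end_date)
    n_days_avail = (d1 - d0).days + 1

    # groups: burrow locations on a line (a dry riverbed), sizes, subjects
    groups = []
    for g in range(config.n_groups):
        off_x = (g - (config.n_groups - 1) / 2) * config.burrow_spacing_m
        burrow = inverse_local_xy(off_x, 0.0, site)
        size = int(rng.integers(config.group_size_range[0], config.group_size_range[1] + 1))
        groups.append({"group_id": f"G{g+1}", "burrow": burrow, "size": size})
    subjects = [
        {"subject_id": f"S{s+1}", "group": groups[s % config.n_groups]}
        for s in range(config.n_subjects)
    ]

    a_beta, b_beta = (None, None)
    if config.straightness_sd > 0 and config.straightness_target < 1:
        a_beta, b_beta = _straightness_params(config.straightness_target, config.straightness_sd)

    mid_size = 0.5 * (config.group_size_range[0] + config.group_size_range[1])
    fix_rows, event_rows = [], []
    truth_tracks, truth_caches = {}, {}
    schedule_cache: dict = {}

    for subj in subjects:
        grp = subj["group"]
        burrow = grp["burrow"]
        day_offsets = sorted(rng.choice(n_days_avail, size=min(config.days_per_subject, n_days_avail), replace=False).tolist())
        for day_off in day_offsets:
            day = d0 + timedelta(days=int(day_off))
            if day not in schedule_cache:
                schedule_cache[day] = observation_periods(day, site)
            sched = schedule_cache[day]
            for si in range(min(config.sessions_per_day, 4)):
                period_start = sched.period_starts[si]
                for nut in range(config.tracks_per_session):
                    tid = f"{subj['subject_id']}_{day.isoformat()}_p{si+1}_n{nut+1}"
                    t_start = period_start + timedelta(minutes=6 * nut)

                    # start point clustered near the burrow, occasional far foray
                    if rng.random() < config.start_outlier_prob:
                        r = rng.uniform(*config.start_outlier_range_m)
                        th = rng.uniform(0, 2 * math.pi)
                        sx, sy = r * math.cos(th), r * math.sin(th)
                    else:
                        sx, sy = rng.normal(0, config.start_cluster_sd_m, 2)
                    bx, by = local_xy(burrow, site)
                    sx, sy = sx + bx, sy + by

                    # latent angular draw
                    comp = 1 if rng.random() < mix.lam else 2
                    mu, sg = (mix.mu1, mix.sigma1) if comp == 1 else (mix.mu2, mix.sigma2)
                    refl = _truncated_normal(rng, mu, sg, -_HALF_PI, _HALF_PI)
                    toward = rng.random() < config.p_toward_sun
                    rel = refl if toward else math.copysign(math.pi - abs(refl), refl)

                    length = rng.uniform(*config.track_length_range_m)
                    n_mid = int(rng.integers(2, 6))
                    if config.straightness_target >= 1.0:
                        s_draw = 1.0
                    elif a_beta is None:
                        s_draw = config.straightness_target
                    else:
                        s_draw = float(np.clip(rng.beta(a_beta, b_beta), 0.05, 1.0))

                    # bearing set against the azimuth at the (approximate)
                    # cache instant so the analysis recovers `rel` exactly
                    walk_t = (length / s_draw) / config.walking_speed_m_s
                    t_cache = t_start + timedelta(seconds=walk_t)
                    az = solar_position(t_cache, site).azimuth_deg
                    brg = math.radians(az) + rel

                    # geometry is laid out in a frame centred on the start
                    # point, so the analysis-side bearing (projected about
                    # the first fix) recovers the latent angle exactly
                    start_gp = inverse_local_xy(sx, sy, site)
                    ux, uy = math.sin(brg), math.cos(brg)  # along-track unit
                    px, py = uy, -ux  # lateral unit
                    step = length / (n_mid + 1)
                    amp = _zigzag_amplitude(step, n_mid, s_draw)
                    pts = [(0.0, 0.0)]
                    for i in range(1, n_mid + 1):
                        a_i = amp * (1 if i % 2 == 1 else -1)
                        pts.append((ux * step * i + px * a_i,
                                    uy * step * i + py * a_i))
                    pts.append((ux * length, uy * length))

                    if config.gps_sd_m > 0:
                        noise = rng.normal(0, config.gps_sd_m / math.sqrt(2), (len(pts), 2))
                        pts = [(x + nx, y + ny) for (x, y), (nx, ny) in zip(pts, noise)]

                    # timestamps along the actual zigzag path
                    t_fix = t_start
                    prev = pts[0]
                    times = [t_fix]
                    for p in pts[1:]:
                        dt = max(1.0, math.dist(prev, p) / config.walking_speed_m_s)
                        t_fix = t_fix + timedelta(seconds=dt)
                        times.append(t_fix)
                        prev = p
                    roles = ["start"] + ["mid"] * n_mid + ["stop"]
                    for (x, y), t, role in zip(pts, times, roles):
                        gp = inverse_local_xy(x, y, start_gp)
                        fix_rows.append({
                            "track_id": tid,
                            "subject_id": subj["subject_id"],
                            "group_id": grp["group_id"],
                            "lat": gp.lat_deg,
                            "lon": gp.lon_deg,
                            "timestamp_utc": t.strftime("%Y-%m-%dT%H:%M:%S.%f+00:00"),
                            "fix_role": role,
                        })
                    cache_time = times[-1]
                    truth_tracks[tid] = {
                        "component": comp,
                        "reflected_rad": refl,
                        "rel_angle_rad": rel,
                        "toward_sun": bool(toward),
                        "bearing_deg": math.degrees(brg) % 360.0,
                        "sun_azimuth_deg": az,
                        "straightness": s_draw,
                        "length_m": length,
                        "obs_period": si + 1,
                    }

                    # ---- cache fate ------------------------------------
                    theta_a_t = cache_time + timedelta(hours=24)
                    theta_a = solar_position(theta_a_t, site).azimuth_deg
                    # individuals present fluctuate around the group roster;
                    # theft pressure and early (PRE24) recovery scale with them
                    n_present = 1 + int(rng.binomial(grp["size"] - 1, config.audience_prob))
                    rate = (config.theft_base_hazard_per_h
                            + config.theft_hazard_per_individual_per_h * n_present)
                    theft_h = float(rng.exponential(1.0 / rate))
                    logit = (config.p_pre24_intercept
                             + config.p_pre24_slope * (n_present - config.audience_prob * mid_size))
                    p_pre24 = 1.0 / (1.0 + math.exp(-logit))
                    want_pre24 = rng.random() < p_pre24
                    jitter_s = (rng.normal(0, config.recovery_jitter_min * 60.0)
                                if config.recovery_jitter_min > 0 else 0.0)
                    if want_pre24:
                        t_mirror = azimuth_crossing_time(
                            mirrored_azimuth(theta_a), cache_time + timedelta(minutes=2),
                            theta_a_t, site)
                        if t_mirror is None:  # no mirror instant: fall back to A24
                            want_pre24 = False
                            t_recover = theta_a_t + timedelta(seconds=jitter_s)
                        else:
                            t_recover = t_mirror + timedelta(seconds=jitter_s)
                    else:
                        t_recover = theta_a_t + timedelta(seconds=jitter_s)
                    recover_h = (t_recover - cache_time).total_seconds() / 3600.0

                    if theft_h < recover_h:
                        if theft_h <= config.monitoring_days * 24.0:
                            outcome = "stolen"
                            event_time = cache_time + timedelta(hours=theft_h)
                        else:
                            outcome, event_time = "intact", None
                    else:
                        outcome = "recovered_by_cacher"
                        event_time = t_recover

                    cache_gp = inverse_local_xy(*pts[-1], start_gp)
                    event_rows.append({
                        "cache_id": tid,
                        "group_id": grp["group_id"],
                        "subject_id": subj["subject_id"],
                        "cache_time_utc": cache_time.strftime("%Y-%m-%dT%H:%M:%S.%f+00:00"),
                        "cache_lat": cache_gp.lat_deg,
                        "cache_lon": cache_gp.lon_deg,
                        "burrow_lat": burrow.lat_deg,
                        "burrow_lon": burrow.lon_deg,
                        "outcome": outcome,
                        "event_time_utc": (
                            event_time.strftime("%Y-%m-%dT%H:%M:%S.%f+00:00")
                            if event_time is not None else ""
                        ),
                        "group_size": n_present,
                    })
                    truth_caches[tid] = {
                        "intended_category": "PRE24" if want_pre24 else "A24",
                        "outcome": outcome,
                        "theft_h": theft_h,
                        "theft_rate_per_h": rate,
                        "p_pre24": p_pre24,
                        "recovery_jitter_s": jitter_s,
                        "group_size": n_present,
                        "group_roster_size": grp["size"],
                    }

    fixes_df = pd.DataFrame(fix_rows)
    events_df = pd.DataFrame(event_rows)
    truth = {
        "run_id": config.run_id(),
        "config": asdict(config),
        "groups": [
            {"group_id": g["group_id"], "size": g["size"],
             "burrow_lat": g["burrow"].lat_deg, "burrow_lon": g["burrow"].lon_deg}
            for g in groups
        ],
        "tracks": truth_tracks,
        "caches": truth_caches,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fixes_df.to_csv(out / "fixes.csv", index=False, float_format="%.12f")
        events_df.to_csv(out / "events.csv", index=False, float_format="%.12f")
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True, default=str)
    return fixes_df, events_df, truth


# ---------------------------------------------------------------------------
# truth scoring


def truth_compare(truth: dict, pipeline_report: dict) -> dict:
    """Score pipeline estimates against the generator's latent truth.

    ``pipeline_report`` is the combined report produced by the CLI pipeline
    (must carry the same ``run_id``).
    """
    if truth.get("run_id") != pipeline_report.get("run_id"):
        raise InvalidComparisonError(
            f"run_id mismatch: truth {truth.get('run_id')} vs "
            f"report {pipeline_report.get('run_id')}"
        )
    out: dict = {"run_id": truth["run_id"]}

    mix_cfg = truth["config"]["mixture"]
    fit = pipeline_report.get("mixture_fit")
    if fit:
        out["mixture_errors"] = {
            "lambda": fit["lambda"] - mix_cfg["lam"],
            "mu1": fit["mu1"] - mix_cfg["mu1"],
            "mu2": fit["mu2"] - mix_cfg["mu2"],
            "sigma1": fit["sigma1"] - mix_cfg["sigma1"],
            "sigma2": fit["sigma2"] - mix_cfg["sigma2"],
        }

    cls = pipeline_report.get("classifications")
    if cls:
        confusion = {"A24": {"A24": 0, "PRE24": 0}, "PRE24": {"A24": 0, "PRE24": 0}}
        n_match = n_tot = 0
        for row in cls:
            intended = truth["caches"].get(row["cache_id"], {}).get("intended_category")
            got = row.get("category")
            if intended in confusion and got in ("A24", "PRE24"):
                confusion[intended][got] += 1
                n_tot += 1
                n_match += intended == got
        out["classification"] = {
            "confusion": confusion,
            "n": n_tot,
            "accuracy": n_match / n_tot if n_tot else None,
        }

    models = pipeline_report.get("models")
    if models:
        slopes = {}
        a = models.get("a_track_vs_sun", {})
        if not a.get("skipped", True):
            slopes["track_vs_sun_slope"] = a["coefficients"].get("sun_signed")
        d = models.get("d_survival_vs_group_size", {})
        if not d.get("skipped", True):
            slopes["survival_vs_group_size_slope"] = d["coefficients"].get("group_size")
        out["model_slopes"] = slopes
    return out
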