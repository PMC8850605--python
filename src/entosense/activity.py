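"""Activity aggregation and sensor-versus-trap comparison statistics.

Sensor events are binned per device and day (or hour) and normalised by
sensor uptime; trap catches are aligned to the emptying schedule (a trap
not emptied on a Sunday pools its catch into the following collection, and
counts are normalised by the number of trapping days covered).  The two
methods are then compared on the days where both are available, with
Spearman's rank correlation and an ordinary least-squares fit.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

__all__ = [
    "ActivitySeries",
    "ComparisonResult",
    "StudySummary",
    "bin_events",
    "counts_to_activity",
    "align_trap_schedule",
    "spearman",
    "compare_methods",
    "summarize_study",
    "plot_comparison",
]


@dataclass
class ActivitySeries:
    """Binned, uptime-normalised event counts of one device."""

    device_id: str
    table: pd.DataFrame  # columns: bin, count, uptime, normalized


@dataclass
class ComparisonResult:
    """Paired-day comparison between sensor and trap daily means."""

    days: list[str]
    sensor_means: list[float]
    trap_means: list[float]
    spearman_rho: float | None
    p_value: float | None
    slope: float | None
    intercept: float | None
    n_days: int = 0
    excluded_dates: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_days": self.n_days,
            "spearman_rho": self.spearman_rho,
            "p_value": self.p_value,
            "slope": self.slope,
            "intercept": self.intercept,
            "days": self.days,
            "sensor_means": self.sensor_means,
            "trap_means": self.trap_means,
            "excluded_dates": self.excluded_dates,
        }


@dataclass
class StudySummary:
    """Per-method daily means with standard errors and their ratio.

    Two sensor/trap ratios are reported and labelled: one from the
    uptime-/trapping-day-normalised means, one from the raw means — the
    two differ whenever uptime is below 1 or collections pool days.
    """

    sensor_mean_daily: float
    sensor_se: float | None
    trap_mean_daily: float
    trap_se: float | None
    ratio_normalized: float | None
    sensor_mean_daily_raw: float
    trap_mean_daily_raw: float
    ratio_raw: float | None
    n_sensor_days: int = 0
    n_trap_days: int = 0

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "sensor_mean_daily", "sensor_se", "trap_mean_daily", "trap_se",
            "ratio_normalized", "sensor_mean_daily_raw",
            "trap_mean_daily_raw", "ratio_raw",
            "n_sensor_days", "n_trap_days",
        )}


# --------------------------------------------------------------------------
# binning
# --------------------------------------------------------------------------

def _to_bin(ts: pd.Series, bin: str) -> pd.Series:
    t = pd.to_datetime(ts)
    if bin == "day":
        return t.dt.strftime("%Y-%m-%d")
    if bin == "hour":
        return t.dt.strftime("%Y-%m-%dT%H:00")
    raise DataError(f"unknown bin size {bin!r} (use 'day' or 'hour')")


def bin_events(
    features: pd.DataFrame,
    uptime: pd.DataFrame,
    bin: str = "day",
    exclude_dates: list[str] | None = None,
) -> pd.DataFrame:
    """Bin valid events per device and normalise by uptime.

    ``features`` needs columns ``device_id``, ``timestamp`` and ``valid``;
    ``uptime`` needs ``device_id``, ``date``, ``fraction``.  Bins with
    zero uptime are excluded (not zero-filled); an event in a bin missing
    from the uptime table is counted with uptime 1 after a warning.
    Dates on the exclusion list (e.g. instrument-malfunction days) are
    dropped entirely.
    """
    for col in ("device_id", "timestamp", "valid"):
        if col not in features.columns:
            raise DataError(f"features table lacks column {col!r}")
    exclude = set(exclude_dates or [])

    up = uptime.copy()
    up["date"] = pd.to_datetime(up["date"]).dt.strftime("%Y-%m-%d")

    valid = features[features["valid"].astype(bool)].copy()
    valid["bin"] = _to_bin(valid["timestamp"], bin)
    valid["date"] = _to_bin(valid["timestamp"], "day")
    counts = (
        valid.groupby(["device_id", "bin", "date"])
        .size().rename("count").reset_index()
    )

    # uptime bins present but without any events still appear, with count 0
    base = up.rename(columns={"date": "date"}).copy()
    if bin == "day":
        base["bin"] = base["date"]
        grid = base[["device_id", "bin", "date", "fraction"]]
        merged = grid.merge(counts[["device_id", "bin", "count"]],
                            on=["device_id", "bin"], how="outer")
        merged["date"] = merged["date"].fillna(merged["bin"])
    else:
        merged = counts.merge(up, on=["device_id", "date"], how="left")
        merged = merged.rename(columns={"fraction": "fraction"})

    if "fraction" not in merged.columns:
        merged["fraction"] = np.nan
    missing = merged["fraction"].isna() & merged.get("count", 0).notna()
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} bin(s) with events but no uptime entry; "
            "counted with uptime 1"
        )
    merged["fraction"] = merged["fraction"].fillna(1.0)
    merged["count"] = merged["count"].fillna(0).astype(int)

    merged = merged[~merged["date"].isin(exclude)]
    merged = merged[merged["fraction"] > 0]
    merged["normalized"] = merged["count"] / merged["fraction"]
    out = merged[["device_id", "bin", "date", "count", "fraction",
                  "normalized"]].sort_values(["device_id", "bin"])
    return out.reset_index(drop=True)


def counts_to_activity(
    counts: pd.DataFrame,
    uptime: pd.DataFrame,
    exclude_dates: list[str] | None = None,
) -> pd.DataFrame:
    """Like :func:`bin_events` but starting from pre-binned daily counts
    (columns ``device_id``, ``date``, ``count``) — the shape the
    synthetic field study and an embedded deployment both produce."""
    exclude = set(exclude_dates or [])
    c = counts.copy()
    c["date"] = pd.to_datetime(c["date"]).dt.strftime("%Y-%m-%d")
    u = uptime.copy()
    u["date"] = pd.to_datetime(u["date"]).dt.strftime("%Y-%m-%d")
    merged = c.merge(u, on=["device_id", "date"], how="left")
    if merged["fraction"].isna().any():
        warnings.warn("daily counts without uptime entry; assuming uptime 1")
        merged["fraction"] = merged["fraction"].fillna(1.0)
    merged = merged[~merged["date"].isin(exclude)]
    merged = merged[merged["fraction"] > 0]
    merged["bin"] = merged["date"]
    merged["normalized"] = merged["count"] / merged["fraction"]
    return merged[["device_id", "bin", "date", "count", "fraction",
                   "normalized"]].reset_index(drop=True)


def align_trap_schedule(collections: pd.DataFrame) -> pd.DataFrame:
    """Normalise trap collections by the number of trapping days covered.

    ``collections`` has columns ``trap_id``, ``collection_date``,
    ``count`` with strictly increasing dates per trap.  Each collection's
    ``days_covered`` is the gap (in days) since that trap's previous
    collection (1 for the first).  No rows are fabricated for un-emptied
    days.  Duplicate collection dates for a trap are an error.
    """
    df = collections.copy()
    for col in ("trap_id", "collection_date", "count"):
        if col not in df.columns:
            raise DataError(f"trap table lacks column {col!r}")
    df["collection_date"] = pd.to_datetime(df["collection_date"])
    out = []
    for trap_id, grp in df.groupby("trap_id"):
        if grp["collection_date"].duplicated().any():
            raise DataError(f"duplicate collection dates for trap {trap_id!r}")
        grp = grp.sort_values("collection_date").reset_index(drop=True)
        gaps = grp["collection_date"].diff().dt.days
        grp["days_covered"] = gaps.fillna(1).astype(int)
        if (grp["days_covered"] < 1).any():
            raise DataError(f"non-increasing dates for trap {trap_id!r}")
        grp["normalized"] = grp["count"] / grp["days_covered"]
        out.append(grp)
    res = pd.concat(out, ignore_index=True)
    res["collection_date"] = res["collection_date"].dt.strftime("%Y-%m-%d")
    return res


# --------------------------------------------------------------------------
# rank statistics
# --------------------------------------------------------------------------

def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value of Spearman's rho (n <= 9).

    Enumerates all pairings of the rank vectors; ties are handled by
    average ranks in the observed statistic and in each permutation.
    """
    n = x.size
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]                      # (n!, n)
    rx_c = rx - rx.mean()
    ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum(axis=1))
    rhos = (ry_c @ rx_c) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman(
    x: np.ndarray,
    y: np.ndarray,
    exact_max_n: int = 9,
) -> tuple[float | None, float | None]:
    """Spearman rank correlation with average-rank ties.

    The p-value is two-sided: an exact permutation enumeration for
    ``n <= exact_max_n``, the t-approximation beyond.  Constant input on
    either side makes rho undefined (``None``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("x and y must be 1-D of equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None, None
    rho = float(stats.spearmanr(x, y).statistic)
    if x.size <= exact_max_n:
        p = _exact_spearman_p(x, y, rho)
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p


def compare_methods(
    activity: pd.DataFrame,
    traps: pd.DataFrame,
    excluded_dates: list[str] | None = None,
) -> ComparisonResult:
    """Compare daily sensor and trap means on their common days.

    ``activity`` is the output of :func:`bin_events` /
    :func:`counts_to_activity` (day bins); ``traps`` the output of
    :func:`align_trap_schedule`.  Per day, normalised counts are averaged
    across sensors and across traps; the paired series (intersection of
    days where both methods have data) feed Spearman's rho and an OLS fit
    of sensor means against trap means.
    """
    sens = (
        activity.groupby("date")["normalized"].mean().rename("sensor")
    )
    trap = (
        traps.groupby("collection_date")["normalized"].mean().rename("trap")
    )
    paired = pd.concat([sens, trap], axis=1, join="inner").dropna()
    if excluded_dates:
        paired = paired[~paired.index.isin(set(excluded_dates))]
    if len(paired) < 3:
        raise DataError(
            f"need at least 3 common days, found {len(paired)}"
        )
    x = paired["trap"].to_numpy()
    y = paired["sensor"].to_numpy()
    rho, p = spearman(y, x)
    if np.ptp(x) > 0:
        fit = stats.linregress(x, y)
        slope, intercept = float(fit.slope), float(fit.intercept)
    else:
        slope = intercept = None
    return ComparisonResult(
        days=list(paired.index),
        sensor_means=[float(v) for v in y],
        trap_means=[float(v) for v in x],
        spearman_rho=rho, p_value=p,
        slope=slope, intercept=intercept,
        n_days=len(paired),
        excluded_dates=list(excluded_dates or []),
    )


def summarize_study(
    activity: pd.DataFrame,
    traps: pd.DataFrame,
) -> StudySummary:
    """Mean daily counts per method, their standard errors and ratio.

    The daily mean is taken across devices first, then averaged over
    days; SE is the SD across days divided by sqrt(n_days).  Single-day
    series have no SE.
    """
    if len(activity) == 0 or len(traps) == 0:
        raise DataError("activity and trap series must be non-empty")
    sens_daily = activity.groupby("date")["normalized"].mean()
    trap_daily = traps.groupby("collection_date")["normalized"].mean()
    sens_daily_raw = activity.groupby("date")["count"].mean()
    trap_daily_raw = traps.groupby("collection_date")["count"].mean()

    def _se(s: pd.Series) -> float | None:
        if len(s) < 2:
            return None
        return float(s.std(ddof=1) / np.sqrt(len(s)))

    t_mean = float(trap_daily.mean())
    t_mean_raw = float(trap_daily_raw.mean())
    return StudySummary(
        sensor_mean_daily=float(sens_daily.mean()),
        sensor_se=_se(sens_daily),
        trap_mean_daily=t_mean,
        trap_se=_se(trap_daily),
        ratio_normalized=(float(sens_daily.mean()) / t_mean
                          if t_mean > 0 else None),
        sensor_mean_daily_raw=float(sens_daily_raw.mean()),
        trap_mean_daily_raw=t_mean_raw,
        ratio_raw=(float(sens_daily_raw.mean()) / t_mean_raw
                   if t_mean_raw > 0 else None),
        n_sensor_days=len(sens_daily),
        n_trap_days=len(trap_daily),
    )


def plot_comparison(result: ComparisonResult, path) -> None:
    """Scatter of daily sensor vs trap means with the OLS line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.trap_means, result.sensor_means, color="k")
    if result.slope is not None:
        xs = np.linspace(min(result.trap_means), max(result.trap_means), 50)
        ax.plot(xs, result.intercept + result.slope * xs, "r-",
                label="least-squares fit")
        ax.legend()
    rho = "n/a" if result.spearman_rho is None else f"{result.spearman_rho:.2f}"
    ax.set_xlabel("trap catches / trapping day")
    ax.set_ylabel("sensor observations / day (uptime-normalised)")
    ax.set_title(f"Spearman rho = {rho}, n = {result.n_days} days")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
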