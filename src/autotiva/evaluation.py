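"""Anesthetic-adequacy scoring and trial statistics.

Scoring works on the 1-Hz Record over the surgery window and mirrors how
the trial defined its endpoints:

* sedation deviates when a *reliable* BIS (signal quality index ≥ 80) lies
  outside the 35–55 band; unreliable samples are routed to missing-data.
* analgesia is insufficient during episodes where systolic pressure AND
  heart rate both rapidly exceed 120% of a rolling baseline (the mean over
  1–5 min before onset), excluding the 5 min after any vasoactive
  administration.
* relaxation deviates when the TOF count differs from 1; invalid TOF
  samples are missing data.

Adequate anesthesia time is operation time minus the union of the three
deviation interval sets and the qualifying missing time (samples where at
least one component is missing and no present component deviates); ratios
are percentages of operation time.

The statistics reproduce the trial's analysis: a pooled two-sample t-test
of non-inferiority with a 5-percentage-point margin at one-sided 2.5%
(with its one-tailed 97.5% confidence bound), its normal-approximation
power, and Fisher's exact test for adverse-event counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DeviationIntervals",
    "AdequacyReport",
    "surgery_window",
    "sedation_deviation",
    "analgesia_insufficiency",
    "relaxation_deviation",
    "adequate_time_ratio",
    "noninferiority_test",
    "power_noninferiority",
    "fisher_exact",
    "merge_intervals",
    "intervals_to_mask",
    "mask_to_intervals",
]

Interval = tuple[float, float]


# ------------------------------------------------------------ interval algebra

def mask_to_intervals(mask: np.ndarray, t: np.ndarray) -> list[Interval]:
    """Contiguous True runs of a 1-Hz boolean mask as [t0, t1) intervals."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0 or not mask.any():
        return []
    d = np.diff(mask.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return [(float(t[s]), float(t[e - 1]) + 1.0) for s, e in zip(starts, ends)]


def merge_intervals(intervals: list[Interval], gap: float = 10.0) -> list[Interval]:
    """Union of intervals, merging neighbours separated by less than ``gap`` s."""
    if not intervals:
        return []
    ordered = sorted(intervals)
    out = [list(ordered[0])]
    for a, b in ordered[1:]:
        if a - out[-1][1] < gap:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [(a, b) for a, b in out]


def intervals_to_mask(intervals: list[Interval], t: np.ndarray) -> np.ndarray:
    mask = np.zeros(t.size, dtype=bool)
    for a, b in intervals:
        mask |= (t >= a) & (t < b)
    return mask


@dataclass
class DeviationIntervals:
    """Per-component deviation and missing-data intervals over surgery."""

    sedation: list[Interval] = field(default_factory=list)
    analgesia: list[Interval] = field(default_factory=list)
    relaxation: list[Interval] = field(default_factory=list)
    missing_sedation: list[Interval] = field(default_factory=list)
    missing_relaxation: list[Interval] = field(default_factory=list)


@dataclass
class AdequacyReport:
    """Adequacy ratios (percent of operation time) and event counts."""

    adequate_time_ratio: float
    sedation_ratio: float
    analgesia_ratio: float
    relaxation_ratio: float
    sedation_analgesia_ratio: float
    sedation_relaxation_ratio: float
    bis_in_range_ratio: float
    missing_time_s: float
    operation_time_s: float
    analgesia_episodes: int
    movement_events: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def surgery_window(record: pd.DataFrame) -> tuple[float, float]:
    """[start, end) of surgery from the record's event flags."""
    ev = record["event"].fillna("").astype(str)
    starts = record.loc[ev.str.contains("surgery_start"), "t_s"]
    ends = record.loc[ev.str.contains("surgery_end"), "t_s"]
    if starts.empty:
        raise ValueError("record has no surgery_start event")
    t0 = float(starts.iloc[0])
    t1 = float(ends.iloc[0]) if not ends.empty else float(record["t_s"].iloc[-1]) + 1.0
    if t1 <= t0:
        raise ValueError("surgery window has non-positive length")
    return t0, t1


def _window(record: pd.DataFrame, window: tuple[float, float] | None) -> pd.DataFrame:
    t0, t1 = window if window is not None else surgery_window(record)
    sub = record[(record["t_s"] >= t0) & (record["t_s"] < t1)]
    if sub.empty:
        raise ValueError("surgery window contains no samples")
    return sub


# ----------------------------------------------------------------- components

def sedation_deviation(
    record: pd.DataFrame,
    band: tuple[float, float] = (35.0, 55.0),
    sqi_min: float = 80.0,
    window: tuple[float, float] | None = None,
    merge_gap: float = 10.0,
) -> tuple[list[Interval], list[Interval]]:
    """(deviation, missing) intervals for sedation.

    Deviation: reliable BIS (SQI ≥ ``sqi_min``) outside ``band``. Samples
    with unreliable BIS are missing data, not deviation.
    """
    sub = _window(record, window)
    t = sub["t_s"].to_numpy(dtype=float)
    bis = sub["bis"].to_numpy(dtype=float)
    sqi = sub["sqi"].to_numpy(dtype=float)
    reliable = (sqi >= sqi_min) & np.isfinite(bis)
    dev = reliable & ((bis < band[0]) | (bis > band[1]))
    return (merge_intervals(mask_to_intervals(dev, t), merge_gap),
            merge_intervals(mask_to_intervals(~reliable, t), merge_gap))


def analgesia_insufficiency(
    record: pd.DataFrame,
    rise_frac: float = 0.2,
    settled_frac: float = 0.1,
    rapid_rise_s: float = 120.0,
    baseline_window: tuple[float, float] = (300.0, 60.0),
    vaso_lockout_s: float = 300.0,
    window: tuple[float, float] | None = None,
    merge_gap: float = 10.0,
    require_both: bool = True,
) -> list[Interval]:
    """Insufficient-analgesia episodes.

    An episode starts where SBP and HR both exceed (1 + ``rise_frac``)×
    their rolling baselines — the baseline being the mean over
    [t−300 s, t−60 s] at episode onset — having risen from below
    (1 + ``settled_frac``)× within ``rapid_rise_s``; samples within
    ``vaso_lockout_s`` after a vasoactive administration are excluded.
    The episode ends when both signals fall back below the threshold.
    """
    sub = _window(record, window)
    t = sub["t_s"].to_numpy(dtype=float)
    sbp = sub["sbp"].to_numpy(dtype=float)
    hr = sub["hr"].to_numpy(dtype=float)
    n = t.size
    far, near = baseline_window
    if len(record) <= far:
        raise ValueError("record shorter than the baseline window")

    ev = sub["event"].fillna("").astype(str).to_numpy()
    vaso_idx = np.flatnonzero(np.char.find(ev.astype(str), "vasoactive") >= 0)
    lockout = np.zeros(n, dtype=bool)
    for i in vaso_idx:
        lockout[i: i + int(vaso_lockout_s)] = True

    # rolling baselines from the full record (context before the window counts)
    allt = record["t_s"].to_numpy(dtype=float)
    allsbp = record["sbp"].to_numpy(dtype=float)
    allhr = record["hr"].to_numpy(dtype=float)
    csum_sbp = np.concatenate([[0.0], np.cumsum(allsbp)])
    csum_hr = np.concatenate([[0.0], np.cumsum(allhr)])

    def baseline(idx_global: int) -> tuple[float, float]:
        a = max(0, idx_global - int(far))
        b = max(a + 1, idx_global - int(near))
        m = b - a
        return (csum_sbp[b] - csum_sbp[a]) / m, (csum_hr[b] - csum_hr[a]) / m

    offset = int(np.searchsorted(allt, t[0]))
    combine = np.logical_and if require_both else np.logical_or

    episodes = np.zeros(n, dtype=bool)
    i = 0
    while i < n:
        g = offset + i
        bl_sbp, bl_hr = baseline(g)
        over = combine(sbp[i] > (1 + rise_frac) * bl_sbp, hr[i] > (1 + rise_frac) * bl_hr)
        if over and not lockout[i]:
            # rapid rise: both settled below (1+settled_frac)x within rapid_rise_s
            lo = max(0, i - int(rapid_rise_s))
            settled = np.logical_and(
                sbp[lo:i] <= (1 + settled_frac) * bl_sbp,
                hr[lo:i] <= (1 + settled_frac) * bl_hr,
            )
            if i == 0 or settled.any():
                j = i
                while j < n and combine(sbp[j] > (1 + rise_frac) * bl_sbp,
                                        hr[j] > (1 + rise_frac) * bl_hr):
                    episodes[j] = True
                    j += 1
                i = j
                continue
        i += 1
    episodes &= ~lockout
    return merge_intervals(mask_to_intervals(episodes, t), merge_gap)


def relaxation_deviation(
    record: pd.DataFrame,
    target_count: int = 1,
    window: tuple[float, float] | None = None,
    merge_gap: float = 10.0,
) -> tuple[list[Interval], list[Interval], int]:
    """(deviation, missing, movement_events) for muscle relaxation.

    Deviation: valid TOF count ≠ ``target_count``. Movement events are
    counted as merged deviation episodes reaching a count of 2 or more.
    """
    sub = _window(record, window)
    t = sub["t_s"].to_numpy(dtype=float)
    count = sub["tof_count"].to_numpy(dtype=float)
    valid = sub["tof_valid"].to_numpy(dtype=bool)
    dev = valid & (count != target_count)
    dev_iv = merge_intervals(mask_to_intervals(dev, t), merge_gap)
    move = valid & (count >= 2)
    movement = len(merge_intervals(mask_to_intervals(move, t), merge_gap))
    missing = merge_intervals(mask_to_intervals(~valid, t), merge_gap)
    return dev_iv, missing, movement


def adequate_time_ratio(
    record: pd.DataFrame,
    band: tuple[float, float] = (35.0, 55.0),
    sqi_min: float = 80.0,
    window: tuple[float, float] | None = None,
) -> AdequacyReport:
    """Full adequacy report over the surgery window.

    Adequate time = operation time − |union(sedation dev, analgesia dev,
    relaxation dev, qualifying missing time)|, where missing time qualifies
    only when at least one component is missing and no present component
    deviates at that sample.
    """
    win = window if window is not None else surgery_window(record)
    sub = _window(record, win)
    t = sub["t_s"].to_numpy(dtype=float)
    n = t.size
    if n == 0:
        raise ValueError("zero-length operation")

    sed_iv, sed_missing_iv = sedation_deviation(record, band, sqi_min, win)
    ana_iv = analgesia_insufficiency(record, window=win)
    rel_iv, rel_missing_iv, movement = relaxation_deviation(record, window=win)

    sed = intervals_to_mask(sed_iv, t)
    ana = intervals_to_mask(ana_iv, t)
    rel = intervals_to_mask(rel_iv, t)
    sed_missing = intervals_to_mask(sed_missing_iv, t)
    rel_missing = intervals_to_mask(rel_missing_iv, t)

    any_dev = sed | ana | rel
    any_missing = sed_missing | rel_missing
    qualifying_missing = any_missing & ~any_dev
    inadequate = any_dev | qualifying_missing

    def ratio(mask: np.ndarray) -> float:
        return 100.0 * (1.0 - mask.mean())

    bis = sub["bis"].to_numpy(dtype=float)
    sqi = sub["sqi"].to_numpy(dtype=float)
    reliable = sqi >= sqi_min
    in_band = reliable & (bis >= band[0]) & (bis <= band[1])
    bis_ratio = 100.0 * in_band.sum() / reliable.sum() if reliable.any() else np.nan

    return AdequacyReport(
        adequate_time_ratio=ratio(inadequate),
        sedation_ratio=ratio(sed | (sed_missing & ~any_dev)),
        analgesia_ratio=ratio(ana),
        relaxation_ratio=ratio(rel | (rel_missing & ~any_dev)),
        sedation_analgesia_ratio=ratio(sed | ana | (sed_missing & ~any_dev)),
        sedation_relaxation_ratio=ratio(sed | rel | ((sed_missing | rel_missing) & ~any_dev)),
        bis_in_range_ratio=float(bis_ratio),
        missing_time_s=float(qualifying_missing.sum()),
        operation_time_s=float(n),
        analgesia_episodes=len(ana_iv),
        movement_events=movement,
    )


# ----------------------------------------------------------------- statistics

def _summary(x) -> tuple[float, float, int]:
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need n >= 2 per group")
    return float(x.mean()), float(x.std(ddof=1)), int(x.size)


def noninferiority_test(
    auto=None,
    manual=None,
    margin: float = 5.0,
    *,
    summary_auto: tuple[float, float, int] | None = None,
    summary_manual: tuple[float, float, int] | None = None,
) -> tuple[float, float, float]:
    """One-sided non-inferiority t-test of automatic vs manual percentages.

    Tests H0: μ_auto − μ_manual ≤ −margin with a pooled-variance two-sample
    t statistic at one-sided 2.5%. Accepts either raw per-patient values or
    ``summary_*=(mean, sd, n)`` tuples; both routes agree exactly.

    Returns (point estimate of the difference, lower bound of the one-sided
    97.5% confidence interval, one-sided p value).
    """
    if summary_auto is None:
        summary_auto = _summary(auto)
    if summary_manual is None:
        summary_manual = _summary(manual)
    m_a, sd_a, n_a = summary_auto
    m_m, sd_m, n_m = summary_manual
    if n_a < 2 or n_m < 2:
        raise ValueError("need n >= 2 per group")
    if sd_a <= 0 and sd_m <= 0:
        raise ValueError("degenerate variance in both groups")
    df = n_a + n_m - 2
    pooled_var = ((n_a - 1) * sd_a**2 + (n_m - 1) * sd_m**2) / df
    se = np.sqrt(pooled_var * (1.0 / n_a + 1.0 / n_m))
    diff = m_a - m_m
    t_stat = (diff + margin) / se
    p = float(stats.t.sf(t_stat, df))
    lower = diff - float(stats.t.ppf(0.975, df)) * se
    return float(diff), float(lower), p


def power_noninferiority(
    mean_a: float,
    sd_a: float,
    mean_m: float,
    sd_m: float,
    margin: float = 5.0,
    alpha_one_sided: float = 0.025,
    n_per_group: int = 45,
) -> float:
    """Normal-approximation power of the non-inferiority test.

    power = Φ( (μ_a − μ_m + margin) / (σ_pooled·√(2/n)) − z_{1−α} ).
    """
    if sd_a <= 0 or sd_m <= 0:
        raise ValueError("standard deviations must be positive")
    if n_per_group < 2:
        raise ValueError("need n >= 2 per group")
    sigma = np.sqrt((sd_a**2 + sd_m**2) / 2.0)
    se = sigma * np.sqrt(2.0 / n_per_group)
    z = (mean_a - mean_m + margin) / se - stats.norm.ppf(1.0 - alpha_one_sided)
    return float(stats.norm.cdf(z))


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact p for a 2×2 count table."""
    table = np.asarray(table)
    if table.shape != (2, 2) or np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        table = table.astype(float)
        if table.shape != (2, 2) or np.any(table < 0) or np.any(table != np.round(table)):
            raise ValueError("table must be 2x2 non-negative integers")
        table = table.astype(int)
    return float(stats.fisher_exact(table, alternative="two-sided")[1])
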