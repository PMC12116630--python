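"""sCOD removal, smoothing, and taxon–performance screening.

Combined two-stage removal is ``100 × (in − out2)/in`` per sampling day,
smoothed with a trailing moving average over the current day and the five
preceding days.  Genera are screened per (stage, feed) by Spearman rank
correlation between their estimated absolute abundance and the smoothed
removal series; correlations with p > alpha (default 0.05) are filtered
out of the final report.  Kruskal–Wallis compares removal across feeds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations as iter_permutations
from typing import Sequence

import numpy as np
from scipy import stats

from .datamodel import Feed, PerformanceSeries, SampleRecord, Stage
from .membership import MembershipResult
from .qpcr import AbundanceTable

log = logging.getLogger("adlink")

#: Largest n for which the exact permutation null of Spearman's rho is used.
EXACT_PERMUTATION_MAX_N = 9


class DegenerateInputError(ValueError):
    """A statistic is undefined (zero variance, too few observations)."""


@dataclass
class CorrelationRecord:
    genus: str
    stage: Stage
    feed: Feed
    rho: float
    p_value: float
    n: int
    membership_class: str  # core | unique | other
    passed_filter: bool


@dataclass
class KruskalResult:
    h: float
    p_value: float
    group_sizes: list[int]


def removal_percent(scod_in: float, scod_out2: float) -> float:
    """Percent sCOD removed across both stages; negative values are kept."""
    if scod_in <= 0:
        raise ValueError("influent sCOD must be positive")
    return 100.0 * (scod_in - scod_out2) / scod_in


def removal_series(series: PerformanceSeries) -> list[tuple[int, float]]:
    """(day, removal percent) for each record of a pair's sCOD series."""
    return [(d, removal_percent(cin, cout)) for d, cin, cout in series.records]


def moving_average(
    series: Sequence[tuple[int, float]], window_days: int = 5
) -> list[tuple[int, float]]:
    """Trailing moving average over days [d - window_days, d].

    Every observed day receives a smoothed value: the mean of all
    observations whose day falls in the trailing window, the current day
    included.
    """
    days = [d for d, _ in series]
    if any(b <= a for a, b in zip(days, days[1:])):
        raise ValueError("moving_average: days must be strictly increasing")
    out = []
    for i, (d, _) in enumerate(series):
        vals = [v for dd, v in series[: i + 1] if dd >= d - window_days]
        out.append((d, float(np.mean(vals))))
    return out


def smooth_performance(
    series: PerformanceSeries, window_days: int = 5
) -> PerformanceSeries:
    """Attach the smoothed removal series to a PerformanceSeries."""
    series.smoothed = moving_average(removal_series(series), window_days)
    return series


def _rho_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman's rho with a two-sided p-value.

    rho is the Pearson correlation of average ranks (ties get average
    ranks).  For n <= 9 the p-value is exact, by full enumeration of the
    n! pairings; for larger n the usual t approximation
    ``t = rho * sqrt((n-2)/(1-rho**2))`` on n-2 degrees of freedom is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("spearman: x and y must be equal-length vectors")
    n = x.size
    if n < 3:
        raise DegenerateInputError("spearman needs at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("spearman undefined for a constant vector")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rho = _rho_of_ranks(rx, ry)

    if n <= EXACT_PERMUTATION_MAX_N:
        return rho, _exact_permutation_p(rx, ry, rho)

    denom = 1.0 - rho * rho
    if denom <= 0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / denom)
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, min(1.0, float(p))


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray, rho: float) -> float:
    """Two-sided exact p by full enumeration of the n! pairings.

    rho is linear in the cross rank sum S = sum(rx * ry_perm), so only S is
    enumerated (in vectorised chunks) and thresholded.
    """
    n = rx.size
    a = rx.sum() * ry.sum() / n
    b = math.sqrt(
        (np.sum(rx**2) - rx.sum() ** 2 / n) * (np.sum(ry**2) - ry.sum() ** 2 / n)
    )
    target = abs(rho) - 1e-12
    count, chunk = 0, []
    total = math.factorial(n)
    for perm in iter_permutations(range(n)):
        chunk.append(perm)
        if len(chunk) == 50000:
            s = ry[np.asarray(chunk)] @ rx
            count += int(np.count_nonzero(np.abs((s - a) / b) >= target))
            chunk = []
    if chunk:
        s = ry[np.asarray(chunk)] @ rx
        count += int(np.count_nonzero(np.abs((s - a) / b) >= target))
    return count / total


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KruskalResult:
    """Tie-corrected Kruskal–Wallis H with a chi-square p-value."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("kruskal_wallis needs >= 2 nonempty groups")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return KruskalResult(h=0.0, p_value=1.0, group_sizes=[g.size for g in groups])
    h, p = stats.kruskal(*groups)
    return KruskalResult(h=float(h), p_value=float(p), group_sizes=[g.size for g in groups])


def series_by_feed(
    series: Sequence[PerformanceSeries], meta: Sequence[SampleRecord]
) -> dict[Feed, PerformanceSeries]:
    """Map each performance series to its feed.

    A pair_id is resolved either as a feed name or as a reactor_id whose
    feed is known from the metadata.
    """
    reactor_feed = {r.reactor_id: r.feed for r in meta}
    feed_names = {f.value: f for f in Feed}
    out: dict[Feed, PerformanceSeries] = {}
    for s in series:
        if s.pair_id in feed_names:
            feed = feed_names[s.pair_id]
        elif s.pair_id in reactor_feed:
            feed = reactor_feed[s.pair_id]
        else:
            raise ValueError(f"cannot resolve feed for performance pair {s.pair_id!r}")
        if feed in out:
            raise ValueError(f"two performance series resolve to feed {feed.value}")
        out[feed] = s
    return out


def _match_removal(
    day: int, smoothed: Sequence[tuple[int, float]], window: int
) -> float | None:
    best, best_gap = None, window + 1
    for d, v in smoothed:
        gap = abs(d - day)
        if gap < best_gap:
            best, best_gap = v, gap
    return best if best_gap <= window else None


def correlate_taxa_performance(
    eaa: AbundanceTable,
    perf: Sequence[PerformanceSeries],
    meta: Sequence[SampleRecord],
    membership: MembershipResult | None = None,
    alpha: float = 0.05,
    min_n: int = 6,
    pairing_window: int = 3,
    smoothing_window: int = 5,
    use_smoothed: bool = True,
) -> list[CorrelationRecord]:
    """Spearman screen of per-genus abundance against sCOD removal.

    For every (stage, feed, genus) with at least ``min_n`` pairable
    observations, abundance samples are matched to the feed's removal value
    on the nearest day within ``pairing_window`` days and correlated.
    Records are annotated core/unique/other and sorted by stage, feed and
    descending |rho|; ``passed_filter`` marks p <= alpha.
    """
    by_feed = series_by_feed(perf, meta)
    removal_of: dict[Feed, list[tuple[int, float]]] = {}
    for feed, s in by_feed.items():
        if use_smoothed:
            if s.smoothed is None:
                smooth_performance(s, smoothing_window)
            removal_of[feed] = list(s.smoothed)
        else:
            removal_of[feed] = removal_series(s)

    sample_set = set(eaa.samples)
    records: list[CorrelationRecord] = []
    stages = sorted({r.stage for r in meta}, key=lambda s: s.value)
    feeds = sorted({r.feed for r in meta}, key=lambda f: f.value)
    for stage in stages:
        for feed in feeds:
            if feed not in removal_of:
                continue
            recs = [
                r for r in meta
                if r.stage == stage and r.feed == feed and r.sample_id in sample_set
            ]
            pairs = []
            for r in recs:
                v = _match_removal(r.day, removal_of[feed], pairing_window)
                if v is None:
                    log.info(
                        "correlate: sample %s (day %d) has no removal value "
                        "within %d days", r.sample_id, r.day, pairing_window,
                    )
                    continue
                pairs.append((r.sample_id, v))
            if len(pairs) < min_n:
                continue
            sample_ids = [s for s, _ in pairs]
            removal = np.array([v for _, v in pairs])
            sub = eaa.eaa[sample_ids]
            for genus in eaa.taxa:
                abund = sub.loc[genus].to_numpy(dtype=float)
                try:
                    rho, p = spearman(abund, removal)
                except DegenerateInputError:
                    continue
                cls = (
                    membership.classify(genus, stage, feed)
                    if membership is not None else "other"
                )
                records.append(
                    CorrelationRecord(
                        genus=genus, stage=stage, feed=feed,
                        rho=rho, p_value=p, n=len(pairs),
                        membership_class=cls, passed_filter=p <= alpha,
                    )
                )
    records.sort(key=lambda r: (r.stage.value, r.feed.value, -abs(r.rho), r.genus))
    return records
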