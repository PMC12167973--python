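"""Cohort-level summaries and statistics.

Per-day activity-state fractions, the mean day-to-day unsilencing rate
u, the theoretical persistently-silent decay (1 - u)^(k-1) it implies
under memoryless recruitment, percentile-bootstrap effect-size
confidence intervals, and thin wrappers around the standard group
comparison tests (Kolmogorov-Smirnov, Kruskal-Wallis with Dunn's post
hoc, Mann-Whitney U, paired t).

The persistently-silent comparison is the key readout: if silent cells
re-enter the active pool at random with per-day probability u, the
fraction still silent after k days decays as (1 - u)^(k-1); an excess
above that curve indicates a subpopulation that stays silent longer
than chance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .tracking import CellTrack

__all__ = [
    "CohortSummary", "EffectSizeCI",
    "session_fractions", "unsilencing_rate", "theoretical_decay",
    "bootstrap_diff_ci", "dunn_posthoc", "group_tests",
]


@dataclass
class CohortSummary:
    per_day_fractions: list[dict]
    persistently_silent_counts: np.ndarray
    persistently_silent_normalized: np.ndarray
    unsilencing_rate: float
    theoretical_curve: np.ndarray

    def to_dict(self) -> dict:
        return {
            "per_day_fractions": self.per_day_fractions,
            "persistently_silent_counts": self.persistently_silent_counts.tolist(),
            "persistently_silent_normalized":
                self.persistently_silent_normalized.tolist(),
            "unsilencing_rate": self.unsilencing_rate,
            "theoretical_curve": self.theoretical_curve.tolist(),
        }


@dataclass
class EffectSizeCI:
    observed: float
    ci_low: float
    ci_high: float
    n_resamples: int
    statistic: str
    bootstrap_mean: float = np.nan
    bootstrap_sd: float = np.nan
    distribution: np.ndarray | None = field(default=None, repr=False)


def session_fractions(tracks: list[CellTrack], day: int,
                      labels: dict[int, str] | None = None) -> dict:
    """Silent / active / place fractions over tracked cells on one day.

    ``day`` is 0-based. ``labels`` optionally maps track_id to the
    place-cell pipeline label for that day; without it place_frac is
    NaN. All fractions use the full tracked population as denominator.
    """
    if not tracks:
        raise ValueError("no tracked cells")
    states = [t.states[day] for t in tracks]
    n = len(states)
    silent = sum(s == "silent" for s in states) / n
    out = {"silent_frac": silent, "active_frac": 1.0 - silent}
    if labels is not None:
        out["place_frac"] = sum(
            labels.get(t.track_id) == "place" for t in tracks) / n
    else:
        out["place_frac"] = float("nan")
    return out


def unsilencing_rate(tracks: list[CellTrack], *, pooled: bool = False
                     ) -> float:
    """Mean silent -> active transition rate over consecutive day pairs.

    For each pair (k, k+1) the rate is the fraction of day-k silent
    cells active on day k+1; pairs with no silent cells are skipped.
    Default is the unweighted mean across pairs; ``pooled=True``
    divides total transitions by total silent-cell days instead.
    """
    if not tracks or tracks[0].n_days < 2:
        raise ValueError("need tracks spanning at least two days")
    states = np.array([t.states for t in tracks])
    n_days = states.shape[1]
    rates, trans, sil = [], 0, 0
    for k in range(n_days - 1):
        silent_k = states[:, k] == "silent"
        n_sil = int(silent_k.sum())
        if n_sil == 0:
            continue
        n_trans = int((silent_k & (states[:, k + 1] == "active")).sum())
        rates.append(n_trans / n_sil)
        trans += n_trans
        sil += n_sil
    if not rates:
        raise ValueError("no day pair with silent cells")
    return trans / sil if pooled else float(np.mean(rates))


def theoretical_decay(u: float, n_days: int) -> np.ndarray:
    """Expected normalized persistently-silent counts, (1-u)^(k-1).

    Day 1 is normalized to 1; under memoryless unsilencing with per-day
    probability u the surviving silent fraction decays geometrically.
    """
    if not 0.0 <= u <= 1.0:
        raise ValueError("u must lie in [0, 1]")
    k = np.arange(n_days)
    return (1.0 - u) ** k


def bootstrap_diff_ci(
    group_a: np.ndarray,
    group_b: np.ndarray,
    statistic: str = "mean",
    n: int = 5000,
    seed: int | np.random.Generator = 0,
    ci: float = 95.0,
    keep_distribution: bool = False,
) -> EffectSizeCI:
    """Percentile-bootstrap CI for a difference of group statistics.

    Resamples each group with replacement ``n`` times (default 5,000)
    and recomputes ``stat(a*) - stat(b*)``; the CI is the (2.5, 97.5)
    percentile interval of that distribution.
    """
    rng = np.random.default_rng(seed)
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    stat = {"mean": np.mean, "median": np.median}[statistic]
    observed = float(stat(a) - stat(b))
    ia = rng.integers(0, a.size, size=(n, a.size))
    ib = rng.integers(0, b.size, size=(n, b.size))
    boot = stat(a[ia], axis=1) - stat(b[ib], axis=1)
    alpha = (100.0 - ci) / 2.0
    lo, hi = np.percentile(boot, [alpha, 100.0 - alpha])
    return EffectSizeCI(
        observed, float(lo), float(hi), n, statistic,
        bootstrap_mean=float(boot.mean()), bootstrap_sd=float(boot.std()),
        distribution=boot if keep_distribution else None,
    )


def dunn_posthoc(groups: dict[str, np.ndarray], *, adjust: str = "holm"
                 ) -> dict[tuple[str, str], float]:
    """Dunn's rank-based post hoc test for all group pairs.

    Standard z statistic on mean ranks with tie correction; p-values
    Holm-adjusted by default ("none" or "bonferroni" also available).
    """
    names = list(groups)
    data = [np.asarray(groups[g], float) for g in names]
    if any(d.size == 0 for d in data):
        raise ValueError("empty group")
    pooled = np.concatenate(data)
    n_tot = pooled.size
    ranks = sstats.rankdata(pooled)
    # tie correction term
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (n_tot - 1))
    mean_ranks, sizes = {}, {}
    off = 0
    for g, d in zip(names, data):
        mean_ranks[g] = float(np.mean(ranks[off:off + d.size]))
        sizes[g] = d.size
        off += d.size

    raw = {}
    for g1, g2 in itertools.combinations(names, 2):
        se = np.sqrt((n_tot * (n_tot + 1) / 12.0 - tie_term)
                     * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se
        raw[(g1, g2)] = 2.0 * sstats.norm.sf(abs(z))

    if adjust == "none":
        return raw
    m = len(raw)
    if adjust == "bonferroni":
        return {k: min(1.0, p * m) for k, p in raw.items()}
    if adjust == "holm":
        out = {}
        running = 0.0
        for rank_i, (k, p) in enumerate(sorted(raw.items(), key=lambda kv: kv[1])):
            running = max(running, min(1.0, (m - rank_i) * p))
            out[k] = running
        return out
    raise ValueError(f"unknown adjustment {adjust!r}")


def group_tests(groups: dict[str, np.ndarray], alpha: float = 0.05) -> dict:
    """Thin adapter over the standard group comparison tests.

    Always reports Kruskal-Wallis across all groups plus Dunn's post
    hoc pairs; with exactly two groups also Kolmogorov-Smirnov and
    Mann-Whitney U, and a paired t test when sizes match.
    """
    names = list(groups)
    data = [np.asarray(groups[g], float) for g in names]
    if len(data) < 2:
        raise ValueError("need at least two groups")
    if any(d.size == 0 for d in data):
        raise ValueError("empty group")
    report: dict = {"alpha": alpha}
    kw_stat, kw_p = sstats.kruskal(*data)
    report["kruskal_wallis"] = {"statistic": float(kw_stat), "p": float(kw_p),
                                "significant": bool(kw_p < alpha)}
    report["dunn"] = {
        f"{a} vs {b}": {"p": float(p), "significant": bool(p < alpha)}
        for (a, b), p in dunn_posthoc(groups).items()}
    if len(data) == 2:
        ks_stat, ks_p = sstats.ks_2samp(data[0], data[1])
        report["kolmogorov_smirnov"] = {
            "statistic": float(ks_stat), "p": float(ks_p),
            "significant": bool(ks_p < alpha)}
        mw_stat, mw_p = sstats.mannwhitneyu(data[0], data[1])
        report["mann_whitney_u"] = {
            "statistic": float(mw_stat), "p": float(mw_p),
            "significant": bool(mw_p < alpha)}
        if data[0].size == data[1].size:
            t_stat, t_p = sstats.ttest_rel(data[0], data[1])
            report["paired_t"] = {"statistic": float(t_stat), "p": float(t_p),
                                  "significant": bool(t_p < alpha)}
    return report
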