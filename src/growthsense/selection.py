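"""Sensor-channel screening: ANOVA, Duncan letters, correlations.

The screening pipeline mirrors common practice in E-nose/E-tongue
studies: for each channel, a one-way ANOVA across storage times,
Duncan's multiple range test to letter the per-time means, and a
count of distinct letters as the channel's discrimination power;
Pearson correlations against the plate-count log series and a
loadings analysis complete the evidence used to pick the channel
that is fitted with a growth model.

ANOVA and Duncan are computed from per-group summary statistics
(mean, sd, n), which reconstruct the sums of squares exactly — raw
replicates are not required.
"""

from __future__ import annotations

from dataclasses import dataclass
from string import ascii_lowercase
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .panel import ReplicatePanel

__all__ = [
    "ChannelSummary",
    "AnovaResult",
    "LetterGrouping",
    "CorrelationTable",
    "summarize_panel",
    "anova_from_summary",
    "duncan_letters",
    "discrimination_count",
    "pearson_with_stars",
    "enose_loadings",
    "rank_sensors",
]


@dataclass(frozen=True)
class ChannelSummary:
    """Per-time summary (mean, sd, n) of one channel's replicates."""

    channel: str
    times: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    ns: np.ndarray

    def __post_init__(self) -> None:
        for name in ("times", "means", "sds", "ns"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        if not (len(self.times) == len(self.means) == len(self.sds) == len(self.ns)):
            raise ValueError("summary arrays must have equal length")
        if np.any(self.sds < 0):
            raise ValueError("sd must be >= 0")
        if np.any(self.ns < 2):
            raise ValueError(f"channel {self.channel}: every group needs n >= 2")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, channel: str) -> "ChannelSummary":
        sub = df[df["channel"] == channel].sort_values("time_h")
        if sub.empty:
            raise KeyError(f"channel {channel!r} not in summary frame")
        return cls(
            channel=channel,
            times=sub["time_h"].to_numpy(float),
            means=sub["mean"].to_numpy(float),
            sds=sub["sd"].to_numpy(float),
            ns=sub["n"].to_numpy(int),
        )


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA reconstructed from group summaries."""

    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    mse: float


@dataclass(frozen=True)
class LetterGrouping:
    """Duncan homogeneous-subset letters, one string per time point.

    ``letters[i]`` annotates ``times[i]``; two time points sharing any
    letter are not significantly different at the test's alpha.
    ``order`` gives the time indices sorted by descending mean.
    """

    channel: str
    times: np.ndarray
    letters: tuple[str, ...]
    order: tuple[int, ...]
    alpha: float


@dataclass(frozen=True)
class CorrelationTable:
    """Pairwise Pearson r with significance stars."""

    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame

    def starred(self, a: str, b: str) -> str:
        return f"{self.r.loc[a, b]:.3f} {self.stars.loc[a, b]}".strip()


def summarize_panel(panel: ReplicatePanel) -> list[ChannelSummary]:
    """Mean, sample sd (n−1) and n per channel × time."""
    df = panel.frame
    g = df.groupby(["channel", "time_h"])["value"]
    agg = g.agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count").reset_index()
    if (agg["n"] < 2).any():
        bad = agg.loc[agg["n"] < 2].iloc[0]
        raise ValueError(
            f"cell (channel={bad.channel}, time_h={bad.time_h}) has fewer than 2 replicates"
        )
    out = []
    for ch in panel.channels:
        sub = agg[agg["channel"] == ch].sort_values("time_h")
        out.append(
            ChannelSummary(
                channel=ch,
                times=sub["time_h"].to_numpy(float),
                means=sub["mean"].to_numpy(float),
                sds=sub["sd"].to_numpy(float),
                ns=sub["n"].to_numpy(int),
            )
        )
    return out


def anova_from_summary(groups: ChannelSummary) -> AnovaResult:
    """Exact one-way ANOVA from (mean, sd, n) per group.

    ``SS_between = Σ n_i (m_i − grand)²`` and ``SS_within =
    Σ (n_i − 1) sd_i²`` reproduce the raw-data decomposition exactly.
    """
    m, sd, n = groups.means, groups.sds, groups.ns
    if len(m) < 2:
        raise ValueError("need at least 2 groups")
    n_tot = int(n.sum())
    grand = float(np.sum(n * m) / n_tot)
    ssb = float(np.sum(n * (m - grand) ** 2))
    ssw = float(np.sum((n - 1) * sd ** 2))
    df_b = len(m) - 1
    df_w = int(np.sum(n - 1))
    msb = ssb / df_b
    msw = ssw / df_w
    if msw == 0.0:
        f = np.inf if ssb > 0 else 0.0
        p = 0.0 if ssb > 0 else 1.0
        return AnovaResult(float(f), df_b, df_w, p, 0.0)
    f = msb / msw
    p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(float(f), df_b, df_w, p, msw)


def _duncan_ranges(alpha: float, df_within: int, n_h: float, mse: float, kmax: int) -> np.ndarray:
    """Critical ranges R_k, k = 2..kmax (index k-2).

    Duncan's protection level for a stretch of k means is
    ``alpha_k = 1 − (1 − alpha)^(k−1)``; the range is the studentized
    range quantile at that level times ``sqrt(MSE / n_h)``.
    """
    ks = np.arange(2, kmax + 1)
    q = stats.studentized_range.ppf((1.0 - alpha) ** (ks - 1), ks, df_within)
    return q * np.sqrt(mse / n_h)


def duncan_letters(
    groups: ChannelSummary,
    anova: AnovaResult,
    alpha: float = 0.05,
) -> LetterGrouping:
    """Duncan's multiple range test with homogeneous-subset letters.

    Means are sorted descending; a stretch of k adjacent means is
    homogeneous when its range is below the Duncan critical range
    R_k.  Letters are assigned to the maximal homogeneous stretches
    (the standard sweep), so any two means inside one stretch share
    its letter.  Unequal group sizes enter through the harmonic mean.
    """
    if not (0.0 < alpha < 0.5):
        raise ValueError("alpha must be in (0, 0.5)")
    if anova.df_within < 1:
        raise ValueError("df_within must be >= 1")
    k = len(groups.means)
    order = np.argsort(-groups.means, kind="stable")
    m = groups.means[order]
    n_h = len(groups.ns) / float(np.sum(1.0 / groups.ns))
    ranges = _duncan_ranges(alpha, anova.df_within, n_h, anova.mse, max(k, 2))

    def homogeneous(i: int, j: int) -> bool:
        if i == j:
            return True
        return (m[i] - m[j]) < ranges[j - i - 1]

    # maximal homogeneous stretches, sweeping from each start
    stretches: list[tuple[int, int]] = []
    for i in range(k):
        j = i
        while j + 1 < k and homogeneous(i, j + 1):
            j += 1
        stretches.append((i, j))
    maximal = [
        s for s in stretches
        if not any(o[0] <= s[0] and s[1] <= o[1] and o != s for o in stretches)
    ]
    maximal.sort()
    if len(maximal) > len(ascii_lowercase):  # pragma: no cover - >26 subsets
        raise RuntimeError("more homogeneous subsets than letters")

    per_sorted = ["" for _ in range(k)]
    for letter, (a, b) in zip(ascii_lowercase, maximal):
        for pos in range(a, b + 1):
            per_sorted[pos] += letter
    letters = ["" for _ in range(k)]
    for pos, idx in enumerate(order):
        letters[idx] = per_sorted[pos]
    return LetterGrouping(
        channel=groups.channel,
        times=groups.times,
        letters=tuple(letters),
        order=tuple(int(i) for i in order),
        alpha=alpha,
    )


def discrimination_count(grouping: LetterGrouping | Sequence[str]) -> int:
    """Number of distinct letters used across all time points."""
    letters = grouping.letters if isinstance(grouping, LetterGrouping) else grouping
    return len(set("".join(letters)))


def pearson_with_stars(series_by_name: Mapping[str, Sequence[float]]) -> CorrelationTable:
    """Pairwise Pearson correlations with 0.05/0.01 significance stars."""
    names = list(series_by_name)
    arrays = {}
    length = None
    for name in names:
        a = np.asarray(series_by_name[name], dtype=float)
        if length is None:
            length = len(a)
        if len(a) != length or length < 3:
            raise ValueError("all series must have equal length >= 3")
        if np.std(a) == 0:
            raise ValueError(f"series {name!r} has zero variance")
        arrays[name] = a
    r = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    p = pd.DataFrame(np.zeros((len(names), len(names))), index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            res = stats.pearsonr(arrays[a], arrays[b])
            r.loc[a, b] = r.loc[b, a] = res.statistic
            p.loc[a, b] = p.loc[b, a] = res.pvalue
    stars = p.map(lambda v: "**" if v < 0.01 else ("*" if v < 0.05 else ""))
    np.fill_diagonal(stars.values, "")
    return CorrelationTable(r=r, p=p, stars=stars)


def enose_loadings(summary_matrix: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Loadings analysis of a time × channel mean-response matrix.

    PCA on the centered (not variance-scaled) matrix, the usual view
    of which gas sensors dominate the array's overall response.
    Returns per-channel loadings on the leading components and the
    explained-variance fractions; rank-deficient input simply yields
    fewer components.
    """
    X = summary_matrix.to_numpy(dtype=float)
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("need at least 3 times and 2 channels")
    k = min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k)
    pca.fit(X)
    keep = pca.explained_variance_ > 1e-12 * pca.explained_variance_[0]
    comps = pca.components_[keep]
    fractions = pca.explained_variance_ratio_[keep]
    loadings = pd.DataFrame(
        comps.T,
        index=summary_matrix.columns,
        columns=[f"PC{i + 1}" for i in range(comps.shape[0])],
    )
    return loadings, fractions


def rank_sensors(
    counts: Mapping[str, int],
    correlations: Mapping[str, float],
    loadings: Mapping[str, float],
) -> list[str]:
    """Order channels by screening evidence; the first is selected.

    Sorts by discrimination count (descending), then |r| with the
    target series, then |PC1 loading|.
    """
    channels = set(counts)
    if channels != set(correlations) or channels != set(loadings):
        missing = (channels ^ set(correlations)) | (channels ^ set(loadings))
        raise ValueError(f"inputs do not cover the same channels: {sorted(missing)}")
    return sorted(
        channels,
        key=lambda ch: (-counts[ch], -abs(correlations[ch]), -abs(loadings[ch]), ch),
    )
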