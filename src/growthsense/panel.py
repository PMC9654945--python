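"""Replicate-level measurement panels.

A :class:`ReplicatePanel` holds tidy repeated measurements indexed by
(channel, time, replicate) — the layout shared by plate-count series
and by E-nose / E-tongue sensor responses.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["ReplicatePanel"]

REQUIRED_COLUMNS = ("time_h", "replicate", "channel", "value")


class ReplicatePanel:
    """Tidy panel of replicate sensor/count measurements.

    Wraps a DataFrame with columns ``time_h, replicate, channel,
    value`` and guarantees uniqueness of each (time, replicate,
    channel) cell.
    """

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"panel is missing column(s): {', '.join(missing)}")
        df = data.loc[:, list(REQUIRED_COLUMNS)].copy()
        df["time_h"] = pd.to_numeric(df["time_h"], errors="raise").astype(float)
        df["value"] = pd.to_numeric(df["value"], errors="raise").astype(float)
        if df["value"].isna().any() or df["time_h"].isna().any():
            raise ValueError("panel contains non-numeric or missing values")
        dup = df.duplicated(subset=["time_h", "replicate", "channel"])
        if dup.any():
            first = df.loc[dup.idxmax()]
            raise ValueError(
                "duplicate (time, replicate, channel) rows, e.g. "
                f"time_h={first.time_h}, replicate={first.replicate}, "
                f"channel={first.channel}"
            )
        self._df = df.sort_values(["channel", "time_h", "replicate"]).reset_index(drop=True)

    # -- basic accessors -------------------------------------------------
    @property
    def frame(self) -> pd.DataFrame:
        return self._df

    @property
    def times(self) -> np.ndarray:
        return np.array(sorted(self._df["time_h"].unique()), dtype=float)

    @property
    def channels(self) -> list[str]:
        return sorted(self._df["channel"].unique())

    @property
    def replicates(self) -> list:
        return sorted(self._df["replicate"].unique())

    def __len__(self) -> int:
        return len(self._df)

    # -- views ------------------------------------------------------------
    def channel(self, name: str) -> "ReplicatePanel":
        sub = self._df[self._df["channel"] == name]
        if sub.empty:
            raise KeyError(f"channel {name!r} not in panel")
        return ReplicatePanel(sub)

    def select_replicates(self, replicates: Iterable) -> "ReplicatePanel":
        keep = set(replicates)
        sub = self._df[self._df["replicate"].isin(keep)]
        if sub.empty:
            raise ValueError("replicate selection is empty")
        return ReplicatePanel(sub)

    def means(self, channel: str | None = None) -> pd.DataFrame:
        """Per-time mean responses; wide ``time x channel`` layout."""
        df = self._df if channel is None else self.channel(channel).frame
        wide = df.pivot_table(index="time_h", columns="channel", values="value", aggfunc="mean")
        wide.columns.name = None
        return wide.sort_index()

    def mean_series(self, channel: str) -> tuple[np.ndarray, np.ndarray]:
        m = self.means(channel)
        return m.index.to_numpy(dtype=float), m[channel].to_numpy(dtype=float)

    def values_matrix(self, channel: str) -> np.ndarray:
        """``time x replicate`` value matrix for one channel."""
        sub = self.channel(channel).frame
        wide = sub.pivot(index="time_h", columns="replicate", values="value")
        return wide.sort_index().to_numpy(dtype=float)

    # -- io ----------------------------------------------------------------
    def to_csv(self, path) -> None:
        # %.17g keeps write->read round-trips bit-exact
        self._df.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "ReplicatePanel":
        return cls(pd.read_csv(path, float_precision="round_trip"))

    @classmethod
    def from_arrays(
        cls,
        times: Sequence[float],
        values: np.ndarray,
        channel: str,
        replicates: Sequence | None = None,
    ) -> "ReplicatePanel":
        """Build a one-channel panel from a ``time x replicate`` matrix."""
        values = np.asarray(values, dtype=float)
        times = np.asarray(times, dtype=float)
        if values.shape[0] != len(times):
            raise ValueError("values must have one row per time point")
        n_rep = values.shape[1]
        reps = list(replicates) if replicates is not None else list(range(1, n_rep + 1))
        rows = {
            "time_h": np.repeat(times, n_rep),
            "replicate": np.tile(reps, len(times)),
            "channel": channel,
            "value": values.ravel(),
        }
        return cls(pd.DataFrame(rows))
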