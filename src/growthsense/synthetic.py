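"""Synthetic study generator for cold-stored juice spoilage panels.

Emulates the statistical design of a 7-day cold-storage experiment on
freshly squeezed strawberry juice: total bacterial counts (Log CFU/mL)
follow a Baranyi curve with a long lag at 4 °C; ten E-nose channels
respond (mostly negatively) to the latent count; nine E-tongue taste
channels carry weaker, mixed-sign associations (sweetness the
strongest positive one).  Sampling runs every 12 h for 168 h with 20
replicates per time, split 15 train / 5 test by replicate.

Channel calibrations are affine-plus-noise::

    value = intercept + slope * latent(t) + Gaussian(0, noise_sd)

with defaults anchored to the magnitudes, directions and
sensor-vs-count correlations a panel of this kind exhibits.  The full
fixture additionally injects smooth *session* components shared by
all replicates of a sampling time — the systematic drift that makes
real mean trajectories deviate from the kinetic curve and gives the
fused PCA its multi-component structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import CurveSeries, GrowthParams, ModelKind, evaluate_curve
from .panel import ReplicatePanel

__all__ = [
    "StudyDesign",
    "ChannelCalibration",
    "Fixture",
    "TABLE1_BARANYI",
    "simulate_counts",
    "simulate_panel",
    "make_fixture",
    "default_enose_calibrations",
    "default_taste_calibrations",
]

#: Plate-count Baranyi parameters of the cold-storage study.
TABLE1_BARANYI = GrowthParams(n0=3.996, nmax=5.337, mu_max=0.064, lag=97.85)

ENOSE_CHANNELS = tuple(f"S{i}" for i in range(1, 11))
TASTE_CHANNELS = (
    "Sourness", "Bitterness", "Astringency", "Aftertaste-B", "Aftertaste-A",
    "Umami", "Richness", "Saltiness", "Sweetness",
)

# E-nose anchors: response mean at 0 h and 168 h, a typical replicate
# sd, and the target mean-level correlation with the log count.
_ENOSE_ANCHORS: dict[str, tuple[float, float, float, float]] = {
    "S1": (0.754, 0.842, 0.014, 0.847),
    "S2": (16.176, 4.737, 1.217, -0.906),
    "S3": (0.881, 0.931, 0.007, 0.823),
    "S4": (1.065, 1.033, 0.005, -0.883),
    "S5": (0.915, 0.956, 0.005, 0.791),
    "S6": (1.776, 1.527, 0.055, -0.875),
    "S7": (10.719, 5.724, 0.656, -0.937),
    "S8": (1.358, 1.254, 0.028, -0.806),
    "S9": (6.022, 3.215, 0.287, -0.934),
    "S10": (1.113, 1.106, 0.007, -0.142),
}

# Taste channels: target correlation of the per-time mean with the
# log count; sweetness is the strong positive association that makes
# the E-tongue usable for growth prediction.
_TASTE_TARGET_R: dict[str, float] = {
    "Sourness": 0.243,
    "Bitterness": -0.044,
    "Astringency": 0.219,
    "Aftertaste-B": 0.092,
    "Aftertaste-A": 0.166,
    "Umami": -0.578,
    "Richness": 0.641,
    "Saltiness": -0.349,
    "Sweetness": 0.772,
}

_TASTE_SCALE = 0.4  # sd of a taste channel's per-time mean trajectory
_TASTE_BASELINE = 5.0  # arbitrary taste-unit offset

# session-drift profile weights (relative amplitudes of the shared
# smooth components); squared values decline like the variance split
# of a fused sensor PCA after the leading count-driven component
_SESSION_WEIGHTS = (0.771, 0.475, 0.422)
_SESSION_SHARE = 0.85  # share of non-signal mean variance that is session drift


@dataclass(frozen=True)
class StudyDesign:
    """Sampling design of the storage experiment."""

    times: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 169.0, 12.0)
    )
    replicates: int = 20
    train_replicates: int = 15
    channels: tuple[str, ...] = ENOSE_CHANNELS + TASTE_CHANNELS

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        if len(self.times) < 5:
            raise ValueError("need at least 5 sampling times")
        if self.replicates < 2:
            raise ValueError("need at least 2 replicates")
        if not (0 < self.train_replicates < self.replicates):
            raise ValueError("train_replicates must split the replicates")

    @property
    def test_replicates(self) -> int:
        return self.replicates - self.train_replicates

    @property
    def train_ids(self) -> list[int]:
        return list(range(1, self.train_replicates + 1))

    @property
    def test_ids(self) -> list[int]:
        return list(range(self.train_replicates + 1, self.replicates + 1))


@dataclass(frozen=True)
class ChannelCalibration:
    """Affine response of one sensor channel to the latent log count."""

    channel: str
    intercept: float
    slope: float
    noise_sd: float

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _latent_default(design: StudyDesign) -> CurveSeries:
    return evaluate_curve(ModelKind.BARANYI, TABLE1_BARANYI, design.times)


def default_enose_calibrations(
    design: StudyDesign | None = None,
) -> list[ChannelCalibration]:
    """E-nose calibrations from the response anchors at 0 h and 168 h."""
    design = design or StudyDesign()
    latent = _latent_default(design).values
    dl = latent[-1] - latent[0]
    out = []
    for ch in ENOSE_CHANNELS:
        v0, v1, sd, _ = _ENOSE_ANCHORS[ch]
        slope = (v1 - v0) / dl
        out.append(
            ChannelCalibration(
                channel=ch, intercept=v0 - slope * latent[0], slope=slope, noise_sd=sd
            )
        )
    return out


def default_taste_calibrations(
    design: StudyDesign | None = None,
) -> list[ChannelCalibration]:
    """Taste calibrations whose replicate noise attenuates the
    mean-level correlation with the latent count to the target value."""
    design = design or StudyDesign()
    latent = _latent_default(design).values
    sd_lat = float(np.std(latent, ddof=1))
    out = []
    for ch in TASTE_CHANNELS:
        r = _TASTE_TARGET_R[ch]
        slope = r * _TASTE_SCALE / sd_lat
        noise_sd = _TASTE_SCALE * np.sqrt((1.0 - r ** 2) * design.replicates)
        out.append(
            ChannelCalibration(
                channel=ch, intercept=_TASTE_BASELINE, slope=slope, noise_sd=noise_sd
            )
        )
    return out


def _streams(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(c) for name, c in zip(names, children)}


def simulate_counts(
    params: GrowthParams = TABLE1_BARANYI,
    kind: ModelKind | str = ModelKind.BARANYI,
    design: StudyDesign | None = None,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> ReplicatePanel:
    """Replicate plate-count panel: curve(t) + Gaussian(0, noise_sd)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    design = design or StudyDesign()
    curve = evaluate_curve(kind, params, design.times).values
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    values = curve[:, None] + rng.normal(0.0, noise_sd, size=(len(design.times), design.replicates))
    return ReplicatePanel.from_arrays(design.times, values, "log_cfu")


def simulate_panel(
    latent: CurveSeries,
    calibrations: list[ChannelCalibration],
    design: StudyDesign | None = None,
    seed: int = 0,
) -> ReplicatePanel:
    """Sensor panel from affine channel calibrations around ``latent``.

    Each channel gets its own random sub-stream, so adding or removing
    channels does not perturb the others.
    """
    design = design or StudyDesign()
    if len(latent.times) != len(design.times) or not np.allclose(latent.times, design.times):
        raise ValueError("latent series must be sampled on the design time grid")
    known = set(design.channels)
    for cal in calibrations:
        if cal.channel not in known:
            raise ValueError(f"calibration channel {cal.channel!r} not in design")
    rngs = _streams(seed, [c.channel for c in calibrations])
    frames = []
    for cal in calibrations:
        base = cal.intercept + cal.slope * latent.values
        noise = rngs[cal.channel].normal(
            0.0, cal.noise_sd, size=(len(design.times), design.replicates)
        ) if cal.noise_sd > 0 else 0.0
        values = base[:, None] + noise
        frames.append(
            ReplicatePanel.from_arrays(design.times, np.atleast_2d(values), cal.channel).frame
        )
    return ReplicatePanel(pd.concat(frames, ignore_index=True))


@dataclass(frozen=True)
class Fixture:
    """A complete synthetic study: counts, sensors, split, provenance."""

    design: StudyDesign
    latent: CurveSeries
    counts: ReplicatePanel
    sensors: ReplicatePanel
    calibrations: dict[str, ChannelCalibration]
    train_ids: list[int]
    test_ids: list[int]
    seed: int

    @property
    def all_channels(self) -> list[str]:
        return list(self.sensors.channels)


def _session_profiles(times: np.ndarray, latent: np.ndarray) -> np.ndarray:
    """Smooth unit-sd drift profiles shared by all channels.

    Each profile is orthogonalised against the latent growth trend so
    that session drift perturbs channels without mimicking growth.
    """
    span = times[-1] - times[0]
    f = np.stack(
        [
            np.sin(2 * np.pi * (times - times[0]) / span),
            np.cos(2 * np.pi * (times - times[0]) / span),
            np.sin(4 * np.pi * (times - times[0]) / span),
        ]
    )
    g = (latent - latent.mean()) / np.linalg.norm(latent - latent.mean())
    f = f - np.outer(f @ g, g)
    f = f - f.mean(axis=1, keepdims=True)
    return f / f.std(axis=1, ddof=1, keepdims=True)


def make_fixture(
    seed: int,
    design: StudyDesign | None = None,
    noise_scale: float = 1.0,
) -> Fixture:
    """Generate the full study dataset.

    ``noise_scale`` scales every stochastic component (replicate noise
    and session drift); 0 yields a noiseless panel whose means sit
    exactly on the calibrated curves.
    """
    design = design or StudyDesign()
    latent = _latent_default(design)
    sd_lat = float(np.std(latent.values, ddof=1))
    n_rep = design.replicates
    t = design.times
    profiles = _session_profiles(t, latent.values)
    w = np.asarray(_SESSION_WEIGHTS)
    w = w / np.sqrt(np.sum(w ** 2))

    counts = simulate_counts(
        TABLE1_BARANYI, ModelKind.BARANYI, design, noise_sd=0.1 * noise_scale, seed=seed
    )

    # per-channel budgets: signal variance is slope²·var(latent); the
    # non-signal mean-level variance needed to reach the target
    # correlation is split between shared session drift and iid noise
    cals: dict[str, ChannelCalibration] = {}
    nuis_sd: dict[str, float] = {}
    enose = {c.channel: c for c in default_enose_calibrations(design)}
    for ch, (v0, v1, sd, r_target) in _ENOSE_ANCHORS.items():
        cal = enose[ch]
        sig_var = (cal.slope * sd_lat) ** 2
        nonsig = sig_var * (1.0 / r_target ** 2 - 1.0)
        iid_mean_var = cal.noise_sd ** 2 / n_rep
        nuis_sd[ch] = float(np.sqrt(max(nonsig - iid_mean_var, 0.0)))
        cals[ch] = cal
    for cal in default_taste_calibrations(design):
        ch = cal.channel
        r = _TASTE_TARGET_R[ch]
        nonsig_var = _TASTE_SCALE ** 2 * (1.0 - r ** 2)
        nuis_sd[ch] = float(np.sqrt(_SESSION_SHARE * nonsig_var))
        iid = float(np.sqrt((1.0 - _SESSION_SHARE) * nonsig_var * n_rep))
        cals[ch] = ChannelCalibration(
            channel=ch, intercept=cal.intercept, slope=cal.slope, noise_sd=iid
        )

    names = list(cals)
    rngs = _streams(seed, ["__session__"] + names)
    frames = []
    for ch in names:
        cal = cals[ch]
        g = rngs[ch].standard_normal(len(w))
        session = noise_scale * nuis_sd[ch] * (w * g) @ profiles
        base = cal.intercept + cal.slope * latent.values + session
        noise = rngs[ch].normal(0.0, cal.noise_sd * noise_scale, size=(len(t), n_rep))
        frames.append(ReplicatePanel.from_arrays(t, base[:, None] + noise, ch).frame)
    sensors = ReplicatePanel(pd.concat(frames, ignore_index=True))

    return Fixture(
        design=design,
        latent=latent,
        counts=counts,
        sensors=sensors,
        calibrations=cals,
        train_ids=design.train_ids,
        test_ids=design.test_ids,
        seed=seed,
    )
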