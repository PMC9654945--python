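"""End-to-end orchestration: screen sensors, fit models, fuse, report.

``run_pipeline`` executes the full study analysis on a tidy
measurement CSV (or a generated fixture): summarise the replicate
panel, screen E-nose channels by ANOVA/Duncan/Pearson/loadings,
pick the taste channel by correlation with the counts, fit the four
primary models to each data source (plate counts, selected E-nose
channel, selected taste channel, negated fused composite), and
predict shelf life from the count fits.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fusion as fusion_mod
from . import selection
from .fitting import FitOptions, FitResult, fit_all, curve_correlation
from .models import CurveSeries, shelf_life_time
from .panel import ReplicatePanel
from .synthetic import ENOSE_CHANNELS, TASTE_CHANNELS, make_fixture

__all__ = ["PipelineConfig", "StudyReport", "run_pipeline", "load_panel", "render_report"]

log = logging.getLogger("growthsense")

MODEL_TABLE_COLUMNS = [
    "model", "lambda_h", "mu_max_per_h", "r2_train", "rmse_train",
    "r2_test", "rmse_test", "r",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one pipeline run.

    ``input_path`` is a measurement CSV (columns ``time_h, replicate,
    channel, value`` including a ``log_cfu`` channel) or the literal
    ``fixture:<seed>`` to generate a synthetic study.
    """

    input_path: str = "fixture:1"
    alpha: float = 0.05
    min_cum_variance: float = 0.90
    shelf_life_threshold: float = 5.0
    fit_options: FitOptions = field(default_factory=FitOptions)
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 0.5):
            raise ValueError("alpha must be in (0, 0.5)")
        if not np.isfinite(self.shelf_life_threshold):
            raise ValueError("shelf-life threshold must be finite")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        fit = raw.pop("fit_options", None)
        cfg = cls(**raw) if fit is None else cls(**raw, fit_options=FitOptions(**fit))
        return cfg

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class StudyReport:
    """Everything one run produced, serialisable to JSON/CSV/markdown."""

    selected_enose: str
    enose_evidence: dict
    selected_taste: str
    taste_evidence: dict
    fits: dict[str, list[dict]]
    failures: list[dict]
    fusion: dict
    shelf_life: dict
    provenance: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_panel(path: str | Path) -> ReplicatePanel:
    """Read a tidy measurement CSV into a validated panel."""
    return ReplicatePanel.from_csv(path)


def fit_packaged_scores(options: FitOptions = FitOptions()) -> list[FitResult]:
    """Fit the four models to the packaged fused composite score.

    Loads the shipped per-time PC-score table, negates the composite
    into a growth-like series and runs :func:`fit_all` — the
    "fused-fit" entry point used when only the published score table
    is available.
    """
    from .datasets import load_pc_scores
    from .fusion import orient_for_fitting

    df, _ = load_pc_scores()
    growth_like, _sign = orient_for_fitting(df["score"])
    series = CurveSeries(df.index.to_numpy(dtype=float), growth_like.to_numpy())
    return fit_all(series, options)


def _fit_source(
    name: str,
    series: CurveSeries,
    options: FitOptions,
    reference: np.ndarray | None,
    fits: dict,
    failures: list,
) -> list[FitResult]:
    t0 = _time.perf_counter()
    try:
        results = fit_all(series, options, reference)
        fits[name] = [fr.to_dict() for fr in results]
        log.info("fitted %s in %.2fs", name, _time.perf_counter() - t0)
        return results
    except Exception as exc:
        failures.append({"source": name, "error": str(exc)})
        fits[name] = []
        log.error("fit failed for %s: %s", name, exc)
        return []


def run_pipeline(config: PipelineConfig) -> StudyReport:
    """Run the full analysis; deterministic for a given config."""
    seed = config.fit_options.seed
    if config.input_path.startswith("fixture:"):
        fixture_seed = int(config.input_path.split(":", 1)[1])
        fx = make_fixture(fixture_seed)
        sensors, counts = fx.sensors, fx.counts
        log.info("generated fixture with seed %d", fixture_seed)
    else:
        panel = load_panel(config.input_path)
        if "log_cfu" not in panel.channels:
            raise ValueError("input panel must contain a 'log_cfu' channel")
        counts = panel.channel("log_cfu")
        rest = panel.frame[panel.frame["channel"] != "log_cfu"]
        sensors = ReplicatePanel(rest)

    times, count_means = counts.mean_series("log_cfu")
    enose = [ch for ch in sensors.channels if ch in ENOSE_CHANNELS]
    taste = [ch for ch in sensors.channels if ch in TASTE_CHANNELS]
    if not enose or not taste:
        raise ValueError("panel must contain E-nose (S1..S10) and taste channels")

    # --- E-nose screening -------------------------------------------------
    summaries = {s.channel: s for s in selection.summarize_panel(sensors)}
    counts_by_channel: dict[str, int] = {}
    letter_table: dict[str, tuple[str, ...]] = {}
    for ch in enose:
        anova = selection.anova_from_summary(summaries[ch])
        letters = selection.duncan_letters(summaries[ch], anova, config.alpha)
        counts_by_channel[ch] = selection.discrimination_count(letters)
        letter_table[ch] = letters.letters
    mean_matrix = sensors.means()
    corr = selection.pearson_with_stars(
        {ch: mean_matrix[ch].to_numpy() for ch in enose} | {"log_cfu": count_means}
    )
    r_with_counts = {ch: float(corr.r.loc[ch, "log_cfu"]) for ch in enose}
    loadings, fractions = selection.enose_loadings(mean_matrix[enose])
    pc1 = {ch: float(loadings.loc[ch, "PC1"]) for ch in enose}
    ranked = selection.rank_sensors(counts_by_channel, r_with_counts, pc1)
    selected_enose = ranked[0]
    enose_evidence = {
        "ranking": ranked,
        "discrimination_counts": counts_by_channel,
        "r_with_log_cfu": r_with_counts,
        "pc1_loadings": pc1,
        "loadings_variance_fractions": [float(v) for v in fractions[:2]],
        "duncan_letters": {ch: list(v) for ch, v in letter_table.items()},
    }

    # --- taste screening ---------------------------------------------------
    taste_corr = selection.pearson_with_stars(
        {ch: mean_matrix[ch].to_numpy() for ch in taste} | {"log_cfu": count_means}
    )
    taste_r = {ch: float(taste_corr.r.loc[ch, "log_cfu"]) for ch in taste}
    selected_taste = max(taste_r, key=lambda ch: abs(taste_r[ch]))
    taste_evidence = {
        "r_with_log_cfu": taste_r,
        "stars": {ch: taste_corr.stars.loc[ch, "log_cfu"] for ch in taste},
    }

    # --- fusion -------------------------------------------------------------
    fuser = fusion_mod.SensorFusionPCA(min_cum_variance=config.min_cum_variance)
    fuser.fit(mean_matrix[enose + taste])
    fres = fuser.fusion_result(mean_matrix[enose + taste])
    growth_like, sign = fusion_mod.orient_for_fitting(fres.composite)
    fusion_info = {
        "k": fres.k,
        "variance_fractions": [float(v) for v in fres.variance_fractions],
        "composite": {float(t): float(v) for t, v in fres.composite.items()},
        "fit_sign": sign,
    }

    # --- model fits ----------------------------------------------------------
    fits: dict[str, list[dict]] = {}
    failures: list[dict] = []
    count_results = _fit_source(
        "counts", CurveSeries(times, count_means), config.fit_options, count_means,
        fits, failures,
    )
    for name, ch in (("enose", selected_enose), ("taste", selected_taste)):
        _t, means = sensors.mean_series(ch)
        _fit_source(name, CurveSeries(times, means), config.fit_options, count_means,
                    fits, failures)
    _fit_source("fused", CurveSeries(times, growth_like.to_numpy()),
                config.fit_options, count_means, fits, failures)

    # --- shelf life from the count fits --------------------------------------
    shelf: dict[str, float | None] = {}
    for fr in count_results:
        shelf[fr.kind.value] = shelf_life_time(fr.kind, fr.params, config.shelf_life_threshold)

    report = StudyReport(
        selected_enose=selected_enose,
        enose_evidence=enose_evidence,
        selected_taste=selected_taste,
        taste_evidence=taste_evidence,
        fits=fits,
        failures=failures,
        fusion=fusion_info,
        shelf_life={"threshold_log_cfu": config.shelf_life_threshold, "hours": shelf},
        provenance={
            "seed": seed,
            "input": config.input_path,
            "config_digest": config.digest(),
            "timestamp": _time.strftime("%Y-%m-%dT%H:%M:%S"),
        },
    )
    if config.output_dir:
        render_report(report, Path(config.output_dir))
    return report


def _model_table(rows: list[dict]) -> pd.DataFrame:
    records = []
    for d in rows:
        records.append(
            {
                "model": d["kind"],
                "lambda_h": d["params"]["lag"],
                "mu_max_per_h": d["params"]["mu_max"],
                "r2_train": d["train"]["r2"],
                "rmse_train": d["train"]["rmse"],
                "r2_test": d["test"]["r2"] if d["test"] else None,
                "rmse_test": d["test"]["rmse"] if d["test"] else None,
                "r": d["r"],
            }
        )
    return pd.DataFrame(records, columns=MODEL_TABLE_COLUMNS)


def render_report(
    report: StudyReport,
    out_dir: str | Path,
    formats: tuple[str, ...] = ("json", "csv", "markdown"),
) -> list[Path]:
    """Write the report as JSON (canonical), CSV model tables and markdown."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if "json" in formats:
        p = out / "report.json"
        p.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
        written.append(p)
    if "csv" in formats:
        for source, rows in report.fits.items():
            if not rows:
                continue
            p = out / f"fits_{source}.csv"
            _model_table(rows).to_csv(p, index=False)
            written.append(p)
    if "markdown" in formats:
        lines = [
            "# Growth-model study report",
            "",
            f"Selected E-nose channel: **{report.selected_enose}**",
            f"Selected taste channel: **{report.selected_taste}**",
            f"Fused components retained: {report.fusion['k']}",
            "",
        ]
        for source, rows in report.fits.items():
            if not rows:
                continue
            lines.append(f"## Fits — {source}")
            lines.append("```\n" + _model_table(rows).to_string(index=False) + "\n```")
            lines.append("")
        threshold = report.shelf_life["threshold_log_cfu"]
        crossed = {
            m: h for m, h in report.shelf_life["hours"].items() if h is not None
        }
        if crossed:
            lines.append(
                f"Shelf life (counts reach {threshold:g} Log CFU/mL): "
                + ", ".join(f"{m}: {h:.1f} h" for m, h in crossed.items())
            )
        if report.failures:
            lines.append("## Failures")
            for f in report.failures:
                lines.append(f"- {f['source']}: {f['error']}")
        p = out / "report.md"
        p.write_text("\n".join(lines))
        written.append(p)
    return written
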