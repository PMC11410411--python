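"""Simulate -> analyze -> stats pipeline with file-based stage boundaries.

Each stage reads and writes files, so stages are independently testable and
resumable: ``simulate`` writes canonical-CSV trials plus ground truth and a
run manifest; ``analyze`` turns a directory of trials into a tidy per-cycle
metrics CSV; ``stats`` turns the metrics CSV into ANOVA/Tukey JSON and a
mean +/- SD summary table (one row per metric, one column per condition,
with significance markers against the no-assistance and AFO references).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CONDITIONS, METRICS, TrialRecording
from .decomposition import decomposition_all_pairs
from .events import detect_events, segment_cycles
from .exceptions import ConfigurationError, DataQualityError, GaitError
from .metrics import compute_sagittal_angles, kinematic_maxima, spatiotemporal
from .stats import AnovaResult, average_hierarchy, oneway_anova_tukey, paired_t_bonferroni
from .synthetic import SyntheticConfig, generate_cohort, generate_comfort_scores
from .trial_io import RunConfig, read_trial, write_metrics_table, write_trial

logger = logging.getLogger("gaitdecomp")

__all__ = [
    "RunManifest",
    "analyze_trial",
    "cmd_simulate",
    "cmd_analyze",
    "cmd_stats",
    "run_all",
    "format_mean_sd",
]


@dataclass
class RunManifest:
    stage: str
    seed: int
    version: str
    config: dict
    files: dict[str, str] = field(default_factory=dict)
    timestamp: str = ""

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _manifest(stage: str, seed: int, config: dict, files: list[Path], root: Path) -> RunManifest:
    from . import __version__

    return RunManifest(
        stage=stage,
        seed=seed,
        version=__version__,
        config=config,
        files={str(p.relative_to(root)): _sha256(p) for p in files},
        timestamp=datetime.now(timezone.utc).isoformat(),
    )


def analyze_trial(
    recording: TrialRecording,
    config: RunConfig | None = None,
    trial_index: int = 1,
) -> pd.DataFrame:
    """All 12 per-cycle metrics for the analyzed (paretic) side of one trial.

    Returns a tidy frame: participant, condition, trial, cycle, metric, value.
    """
    cfg = config or RunConfig()
    side = recording.paretic_side if cfg.side == "paretic" else cfg.side
    events = detect_events(recording, filter_cutoff=cfg.filter_cutoff)
    cycles = segment_cycles(events, side)
    angles = compute_sagittal_angles(recording)
    st = spatiotemporal(recording, events, side=side, filter_cutoff=cfg.filter_cutoff)
    decomp = decomposition_all_pairs(
        angles,
        cycles,
        side=side,
        pause_threshold_fraction=cfg.pause_threshold_fraction,
        velocity_floor=cfg.velocity_floor,
        filter_cutoff=cfg.filter_cutoff,
    )
    rows = []
    for c_idx, cycle in enumerate(cycles):
        km = kinematic_maxima(angles, cycle, side=side)
        values = {m: st.per_cycle[m][c_idx] for m in st.per_cycle}
        values.update(km.as_dict())
        for pair, vals in decomp.per_cycle.items():
            values[f"{pair}_decomposition"] = vals[c_idx]
        for metric in METRICS:
            rows.append(
                (recording.participant_id, recording.condition, trial_index, c_idx, metric, values[metric])
            )
    return pd.DataFrame(rows, columns=["participant", "condition", "trial", "cycle", "metric", "value"])


def cmd_simulate(
    config: RunConfig | None = None,
    out_dir=None,
    seed: int | None = None,
    trial_format: str = "canonical_csv",
) -> RunManifest:
    """Generate the synthetic cohort and write trials + ground truth + manifest."""
    cfg = config or RunConfig()
    cfg.validate()
    out = Path(out_dir or cfg.output_dir or ".")
    trials_dir = out / "trials"
    trials_dir.mkdir(parents=True, exist_ok=True)
    syn = SyntheticConfig(**{**cfg.synthetic, "seed": seed if seed is not None else cfg.seed})
    syn.validate()
    logger.info("simulate: %d participants x %d conditions", syn.n_participants, len(syn.conditions))
    trials, truth = generate_cohort(syn)
    ext = {"canonical_csv": ".csv", "trc": ".trc"}.get(trial_format)
    if ext is None:
        raise ConfigurationError(f"unsupported simulate output format {trial_format!r}")
    files = []
    counters: dict[tuple[str, str], int] = {}
    for rec in trials:
        key = (rec.participant_id, rec.condition)
        counters[key] = counters.get(key, 0) + 1
        path = trials_dir / f"{rec.participant_id}_{rec.condition}_t{counters[key]}{ext}"
        write_trial(rec, path, format=trial_format)
        files.append(path)
    truth_path = out / "ground_truth.json"
    truth.to_json(truth_path)
    files.append(truth_path)
    comfort = generate_comfort_scores(syn.n_participants, seed=syn.seed)
    comfort_path = out / "comfort_scores.csv"
    comfort.to_csv(comfort_path, index_label="participant")
    files.append(comfort_path)
    manifest = _manifest("simulate", syn.seed, {"run": asdict(cfg)}, files, out)
    manifest.write(out / "manifest.json")
    logger.info("simulate: wrote %d trials to %s", len(trials), trials_dir)
    return manifest


def cmd_analyze(in_dir, out_path, config: RunConfig | None = None) -> pd.DataFrame:
    """Analyze every trial in a directory into the tidy metrics CSV.

    Unreadable or unanalyzable trials are logged and skipped; the run fails
    with a data-quality error when more than 10% of trials are skipped.
    """
    cfg = config or RunConfig()
    in_dir = Path(in_dir)
    trial_paths = sorted(
        p for p in in_dir.glob("*") if p.suffix.lower() in (".csv", ".trc")
    )
    if not trial_paths:
        raise DataQualityError(f"no trial files found in {in_dir}")
    frames, skipped = [], []
    for path in trial_paths:
        try:
            rec = read_trial(path, max_gap=cfg.max_gap_frames)
            t_idx = 1
            stem = path.stem
            if "_t" in stem:
                try:
                    t_idx = int(stem.rsplit("_t", 1)[1])
                except ValueError:
                    pass
            frames.append(analyze_trial(rec, cfg, trial_index=t_idx))
        except GaitError as exc:
            skipped.append(path.name)
            logger.warning("analyze: skipping %s: %s", path.name, exc)
    if skipped and len(skipped) > 0.10 * len(trial_paths):
        raise DataQualityError(
            f"{len(skipped)}/{len(trial_paths)} trials skipped: {skipped[:5]} ..."
        )
    table = pd.concat(frames, ignore_index=True)
    if out_path is not None:
        write_metrics_table(table, out_path)
        logger.info("analyze: %d trials -> %s (%d skipped)", len(frames), out_path, len(skipped))
    return table


def format_mean_sd(mean: float, sd: float) -> str:
    """Render a table cell like ``0.65 ± 0.25`` (two decimals below 10, one above)."""

    def fmt(v: float) -> str:
        return f"{v:.1f}" if abs(v) >= 10 else f"{v:.2f}"

    return f"{fmt(mean)} ± {fmt(sd)}"


def _summary_table(cohort: pd.DataFrame, results: dict[str, AnovaResult], conditions) -> pd.DataFrame:
    rows = []
    reference, afo_ref = conditions[0], "afo"
    for metric, res in results.items():
        row: dict[str, str] = {"metric": metric}
        sig = {t.pair: t.significant for t in res.tukey}
        sig.update({(b, a): s for (a, b), s in list(sig.items())})
        omnibus = res.p < res.alpha
        for cond in conditions:
            vals = cohort.loc[cohort["condition"] == cond, metric].to_numpy(dtype=float)
            cell = format_mean_sd(float(np.mean(vals)), float(np.std(vals, ddof=1)))
            marks = []
            if omnibus and cond != reference and sig.get((reference, cond), False):
                marks.append("*")
            if omnibus and cond not in (reference, afo_ref) and sig.get((afo_ref, cond), False):
                marks.append("**")
            row[cond] = cell + ",".join(marks)
        rows.append(row)
    return pd.DataFrame(rows)


def cmd_stats(
    metrics_csv,
    out_dir,
    config: RunConfig | None = None,
    comfort_csv=None,
) -> dict:
    """ANOVA + Tukey for every metric; writes stats.json and summary_table.csv."""
    cfg = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tidy = pd.read_csv(metrics_csv)
    conditions = tuple(c for c in CONDITIONS if c in set(tidy["condition"]))
    if not conditions:
        conditions = tuple(dict.fromkeys(tidy["condition"]))
    cohort = average_hierarchy(tidy, conditions=conditions)
    results: dict[str, AnovaResult] = {}
    for metric in METRICS:
        if metric in cohort.columns:
            results[metric] = oneway_anova_tukey(cohort, metric, alpha=cfg.alpha, conditions=conditions)
    payload: dict = {"metrics": {m: r.to_dict() for m, r in results.items()}}

    if comfort_csv is not None and Path(comfort_csv).exists():
        comfort = pd.read_csv(comfort_csv, index_col=0)
        payload["comfort"] = {
            "alpha_adjusted": cfg.comfort_alpha,
            "pairs": [r.to_dict() for r in paired_t_bonferroni(comfort, cfg.comfort_alpha)],
        }

    with open(out / "stats.json", "w") as fh:
        json.dump(payload, fh, indent=1)
    table = _summary_table(cohort, results, conditions)
    table.to_csv(out / "summary_table.csv", index=False)
    cohort.to_csv(out / "cohort_table.csv", index=False)
    logger.info("stats: %d metric blocks -> %s", len(results), out / "stats.json")
    return payload


def run_all(config: RunConfig | None = None, out_dir=".", seed: int | None = None) -> dict:
    """simulate -> analyze -> stats in one call; returns the stats payload."""
    cfg = config or RunConfig()
    out = Path(out_dir)
    cmd_simulate(cfg, out, seed=seed)
    metrics_csv = out / "metrics.csv"
    cmd_analyze(out / "trials", metrics_csv, cfg)
    return cmd_stats(metrics_csv, out / "stats", cfg, comfort_csv=out / "comfort_scores.csv")
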