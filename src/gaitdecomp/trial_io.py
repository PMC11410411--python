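"""Trial and results I/O.

Canonical trial dialect: CSV with a ``#``-prefixed metadata block
(``sample_rate``, ``participant_id``, ``condition``, ``paretic_side``), a
header row (``time`` then ``<marker>_<side>_{X,Y,Z}`` columns, sacrum
side-less), a units row (``s`` then ``m``), and one row per frame. The
reader is dialect-strict: missing metadata, wrong units, or a missing
required marker is an error, never a silent guess. Marker dropouts (empty
cells) up to ``max_gap`` frames are linearly interpolated; longer gaps are a
data-quality error naming the frame range.

TRC (tab-separated Motion Analysis text format) import/export carries
positions and rate only; C3D is a binary format this installation does not
read or write.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import SIDES, TrialRecording, marker_name
from .exceptions import (
    ConfigurationError,
    DataQualityError,
    FormatError,
    UnsupportedFormatError,
)

__all__ = [
    "RunConfig",
    "read_trial",
    "write_trial",
    "write_metrics_table",
    "load_config",
    "fill_gaps",
]

_META_KEYS = ("sample_rate", "participant_id", "condition", "paretic_side")
_AXES = ("X", "Y", "Z")


@dataclass
class RunConfig:
    """Analysis-stage parameters.

    ``pause_threshold_fraction`` is the relative angular-velocity threshold
    below which a joint counts as paused (0.05 = 5% of the per-cycle peak);
    ``velocity_floor`` (deg/s) triggers the frozen-joint rule;
    ``filter_cutoff`` (Hz) is the zero-phase low-pass applied before
    differentiation and event detection; ``alpha`` the significance level of
    the condition comparisons and ``comfort_alpha`` the Bonferroni-adjusted
    level for the comfort-score paired t-tests.
    """

    pause_threshold_fraction: float = 0.05
    velocity_floor: float = 1.0
    filter_cutoff: float = 6.0
    alpha: float = 0.05
    comfort_alpha: float = 0.03
    seed: int = 0
    max_gap_frames: int = 10
    side: str = "paretic"
    input_dir: str | None = None
    output_dir: str | None = None
    synthetic: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not 0.0 < self.pause_threshold_fraction < 1.0:
            raise ConfigurationError(
                f"pause_threshold_fraction must be in (0, 1), got {self.pause_threshold_fraction}"
            )
        if self.velocity_floor < 0:
            raise ConfigurationError(f"velocity_floor must be >= 0, got {self.velocity_floor}")
        for key in ("alpha", "comfort_alpha"):
            val = getattr(self, key)
            if not 0.0 < val < 1.0:
                raise ConfigurationError(f"{key} must be in (0, 1), got {val}")
        if self.max_gap_frames < 0:
            raise ConfigurationError(f"max_gap_frames must be >= 0, got {self.max_gap_frames}")
        if self.side not in ("paretic", "left", "right", "both"):
            raise ConfigurationError(f"side must be paretic/left/right/both, got {self.side!r}")
        if self.synthetic:
            from .synthetic import SyntheticConfig

            known = {f.name for f in dc_fields(SyntheticConfig)}
            unknown = set(self.synthetic) - known
            if unknown:
                raise ConfigurationError(f"unknown synthetic config keys: {sorted(unknown)}")


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration (strict schema)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config root must be a mapping, got {type(raw).__name__}")
    known = {f.name for f in dc_fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def fill_gaps(arr: np.ndarray, max_gap: int, name: str = "marker") -> np.ndarray:
    """Linearly interpolate NaN runs of length <= max_gap; longer runs error."""
    out = arr.astype(float).copy()
    for col in range(out.shape[1]):
        y = out[:, col]
        isnan = np.isnan(y)
        if not isnan.any():
            continue
        # locate NaN runs
        idx = np.where(isnan)[0]
        runs = np.split(idx, np.where(np.diff(idx) > 1)[0] + 1)
        for run in runs:
            a, b = int(run[0]), int(run[-1])
            if a == 0 or b == out.shape[0] - 1 or len(run) > max_gap:
                raise DataQualityError(
                    f"{name}: gap of {len(run)} frame(s) at frames {a}-{b} exceeds "
                    f"the {max_gap}-frame interpolation limit or touches the trial edge"
                )
            y[a : b + 1] = np.interp(np.arange(a, b + 1), [a - 1, b + 1], [y[a - 1], y[b + 1]])
    return out


def _required_columns() -> list[str]:
    cols = [f"sacrum_{ax}" for ax in _AXES]
    for side in SIDES:
        for base in ("hip", "knee", "ankle", "heel", "toe"):
            cols += [f"{marker_name(base, side)}_{ax}" for ax in _AXES]
    return cols


def write_trial(recording: TrialRecording, path, format: str = "canonical_csv") -> None:
    """Write a trial in the canonical CSV dialect or as TRC."""
    recording.validate()
    path = Path(path)
    if format == "canonical_csv":
        _write_canonical_csv(recording, path)
    elif format == "trc":
        _write_trc(recording, path)
    elif format == "c3d":
        raise UnsupportedFormatError("C3D export is not available; use canonical_csv or trc")
    else:
        raise FormatError(f"unknown trial format {format!r}")


def read_trial(path, format: str | None = None, max_gap: int = 10) -> TrialRecording:
    """Read a trial; format inferred from the extension when omitted."""
    path = Path(path)
    if format is None:
        format = {".csv": "canonical_csv", ".trc": "trc", ".c3d": "c3d"}.get(path.suffix.lower())
        if format is None:
            raise FormatError(f"cannot infer trial format from {path.name!r}")
    if format == "canonical_csv":
        return _read_canonical_csv(path, max_gap)
    if format == "trc":
        return _read_trc(path, max_gap)
    if format == "c3d":
        raise UnsupportedFormatError("C3D import is not available; convert to canonical_csv or trc")
    raise FormatError(f"unknown trial format {format!r}")


def _write_canonical_csv(rec: TrialRecording, path: Path) -> None:
    n = rec.n_frames
    cols = _required_columns()
    data = np.column_stack([np.arange(n) / rec.sample_rate] + [
        rec.markers[c.rsplit("_", 1)[0]][:, _AXES.index(c.rsplit("_", 1)[1])] for c in cols
    ])
    with open(path, "w") as fh:
        fh.write("# gaitdecomp-trial v1\n")
        fh.write(f"# sample_rate: {rec.sample_rate!r}\n")
        fh.write(f"# participant_id: {rec.participant_id}\n")
        fh.write(f"# condition: {rec.condition}\n")
        fh.write(f"# paretic_side: {rec.paretic_side}\n")
        fh.write("time," + ",".join(cols) + "\n")
        fh.write("s," + ",".join(["m"] * len(cols)) + "\n")
        np.savetxt(fh, data, fmt="%.9g", delimiter=",")


def _read_canonical_csv(path: Path, max_gap: int) -> TrialRecording:
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line[1:].strip()
                if ":" in stripped:
                    key, _, val = stripped.partition(":")
                    meta[key.strip()] = val.strip()
            else:
                body_lines.append(line)
    missing_meta = [k for k in _META_KEYS if k not in meta]
    if missing_meta:
        raise FormatError(f"{path.name}: metadata key(s) missing: {missing_meta}")
    if len(body_lines) < 3:
        raise FormatError(f"{path.name}: no data rows")
    header = [c.strip() for c in body_lines[0].strip().split(",")]
    units = [c.strip() for c in body_lines[1].strip().split(",")]
    if header[0] != "time":
        raise FormatError(f"{path.name}: first column must be 'time', got {header[0]!r}")
    if units[0] != "s" or any(u != "m" for u in units[1:]):
        raise FormatError(f"{path.name}: units row must be 's' then 'm' per marker column")
    for col in _required_columns():
        if col not in header:
            base = col.rsplit("_", 1)[0]
            raise FormatError(f"{path.name}: required marker absent: {base}")
    df = pd.read_csv(io.StringIO("".join(body_lines[2:])), header=None, names=header)
    markers: dict[str, np.ndarray] = {}
    bases = sorted({c.rsplit("_", 1)[0] for c in header[1:]})
    for base in bases:
        arr = np.column_stack([df[f"{base}_{ax}"].to_numpy(dtype=float) for ax in _AXES])
        markers[base] = fill_gaps(arr, max_gap, name=base)
    try:
        rate = float(meta["sample_rate"])
    except ValueError as exc:
        raise FormatError(f"{path.name}: sample_rate is not numeric: {meta['sample_rate']!r}") from exc
    rec = TrialRecording(
        participant_id=meta["participant_id"],
        condition=meta["condition"],
        sample_rate=rate,
        markers=markers,
        paretic_side=meta["paretic_side"],
    )
    rec.validate()
    return rec


def _write_trc(rec: TrialRecording, path: Path) -> None:
    names = ["sacrum"] + [marker_name(b, s) for s in SIDES for b in ("hip", "knee", "ankle", "heel", "toe")]
    n = rec.n_frames
    rate = rec.sample_rate
    with open(path, "w") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{path.name}\n")
        fh.write(
            "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\t"
            "OrigDataStartFrame\tOrigNumFrames\n"
        )
        fh.write(f"{rate:g}\t{rate:g}\t{n}\t{len(names)}\tm\t{rate:g}\t1\t{n}\n")
        fh.write("Frame#\tTime\t" + "\t\t\t".join(names) + "\t\t\n")
        sub = "\t".join(f"X{i+1}\tY{i+1}\tZ{i+1}" for i in range(len(names)))
        fh.write(f"\t\t{sub}\n\n")
        for f in range(n):
            row = [str(f + 1), f"{f / rate:.6f}"]
            for nm in names:
                row += [f"{v:.9g}" for v in rec.markers[nm][f]]
            fh.write("\t".join(row) + "\n")


def _read_trc(path: Path, max_gap: int) -> TrialRecording:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 6 or not lines[0].startswith("PathFileType"):
        raise FormatError(f"{path.name}: not a TRC file")
    hdr_vals = lines[2].split("\t")
    try:
        rate = float(hdr_vals[0])
        n_markers = int(hdr_vals[3])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path.name}: malformed TRC header") from exc
    if hdr_vals[4].strip().lower() != "m":
        raise FormatError(f"{path.name}: TRC units must be m, got {hdr_vals[4]!r}")
    names = [c for c in lines[3].split("\t")[2:] if c.strip()]
    if len(names) != n_markers:
        raise FormatError(f"{path.name}: {len(names)} marker names for {n_markers} markers")
    rows = []
    for line in lines[5:]:
        if not line.strip():
            continue
        parts = line.split("\t")
        rows.append([float(p) if p.strip() else np.nan for p in parts[2 : 2 + 3 * n_markers]])
    data = np.asarray(rows, dtype=float)
    if data.shape[1] != 3 * n_markers:
        raise FormatError(f"{path.name}: data width {data.shape[1]} != 3 x {n_markers}")
    markers = {
        nm: fill_gaps(data[:, 3 * i : 3 * i + 3], max_gap, name=nm) for i, nm in enumerate(names)
    }
    rec = TrialRecording(
        participant_id=path.stem,
        condition="unknown",
        sample_rate=rate,
        markers=markers,
        paretic_side="left",
    )
    rec.validate()
    return rec


def write_metrics_table(table: pd.DataFrame, path) -> None:
    """Write a tidy metrics table (one row per participant x condition x
    trial x cycle x metric) as CSV."""
    table.to_csv(path, index=False)
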