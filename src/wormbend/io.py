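"""Readers, writers, configuration and the pipeline runner.

File formats: multi-page TIFF for movies, CSV for kymographs / traces /
correlograms / bout tables, YAML for configuration and fit reports.  Every
analysis constant (100 segments, 18% head region, 20 s correlation lag, 1 s
peak window, 150-frame minimum) is a named configuration key so that it can
be pinned, logged and reproduced.
"""

from __future__ import annotations

import importlib.metadata
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from .containers import CurvatureKymograph, FluorescenceTrace, WormFrame
from .errors import ConfigurationError, WormbendError

__all__ = [
    "AnalysisConfig",
    "read_stack",
    "write_movie",
    "write_table",
    "read_table",
    "kymograph_to_frame",
    "kymograph_from_frame",
    "run_pipeline",
]


@dataclass
class AnalysisConfig:
    """All tunable constants of the pipeline, with their standard defaults."""

    mm_per_px: float = 0.005          # image scale
    frame_rate: float = 5.0           # Hz, effective acquisition rate
    n_segments: int = 100             # body segments of the kymograph
    head_fraction: float = 0.18       # anterior fraction defining the head
    xcorr_max_lag: float = 20.0       # s
    xcorr_window: float = 1.0         # s, peak-statistic window around T_p
    min_bout_duration: float = 10.0   # s
    min_frames: int = 150             # frames required for an amplitude
    smoothing_cutoff: float = 4.0     # tangent-angle low-pass, cycles/body
    turn_threshold: float = float(np.pi / 2)  # |mean kappa*L| marking a turn
    theta_cap: float = 60.0           # deg, small-angle validity cap for the fit
    n_bootstrap: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mm_per_px", "frame_rate", "head_fraction", "xcorr_max_lag",
                     "xcorr_window", "min_bout_duration", "turn_threshold",
                     "theta_cap"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_segments < 10:
            raise ConfigurationError("n_segments must be >= 10")
        n_head = self.head_fraction * self.n_segments
        if abs(n_head - round(n_head)) > 1e-9:
            raise ConfigurationError(
                "head_fraction * n_segments must be an integer number of segments"
            )

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def read_stack(path, frame_rate: Optional[float] = None):
    """Read a movie from a multi-page TIFF or a directory of numbered images.

    Returns ``(frames, timestamps)`` with frames as a (T, H, W) array and
    timestamps derived from ``frame_rate`` (1 Hz when unspecified).
    """
    path = Path(path)
    if not path.exists():
        raise WormbendError(f"no such file or directory: {path}")
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff", ".png")
        )
        if not files:
            raise WormbendError(f"no image files in {path}")
        from imageio.v3 import imread as _imread

        frames = []
        shape = None
        for p in files:
            img = tifffile.imread(p) if p.suffix.lower() in (".tif", ".tiff") else _imread(p)
            if shape is None:
                shape = img.shape
            elif img.shape != shape:
                raise WormbendError(f"frame {p.name} has shape {img.shape}, expected {shape}")
            frames.append(img)
        stack = np.stack(frames)
    else:
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
        if stack.ndim != 3:
            raise WormbendError(f"{path} is not a single-channel movie (ndim={stack.ndim})")
    fs = frame_rate if frame_rate else 1.0
    timestamps = np.arange(len(stack)) / fs
    return stack, timestamps


def write_movie(frames: Sequence[Union[WormFrame, np.ndarray]], path) -> None:
    """Write frames (masks scaled to 8-bit) as a multi-page TIFF."""
    arrs = []
    for f in frames:
        a = f.mask if isinstance(f, WormFrame) else np.asarray(f)
        if a.dtype == bool:
            a = (a * 255).astype(np.uint8)
        arrs.append(a)
    tifffile.imwrite(path, np.stack(arrs))


def write_table(records, path, schema: Sequence[str]) -> None:
    """Write records as CSV with a fixed column order.

    ``records`` is a DataFrame or a list of dicts.  Column mismatches raise
    :class:`ConfigurationError` listing the offending columns.  An empty
    record list yields a header-only file.  Values round-trip to at least 12
    significant digits.
    """
    schema = list(schema)
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(list(records), columns=schema if not records else None)
    missing = [c for c in schema if c not in df.columns]
    extra = [c for c in df.columns if c not in schema]
    if missing or extra:
        raise ConfigurationError(
            f"schema mismatch: missing columns {missing}, unexpected columns {extra}"
        )
    df[schema].to_csv(path, index=False, float_format="%.12g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


KYMO_META_COLS = ["frame", "time_s", "length_mm"]


def kymograph_to_frame(kymo: CurvatureKymograph) -> pd.DataFrame:
    """One kymograph row per frame: metadata columns then k000..kNNN."""
    n = kymo.n_segments
    cols = {f"k{i:03d}": kymo.values[:, i] for i in range(n)}
    lengths = (
        kymo.body_lengths
        if kymo.body_lengths is not None
        else np.full(kymo.n_frames, kymo.body_length)
    )
    return pd.DataFrame(
        {"frame": np.arange(kymo.n_frames), "time_s": kymo.times, "length_mm": lengths, **cols}
    )


def kymograph_from_frame(df: pd.DataFrame) -> CurvatureKymograph:
    kcols = [c for c in df.columns if c.startswith("k") and c[1:].isdigit()]
    kcols.sort()
    values = df[kcols].to_numpy(dtype=float)
    t = df["time_s"].to_numpy(dtype=float)
    fr = 1.0 / np.median(np.diff(t)) if len(t) > 1 else 1.0
    lengths = df["length_mm"].to_numpy(dtype=float)
    failed = [int(i) for i in np.nonzero(~np.isfinite(values).all(axis=1))[0]]
    return CurvatureKymograph(
        values=values,
        frame_rate=fr,
        body_length=float(np.nanmean(lengths)),
        body_lengths=lengths,
        failed_frames=failed,
    )


TRACE_SCHEMA = ["frame", "time_s", "raw", "normalized"]


def trace_to_frame(trace: FluorescenceTrace) -> pd.DataFrame:
    norm = trace.normalized if trace.normalized is not None else np.full(len(trace.raw), np.nan)
    return pd.DataFrame(
        {"frame": np.arange(len(trace.raw)), "time_s": trace.times,
         "raw": trace.raw, "normalized": norm}
    )


# ---------------------------------------------------------------------------
# pipeline runner
# ---------------------------------------------------------------------------

_STAGE_ORDER = ["simulate", "track", "bend", "calcium", "xcorr", "rft"]
_STAGE_NEEDS = {
    "simulate": set(),
    "track": {"movie"},
    "bend": {"kymo"},
    "calcium": {"kymo"},
    "xcorr": {"bend_trace", "ca_trace"},
    "rft": {"kymo", "track"},
}


def run_pipeline(config: AnalysisConfig, stages: Sequence[str], out_dir) -> dict:
    """Execute a chain of analysis stages on synthetic or tracked data.

    Stages must be a subset of ``simulate, track, bend, calcium, xcorr, rft``
    in that order, and each stage's inputs must be produced by an earlier
    stage (``simulate`` seeds the chain).  Per-stage CSV outputs and a
    structured YAML log (parameters, package versions, seed, per-frame
    failure counts) are written to ``out_dir``; the returned dict maps
    artifact names to paths and in-memory objects.
    """
    from . import headbend, posture, rft, synthetic, xcorr as xc
    from .calcium import normalize_trace

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = list(stages)
    unknown = [s for s in stages if s not in _STAGE_ORDER]
    if unknown:
        raise ConfigurationError(f"unknown stages: {unknown}")
    if [s for s in _STAGE_ORDER if s in stages] != stages:
        raise ConfigurationError(
            f"stages must follow the order {_STAGE_ORDER}, got {stages}"
        )
    have = set()
    for s in stages:
        needs = _STAGE_NEEDS[s] - have
        if needs:
            raise ConfigurationError(f"stage '{s}' requires earlier output {sorted(needs)}")
        have |= {"movie"} if s == "simulate" else set()
        have |= {"kymo"} if s == "track" else set()
        have |= {"bend_trace"} if s == "bend" else set()
        have |= {"ca_trace"} if s == "calcium" else set()

    artifacts: dict = {}
    log: dict = {
        "config": asdict(config),
        "stages": stages,
        "versions": {
            "wormbend": importlib.metadata.version("wormbend"),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "failures": {},
    }
    for stage in stages:
        if stage == "simulate":
            params = synthetic.WaveParams(
                frame_rate=config.frame_rate,
                n_segments=config.n_segments,
                seed=config.seed,
            )
            frames, gt = synthetic.make_synthetic_movie(
                params, mm_per_px=config.mm_per_px
            )
            write_movie(frames, out_dir / "movie.tif")
            params_yaml = out_dir / "movie_params.yaml"
            with open(params_yaml, "w") as fh:
                yaml.safe_dump(asdict(params), fh, sort_keys=False)
            gt_df = kymograph_to_frame(gt.kymograph)
            write_table(gt_df, out_dir / "ground_truth_kymo.csv", list(gt_df.columns))
            artifacts["movie"] = frames
            artifacts["ground_truth"] = gt
        elif stage == "track":
            kymo, centerlines = posture.build_kymograph(
                artifacts["movie"],
                n_segments=config.n_segments,
                smoothing_cutoff=config.smoothing_cutoff,
            )
            df = kymograph_to_frame(kymo)
            write_table(df, out_dir / "kymo.csv", list(df.columns))
            track = np.array(
                [
                    cl.points.mean(axis=0) if cl is not None else (np.nan, np.nan)
                    for cl in centerlines
                ]
            )
            tdf = pd.DataFrame(
                {"frame": np.arange(len(track)), "x_mm": track[:, 0], "y_mm": track[:, 1]}
            )
            write_table(tdf, out_dir / "track.csv", list(tdf.columns))
            log["failures"]["track"] = len(kymo.failed_frames)
            artifacts["kymo"], artifacts["centerlines"], artifacts["track"] = kymo, centerlines, track
        elif stage == "bend":
            trace = headbend.head_curvature(artifacts["kymo"], config.head_fraction)
            amp = headbend.head_bending_amplitude(trace, min_frames=min(
                config.min_frames, artifacts["kymo"].n_frames))
            bdf = pd.DataFrame({"frame": np.arange(len(trace.values)),
                                "head_curvature": trace.values})
            write_table(bdf, out_dir / "head_curvature.csv", list(bdf.columns))
            write_table(pd.DataFrame([{"head_bending_amplitude": amp}]),
                        out_dir / "amplitude.csv", ["head_bending_amplitude"])
            artifacts["bend_trace"], artifacts["amplitude"] = trace, amp
        elif stage == "calcium":
            ventral, dorsal = synthetic.make_calcium_traces(
                artifacts["kymo"], seed=config.seed,
                head_fraction=config.head_fraction,
            )
            ventral = normalize_trace(ventral)
            vdf = trace_to_frame(ventral)
            write_table(vdf, out_dir / "trace_ventral.csv", TRACE_SCHEMA)
            artifacts["ca_trace"] = ventral
        elif stage == "xcorr":
            cg = xc.cross_correlate(
                artifacts["bend_trace"], artifacts["ca_trace"],
                max_lag=min(config.xcorr_max_lag,
                            0.5 * len(artifacts["bend_trace"].values)
                            / artifacts["bend_trace"].frame_rate),
            )
            cdf = pd.DataFrame({"lag_s": cg.lags, "coefficient": cg.coefficients})
            write_table(cdf, out_dir / "correlogram.csv", ["lag_s", "coefficient"])
            artifacts["correlogram"] = cg
        elif stage == "rft":
            kymo = artifacts["kymo"]
            bouts = rft.segment_bouts(
                kymo, artifacts["track"],
                min_duration=min(config.min_bout_duration,
                                 kymo.n_frames / kymo.frame_rate / 2),
                turn_threshold=config.turn_threshold,
            )
            rows = []
            for b in bouts:
                rft.bout_kinematics(b, kymo, artifacts["track"],
                                    artifacts.get("centerlines"),
                                    head_fraction=config.head_fraction)
                rows.append({
                    "t_start": b.start / b.frame_rate,
                    "t_end": (b.stop - 1) / b.frame_rate,
                    "v_a": b.v_a, "v_w": b.v_w, "theta_a_deg": b.theta_a,
                    "efficiency": b.efficiency, "head_amplitude": b.head_amplitude,
                })
            schema = ["t_start", "t_end", "v_a", "v_w", "theta_a_deg",
                      "efficiency", "head_amplitude"]
            write_table(rows, out_dir / "bouts.csv", schema)
            artifacts["bouts"] = rows
    with open(out_dir / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=False)
    artifacts["log"] = log
    return artifacts
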