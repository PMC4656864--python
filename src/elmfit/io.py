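"""File I/O and pipeline configuration.

Frames are grayscale TIFFs (the instrument records 12-bit gray levels in a
16-bit container); per-candidate results go to CSV with a stable column
order, experiment summaries to JSON, and the pipeline configuration
round-trips through a flat YAML file.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .fitting import ExperimentSummary, RandomSearchSchedule, ShellFitResult
from .segmentation import Frame

__all__ = [
    "PipelineConfig",
    "read_frame",
    "write_frame",
    "write_results",
    "read_results",
    "write_summary",
    "read_summary",
    "RESULT_COLUMNS",
]

#: stable per-candidate CSV schema
RESULT_COLUMNS = ["frame_id", "index", "model", "x0", "y0", "a", "b", "phi",
                  "q", "brightness", "sigma_fit", "epsilon", "accepted",
                  "reject_reason"]


@dataclass
class PipelineConfig:
    """Flat configuration of the whole analysis pipeline.

    Defaults mirror the instrument and the segmentation / fitting design
    defaults; every key is settable from the CLI (flag wins over file).
    """

    pixel_width: float = 74.0        # nm on the specimen
    sigma_known: float = 130.0       # calibrated PSF radius, nm
    region_size: int = 27
    hough_min_radius_px: int = 4
    hough_max_radius_px: int = 12
    hough_peak_threshold: float = 0.8
    hough_smoothing_sigma: float = 1.0
    collision_distance_px: float = 13.0
    model_kind: str = "sphere_algebraic"
    n_fluorophores: int = 2500
    search_iterations: int = 300
    search_decay: float = 0.985
    seed: int = 0
    output_dir: str = "."

    def schedule(self) -> RandomSearchSchedule:
        return RandomSearchSchedule(n_iterations=self.search_iterations,
                                    decay=self.search_decay)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def read_frame(path, pixel_width: float = 74.0) -> Frame:
    """Read a grayscale TIFF as a Frame.

    Accepts 8/12/16-bit integer or float data; rejects RGB/multichannel
    images with a clear error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"frame file not found: {path}")
    try:
        data = tifffile.imread(path)
    except Exception as exc:
        raise ValueError(f"could not read TIFF {path}: {exc}") from exc
    if data.ndim != 2:
        raise ValueError(
            f"{path}: expected a single grayscale image, got shape "
            f"{data.shape} (RGB/multichannel input is not supported)")
    return Frame(image=np.asarray(data, dtype=float),
                 pixel_width=pixel_width,
                 metadata={"source": str(path), "frame_id": path.stem})


def write_frame(frame: Frame, path) -> None:
    """Write a frame as a 16-bit grayscale TIFF (values clipped to the
    container range; the camera's 12-bit data occupy the low bits)."""
    data = np.clip(np.round(frame.image), 0, 65535).astype(np.uint16)
    tifffile.imwrite(Path(path), data)


def _result_row(r: ShellFitResult) -> dict:
    return {"frame_id": r.frame_id, "index": r.candidate_index,
            "model": r.model_kind, "x0": r.x0, "y0": r.y0, "a": r.a,
            "b": r.b, "phi": r.phi, "q": r.q, "brightness": r.brightness,
            "sigma_fit": r.sigma_fit, "epsilon": r.epsilon,
            "accepted": bool(r.accepted), "reject_reason": r.reject_reason}


def write_results(results: list, path) -> None:
    """Per-candidate fit results as CSV in the stable column order."""
    df = pd.DataFrame([_result_row(r) for r in results],
                      columns=RESULT_COLUMNS)
    df.to_csv(Path(path), index=False, float_format="%.6f")


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    missing = set(RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"results file {path} missing columns: "
                         f"{sorted(missing)}")
    return df


def _clean(x):
    if isinstance(x, float) and not math.isfinite(x):
        return None
    return x


def write_summary(summary: ExperimentSummary, path) -> None:
    """Experiment summary as JSON (per-field summaries plus across-field
    mean and standard deviation of each quantity)."""
    payload = {
        "n_fields": summary.n_fields,
        "mean_radius_nm": _clean(summary.mean_radius),
        "std_radius_nm": _clean(summary.std_radius),
        "mean_aspect_ratio": _clean(summary.mean_aspect_ratio),
        "std_aspect_ratio": _clean(summary.std_aspect_ratio),
        "mean_polarity": _clean(summary.mean_polarity),
        "std_polarity": _clean(summary.std_polarity),
        "fields": [
            {"frame_id": f.frame_id, "n_candidates": f.n_candidates,
             "n_accepted": f.n_accepted,
             "mean_radius_nm": _clean(f.mean_radius),
             "mean_aspect_ratio": _clean(f.mean_aspect_ratio),
             "mean_polarity": _clean(f.mean_polarity),
             "mean_sigma_nm": _clean(f.mean_sigma),
             "mean_epsilon": _clean(f.mean_epsilon)}
            for f in summary.frames
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_summary(path) -> dict:
    return json.loads(Path(path).read_text())
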