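"""File round-trips: multi-page TIFF stacks, HDF5 factors/truth, YAML config.

Stacks default to float32 TIFF pages so that a simulate -> write -> read ->
reconstruct round trip is bit-exact; unsigned 16-bit output is available
for camera-like files.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

from .simulate import EmitterMap, FrameStack, GroundTruth, OpticalConfig

__all__ = [
    "write_stack",
    "read_stack",
    "write_truth",
    "read_truth",
    "write_factors",
    "read_factors",
    "load_yaml",
    "write_report",
]


def write_stack(path: str | Path, stack: FrameStack, dtype: str = "float32") -> None:
    """Write a frame stack as a multi-page TIFF (one frame per page)."""
    frames = stack.frames
    if dtype == "uint16":
        peak = frames.max()
        scale = 65535.0 / peak if peak > 0 else 1.0
        data = np.rint(frames * scale).astype(np.uint16)
    elif dtype == "float32":
        data = frames.astype(np.float32)
    else:
        raise ValueError("dtype must be 'float32' or 'uint16'")
    tifffile.imwrite(str(path), data, photometric="minisblack")


def read_stack(path: str | Path) -> FrameStack:
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None, :, :]
    return FrameStack(frames=np.asarray(data, dtype=float))


def _config_to_group(grp: h5py.Group, config: OpticalConfig) -> None:
    for field in (
        "frame_height", "frame_width", "grain_size", "me_range",
        "read_noise_sigma", "seed",
    ):
        grp.attrs[field] = getattr(config, field)
    grp.attrs["noise_photons"] = (
        -1.0 if config.noise_photons is None else config.noise_photons
    )


def _config_from_group(grp: h5py.Group) -> OpticalConfig:
    np_val = float(grp.attrs["noise_photons"])
    return OpticalConfig(
        frame_height=int(grp.attrs["frame_height"]),
        frame_width=int(grp.attrs["frame_width"]),
        grain_size=float(grp.attrs["grain_size"]),
        me_range=float(grp.attrs["me_range"]),
        noise_photons=None if np_val < 0 else np_val,
        read_noise_sigma=float(grp.attrs["read_noise_sigma"]),
        seed=int(grp.attrs["seed"]),
    )


def write_truth(path: str | Path, truth: GroundTruth) -> None:
    """Ground truth HDF5 layout: /W (pixels x P), /H (P x T),
    /positions (P x 2), /brightness (P,), config attrs on /config."""
    with h5py.File(str(path), "w") as f:
        f.create_dataset("W", data=truth.fingerprints)
        f.create_dataset("H", data=truth.weights)
        f.create_dataset("positions", data=truth.emitter_map.positions)
        f.create_dataset("brightness", data=truth.emitter_map.brightness)
        _config_to_group(f.create_group("config"), truth.config)


def read_truth(path: str | Path) -> GroundTruth:
    with h5py.File(str(path), "r") as f:
        emitters = EmitterMap(
            positions=f["positions"][...], brightness=f["brightness"][...]
        )
        return GroundTruth(
            fingerprints=f["W"][...],
            weights=f["H"][...],
            emitter_map=emitters,
            config=_config_from_group(f["config"]),
        )


def write_factors(
    path: str | Path,
    fingerprints: np.ndarray,
    weights: np.ndarray,
    frame_shape: tuple[int, int],
    residual_trace: np.ndarray | None = None,
    rank_scan: dict | None = None,
) -> None:
    """Factorisation HDF5 layout: /W, /H, /residual_trace, /rank_scan/*."""
    with h5py.File(str(path), "w") as f:
        f.create_dataset("W", data=fingerprints)
        f.create_dataset("H", data=weights)
        f.attrs["frame_height"], f.attrs["frame_width"] = frame_shape
        if residual_trace is not None:
            f.create_dataset("residual_trace", data=residual_trace)
        if rank_scan is not None:
            g = f.create_group("rank_scan")
            g.create_dataset("ranks", data=np.asarray(rank_scan["ranks"]))
            g.create_dataset(
                "rms_residuals", data=np.asarray(rank_scan["rms_residuals"])
            )
            g.attrs["chosen_rank"] = int(rank_scan["chosen_rank"])


def read_factors(path: str | Path) -> dict:
    with h5py.File(str(path), "r") as f:
        out = {
            "W": f["W"][...],
            "H": f["H"][...],
            "frame_shape": (int(f.attrs["frame_height"]), int(f.attrs["frame_width"])),
        }
        if "residual_trace" in f:
            out["residual_trace"] = f["residual_trace"][...]
        if "rank_scan" in f:
            g = f["rank_scan"]
            out["rank_scan"] = {
                "ranks": g["ranks"][...],
                "rms_residuals": g["rms_residuals"][...],
                "chosen_rank": int(g.attrs["chosen_rank"]),
            }
        return out


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def write_report(path: str | Path, report: dict) -> None:
    def _default(obj):
        if isinstance(obj, np.bool_):
            return bool(obj)
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON-serialisable: {type(obj)}")

    Path(path).write_text(json.dumps(report, indent=2, default=_default))
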