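"""File formats, deterministic fixtures, and run manifests.

Trajectory files are line-delimited text: a two-line header (format tag and
a JSON object carrying the environment config, seed, target mask and
labels) followed by one line per frame with the time index and each
object's x, y in pixels at full precision.  Reading re-validates the
trajectory invariants and reports malformed input with the offending line
number.

Configs are flat ``key = value`` text with ``inf`` sentinels.  Every CLI
run writes a JSON manifest beside its outputs so results are traceable to
the exact configuration and seed that produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import time
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .dynamics import EnvironmentConfig, Trajectory, min_pairwise_distance
from .model import ModelParams

__all__ = [
    "TrajectoryFormatError",
    "write_trajectory",
    "read_trajectory",
    "make_fixture",
    "FIXTURE_KINDS",
    "parse_keyvalue",
    "format_keyvalue",
    "env_config_from_file",
    "model_params_from_file",
    "write_manifest",
]

_FORMAT_TAG = "# mottrack-trajectory v1"

FIXTURE_KINDS = ("static", "constant_velocity", "swap_pair", "crossing_pair")


class TrajectoryFormatError(ValueError):
    """Malformed trajectory file; ``line`` is the 1-based offending line."""

    def __init__(self, message: str, line: Optional[int] = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


def write_trajectory(traj: Trajectory, path: Union[str, Path]) -> Path:
    """Serialise a trajectory losslessly (positions via float repr)."""
    path = Path(path)
    header = {
        "config": dataclasses.asdict(traj.config),
        "seed": traj.seed,
        "target_mask": [int(i) for i in traj.target_mask],
        "labels": list(traj.labels),
    }
    with path.open("w") as fh:
        fh.write(_FORMAT_TAG + "\n")
        fh.write("# " + json.dumps(header) + "\n")
        for t, frame in enumerate(traj.frames):
            fields = [str(t)] + [repr(float(v)) for xy in frame for v in xy]
            fh.write(" ".join(fields) + "\n")
    return path


def read_trajectory(path: Union[str, Path]) -> Trajectory:
    """Parse and validate a trajectory file.

    Raises :class:`TrajectoryFormatError` on a bad header, a frame-count or
    frame-length mismatch, an out-of-bounds position, or (for the regimes
    that guarantee it) a minimum-distance violation.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != _FORMAT_TAG:
        raise TrajectoryFormatError("missing format tag", line=1)
    if len(lines) < 2 or not lines[1].startswith("# "):
        raise TrajectoryFormatError("missing JSON header", line=2)
    try:
        header = json.loads(lines[1][2:])
        config = EnvironmentConfig(**header["config"])
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise TrajectoryFormatError(f"bad header: {exc}", line=2) from exc
    config = dataclasses.replace(config, arena=tuple(config.arena))
    body = lines[2:]
    if len(body) != config.n_updates:
        raise TrajectoryFormatError(
            f"expected {config.n_updates} frames, found {len(body)}",
            line=len(lines))
    frames = np.empty((config.n_updates, config.n_objects, 2))
    w, h = config.arena
    for i, line in enumerate(body):
        lineno = i + 3
        parts = line.split()
        if len(parts) != 1 + 2 * config.n_objects:
            raise TrajectoryFormatError(
                f"expected {1 + 2 * config.n_objects} fields, "
                f"found {len(parts)}", line=lineno)
        try:
            vals = [float(p) for p in parts[1:]]
        except ValueError as exc:
            raise TrajectoryFormatError(str(exc), line=lineno) from exc
        frame = np.array(vals).reshape(config.n_objects, 2)
        if (frame[:, 0] < 0).any() or (frame[:, 0] >= w).any() \
                or (frame[:, 1] < 0).any() or (frame[:, 1] >= h).any():
            raise TrajectoryFormatError("position outside the arena",
                                        line=lineno)
        frames[i] = frame
    traj = Trajectory(frames=frames,
                      target_mask=np.array(header["target_mask"], dtype=int),
                      config=config, seed=header.get("seed"),
                      labels=header.get("labels"))
    # Hard separation floor only in the regimes that guarantee one (in the
    # constant-speed regime min_distance is the repulsion radius, which
    # objects must enter to be repelled).
    if config.min_distance > 0 and config.n_objects > 1 \
            and config.dynamics_kind in ("constrained_ou", "shell_game"):
        if min_pairwise_distance(traj) < config.min_distance:
            raise TrajectoryFormatError(
                "minimum object distance violated by the stored frames")
    return traj


# ---------------------------------------------------------------------------
# Deterministic fixtures
# ---------------------------------------------------------------------------

def make_fixture(kind: str, n_frames: int = 60,
                 arena: tuple[float, float] = (400.0, 300.0),
                 separation: float = 100.0) -> Trajectory:
    """Tiny deterministic trajectories with known ground truth.

    static : four objects (two targets) that never move.
    constant_velocity : the same objects drifting uniformly at (2, 0)
        pixels per frame.
    swap_pair : two targets that exchange their x-order at constant speed
        while staying ``separation`` apart vertically — tracked perfectly,
        but a stale identity sequence labels them both wrongly.
    crossing_pair : two targets whose straight paths cross mid-trial within
        a single cell, so tracking confusions become possible at speed.
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; "
                         f"expected one of {FIXTURE_KINDS}")
    w, h = arena
    T = n_frames
    if kind in ("static", "constant_velocity"):
        base = np.array([[50.0, 50.0], [120.0, 120.0],
                         [190.0, 60.0], [250.0, 200.0]])
        vel = np.array([2.0, 0.0]) if kind == "constant_velocity" else \
            np.array([0.0, 0.0])
        frames = np.stack([base + t * vel for t in range(T)])
        if frames[..., 0].max() >= w or frames[..., 1].max() >= h:
            raise ValueError("fixture drift exceeds the arena; "
                             "use fewer frames or a larger arena")
        n_targets, sigma = 2, float(np.hypot(*vel))
    elif kind == "swap_pair":
        y1, y2 = h / 2 - separation / 2, h / 2 + separation / 2
        x_a = np.linspace(60.0, w - 60.0, T)
        x_b = np.linspace(w - 60.0, 60.0, T)
        frames = np.stack([
            np.array([[x_a[t], y1], [x_b[t], y2]]) for t in range(T)
        ])
        n_targets, sigma = 2, float(abs(x_a[1] - x_a[0]))
    else:  # crossing_pair
        x = np.linspace(60.0, w - 60.0, T)
        y_a = np.linspace(60.0, h - 60.0, T)
        y_b = y_a[::-1].copy()
        y_b[(T - 1) // 2] = y_a[(T - 1) // 2]  # guarantee a shared cell
        frames = np.stack([
            np.array([[x[t], y_a[t]], [x[t], y_b[t]]]) for t in range(T)
        ])
        n_targets = 2
        sigma = float(np.hypot(x[1] - x[0], y_a[1] - y_a[0]))
    config = EnvironmentConfig(
        dynamics_kind="constant_speed", sigma=sigma, arena=arena,
        updates_per_second=10.0, n_updates=T, min_distance=0.0,
        n_targets=n_targets, n_objects=frames.shape[1])
    return Trajectory(frames=frames, target_mask=np.arange(n_targets),
                      config=config, seed=0)


# ---------------------------------------------------------------------------
# Key-value configs
# ---------------------------------------------------------------------------

def _parse_value(raw: str):
    raw = raw.strip()
    low = raw.lower()
    if low in ("inf", "infinity"):
        return math.inf
    if "," in raw:
        return tuple(_parse_value(p) for p in raw.split(","))
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            pass
    return raw


def parse_keyvalue(text: str) -> dict:
    """Parse flat ``key = value`` text ('#' starts a comment)."""
    out: dict = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'key = value'")
        key, raw = line.split("=", 1)
        out[key.strip()] = _parse_value(raw)
    return out


def format_keyvalue(mapping: dict) -> str:
    def fmt(v):
        if isinstance(v, tuple):
            return ",".join(str(x) for x in v)
        if isinstance(v, float) and math.isinf(v):
            return "inf"
        return str(v)
    return "".join(f"{k} = {fmt(v)}\n" for k, v in mapping.items())


def env_config_from_file(path: Union[str, Path],
                         **overrides) -> EnvironmentConfig:
    data = parse_keyvalue(Path(path).read_text())
    data.update(overrides)
    if "arena" in data and not isinstance(data["arena"], tuple):
        raise ValueError("arena must be 'width,height'")
    return EnvironmentConfig(**data)


def model_params_from_file(path: Union[str, Path], **overrides) -> ModelParams:
    data = parse_keyvalue(Path(path).read_text())
    data.update(overrides)
    return ModelParams(**data)


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------

def write_manifest(out_path: Union[str, Path], command: str, seed: Optional[int],
                   config_text: str, outputs: list[str]) -> Path:
    """JSON manifest tying result files to the command, config and seed."""
    from . import __version__

    path = Path(out_path)
    manifest = {
        "command": command,
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "config": config_text,
        "seed": seed,
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "outputs": outputs,
    }
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path
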