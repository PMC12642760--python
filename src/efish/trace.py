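"""Episode traces: the interchange format between simulator and analytics.

An :class:`EpisodeTrace` is a columnar record of one episode — per-step
arrays of every agent's pose, actions, rewards, observations, plus food
summaries, the arena config and the seed.  On disk it is a NumPy ``.npz``
archive (one array per record kind) with a JSON metadata block carrying an
integer schema version; readers reject unknown versions.  A JSON-Lines
export (one step per line) is provided for portability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import ArenaConfig
from .sensors import block_layout

__all__ = ["EpisodeTrace", "TraceRecorder", "write_trace", "read_trace",
           "export_jsonl", "import_jsonl", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1

_ARRAY_FIELDS = ("positions", "headings", "speeds", "actions", "rewards",
                 "eod", "food_eaten", "observations", "dominance",
                 "patch_centers", "items_per_patch")


@dataclass
class EpisodeTrace:
    config: dict                      # ArenaConfig snapshot
    seed: int
    positions: np.ndarray             # (T, N, 2) cm
    headings: np.ndarray              # (T, N) rad
    speeds: np.ndarray                # (T, N) cm/s
    actions: np.ndarray               # (T, N, 4): thrust, turn, eod, bite
    rewards: np.ndarray               # (T, N)
    eod: np.ndarray                   # (T, N) uint8
    food_eaten: np.ndarray            # (T, N) cumulative int
    dominance: np.ndarray             # (N,)
    patch_centers: np.ndarray         # (P, 2)
    items_per_patch: np.ndarray       # (T, P) int
    observations: Optional[np.ndarray] = None   # (T, N, D) or None
    obs_layout: dict = field(default_factory=dict)

    @property
    def n_steps(self) -> int:
        return self.positions.shape[0]

    @property
    def n_agents(self) -> int:
        return self.positions.shape[1]

    @property
    def dt_s(self) -> float:
        return float(self.config["dt_s"])

    def __eq__(self, other) -> bool:
        if not isinstance(other, EpisodeTrace):
            return NotImplemented
        if self.config != other.config or self.seed != other.seed:
            return False
        for name in _ARRAY_FIELDS:
            a, b = getattr(self, name), getattr(other, name)
            if (a is None) != (b is None):
                return False
            if a is not None and not np.array_equal(a, b):
                return False
        return True


class TraceRecorder:
    """Accumulates per-step records during a rollout and finalizes a trace."""

    def __init__(self, config: ArenaConfig, seed: int, record_obs: bool = True):
        self.config = config
        self.seed = int(seed)
        self.record_obs = record_obs
        self._rows: dict = {k: [] for k in ("positions", "headings", "speeds",
                                            "actions", "rewards", "eod",
                                            "food_eaten", "items_per_patch",
                                            "observations")}
        self.dominance: Optional[np.ndarray] = None
        self.patch_centers: Optional[np.ndarray] = None

    def record(self, world, actions: np.ndarray, rewards: np.ndarray,
               observations: Optional[np.ndarray] = None) -> None:
        if self.dominance is None:
            self.dominance = world.dominance.copy()
            self.patch_centers = world.food.patch_centers.copy()
        r = self._rows
        r["positions"].append(world.positions.copy())
        r["headings"].append(world.headings.copy())
        r["speeds"].append(world.speeds.copy())
        r["actions"].append(np.asarray(actions, float).copy())
        r["rewards"].append(np.asarray(rewards, float).copy())
        r["eod"].append(world.eod.astype(np.uint8).copy())
        r["food_eaten"].append(world.food_eaten.copy())
        r["items_per_patch"].append(world.food.items_remaining_per_patch.copy())
        if self.record_obs and observations is not None:
            r["observations"].append(np.asarray(observations, float).copy())

    def finalize(self) -> EpisodeTrace:
        r = self._rows
        obs = np.stack(r["observations"]) if r["observations"] else None
        return EpisodeTrace(
            config=self.config.to_dict(), seed=self.seed,
            positions=np.stack(r["positions"]), headings=np.stack(r["headings"]),
            speeds=np.stack(r["speeds"]), actions=np.stack(r["actions"]),
            rewards=np.stack(r["rewards"]), eod=np.stack(r["eod"]),
            food_eaten=np.stack(r["food_eaten"]), dominance=self.dominance,
            patch_centers=self.patch_centers,
            items_per_patch=np.stack(r["items_per_patch"]),
            observations=obs, obs_layout=block_layout(self.config))


def write_trace(trace: EpisodeTrace, path: str) -> None:
    meta = {"schema_version": SCHEMA_VERSION, "config": trace.config,
            "seed": trace.seed, "obs_layout": trace.obs_layout,
            "has_observations": trace.observations is not None}
    arrays = {name: getattr(trace, name) for name in _ARRAY_FIELDS
              if getattr(trace, name) is not None}
    np.savez_compressed(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def read_trace(path: str) -> EpisodeTrace:
    try:
        z = np.load(path)
    except Exception as exc:
        raise IOError(f"cannot read trace file {path!r}: {exc}") from exc
    with z:
        if "__meta__" not in z.files:
            raise IOError(f"{path!r} is not an episode trace (missing metadata)")
        meta = json.loads(bytes(z["__meta__"]).decode())
        version = meta.get("schema_version")
        if version != SCHEMA_VERSION:
            raise IOError(f"unsupported trace schema version {version!r} "
                          f"(reader supports {SCHEMA_VERSION})")
        kw = {name: z[name] for name in _ARRAY_FIELDS if name in z.files}
    kw.setdefault("observations", None)
    return EpisodeTrace(config=meta["config"], seed=meta["seed"],
                        obs_layout={k: tuple(v) for k, v in meta["obs_layout"].items()},
                        **kw)


def export_jsonl(trace: EpisodeTrace, path: str) -> None:
    """Portable export: a metadata header line, then one step per line."""
    with open(path, "w") as fh:
        header = {"schema_version": SCHEMA_VERSION, "config": trace.config,
                  "seed": trace.seed, "obs_layout": trace.obs_layout,
                  "dominance": trace.dominance.tolist(),
                  "patch_centers": trace.patch_centers.tolist(),
                  "has_observations": trace.observations is not None}
        fh.write(json.dumps(header) + "\n")
        for t in range(trace.n_steps):
            row = {"t": t,
                   "positions": trace.positions[t].tolist(),
                   "headings": trace.headings[t].tolist(),
                   "speeds": trace.speeds[t].tolist(),
                   "actions": trace.actions[t].tolist(),
                   "rewards": trace.rewards[t].tolist(),
                   "eod": trace.eod[t].tolist(),
                   "food_eaten": trace.food_eaten[t].tolist(),
                   "items_per_patch": trace.items_per_patch[t].tolist()}
            if trace.observations is not None:
                row["observations"] = trace.observations[t].tolist()
            fh.write(json.dumps(row) + "\n")


def import_jsonl(path: str) -> EpisodeTrace:
    with open(path) as fh:
        header = json.loads(fh.readline())
        if header.get("schema_version") != SCHEMA_VERSION:
            raise IOError(f"unsupported trace schema version "
                          f"{header.get('schema_version')!r}")
        rows = [json.loads(line) for line in fh if line.strip()]
    def col(name, dtype=float):
        return np.array([r[name] for r in rows], dtype=dtype)
    obs = col("observations") if header["has_observations"] else None
    return EpisodeTrace(
        config=header["config"], seed=header["seed"],
        obs_layout={k: tuple(v) for k, v in header["obs_layout"].items()},
        positions=col("positions"), headings=col("headings"),
        speeds=col("speeds"), actions=col("actions"), rewards=col("rewards"),
        eod=col("eod", np.uint8), food_eaten=col("food_eaten", int),
        dominance=np.array(header["dominance"]),
        patch_centers=np.array(header["patch_centers"]).reshape(-1, 2),
        items_per_patch=col("items_per_patch", int), observations=obs)
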