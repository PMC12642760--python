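"""Biomimetic electrosensory transduction.

Each agent carries ``n_receptors`` point receptors on an ellipse around its
body and senses three channel families plus proprioception:

* **active** — perturbation of the illuminating EOD field by nearby
  scatterers: ``|E_total| - |E_direct|`` per receptor, where ``E_direct`` is
  the field of the illuminating emitters alone and ``E_total`` adds the
  dipoles they induce on food and conspecific bodies plus wall images.  The
  agent's own EOD always illuminates; neighbours' EODs also illuminate when
  collective sensing is enabled, which is the entire collective-sensing
  pathway (a silent fish can then see food lit by a neighbour's discharge).
* **passive** — magnitude of the weak static dipole fields carried by food
  items (prey bioelectric fields); independent of any EOD and short-range
  because of the 1/r^3 law.
* **knollenorgan** — conspecific EOD pulses binned by egocentric direction,
  amplitude A0 / max(d, r_min)^2 with a hard cutoff at the communication
  radius; the long-range social channel.  Own EODs are excluded.
* **proprio** — (speed / v_max, last turn command, own EOD flag).

Blocks are concatenated in the order above and compressed per element with
``y = sign(x) * log(1 + |x| / s)`` (field magnitudes span decades).
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from functools import lru_cache

from .config import ArenaConfig
from .field import dipole_field_raw, image_arrays

__all__ = ["receptor_offsets", "receptor_positions", "active_channels",
           "passive_channels", "knollenorgan_channels", "assemble_observation",
           "block_layout", "signed_log"]

TWO_PI = 2.0 * math.pi


@lru_cache(maxsize=16)
def _offsets_cached(n: int, a: float, b: float) -> np.ndarray:
    th = TWO_PI * np.arange(n) / n
    return np.column_stack([a * np.cos(th), b * np.sin(th)])


def receptor_offsets(config: ArenaConfig) -> np.ndarray:
    """Body-frame receptor coordinates on the body ellipse, (n_receptors, 2)."""
    return _offsets_cached(config.n_receptors, config.body_semi_major_cm,
                           config.body_semi_minor_cm)


def receptor_positions(position: np.ndarray, heading: float,
                       config: ArenaConfig) -> np.ndarray:
    """World-frame receptor positions for a pose."""
    off = receptor_offsets(config)
    c, s = math.cos(heading), math.sin(heading)
    rot = np.array([[c, -s], [s, c]])
    return np.asarray(position, float)[None, :] + off @ rot.T


def _illuminating_emitters(world, agent_idx: int):
    """(owner ids, positions (S,2), moments (S,2)) of the emitters whose EODs
    illuminate this agent's active channels."""
    cfg = world.config
    owners = [j for j in range(cfg.n_agents) if world.eod[j]
              and (j == agent_idx or cfg.collective_sensing_enabled)]
    if not owners:
        return owners, np.zeros((0, 2)), np.zeros((0, 2))
    pos = world.positions[owners]
    hd = world.headings[owners]
    mom = cfg.emitter_amplitude * np.column_stack([np.cos(hd), np.sin(hd)])
    return owners, pos, mom


def active_channels(world, agent_idx: int) -> np.ndarray:
    """Self/collective EOD perturbation magnitude at each receptor."""
    cfg = world.config
    owners, epos, emom = _illuminating_emitters(world, agent_idx)
    if not owners:
        return np.zeros(cfg.n_receptors)
    rec = receptor_positions(world.positions[agent_idx], world.headings[agent_idx], cfg)
    e_direct = dipole_field_raw(rec, epos, emom, cfg.kappa, cfg.r_min_cm)

    spos, smom = [], []
    items = world.food.item_positions
    if len(items):
        e_items = dipole_field_raw(items, epos, emom, cfg.kappa, cfg.r_min_cm)
        spos.append(items)
        smom.append(cfg.alpha_food * e_items)
    for j in range(cfg.n_agents):
        if j == agent_idx:
            continue  # receptors sit on this body
        keep = [k for k, o in enumerate(owners) if o != j]
        if keep:
            e_body = dipole_field_raw(world.positions[j][None, :], epos[keep],
                                      emom[keep], cfg.kappa, cfg.r_min_cm)
            spos.append(world.positions[j][None, :])
            smom.append(cfg.alpha_body * e_body)
    tpos = np.vstack([epos] + spos) if spos else epos
    tmom = np.vstack([emom] + smom) if smom else emom
    if cfg.reflections_enabled:
        ipos, imom = image_arrays(tpos, tmom, cfg.width_cm, cfg.height_cm)
        tpos, tmom = np.vstack([tpos, ipos]), np.vstack([tmom, imom])
    e_total = dipole_field_raw(rec, tpos, tmom, cfg.kappa, cfg.r_min_cm)
    return np.linalg.norm(e_total, axis=1) - np.linalg.norm(e_direct, axis=1)


def passive_channels(world, agent_idx: int) -> np.ndarray:
    """|E| of the static food dipoles at each receptor."""
    cfg = world.config
    items = world.food.item_positions
    if len(items) == 0:
        return np.zeros(cfg.n_receptors)
    rec = receptor_positions(world.positions[agent_idx], world.headings[agent_idx], cfg)
    e = dipole_field_raw(rec, items, world.food.item_moments, cfg.kappa, cfg.r_min_cm)
    return np.linalg.norm(e, axis=1)


def knollenorgan_channels(world, agent_idx: int) -> np.ndarray:
    """Conspecific EOD pulses, direction-binned in the egocentric frame."""
    cfg = world.config
    out = np.zeros(cfg.n_bins)
    if not cfg.knollenorgan_enabled:
        return out
    p0 = world.positions[agent_idx]
    h0 = world.headings[agent_idx]
    for j in range(cfg.n_agents):
        if j == agent_idx or not world.eod[j]:
            continue
        rel = world.positions[j] - p0
        d = float(np.linalg.norm(rel))
        if d > cfg.comm_radius_cm:
            continue
        bearing = (math.atan2(rel[1], rel[0]) - h0) % TWO_PI
        b = min(int(bearing / (TWO_PI / cfg.n_bins)), cfg.n_bins - 1)
        out[b] += cfg.knollenorgan_a0 / max(d, cfg.r_min_cm) ** 2
    return out


def signed_log(x: np.ndarray, scale: float) -> np.ndarray:
    return np.sign(x) * np.log1p(np.abs(x) / scale)


def block_layout(config: ArenaConfig) -> dict:
    """Name -> (offset, length) of each observation block."""
    n_r, n_b = config.n_receptors, config.n_bins
    return {"active": (0, n_r),
            "passive": (n_r, n_r),
            "knollenorgan": (2 * n_r, n_b),
            "proprio": (2 * n_r + n_b, 3)}


def assemble_observation(world, agent_idx: int,
                         noise_rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Fixed-length egocentric observation vector for one agent."""
    cfg = world.config
    active = active_channels(world, agent_idx)
    passive = passive_channels(world, agent_idx)
    kn = knollenorgan_channels(world, agent_idx)
    proprio = np.array([world.speeds[agent_idx] / cfg.v_max_cm_s,
                        world.last_turn[agent_idx],
                        float(world.eod[agent_idx])])
    obs = np.concatenate([signed_log(active, cfg.log_scale),
                          signed_log(passive, cfg.log_scale),
                          signed_log(kn, cfg.log_scale),
                          proprio])
    if cfg.sensor_noise_std > 0.0 and noise_rng is not None:
        obs = obs + noise_rng.normal(0.0, cfg.sensor_noise_std, obs.shape)
    return obs
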