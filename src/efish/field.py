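"""Forward model of the electric landscape.

Every contributor to the field is an ideal point dipole: EOD emitters on the
fish's head-tail axis, dipoles induced on polarizable objects (food items,
conspecific bodies) by the emitters, and mirror images of both across the
arena walls.  The field of a dipole with moment ``p`` at displacement ``r``
is

    E(r) = kappa * (3 (p . rhat) rhat - p) / max(|r|, r_min)^3

evaluated in the 2D arena plane (the conventional fish-scale 1/r^3 law, with
a softening radius ``r_min`` that removes the singularity).  Scattering is
first order: objects are polarized by emitters only (no object-object
re-induction) and walls image each real source once (no images of images).
Walls are insulating, so an image carries its parent's tangential moment and
a negated normal moment, cancelling the wall-normal field component.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .config import ArenaConfig

__all__ = [
    "FieldSource",
    "FieldSnapshot",
    "emitter_source",
    "field_at",
    "field_at_many",
    "induced_sources",
    "image_sources",
    "snapshot",
    "render_grid",
]


@dataclass
class FieldSource:
    kind: str                    # "emitter" | "induced" | "image"
    position: np.ndarray         # (2,) cm
    moment: np.ndarray           # (2,) field units * cm
    owner_agent: Optional[int] = None
    step_emitted: Optional[int] = None
    parent_kind: Optional[str] = None   # for images: kind of the mirrored source
    wall: Optional[str] = None          # for images: "left"|"right"|"bottom"|"top"

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.moment = np.asarray(self.moment, dtype=float)


@dataclass
class FieldSnapshot:
    step: int
    sources: list

    def to_records(self) -> list:
        """Plain-dict source table (kind, position, moment, owner, wall)."""
        return [{"step": self.step, "kind": s.kind,
                 "x_cm": float(s.position[0]), "y_cm": float(s.position[1]),
                 "px": float(s.moment[0]), "py": float(s.moment[1]),
                 "owner_agent": s.owner_agent, "wall": s.wall}
                for s in self.sources]


def emitter_source(agent, amplitude: float, step: Optional[int] = None) -> FieldSource:
    """Dipole of one EOD: moment of size ``amplitude`` along the body axis."""
    if not agent.eod_emitted:
        raise ValueError("emitter_source called for an agent whose eod flag is 0")
    moment = amplitude * np.array([np.cos(agent.heading), np.sin(agent.heading)])
    return FieldSource("emitter", np.asarray(agent.position, float), moment,
                       owner_agent=agent.agent_id, step_emitted=step)


def _stack(sources: Sequence[FieldSource]):
    pos = np.array([s.position for s in sources], dtype=float).reshape(len(sources), 2)
    mom = np.array([s.moment for s in sources], dtype=float).reshape(len(sources), 2)
    return pos, mom


def dipole_field_raw(points: np.ndarray, src_pos: np.ndarray, src_mom: np.ndarray,
                     kappa: float = 1.0, r_min: float = 1.0) -> np.ndarray:
    """Superposed dipole field on raw (S,2) position/moment arrays."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(src_pos) == 0:
        return np.zeros_like(points)
    d = points[:, None, :] - src_pos[None, :, :]      # (K,S,2)
    r = np.linalg.norm(d, axis=-1)                    # (K,S)
    safe = np.where(r > 0, r, 1.0)
    rhat = d / safe[..., None]
    rhat[r == 0] = 0.0
    reff = np.maximum(r, r_min)
    p_dot = np.einsum("sj,ksj->ks", src_mom, rhat)    # (K,S)
    e = (3.0 * p_dot[..., None] * rhat - src_mom[None, :, :]) / reff[..., None] ** 3
    return kappa * e.sum(axis=1)


def field_at_many(points: np.ndarray, sources: Sequence[FieldSource],
                  kappa: float = 1.0, r_min: float = 1.0) -> np.ndarray:
    """Superposed dipole field at each of ``points`` (K,2) -> (K,2)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(sources) == 0:
        return np.zeros_like(points)
    pos, mom = _stack(sources)
    return dipole_field_raw(points, pos, mom, kappa, r_min)


def field_at(point: np.ndarray, sources: Sequence[FieldSource],
             kappa: float = 1.0, r_min: float = 1.0) -> np.ndarray:
    """Field vector (2,) at a single point."""
    return field_at_many(np.asarray(point, float)[None, :], sources, kappa, r_min)[0]


def induced_sources(emitters: Sequence[FieldSource],
                    objects: Sequence[tuple],
                    kappa: float = 1.0, r_min: float = 1.0,
                    step: Optional[int] = None) -> list:
    """One induced dipole per object, p = alpha * E_emitters(object position).

    ``objects`` is a sequence of (position, polarizability[, owner_agent]).
    First Born approximation: objects never re-induce on each other.
    """
    out = []
    if not objects:
        return out
    positions = np.array([np.asarray(o[0], float) for o in objects])
    e = field_at_many(positions, list(emitters), kappa, r_min)
    for i, obj in enumerate(objects):
        alpha = float(obj[1])
        owner = obj[2] if len(obj) > 2 else None
        out.append(FieldSource("induced", positions[i], alpha * e[i],
                               owner_agent=owner, step_emitted=step))
    return out


_WALLS = ("left", "right", "bottom", "top")


def image_arrays(pos: np.ndarray, mom: np.ndarray, width: float, height: float):
    """Raw-array mirror of :func:`image_sources`: (S,2)+(S,2) -> (4S,2)+(4S,2)."""
    x, y = pos[:, 0], pos[:, 1]
    px, py = mom[:, 0], mom[:, 1]
    ipos = np.concatenate([
        np.column_stack([-x, y]), np.column_stack([2 * width - x, y]),
        np.column_stack([x, -y]), np.column_stack([x, 2 * height - y])])
    imom = np.concatenate([
        np.column_stack([-px, py]), np.column_stack([-px, py]),
        np.column_stack([px, -py]), np.column_stack([px, -py])])
    return ipos, imom


def image_sources(sources: Sequence[FieldSource], config: ArenaConfig) -> list:
    """First-order mirror images of each source across the 4 insulating walls.

    Reflection across a wall plane maps position by mirror geometry and the
    moment by negating its wall-normal component (tangential preserved), which
    cancels the normal field on that wall.
    """
    images = []
    w, h = config.width_cm, config.height_cm
    for s in sources:
        x, y = s.position
        px, py = s.moment
        mirrors = {
            "left": ((-x, y), (-px, py)),
            "right": ((2 * w - x, y), (-px, py)),
            "bottom": ((x, -y), (px, -py)),
            "top": ((x, 2 * h - y), (px, -py)),
        }
        for wall in _WALLS:
            pos, mom = mirrors[wall]
            images.append(FieldSource("image", np.array(pos), np.array(mom),
                                      owner_agent=s.owner_agent,
                                      step_emitted=s.step_emitted,
                                      parent_kind=s.kind, wall=wall))
    return images


def scatter_objects(world, exclude_agent: Optional[int] = None) -> list:
    """Polarizable objects of a world: food items and agent bodies.

    ``exclude_agent`` drops that agent's body (an agent does not scatter off
    itself).  Returns (position, alpha, owner) tuples.
    """
    cfg = world.config
    objs = [(pos, cfg.alpha_food, None) for pos in world.food.item_positions]
    for i in range(cfg.n_agents):
        if i == exclude_agent:
            continue
        objs.append((world.positions[i], cfg.alpha_body, i))
    return objs


def snapshot(world, config: Optional[ArenaConfig] = None) -> FieldSnapshot:
    """Global field snapshot: emitters this step, induced sources on all food
    items and on every agent body other than the emitter's own, and
    first-order images of both."""
    cfg = config or world.config
    emitters = []
    for i in range(cfg.n_agents):
        if world.eod[i]:
            emitters.append(FieldSource(
                "emitter", world.positions[i].copy(),
                cfg.emitter_amplitude * np.array([np.cos(world.headings[i]),
                                                  np.sin(world.headings[i])]),
                owner_agent=i, step_emitted=world.step_count))
    sources = list(emitters)
    if emitters:
        objs = [(pos, cfg.alpha_food, None) for pos in world.food.item_positions]
        for i in range(cfg.n_agents):
            body_emitters = [e for e in emitters if e.owner_agent != i]
            if body_emitters:
                sources += induced_sources(body_emitters,
                                           [(world.positions[i], cfg.alpha_body, i)],
                                           cfg.kappa, cfg.r_min_cm, world.step_count)
        if objs:
            sources += induced_sources(emitters, objs, cfg.kappa, cfg.r_min_cm,
                                       world.step_count)
    if cfg.reflections_enabled:
        sources += image_sources(sources, cfg)
    return FieldSnapshot(step=world.step_count, sources=sources)


def render_grid(snap: FieldSnapshot, config: ArenaConfig, resolution: int = 64) -> np.ndarray:
    """|E| sampled on a regular ``resolution`` x ``resolution`` grid (row = y)."""
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    xs = np.linspace(0, config.width_cm, resolution)
    ys = np.linspace(0, config.height_cm, resolution)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    e = field_at_many(pts, snap.sources, config.kappa, config.r_min_cm)
    return np.linalg.norm(e, axis=1).reshape(resolution, resolution)
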