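"""Three-dimensional zonal (repulsion / orientation / attraction) flocking simulator.

Each agent carries a position and a unit heading.  At every step it reacts to
visible neighbours in three concentric spherical shells: it turns away from
neighbours inside the repulsion shell; otherwise it aligns with neighbours in
the orientation shell and steers toward neighbours in the attraction shell.
A rear blind cone hides neighbours behind the agent.  The heading change per
step is capped at ``tau * max_turn_rate_theta`` and every agent advances by
``speed * tau`` along its new heading.  Updates are synchronous.

Depending on the shell radii the group settles into one of four regimes --
swarm, torus (milling), dynamic parallel or highly parallel -- exposed here
as the :data:`PRESETS` table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .trajio import Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "ZoneParams",
    "AgentState",
    "SwarmConfig",
    "SwarmState",
    "PRESETS",
    "preset_config",
    "visible_neighbors",
    "repulsion_direction",
    "social_direction",
    "turn_toward",
    "step",
    "simulate",
    "order_parameters",
]

_UNIT_TOL = 1e-9


@dataclass(frozen=True)
class ZoneParams:
    """Interaction-zone geometry and kinematic limits, in body-length (BL) units.

    ``blind_halfangle`` is the half-angle of the rear blind cone measured from
    the anti-heading direction: a neighbour whose bearing from the focal agent
    makes an angle <= ``blind_halfangle`` with ``-d`` is invisible.
    """

    r_repulsion: float
    r_orientation: float
    r_attraction: float
    blind_halfangle: float = math.pi / 6
    max_turn_rate_theta: float = 0.7  # rad per unit time
    speed: float = 3.0  # BL per unit time
    tau: float = 0.1  # time step
    noise_sd: float = 0.0  # angular noise sd (rad) per step

    def __post_init__(self) -> None:
        if not (0.0 < self.r_repulsion <= self.r_orientation <= self.r_attraction):
            raise ValueError(
                "zone radii must satisfy 0 < r_repulsion <= r_orientation <= r_attraction"
            )
        if not (0.0 <= self.blind_halfangle < math.pi):
            raise ValueError("blind_halfangle must lie in [0, pi)")
        if self.max_turn_rate_theta <= 0:
            raise ValueError("max_turn_rate_theta must be positive")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.speed < 0:
            raise ValueError("speed must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def max_turn_angle(self) -> float:
        """Maximum heading rotation per step, tau * theta."""
        return self.tau * self.max_turn_rate_theta


@dataclass(frozen=True)
class AgentState:
    """Position and unit heading of a single agent."""

    position: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.position, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        if p.shape != (3,) or d.shape != (3,):
            raise ValueError("position and direction must be 3-vectors")
        if abs(np.linalg.norm(d) - 1.0) > _UNIT_TOL:
            raise ValueError("direction must be unit-norm within 1e-9")
        object.__setattr__(self, "position", p)
        object.__setattr__(self, "direction", d)


@dataclass(frozen=True)
class SwarmConfig:
    """Full specification of a simulation run."""

    n_agents: int
    zones: ZoneParams
    n_steps: int
    burn_in_steps: int = 0
    init_box_side: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents < 2:
            raise ValueError("n_agents must be >= 2")
        if self.n_steps <= self.burn_in_steps:
            raise ValueError("n_steps must exceed burn_in_steps")
        if self.burn_in_steps < 0:
            raise ValueError("burn_in_steps must be non-negative")
        if self.init_box_side <= 0:
            raise ValueError("init_box_side must be positive")


@dataclass
class SwarmState:
    """Positions ``(n, 3)`` and unit headings ``(n, 3)`` of all agents at one time."""

    time: float
    positions: np.ndarray
    directions: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.directions = np.asarray(self.directions, dtype=float)
        if self.positions.shape != self.directions.shape or self.positions.ndim != 2:
            raise ValueError("positions and directions must share shape (n, 3)")

    @property
    def n_agents(self) -> int:
        return self.positions.shape[0]

    @property
    def agents(self) -> list[AgentState]:
        return [
            AgentState(self.positions[i], self.directions[i])
            for i in range(self.n_agents)
        ]


#: Zone-radius presets (BL) reproducing the four collective regimes at the
#: default kinematics.  Calibrated in-repo; override any field via
#: :func:`preset_config`.
PRESETS: dict[str, ZoneParams] = {
    "swarm": ZoneParams(1.0, 1.0, 14.0, noise_sd=0.05),
    "torus": ZoneParams(1.0, 1.4, 14.0, noise_sd=0.05),
    "dpg": ZoneParams(1.0, 3.0, 14.0, noise_sd=0.05),
    "hpg": ZoneParams(1.0, 12.0, 14.0, noise_sd=0.05),
}


def preset_config(
    name: str,
    n_agents: int = 50,
    n_steps: int = 2000,
    burn_in_steps: int = 0,
    seed: int = 0,
    **zone_overrides: float,
) -> SwarmConfig:
    """Build a :class:`SwarmConfig` from a named regime preset.

    ``zone_overrides`` are forwarded to :func:`dataclasses.replace` on the
    preset :class:`ZoneParams`.
    """
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    zones = replace(PRESETS[name], **zone_overrides) if zone_overrides else PRESETS[name]
    return SwarmConfig(
        n_agents=n_agents,
        zones=zones,
        n_steps=n_steps,
        burn_in_steps=burn_in_steps,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# elementary interaction rules (single-agent API)
# ---------------------------------------------------------------------------


def visible_neighbors(
    focal: AgentState,
    others: list[AgentState] | np.ndarray,
    r_min: float,
    r_max: float,
    blind_halfangle: float,
) -> list[int]:
    """Indices of ``others`` inside the half-open shell ``[r_min, r_max)`` and
    outside the rear blind cone.

    Coincident neighbours (zero separation) are excluded from every zone, with
    a warning, because their bearing is undefined.  The innermost shell uses
    ``r_min = 0`` and is open at zero by this rule.
    """
    if not r_min < r_max:
        raise ValueError("r_min must be < r_max")
    if isinstance(others, np.ndarray):
        positions = others
    else:
        positions = np.array([o.position for o in others], dtype=float)
    if positions.size == 0:
        return []
    rel = positions - focal.position
    dist = np.linalg.norm(rel, axis=1)
    out: list[int] = []
    cos_blind = math.cos(blind_halfangle)
    for j in range(len(dist)):
        if dist[j] == 0.0:
            logger.warning("coincident neighbour at index %d excluded from all zones", j)
            continue
        if not (r_min <= dist[j] < r_max):
            continue
        # angle(rel, -d) > blind_halfangle  <=>  cos(angle) < cos(blind_halfangle)
        cos_back = float(rel[j] @ (-focal.direction)) / dist[j]
        if cos_back < cos_blind:
            out.append(j)
    return out


def _normalize(v: np.ndarray, fallback: np.ndarray | None = None) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0.0:
        if fallback is None:
            raise ValueError("cannot normalize zero vector")
        return np.array(fallback, dtype=float)
    return v / n


def repulsion_direction(focal: AgentState, repulsion_neighbors: np.ndarray) -> np.ndarray:
    """Unit desired direction pointing away from the repulsion-shell neighbours.

    Sums the negated unit bearings to each neighbour; symmetric cancellation
    falls back to the current heading.
    """
    positions = np.atleast_2d(np.asarray(repulsion_neighbors, dtype=float))
    if positions.shape[0] == 0:
        raise ValueError("repulsion_neighbors must be nonempty")
    rel = positions - focal.position
    norms = np.linalg.norm(rel, axis=1)
    w = -(rel / norms[:, None]).sum(axis=0)
    return _normalize(w, fallback=focal.direction)


def social_direction(
    focal: AgentState,
    orient_neighbors: np.ndarray,
    attract_neighbors: np.ndarray,
) -> np.ndarray:
    """Desired direction when the repulsion shell is empty.

    Alignment term: normalised sum of neighbour headings *including the focal
    agent's own heading*.  Attraction term: normalised sum of unit bearings to
    attraction-shell neighbours.  With both shells occupied the two unit
    terms are averaged and renormalised; with neither, the heading is kept.
    """
    directions = np.atleast_2d(np.asarray(orient_neighbors, dtype=float))
    positions = np.atleast_2d(np.asarray(attract_neighbors, dtype=float))
    n_o, n_a = directions.shape[0], positions.shape[0]
    if n_o == 0 and n_a == 0:
        return np.array(focal.direction, dtype=float)

    w_o = None
    if n_o > 0:
        s = directions.sum(axis=0) + focal.direction
        w_o = _normalize(s, fallback=focal.direction)
    w_a = None
    if n_a > 0:
        rel = positions - focal.position
        norms = np.linalg.norm(rel, axis=1)
        if np.any(norms == 0.0):
            raise ValueError("attraction neighbour coincident with focal agent")
        s = (rel / norms[:, None]).sum(axis=0)
        if np.linalg.norm(s) == 0.0:
            logger.debug("attraction sum cancelled; falling back to current heading")
            w_a = np.array(focal.direction, dtype=float)
        else:
            w_a = s / np.linalg.norm(s)

    if w_o is not None and w_a is not None:
        return _normalize((w_o + w_a) / 2.0, fallback=focal.direction)
    return w_o if w_o is not None else w_a  # type: ignore[return-value]


def _perp_axis(d: np.ndarray) -> np.ndarray:
    """Deterministic unit axis perpendicular to ``d``: the component of the
    first canonical basis vector not parallel to ``d``, orthogonalised."""
    for k in range(3):
        e = np.zeros(3)
        e[k] = 1.0
        perp = e - (e @ d) * d
        n = np.linalg.norm(perp)
        if n > 1e-9:
            return perp / n
    raise RuntimeError("unreachable: d cannot be parallel to all basis vectors")


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of ``v`` about unit ``axis`` by ``angle``."""
    c, s = math.cos(angle), math.sin(angle)
    return v * c + np.cross(axis, v) * s + axis * (axis @ v) * (1.0 - c)


def turn_toward(
    d_current: np.ndarray, w_desired: np.ndarray, max_angle: float
) -> np.ndarray:
    """Rotate ``d_current`` toward ``w_desired`` by at most ``max_angle``.

    If the desired direction is within the turn limit it is adopted outright
    (normalised).  An antiparallel target has no unique turning plane; the
    rotation then uses a deterministic perpendicular axis so runs stay
    reproducible.  A zero desired vector keeps the current heading.
    """
    d = np.asarray(d_current, dtype=float)
    w = np.asarray(w_desired, dtype=float)
    wn = np.linalg.norm(w)
    if wn == 0.0:
        return d.copy()
    w_hat = w / wn
    cosang = float(np.clip(d @ w_hat, -1.0, 1.0))
    angle = math.acos(cosang)
    if angle <= max_angle:
        return w_hat
    axis = np.cross(d, w_hat)
    axis_norm = np.linalg.norm(axis)
    if axis_norm < 1e-12:  # antiparallel: plane undefined
        axis = _perp_axis(d)
    else:
        axis = axis / axis_norm
    out = _rotate_about(d, axis, max_angle)
    return out / np.linalg.norm(out)


# ---------------------------------------------------------------------------
# synchronous swarm update (vectorised)
# ---------------------------------------------------------------------------


def _desired_directions(state: SwarmState, zones: ZoneParams) -> np.ndarray:
    """Desired direction of every agent from the zonal rules (before noise and
    the turn limit), computed synchronously from ``state``."""
    P, D = state.positions, state.directions
    n = P.shape[0]
    rel = P[None, :, :] - P[:, None, :]  # rel[i, j] = p_j - p_i
    dist = np.linalg.norm(rel, axis=2)
    np.fill_diagonal(dist, np.inf)  # self never a neighbour

    coincident = np.isfinite(dist) & (dist == 0.0)
    if coincident.any():
        logger.warning(
            "%d coincident agent pairs excluded from all zones", int(coincident.sum()) // 2
        )
        dist[coincident] = np.inf

    with np.errstate(invalid="ignore"):
        unit = rel / dist[:, :, None]
    unit[~np.isfinite(unit)] = 0.0

    # visibility: angle(rel_ij, -d_i) > blind_halfangle
    cos_back = -np.einsum("ijk,ik->ij", unit, D)
    visible = cos_back < math.cos(zones.blind_halfangle)
    visible &= np.isfinite(dist)

    rep = visible & (dist < zones.r_repulsion)
    ori = visible & (dist >= zones.r_repulsion) & (dist < zones.r_orientation)
    att = visible & (dist >= zones.r_orientation) & (dist < zones.r_attraction)

    n_r = rep.sum(axis=1)
    n_o = ori.sum(axis=1)
    n_a = att.sum(axis=1)

    w_r = -np.einsum("ij,ijk->ik", rep.astype(float), unit)
    w_o = ori.astype(float) @ D + D  # own heading included in the alignment sum
    w_a = np.einsum("ij,ijk->ik", att.astype(float), unit)

    def unit_rows(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        norms = np.linalg.norm(m, axis=1)
        ok = norms > 0.0
        out = np.where(ok[:, None], m / np.where(ok, norms, 1.0)[:, None], D)
        return out, ok

    u_r, _ = unit_rows(w_r)  # cancellation rows already fall back to D
    u_o, _ = unit_rows(w_o)
    u_a, ok_a = unit_rows(w_a)
    u_a = np.where(ok_a[:, None], u_a, D)

    both, _ = unit_rows(u_o + u_a)  # (u_o + u_a)/2 renormalised

    desired = np.where(
        (n_r > 0)[:, None],
        u_r,
        np.where(
            ((n_o > 0) & (n_a > 0))[:, None],
            both,
            np.where((n_o > 0)[:, None], u_o, np.where((n_a > 0)[:, None], u_a, D)),
        ),
    )
    return desired


def _apply_noise(desired: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Rotate each row by a Gaussian angle about a uniformly random
    perpendicular axis.  Skipped entirely (no RNG draws) when noise_sd == 0."""
    if noise_sd == 0.0:
        return desired
    n = desired.shape[0]
    angles = rng.normal(0.0, noise_sd, size=n)
    raw = rng.normal(size=(n, 3))
    proj = raw - np.einsum("ij,ij->i", raw, desired)[:, None] * desired
    norms = np.linalg.norm(proj, axis=1)
    # degenerate draws (raw parallel to desired) are measure-zero; guard anyway
    bad = norms < 1e-12
    if bad.any():
        for i in np.flatnonzero(bad):
            proj[i] = _perp_axis(desired[i])
            norms[i] = 1.0
    axes = proj / norms[:, None]
    c, s = np.cos(angles)[:, None], np.sin(angles)[:, None]
    dots = np.einsum("ij,ij->i", axes, desired)[:, None]
    out = desired * c + np.cross(axes, desired) * s + axes * dots * (1.0 - c)
    return out / np.linalg.norm(out, axis=1)[:, None]


def _turn_all(D: np.ndarray, W: np.ndarray, max_angle: float) -> np.ndarray:
    """Vectorised turn limit: rotate each heading toward its desired direction
    by at most ``max_angle`` (see :func:`turn_toward`)."""
    wn = np.linalg.norm(W, axis=1)
    keep = wn == 0.0
    w_hat = np.where(keep[:, None], D, W / np.where(keep, 1.0, wn)[:, None])
    cosang = np.clip(np.einsum("ij,ij->i", D, w_hat), -1.0, 1.0)
    angle = np.arccos(cosang)

    axis = np.cross(D, w_hat)
    axis_norm = np.linalg.norm(axis, axis=1)
    anti = (axis_norm < 1e-12) & (angle > max_angle)
    if anti.any():
        for i in np.flatnonzero(anti):
            axis[i] = _perp_axis(D[i])
            axis_norm[i] = 1.0
    safe = np.where(axis_norm > 0.0, axis_norm, 1.0)
    axis = axis / safe[:, None]

    c, s = math.cos(max_angle), math.sin(max_angle)
    rotated = D * c + np.cross(axis, D) * s  # axis is perpendicular to D
    rotated /= np.linalg.norm(rotated, axis=1)[:, None]

    within = angle <= max_angle
    out = np.where(within[:, None], w_hat, rotated)
    out = np.where(keep[:, None], D, out)
    return out / np.linalg.norm(out, axis=1)[:, None]


def step(state: SwarmState, zones: ZoneParams, rng: np.random.Generator | None = None) -> SwarmState:
    """One synchronous update of the whole swarm.

    All desired directions are computed from the previous state, optionally
    perturbed by angular noise, clipped by the turn-rate limit, and every
    agent then advances by ``speed * tau``.
    """
    desired = _desired_directions(state, zones)
    if zones.noise_sd > 0.0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an rng")
        desired = _apply_noise(desired, zones.noise_sd, rng)
    new_dir = _turn_all(state.directions, desired, zones.max_turn_angle)
    new_pos = state.positions + zones.speed * zones.tau * new_dir
    return SwarmState(time=state.time + zones.tau, positions=new_pos, directions=new_dir)


def _init_state(config: SwarmConfig, rng: np.random.Generator) -> SwarmState:
    """Uniform positions in a cube of side init_box_side, headings uniform on
    the unit sphere."""
    n = config.n_agents
    pos = rng.uniform(-config.init_box_side / 2.0, config.init_box_side / 2.0, size=(n, 3))
    raw = rng.normal(size=(n, 3))
    dirs = raw / np.linalg.norm(raw, axis=1)[:, None]
    return SwarmState(time=0.0, positions=pos, directions=dirs)


def simulate(config: SwarmConfig) -> Trajectory:
    """Run the simulator and return the post-burn-in trajectory (positions and
    headings at every retained step, including the state at the end of the
    burn-in itself as frame 0)."""
    rng = np.random.default_rng(config.seed)
    state = _init_state(config, rng)
    zones = config.zones
    n_keep = config.n_steps - config.burn_in_steps
    times = np.empty(n_keep)
    positions = np.empty((n_keep, config.n_agents, 3))
    directions = np.empty((n_keep, config.n_agents, 3))
    k = 0
    for t in range(config.n_steps):
        state = step(state, zones, rng)
        if not np.all(np.isfinite(state.positions)):
            raise FloatingPointError(f"non-finite coordinates at step {t}")
        if t >= config.burn_in_steps:
            times[k] = state.time
            positions[k] = state.positions
            directions[k] = state.directions
            k += 1
    agent_ids = [str(i) for i in range(config.n_agents)]
    return Trajectory(times=times, positions=positions, directions=directions, agent_ids=agent_ids)


def order_parameters(state: SwarmState) -> tuple[float, float]:
    """Group polarization and angular momentum, both in [0, 1].

    Polarization is the norm of the mean heading.  Angular momentum is the
    norm of the mean of r_hat x d over agents, with r_hat the unit vector
    from the group centroid to the agent (agents at the centroid contribute
    zero); it peaks for milling (torus) configurations.
    """
    D = state.directions
    n = D.shape[0]
    pol = float(np.linalg.norm(D.sum(axis=0)) / n)
    r = state.positions - state.positions.mean(axis=0)
    norms = np.linalg.norm(r, axis=1)
    ok = norms > 0.0
    r_hat = np.zeros_like(r)
    r_hat[ok] = r[ok] / norms[ok, None]
    mom = float(np.linalg.norm(np.cross(r_hat, D).sum(axis=0)) / n)
    return pol, mom
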