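"""Spatial winner-loser agent-based model of dominance-hierarchy formation.

Agents move on a continuous toroidal plane, group with others they see at
medium or far range, and compete when another comes very close.  A potential
fight starts with one or more "mental battles": the focal agent attacks only
if it wins an internal simulation of the fight.  A real fight is won by the
initiator with probability ``D_i / (D_i + D_j)``; afterwards the winner's
dominance value rises and the loser's falls by the same, outcome-damped
amount (the winner-loser effect), the winner chases and the loser flees.

Sexual dimorphism is represented by sex-specific initial dominance values and
sex-specific intensities of aggression (``StepDom``): males start with twice
the dominance of females and their fights shift dominance values tenfold more.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .core import GroupComposition, InteractionMatrix, make_ids

__all__ = [
    "SimParams",
    "AgentState",
    "FightRecord",
    "SimulationResult",
    "init_world",
    "mental_battle",
    "fight_outcome",
    "update_dominance",
    "resolve_activation",
    "run_simulation",
]

STEP_DOM_CONVENTIONS = ("initiator", "winner", "opponent", "mean")


@dataclass
class SimParams:
    """Simulation parameters; defaults follow the standard female/male setting.

    Distances are in world units, angles in degrees.  ``step_dom`` is the
    per-sex intensity of aggression: the scale of the dominance update after
    a fight.  ``step_dom_convention`` selects whose intensity scales a fight
    between individuals of unequal intensity (the update itself is always
    symmetric: winner gains what the loser loses).
    """

    initial_dominance: dict = field(
        default_factory=lambda: {"female": 16.0, "male": 32.0}
    )
    step_dom: dict = field(default_factory=lambda: {"female": 0.1, "male": 1.0})
    num_mental_battles: int = 1
    field_of_view: float = 120.0
    pers_space: float = 4.0
    near_view: float = 24.0
    max_view: float = 48.0
    flee_dist: float = 2.0
    withdraw_dist: float = 0.0
    chase_dist: float = 1.0
    move_dist: float = 1.0
    wiggle_turn: float = 0.0
    wiggle_turn_error: float = 10.0
    search_turn: float = 90.0
    search_turn_error: float = 10.0
    won_turn: float = 0.0
    won_turn_error: float = 0.0
    flee_turn: float = 180.0
    flee_turn_error: float = 10.0
    world_size: float = 200.0
    start_radius: float = 20.0
    n_periods: int = 300
    burn_in_periods: int = 60
    step_dom_convention: str = "initiator"
    dominance_floor: float = 0.01

    def validate(self) -> None:
        for name in (
            "pers_space",
            "near_view",
            "max_view",
            "flee_dist",
            "withdraw_dist",
            "chase_dist",
            "move_dist",
            "world_size",
            "start_radius",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (self.pers_space <= self.near_view <= self.max_view):
            raise ValueError("need pers_space <= near_view <= max_view")
        if not (0 < self.field_of_view <= 360):
            raise ValueError("field_of_view must be in (0, 360]")
        if self.num_mental_battles < 1:
            raise ValueError("num_mental_battles must be >= 1")
        if self.burn_in_periods >= self.n_periods:
            raise ValueError("burn_in_periods must be < n_periods")
        if self.dominance_floor <= 0:
            raise ValueError("dominance_floor must be > 0")
        if self.step_dom_convention not in STEP_DOM_CONVENTIONS:
            raise ValueError(
                f"unknown step_dom_convention {self.step_dom_convention!r}; "
                f"expected one of {STEP_DOM_CONVENTIONS}"
            )
        for d in (self.initial_dominance, self.step_dom):
            if set(d) != {"female", "male"}:
                raise ValueError("per-sex parameters need 'female' and 'male' keys")

    def with_overrides(self, **kwargs) -> "SimParams":
        p = replace(self, **kwargs)
        p.validate()
        return p


@dataclass
class AgentState:
    """One simulated individual."""

    id: str
    sex: str
    x: float
    y: float
    heading: float  # degrees, counter-clockwise, 0 = +x
    D: float  # dominance value, > 0
    step_dom: float


@dataclass(frozen=True)
class FightRecord:
    initiator: int
    opponent: int
    winner: int

    @property
    def loser(self) -> int:
        return self.opponent if self.winner == self.initiator else self.initiator


def init_world(
    params: SimParams, comp: GroupComposition, rng: np.random.Generator
) -> list[AgentState]:
    """Create the agents of one group, clustered near the world centre.

    Males take the male initial dominance and intensity, females the female
    values.  Positions are uniform in a disc of ``start_radius`` around the
    world centre so that every agent starts within view of the others;
    headings are uniform on [0, 360).
    """
    params.validate()
    ids = make_ids(comp)
    half = params.world_size / 2.0
    agents: list[AgentState] = []
    for ident in ids:
        sex = "male" if ident.startswith("m") else "female"
        # uniform in a disc via rejection-free polar sampling
        r = params.start_radius * math.sqrt(rng.random())
        phi = rng.random() * 2 * math.pi
        agents.append(
            AgentState(
                id=ident,
                sex=sex,
                x=(half + r * math.cos(phi)) % params.world_size,
                y=(half + r * math.sin(phi)) % params.world_size,
                heading=rng.random() * 360.0,
                D=float(params.initial_dominance[sex]),
                step_dom=float(params.step_dom[sex]),
            )
        )
    return agents


def mental_battle(
    di: float, dj: float, n_battles: int, rng: np.random.Generator
) -> bool:
    """Decide whether to attack: win ``n_battles`` independent imagined fights.

    Each imagined fight is won when ``di / (di + dj)`` exceeds a uniform
    draw, so the attack probability is ``(di / (di + dj)) ** n_battles``.
    """
    if di <= 0 or dj <= 0:
        raise ValueError("dominance values must be positive")
    if n_battles < 1:
        raise ValueError("n_battles must be >= 1")
    p = di / (di + dj)
    for _ in range(n_battles):
        if not p > rng.random():
            return False
    return True


def fight_outcome(di: float, dj: float, rng: np.random.Generator) -> int:
    """Return 1 if the initiator wins, 0 otherwise; P(win) = di / (di + dj)."""
    if di <= 0 or dj <= 0:
        raise ValueError("dominance values must be positive")
    return 1 if di / (di + dj) > rng.random() else 0


def update_dominance(
    di: float,
    dj: float,
    w: int,
    si: float,
    sj: float,
    convention: str = "initiator",
    floor: float = 0.01,
) -> tuple[float, float]:
    """Winner-loser update of the two dominance values after a decided fight.

    The change is ``delta = (w - di/(di+dj)) * S``: an expected outcome moves
    the values little, an upset moves them much (damped positive feedback).
    Winner and loser change by the same amount, so the update is zero-sum
    except when the floor is hit.  ``S`` is picked from the two intensities
    by `convention`.
    """
    if di <= 0 or dj <= 0:
        raise ValueError("dominance values must be positive")
    if w not in (0, 1):
        raise ValueError("w must be 0 or 1")
    if convention == "initiator":
        s = si
    elif convention == "winner":
        s = si if w == 1 else sj
    elif convention == "opponent":
        s = sj
    elif convention == "mean":
        s = 0.5 * (si + sj)
    else:
        raise ValueError(
            f"unknown convention {convention!r}; expected one of {STEP_DOM_CONVENTIONS}"
        )
    delta = (w - di / (di + dj)) * s
    return max(floor, di + delta), max(floor, dj - delta)


def _torus_delta(a: AgentState, b: AgentState, size: float) -> tuple[float, float]:
    half = size / 2.0
    dx = (b.x - a.x + half) % size - half
    dy = (b.y - a.y + half) % size - half
    return dx, dy


def _advance(agent: AgentState, dist: float, size: float) -> None:
    rad = math.radians(agent.heading)
    agent.x = (agent.x + dist * math.cos(rad)) % size
    agent.y = (agent.y + dist * math.sin(rad)) % size


def _uniform_error(rng: np.random.Generator, err: float) -> float:
    return (rng.random() * 2.0 - 1.0) * err if err > 0 else 0.0


def resolve_activation(
    world: list[AgentState],
    focal_index: int,
    params: SimParams,
    rng: np.random.Generator,
) -> Optional[FightRecord]:
    """Activate one agent; returns a fight record iff a fight occurred.

    Behaviour keys on the nearest other that is visible (within the field of
    view and within ``max_view``, toroidal metric):

    - within ``pers_space``: run the mental battle; on attack, fight, update
      dominance, winner chases (``chase_dist`` toward the loser) and the loser
      flees (``flee_dist`` away, flee-turn error applied); on no attack the
      focal turns away 180 deg (+- 10) and withdraws ``withdraw_dist``;
    - within ``near_view``: keep going (``move_dist`` along heading with
      wiggle error) - the agent is already in a group;
    - within ``max_view`` beyond ``near_view``: turn toward that other and
      advance ``move_dist`` (returning to the group);
    - nobody visible: search-turn to a random side and advance ``move_dist``.
    """
    focal = world[focal_index]
    size = params.world_size
    half_fov = params.field_of_view / 2.0

    nearest = -1
    nearest_d2 = params.max_view * params.max_view
    head = focal.heading % 360.0
    for j, other in enumerate(world):
        if j == focal_index:
            continue
        dx, dy = _torus_delta(focal, other, size)
        d2 = dx * dx + dy * dy
        if d2 > nearest_d2:
            continue
        bearing = math.degrees(math.atan2(dy, dx))
        rel = (bearing - head + 180.0) % 360.0 - 180.0
        if abs(rel) > half_fov:
            continue
        if d2 < nearest_d2 or nearest == -1:
            nearest = j
            nearest_d2 = d2

    if nearest == -1:
        side = 1.0 if rng.random() < 0.5 else -1.0
        focal.heading = (
            focal.heading
            + side * (params.search_turn + _uniform_error(rng, params.search_turn_error))
        ) % 360.0
        _advance(focal, params.move_dist, size)
        return None

    other = world[nearest]
    dist = math.sqrt(nearest_d2)

    if dist <= params.pers_space:
        if mental_battle(focal.D, other.D, params.num_mental_battles, rng):
            w = fight_outcome(focal.D, other.D, rng)
            focal.D, other.D = update_dominance(
                focal.D,
                other.D,
                w,
                focal.step_dom,
                other.step_dom,
                params.step_dom_convention,
                params.dominance_floor,
            )
            winner, loser = (focal, other) if w == 1 else (other, focal)
            dx, dy = _torus_delta(winner, loser, size)
            away = math.degrees(math.atan2(dy, dx))  # direction winner -> loser
            loser.heading = (
                away
                + (params.flee_turn - 180.0)
                + _uniform_error(rng, params.flee_turn_error)
            ) % 360.0
            _advance(loser, params.flee_dist, size)
            winner.heading = (
                away + params.won_turn + _uniform_error(rng, params.won_turn_error)
            ) % 360.0
            _advance(winner, params.chase_dist, size)
            return FightRecord(
                initiator=focal_index,
                opponent=nearest,
                winner=focal_index if w == 1 else nearest,
            )
        # lost the mental battle: turn away and withdraw
        focal.heading = (focal.heading + 180.0 + _uniform_error(rng, 10.0)) % 360.0
        _advance(focal, params.withdraw_dist, size)
        return None

    if dist <= params.near_view:
        focal.heading = (
            focal.heading
            + params.wiggle_turn
            + _uniform_error(rng, params.wiggle_turn_error)
        ) % 360.0
        _advance(focal, params.move_dist, size)
        return None

    # beyond near_view but within max_view: turn toward the other
    dx, dy = _torus_delta(focal, other, size)
    focal.heading = math.degrees(math.atan2(dy, dx)) % 360.0
    _advance(focal, params.move_dist, size)
    return None


@dataclass
class SimulationResult:
    """Outcome of one simulated group: post-burn-in tallies and D trajectories."""

    matrix: InteractionMatrix  # winner x loser counts
    attacks: np.ndarray  # initiator x target counts (same id order)
    dominance_history: np.ndarray  # (n_periods + 1, n) dominance values
    params: SimParams
    comp: GroupComposition
    seed: object


def run_simulation(
    params: SimParams,
    comp: GroupComposition,
    seed: int | np.random.SeedSequence,
) -> SimulationResult:
    """Run one group for ``n_periods`` activation periods.

    Within a period every agent is activated exactly once, in a fresh uniform
    random order.  Fights occurring after ``burn_in_periods`` are tallied into
    the winner-loser matrix and the initiator-attributed attack matrix.  The
    run is deterministic given the seed.
    """
    params.validate()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    world = init_world(params, comp, rng)
    n = len(world)
    wins = np.zeros((n, n), dtype=np.int64)
    attacks = np.zeros((n, n), dtype=np.int64)
    history = np.empty((params.n_periods + 1, n))
    history[0] = [a.D for a in world]
    for period in range(params.n_periods):
        record = period >= params.burn_in_periods
        for i in rng.permutation(n):
            rec = resolve_activation(world, int(i), params, rng)
            if rec is not None and record:
                wins[rec.winner, rec.loser] += 1
                attacks[rec.initiator, rec.opponent] += 1
        history[period + 1] = [a.D for a in world]
    matrix = InteractionMatrix(
        ids=[a.id for a in world], sexes=[a.sex for a in world], counts=wins
    )
    return SimulationResult(
        matrix=matrix,
        attacks=attacks,
        dominance_history=history,
        params=params,
        comp=comp,
        seed=seed,
    )
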