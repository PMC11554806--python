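"""Seeded generators for habitat event streams and arena trajectories.

The habitat simulator is an agent-based continuous-time Markov model on the
four-compartment ring.  Each animal waits an exponential time whose rate
follows the 12-h dark/light cycle (mice transition more in the dark), then
moves to one of the two ring-adjacent compartments.  Destination choice is
socially biased: compartment *d* is drawn with weight ``exp(α · m_d)`` where
``m_d`` counts cohort mates currently in *d* and α ≥ 0 is the social
affinity.  α = 0 gives independent exploration — the null of the in-cohort
sociability statistic.  A move takes ``transit_s`` seconds and emits an
origin-side then a destination-side antenna read, each detected with
probability ``p_det``.

Everything is driven by one seeded RNG stream advanced in a documented
order (events processed in time order, ties by animal id; per move: origin
detection, destination choice; per arrival: destination detection, next
waiting time), so identical configs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .apparatus import (
    HOUR,
    Animal,
    AnimalRegistry,
    Apparatus,
    ProtocolWindows,
)
from .io import events_frame
from .occupancy import VISIT_COLUMNS
from .three_chamber import ArenaSpec, Trajectory2D


@dataclass(frozen=True)
class SimConfig:
    """Habitat simulation parameters.

    Defaults follow the 84-h protocol with a 10-animal cohort; rates are
    per-animal compartment transitions per hour in each light phase, chosen
    to give nocturnal activity of realistic order (a few hundred visits per
    12-h dark bin per animal).
    """

    n_animals: int = 10
    duration_h: float = 84.0
    lambda_dark: float = 12.0     # transitions/h during dark phase
    lambda_light: float = 4.0     # transitions/h during light phase
    alpha: float = 0.0            # social affinity (log-weight per mate)
    transit_s: float = 2.0        # tube crossing time
    p_det: float = 0.98           # per-read detection probability
    seed: int = 0
    genotypes: tuple[str, ...] = ()   # cycled over animals; default all WT
    sexes: tuple[str, ...] = ("M",)
    affinity_matrix: np.ndarray | None = None  # optional per-pair weights
    dark_onset_h: float = 0.0

    def __post_init__(self) -> None:
        if self.lambda_dark <= 0 or self.lambda_light <= 0:
            raise ValueError("transition rates must be positive")
        if not 0.0 <= self.p_det <= 1.0:
            raise ValueError("p_det must be in [0, 1]")
        if self.alpha < 0:
            raise ValueError("affinity must be non-negative")
        if self.affinity_matrix is not None:
            w = np.asarray(self.affinity_matrix, dtype=float)
            if w.shape != (self.n_animals, self.n_animals) or not np.allclose(w, w.T):
                raise ValueError("affinity matrix must be symmetric n×n")

    def protocol(self) -> ProtocolWindows:
        return ProtocolWindows(duration_h=self.duration_h,
                               dark_onset_h=self.dark_onset_h)


@dataclass
class GroundTruth:
    """What the simulator actually did, independent of antenna detection."""

    visits: pd.DataFrame        # true per-animal compartment intervals
    transitions: pd.DataFrame   # animal, time_s of each completed arrival
    registry: AnimalRegistry
    config: SimConfig

    def transition_counts(self, protocol: ProtocolWindows) -> pd.DataFrame:
        edges = np.asarray(protocol.bin_edges_s())
        rows = []
        for a in self.registry.animal_ids:
            t = self.transitions.loc[self.transitions["animal"] == a, "time_s"].to_numpy()
            counts, _ = np.histogram(t, bins=edges)
            rows.extend((a, b, int(c)) for b, c in enumerate(counts))
        return pd.DataFrame(rows, columns=["animal", "bin", "visits"])


def make_registry(config: SimConfig, cohort: str = "sim") -> AnimalRegistry:
    genos = config.genotypes or ("WT",)
    animals = [
        Animal(
            animal_id=f"m{i:02d}",
            tag=f"TAG{i:04d}",
            genotype=genos[i % len(genos)],
            sex=config.sexes[i % len(config.sexes)],
            cohort=cohort,
        )
        for i in range(config.n_animals)
    ]
    return AnimalRegistry(animals)


def simulate_habitat(
    config: SimConfig,
    apparatus: Apparatus | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the cohort; returns (antenna events, ground truth).

    Initial compartments are drawn uniformly (so each animal's marginal
    occupancy is 1/4 at all times under α = 0, which makes the analytic
    expectation of the sociability statistic zero).  Waiting clocks are
    re-drawn at each 12-h phase boundary with the new rate, which is
    statistically exact for exponential clocks.
    """
    apparatus = apparatus or Apparatus()
    rng = np.random.default_rng(config.seed)
    n = config.n_animals
    duration = config.duration_h * HOUR
    tau = config.transit_s

    def phase_at(t_s: float) -> str:
        h = t_s / HOUR - config.dark_onset_h
        return "dark" if int(h // 12.0) % 2 == 0 else "light"

    w_pair = (
        np.asarray(config.affinity_matrix, dtype=float)
        if config.affinity_matrix is not None
        else np.ones((n, n)) - np.eye(n)
    )

    def rate_per_s(t: float) -> float:
        lam = (config.lambda_dark
               if phase_at(t) == "dark" else config.lambda_light)
        return lam / HOUR

    loc = rng.integers(1, 5, size=n)            # current compartment
    in_transit = np.zeros(n, dtype=bool)
    dest = np.zeros(n, dtype=int)
    next_t = np.array([rng.exponential(1.0 / rate_per_s(0.0)) for _ in range(n)])
    visit_start = np.zeros(n)

    boundaries = [b for b in np.arange(12 * HOUR, duration, 12 * HOUR)]
    bi = 0

    ev_t: list[float] = []
    ev_ant: list[int] = []
    ev_tag: list[str] = []
    visit_rows: list[tuple[str, int, float, float]] = []
    trans_rows: list[tuple[str, float]] = []
    registry = make_registry(config)
    tags = [a.tag for a in registry.animals]
    ids = registry.animal_ids

    while True:
        a = int(np.argmin(next_t))              # ties resolved by animal id
        t = float(next_t[a])
        if bi < len(boundaries) and t > boundaries[bi]:
            b = boundaries[bi]
            r = rate_per_s(b)
            for j in range(n):                  # re-draw waiting clocks only
                if not in_transit[j]:
                    next_t[j] = b + rng.exponential(1.0 / r)
            bi += 1
            continue
        if t >= duration:
            break
        if not in_transit[a]:
            # departure decision from compartment c
            c = int(loc[a])
            d1, d2 = apparatus.neighbors(c)
            occupied = ~in_transit
            m1 = float(w_pair[a, (loc == d1) & occupied].sum())
            m2 = float(w_pair[a, (loc == d2) & occupied].sum())
            tube_det = rng.random()             # origin-read detection draw
            logw = config.alpha * np.array([m1, m2])
            pw = np.exp(logw - logw.max())
            d = d1 if rng.random() < pw[0] / pw.sum() else d2
            tube = apparatus.tube_between(c, d)
            if tube_det < config.p_det:
                ev_t.append(t)
                ev_ant.append(apparatus.antenna_for(tube.id, c))
                ev_tag.append(tags[a])
            visit_rows.append((ids[a], c, float(visit_start[a]), t))
            in_transit[a] = True
            dest[a] = d
            next_t[a] = t + tau
        else:
            # arrival in destination compartment
            d = int(dest[a])
            if rng.random() < config.p_det:
                tube = apparatus.tube_between(int(loc[a]), d)
                ev_t.append(t)
                ev_ant.append(apparatus.antenna_for(tube.id, d))
                ev_tag.append(tags[a])
            loc[a] = d
            in_transit[a] = False
            visit_start[a] = t
            trans_rows.append((ids[a], t))
            next_t[a] = t + rng.exponential(1.0 / rate_per_s(t))

    for j in range(n):                          # close visits at session end
        if not in_transit[j] and duration > visit_start[j]:
            visit_rows.append((ids[j], int(loc[j]), float(visit_start[j]), duration))

    events = events_frame(ev_t, ev_ant, ev_tag)
    visits = pd.DataFrame(visit_rows, columns=list(VISIT_COLUMNS))
    visits = visits.sort_values(["animal", "start_s"], ignore_index=True)
    transitions = pd.DataFrame(trans_rows, columns=["animal", "time_s"])
    truth = GroundTruth(visits, transitions, registry, config)
    return events, truth


def with_alpha(config: SimConfig, alpha: float) -> SimConfig:
    """Same conditions and seed, different social affinity (coupled runs)."""
    return replace(config, alpha=alpha)


# ---------------------------------------------------------------------------
# three-chamber trajectory generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WalkConfig:
    """Biased random walk parameters for the three-chamber arena.

    ``zone_weights`` maps zone names (``near_cup_left``, ``near_cup_right``,
    or chamber names) to non-negative attraction weights; each step drifts
    toward the highest-weight zone's center, scaled by that weight.  All
    weights zero gives an unbiased reflecting walk.
    """

    duration_s: float = 600.0
    rate_hz: float = 25.0
    step_sd_mm: float = 15.0
    drift_mm_per_unit: float = 3.0
    zone_weights: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    confine: str | None = None   # chamber name; doors-closed sessions


def _zone_center(arena: ArenaSpec, zone: str) -> tuple[float, float]:
    if zone.startswith("near_cup_"):
        return arena.cup_centers[zone.removeprefix("near_cup_")]
    x0, x1 = arena.chamber_bounds_x(zone)
    return ((x0 + x1) / 2.0, arena.width_mm / 2.0)


def simulate_three_chamber(
    arena: ArenaSpec,
    walk: WalkConfig,
    *,
    animal: str = "m00",
    session: str = "test",
    stimulus_side: str = "left",
) -> tuple[Trajectory2D, pd.DataFrame]:
    """Generate a trajectory and its true per-sample zone schedule.

    Reflecting outer walls; partition crossings are only allowed through
    the door opening (or not at all when ``confine`` names a chamber, as in
    the doors-closed habituation session).
    """
    if walk.duration_s <= 0:
        raise ValueError("duration must be positive")
    if any(w < 0 for w in walk.zone_weights.values()):
        raise ValueError("zone weights must be non-negative")
    rng = np.random.default_rng(walk.seed)
    dt = 1.0 / walk.rate_hz
    n = int(round(walk.duration_s * walk.rate_hz))
    t = np.arange(n) * dt

    if walk.confine:
        x0, x1 = arena.chamber_bounds_x(walk.confine)
    else:
        x0, x1 = 0.0, arena.length_mm
    y0, y1 = 0.0, arena.width_mm
    dlo, dhi = arena.door_y

    target = None
    wmax = 0.0
    for zone, w in walk.zone_weights.items():
        if w > wmax:
            wmax, target = w, _zone_center(arena, zone)

    pos = np.array([(x0 + x1) / 2.0, arena.width_mm / 2.0])
    xs = np.empty(n)
    ys = np.empty(n)
    zones: list[str] = []
    for i in range(n):
        xs[i], ys[i] = pos
        zones.append(arena.zone_of(pos[0], pos[1]))
        step = rng.normal(0.0, walk.step_sd_mm, size=2)
        if target is not None:
            delta = np.array(target) - pos
            dist = np.hypot(*delta)
            if dist > 1e-9:
                step += walk.drift_mm_per_unit * wmax * delta / dist
        new = pos + step
        # reflect off outer (or confinement) walls
        new[0] = _reflect(new[0], x0, x1)
        new[1] = _reflect(new[1], y0, y1)
        if not walk.confine and arena.chamber_of(new[0]) != arena.chamber_of(pos[0]):
            if not (dlo <= new[1] <= dhi and dlo <= pos[1] <= dhi):
                new[0] = pos[0]   # blocked by the partition; slide along it
        pos = new
    traj = Trajectory2D(animal, session, t, xs, ys,
                        stimulus_side=stimulus_side, duration_s=walk.duration_s)
    schedule = pd.DataFrame({"t_s": t, "zone": zones})
    return traj, schedule


def _reflect(v: float, lo: float, hi: float) -> float:
    width = hi - lo
    if width <= 0:
        raise ValueError("degenerate bounds")
    v = (v - lo) % (2 * width)
    return lo + (width - abs(v - width))
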