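"""Three-chamber social-approach analysis: zones, dwell times, exclusion.

The arena is an 820 × 420 mm rectangle split along its long axis into a
300-mm left chamber, a 200-mm center chamber and a 300-mm right chamber by
10-mm partitions with 80-mm door openings.  Each side chamber holds a
100 × 100 mm stimulus cup; the "near cup" zone is the concentric
140 × 140 mm square (a 2-cm border around the cup).  Preference is measured
as dwell time in the near-cup zones during the 10-min test session.

Coordinates: origin at the arena's lower-left corner, x along the 820-mm
axis, y along the 420-mm axis, millimeters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .apparatus import AnimalRegistry

SESSIONS = ("habituation_center", "habituation_all", "test")
CHAMBERS = ("left", "center", "right")
ZONES = CHAMBERS + ("near_cup_left", "near_cup_right")


@dataclass(frozen=True)
class ArenaSpec:
    """Three-chamber arena geometry in millimeters."""

    length_mm: float = 820.0
    width_mm: float = 420.0
    side_chamber_mm: float = 300.0
    center_chamber_mm: float = 200.0
    wall_mm: float = 10.0
    door_mm: float = 80.0
    cup_mm: float = 100.0
    near_cup_mm: float = 140.0
    session_s: float = 600.0

    def __post_init__(self) -> None:
        interior = 2 * self.side_chamber_mm + self.center_chamber_mm + 2 * self.wall_mm
        if abs(interior - self.length_mm) > 1e-6:
            raise ValueError("chamber widths plus partitions must equal arena length")
        if self.near_cup_mm < self.cup_mm:
            raise ValueError("near-cup zone must contain the cup")

    # chamber split: partition walls are halved between their neighbours so
    # the three chambers exactly partition the arena interior
    @property
    def left_boundary_x(self) -> float:
        return self.side_chamber_mm + self.wall_mm / 2.0

    @property
    def right_boundary_x(self) -> float:
        return self.length_mm - self.side_chamber_mm - self.wall_mm / 2.0

    @property
    def door_y(self) -> tuple[float, float]:
        c = self.width_mm / 2.0
        return (c - self.door_mm / 2.0, c + self.door_mm / 2.0)

    @property
    def cup_centers(self) -> dict[str, tuple[float, float]]:
        return {
            "left": (self.side_chamber_mm / 2.0, self.width_mm / 2.0),
            "right": (self.length_mm - self.side_chamber_mm / 2.0, self.width_mm / 2.0),
        }

    def chamber_bounds_x(self, chamber: str) -> tuple[float, float]:
        return {
            "left": (0.0, self.left_boundary_x),
            "center": (self.left_boundary_x, self.right_boundary_x),
            "right": (self.right_boundary_x, self.length_mm),
        }[chamber]

    def chamber_of(self, x: float) -> str:
        if x < self.left_boundary_x:
            return "left"
        if x < self.right_boundary_x:
            return "center"
        return "right"

    def in_near_cup(self, x: float, y: float, side: str) -> bool:
        cx, cy = self.cup_centers[side]
        h = self.near_cup_mm / 2.0
        return (abs(x - cx) <= h) and (abs(y - cy) <= h)

    def zone_of(self, x: float, y: float) -> str:
        """Most specific zone containing a point (near-cup over chamber).

        A point exactly on a zone edge goes to the zone whose cup center is
        nearer, ties resolved toward the near-cup zone; the closed near-cup
        test above implements exactly that for this geometry.
        """
        for side in ("left", "right"):
            if self.in_near_cup(x, y, side):
                return f"near_cup_{side}"
        return self.chamber_of(x)

    def contains(self, x: float, y: float, tol: float = 0.0) -> bool:
        return (-tol <= x <= self.length_mm + tol) and (-tol <= y <= self.width_mm + tol)


@dataclass
class Trajectory2D:
    """Positional samples for one animal in one session.

    ``x``/``y`` may be NaN for missing (untracked) samples; ``t`` is
    strictly increasing.  ``stimulus_side`` names the side chamber holding
    the social cup in the test session.
    """

    animal: str
    session: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    stimulus_side: str = "left"
    duration_s: float = 600.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.session not in SESSIONS:
            raise ValueError(f"session must be one of {SESSIONS}")
        if len(self.t) and np.any(np.diff(self.t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if self.t.size and self.t[-1] > self.duration_s + 1e-9:
            raise ValueError("samples extend past the session duration")

    @property
    def valid(self) -> np.ndarray:
        return ~(np.isnan(self.x) | np.isnan(self.y))

    def to_csv(self, path) -> None:
        pd.DataFrame({"t_s": self.t, "x_mm": self.x, "y_mm": self.y}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, animal: str, session: str, **kw) -> "Trajectory2D":
        df = pd.read_csv(path)
        return cls(animal, session, df["t_s"].to_numpy(),
                   df["x_mm"].to_numpy(), df["y_mm"].to_numpy(), **kw)


def zone_times(traj: Trajectory2D, arena: ArenaSpec, *, tol_mm: float = 5.0) -> dict[str, float]:
    """Dwell seconds per zone plus untracked time.

    Each sample contributes its inter-sample interval (the last sample
    contributes up to the session end) to the zone containing its point;
    missing samples contribute to ``"missing"``.  Near-cup time is also
    included in the containing chamber's time, so chamber times plus missing
    time always sum exactly to the session duration.
    """
    out = {z: 0.0 for z in ZONES}
    out["missing"] = 0.0
    t, x, y = traj.t, traj.x, traj.y
    valid = traj.valid
    if x[valid].size:
        xm, ym = x[valid], y[valid]
        if (np.any(xm < -tol_mm) or np.any(xm > arena.length_mm + tol_mm)
                or np.any(ym < -tol_mm) or np.any(ym > arena.width_mm + tol_mm)):
            raise ValueError("trajectory leaves the arena beyond tolerance")
    ends = np.empty_like(t)
    ends[:-1] = t[1:]
    if len(t):
        ends[-1] = max(traj.duration_s, t[-1])
    for i in range(len(t)):
        dt = ends[i] - t[i]
        if not valid[i]:
            out["missing"] += dt
            continue
        zone = arena.zone_of(float(x[i]), float(y[i]))
        out[zone] += dt
        if zone.startswith("near_cup_"):
            out[zone.removeprefix("near_cup_")] += dt
    if len(t) and t[0] > 0:
        out["missing"] += t[0]  # time before the first sample is untracked
    return out


def path_length(traj: Trajectory2D) -> float:
    """Total distance moved (mm): sum of Euclidean steps between
    consecutive valid samples; steps across missing samples are excluded."""
    valid = traj.valid
    if valid.sum() < 2:
        raise ValueError("need at least 2 valid samples")
    total = 0.0
    prev: tuple[float, float] | None = None
    prev_i = -1
    for i in np.flatnonzero(valid):
        if prev is not None and i == prev_i + 1:
            total += math.hypot(traj.x[i] - prev[0], traj.y[i] - prev[1])
        prev = (float(traj.x[i]), float(traj.y[i]))
        prev_i = int(i)
    return total


@dataclass
class PreferenceResult:
    """Per-animal three-chamber outcome across the session battery."""

    animal: str
    time_near_social_s: float = np.nan
    time_near_nonsocial_s: float = np.nan
    chamber_times_s: dict[str, float] = field(default_factory=dict)
    path_length_center_mm: float = np.nan
    included: bool = True
    exclusion_reason: str = ""


def apply_exclusion(zone_times_by_session: dict[str, dict[str, float]]) -> tuple[bool, str]:
    """Inclusion rule for one animal.

    Excluded iff, in the all-chambers habituation session or the test
    session, the animal spent zero time in at least one side chamber (the
    extremely-low-activity cases); a missing session also excludes.
    Returns ``(included, reason)``.
    """
    for session in ("habituation_all", "test"):
        zt = zone_times_by_session.get(session)
        if zt is None:
            return False, f"missing session: {session}"
        for chamber in ("left", "right"):
            if zt.get(chamber, 0.0) <= 0.0:
                return False, f"no {chamber}-chamber visit in {session}"
    return True, ""


def analyze_animal(
    trajectories: dict[str, Trajectory2D],
    arena: ArenaSpec,
) -> PreferenceResult:
    """Run the full per-animal analysis over its session trajectories."""
    if not trajectories:
        raise ValueError("no sessions provided")
    animal = next(iter(trajectories.values())).animal
    res = PreferenceResult(animal)
    zts = {s: zone_times(tr, arena) for s, tr in trajectories.items()}
    res.included, res.exclusion_reason = apply_exclusion(zts)
    if "habituation_center" in trajectories:
        res.path_length_center_mm = path_length(trajectories["habituation_center"])
    test = trajectories.get("test")
    if test is not None:
        zt = zts["test"]
        social = test.stimulus_side
        nonsocial = "right" if social == "left" else "left"
        res.time_near_social_s = zt[f"near_cup_{social}"]
        res.time_near_nonsocial_s = zt[f"near_cup_{nonsocial}"]
        res.chamber_times_s = {c: zt[c] for c in CHAMBERS}
    return res


def preference_table(
    results: list[PreferenceResult],
    registry: AnimalRegistry,
) -> pd.DataFrame:
    """Long-format table for :func:`habsoc.cohort_stats.two_way_anova_lsd`.

    One row per included animal per stimulus with the near-cup dwell time;
    excluded animals contribute no rows.
    """
    animal_meta = {a.animal_id: a for a in registry.animals}
    rows = []
    for r in results:
        if not r.included:
            continue
        meta = animal_meta[r.animal]
        rows.append((r.animal, meta.genotype, meta.sex, "social",
                     r.time_near_social_s))
        rows.append((r.animal, meta.genotype, meta.sex, "nonsocial",
                     r.time_near_nonsocial_s))
    if not rows:
        raise ValueError("no included animals")
    return pd.DataFrame(rows, columns=["animal", "genotype", "sex",
                                       "stimulus", "value"])
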