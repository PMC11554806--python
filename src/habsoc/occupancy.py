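"""Reconstruct compartment visits from antenna reads; activity and budgets.

A completed tube crossing produces two reads: origin-side antenna first,
destination-side second.  The visit in the origin compartment ends at the
first read and the visit in the destination starts at the second read; the
gap between them is tube transit and belongs to no compartment.  Dropped
reads are repaired by documented rules and every repair is logged.

All intervals are half-open ``[start, end)``: a boundary instant belongs to
the later interval, so dwell time is never double-counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .apparatus import AnimalRegistry, Apparatus, ProtocolWindows

VISIT_COLUMNS = ("animal", "compartment", "start_s", "end_s")


@dataclass(frozen=True)
class Repair:
    """One deviation from the ideal two-reads-per-crossing pattern."""

    animal: str
    time_s: float
    kind: str  # "inserted_crossing" | "truncated_visit"
    detail: str


def empty_visits() -> pd.DataFrame:
    return pd.DataFrame({
        "animal": pd.Series(dtype=str),
        "compartment": pd.Series(dtype=int),
        "start_s": pd.Series(dtype=float),
        "end_s": pd.Series(dtype=float),
    })


def reconstruct_visits(
    events: pd.DataFrame,
    apparatus: Apparatus,
    registry: AnimalRegistry,
    *,
    session_start: float = 0.0,
    session_end: float | None = None,
) -> tuple[pd.DataFrame, list[Repair]]:
    """Turn antenna reads into per-animal compartment visit intervals.

    Each read places its animal at a known tube end, i.e. in a known
    compartment, at the read time.  Consecutive placements in the same
    compartment extend one visit; a placement change via the two antennas of
    one tube is a clean crossing (visit ends at the origin-side read, next
    visit starts at the destination-side read).  Anything else means dropped
    reads and is repaired:

    * placements in adjacent compartments not forming a clean crossing: the
      unique connecting tube is inserted and the ambiguous gap is split at
      its midpoint;
    * placements in non-adjacent compartments (two equal-length ring paths,
      no unique repair): the visit is truncated at the last consistent read
      and the gap left unassigned.

    The first visit starts at ``session_start``; the last open visit is
    closed at ``session_end`` (defaults to the last read time).  Animals in
    the registry with no reads yield no visits and a warning.

    Returns the visits table (sorted by animal, start) and the repair log.
    Reconstruction is deterministic: identical inputs give identical output.
    """
    if len(events):
        if events["time_s"].min() < session_start:
            raise ValueError("events before session start")
        if not events["time_s"].is_monotonic_increasing:
            raise ValueError("events must be sorted by time")
    if session_end is None:
        session_end = float(events["time_s"].max()) if len(events) else session_start

    tag_to_id = {a.tag: a.animal_id for a in registry.animals}
    repairs: list[Repair] = []
    rows: list[tuple[str, int, float, float]] = []

    events_by_tag = dict(tuple(events.groupby("tag", sort=False))) if len(events) else {}
    for animal in registry.animals:
        sub = events_by_tag.get(animal.tag)
        if sub is None or not len(sub):
            warnings.warn(f"animal {animal.animal_id}: no antenna events")
            continue
        rows.extend(
            _reconstruct_one(
                animal.animal_id,
                sub["time_s"].to_numpy(),
                sub["antenna"].to_numpy(),
                apparatus,
                session_start,
                session_end,
                repairs,
            )
        )

    visits = pd.DataFrame(rows, columns=list(VISIT_COLUMNS)) if rows else empty_visits()
    visits = visits.sort_values(["animal", "start_s"], ignore_index=True)
    return visits, repairs


def _reconstruct_one(
    animal: str,
    times: np.ndarray,
    antennas: np.ndarray,
    apparatus: Apparatus,
    session_start: float,
    session_end: float,
    repairs: list[Repair],
) -> list[tuple[str, int, float, float]]:
    # placements: (time, compartment, tube) for each read
    tubes = np.array([apparatus.antenna_map[int(a)][0] for a in antennas])
    comps = np.array([apparatus.antenna_compartment(int(a)) for a in antennas])

    out: list[tuple[str, int, float, float]] = []
    cur_comp = int(comps[0])
    cur_start = session_start
    last_t = float(times[0])
    last_tube = int(tubes[0])

    for t, comp, tube in zip(times[1:], comps[1:], tubes[1:]):
        t, comp, tube = float(t), int(comp), int(tube)
        if comp == cur_comp:
            last_t, last_tube = t, tube
            continue
        connecting = apparatus.tube_between(cur_comp, comp)
        if connecting is not None and connecting.id == last_tube == tube:
            # clean crossing: origin-side read at last_t, destination at t
            out.append((animal, cur_comp, cur_start, last_t))
            cur_comp, cur_start = comp, t
        elif connecting is not None:
            # adjacent, but one read of the connecting tube was dropped:
            # insert the unique tube path; whichever crossing endpoint was
            # observed is kept, the unobserved one takes the gap midpoint
            mid = 0.5 * (last_t + t)
            end = last_t if last_tube == connecting.id else mid
            start = t if tube == connecting.id else mid
            out.append((animal, cur_comp, cur_start, end))
            repairs.append(Repair(animal, mid, "inserted_crossing",
                                  f"{cur_comp}->{comp} via tube {connecting.id}"))
            cur_comp, cur_start = comp, start
        else:
            # non-adjacent jump: no unique shortest path on the ring;
            # truncate at the last consistent read, leave the gap unassigned
            out.append((animal, cur_comp, cur_start, last_t))
            repairs.append(Repair(animal, last_t, "truncated_visit",
                                  f"jump {cur_comp}->{comp}"))
            cur_comp, cur_start = comp, t
        last_t, last_tube = t, tube

    if session_end > cur_start:
        out.append((animal, cur_comp, cur_start, session_end))
    return [(a, c, s, e) for (a, c, s, e) in out if e > s]


def compute_activity(
    visits: pd.DataFrame,
    protocol: ProtocolWindows,
    *,
    animals: list[str] | None = None,
) -> pd.DataFrame:
    """Visits per animal per 12-h bin over the whole protocol.

    A visit is counted in the bin containing its start.  The first visit of
    the session (the one ongoing at t = 0) is not a completed transition and
    is not counted.  Animals with no counted visits get explicit zero rows.
    """
    edges = np.asarray(protocol.bin_edges_s())
    if len(visits) and visits["end_s"].max() > edges[-1] + 1e-9:
        raise ValueError("bins do not cover the protocol duration")
    if animals is None:
        animals = sorted(visits["animal"].unique())
    n_bins = protocol.n_bins
    counts = {a: np.zeros(n_bins, dtype=int) for a in animals}
    for animal, start in zip(visits["animal"], visits["start_s"]):
        if animal not in counts or start <= 0.0:
            continue  # ongoing-at-start visit is not a transition
        b = int(np.searchsorted(edges, start, side="right")) - 1
        if 0 <= b < n_bins:
            counts[animal][b] += 1
    rows = [(a, b, int(counts[a][b])) for a in animals for b in range(n_bins)]
    return pd.DataFrame(rows, columns=["animal", "bin", "visits"])


def _clipped_total(starts: np.ndarray, ends: np.ndarray, w0: float, w1: float) -> float:
    s = np.maximum(starts, w0)
    e = np.minimum(ends, w1)
    d = e - s
    return float(d[d > 0].sum())


def compute_time_budget(
    visits: pd.DataFrame,
    window: tuple[float, float],
    *,
    animal: str | None = None,
) -> np.ndarray:
    """Fractions of ``window`` spent in each compartment (t_1..t_4).

    Dwell times are clipped to the half-open window and normalized by its
    length, so each fraction lies in [0, 1] and the four sum to at most 1
    (tube transit belongs to no compartment).
    """
    w0, w1 = window
    if not w1 > w0:
        raise ValueError("window must have positive length")
    sub = visits if animal is None else visits[visits["animal"] == animal]
    out = np.zeros(4)
    for c in (1, 2, 3, 4):
        vc = sub[sub["compartment"] == c]
        out[c - 1] = _clipped_total(
            vc["start_s"].to_numpy(), vc["end_s"].to_numpy(), w0, w1
        ) / (w1 - w0)
    return out


def time_budgets(
    visits: pd.DataFrame,
    windows: list[tuple[float, float]],
    *,
    animals: list[str] | None = None,
) -> pd.DataFrame:
    """Tidy table of per-animal time budgets over several windows."""
    if animals is None:
        animals = sorted(visits["animal"].unique())
    rows = []
    for a in animals:
        sub = visits[visits["animal"] == a]
        for (w0, w1) in windows:
            t = compute_time_budget(sub, (w0, w1))
            rows.append((a, w0, w1, *t))
    return pd.DataFrame(
        rows, columns=["animal", "window_start_s", "window_end_s", "t1", "t2", "t3", "t4"]
    )
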