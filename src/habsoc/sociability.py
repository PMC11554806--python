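"""In-cohort sociability: pairwise co-dwelling vs. the independence null.

For a pair of animals *a*, *b* and an analysis window, let ``t_ac`` be the
fraction of the window animal *a* spends in compartment *c* and ``t_ab_c``
the fraction the pair spends in *c* simultaneously.  The in-cohort
sociability statistic is

    S = t_ab − (t_a1·t_b1 + t_a2·t_b2 + t_a3·t_b3 + t_a4·t_b4)

with ``t_ab = Σ_c t_ab_c``: time actually spent together minus the time the
pair would spend together if each explored the habitat independently.
S > 0 means the pair co-dwells more than chance; S < 0 means avoidance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .apparatus import AnimalRegistry, ProtocolWindows
from .occupancy import compute_time_budget

COMPARTMENTS = (1, 2, 3, 4)


@dataclass(frozen=True)
class CoDwellRecord:
    """Normalized pairwise co-dwelling over one window, per compartment."""

    animal_a: str
    animal_b: str
    window: tuple[float, float]
    t_c: np.ndarray  # shape (4,), co-dwell fraction per compartment

    @property
    def t_ab(self) -> float:
        return float(self.t_c.sum())


@dataclass(frozen=True)
class SociabilityRecord:
    animal_a: str
    animal_b: str
    window: tuple[float, float]
    t_ab: float
    s: float


def _interval_intersection_total(
    s1: np.ndarray, e1: np.ndarray, s2: np.ndarray, e2: np.ndarray
) -> float:
    """Total overlap length of two disjoint, sorted interval sets (two-pointer sweep)."""
    i = j = 0
    total = 0.0
    while i < len(s1) and j < len(s2):
        lo = max(s1[i], s2[j])
        hi = min(e1[i], e2[j])
        if hi > lo:
            total += hi - lo
        if e1[i] <= e2[j]:
            i += 1
        else:
            j += 1
    return total


def compute_codwell(
    visits_a: pd.DataFrame,
    visits_b: pd.DataFrame,
    window: tuple[float, float],
) -> CoDwellRecord:
    """Pairwise co-dwelling fractions by exact interval intersection.

    For each compartment the two animals' visit intervals are clipped to the
    half-open window and intersected with a sorted two-pointer sweep — no
    discretization.  Tube transit counts as "not together".
    """
    w0, w1 = window
    if not w1 > w0:
        raise ValueError("window must have positive length")
    t_c = np.zeros(4)
    for c in COMPARTMENTS:
        va = visits_a[visits_a["compartment"] == c]
        vb = visits_b[visits_b["compartment"] == c]
        if not len(va) or not len(vb):
            continue
        s1 = np.maximum(va["start_s"].to_numpy(), w0)
        e1 = np.minimum(va["end_s"].to_numpy(), w1)
        s2 = np.maximum(vb["start_s"].to_numpy(), w0)
        e2 = np.minimum(vb["end_s"].to_numpy(), w1)
        t_c[c - 1] = _interval_intersection_total(s1, e1, s2, e2) / (w1 - w0)
    a = str(visits_a["animal"].iloc[0]) if len(visits_a) else "a"
    b = str(visits_b["animal"].iloc[0]) if len(visits_b) else "b"
    return CoDwellRecord(a, b, window, t_c)


def compute_sociability(
    budget_a: np.ndarray,
    budget_b: np.ndarray,
    codwell: CoDwellRecord,
) -> SociabilityRecord:
    """S = t_ab − Σ_c t_ac·t_bc, exact arithmetic on the stored fractions.

    All three inputs must refer to the same window.  The record is symmetric
    in the pair; bounds ``t_ab ≤ Σ_c min(t_ac, t_bc)`` and ``S ≤ t_ab`` are
    asserted on every record.
    """
    t_ab = codwell.t_ab
    expected = float(np.dot(budget_a, budget_b))
    s = t_ab - expected
    bound = float(np.minimum(budget_a, budget_b).sum())
    if t_ab > bound + 1e-9:
        raise ValueError(
            f"co-dwell {t_ab:.6f} exceeds per-compartment bound {bound:.6f}; "
            "budgets and co-dwell were not computed over the same window"
        )
    return SociabilityRecord(codwell.animal_a, codwell.animal_b,
                             codwell.window, t_ab, s)


def pairwise_sociability(
    visits: pd.DataFrame,
    registry: AnimalRegistry,
    protocol: ProtocolWindows,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sociability for every unordered pair over the testing-phase bins.

    The adaptation phase is excluded: only the 12-h bins tiling the testing
    phase enter.  Returns ``(per_bin, per_pair)``: per-bin records for all
    n(n−1)/2 pairs, and per-pair means across bins (the values used for
    cohort histograms and tests).  Pairs with a member lacking visits are
    skipped with a warning.
    """
    windows = protocol.testing_windows_s()
    ids = registry.animal_ids
    by_animal = {a: visits[visits["animal"] == a] for a in ids}
    rows = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            va, vb = by_animal[a], by_animal[b]
            if not len(va) or not len(vb):
                warnings.warn(f"pair ({a}, {b}) skipped: missing visits")
                continue
            for (w0, w1) in windows:
                ta = compute_time_budget(va, (w0, w1))
                tb = compute_time_budget(vb, (w0, w1))
                rec = compute_sociability(ta, tb, compute_codwell(va, vb, (w0, w1)))
                rows.append((a, b, w0, w1, rec.t_ab, rec.s))
    per_bin = pd.DataFrame(
        rows, columns=["animal_a", "animal_b", "window_start_s",
                       "window_end_s", "t_ab", "s"]
    )
    per_pair = (
        per_bin.groupby(["animal_a", "animal_b"], as_index=False)[["t_ab", "s"]]
        .mean()
        if len(per_bin) else per_bin[["animal_a", "animal_b", "t_ab", "s"]]
    )
    return per_bin, per_pair
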