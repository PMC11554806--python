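"""Habitat topology, animal registry, and protocol timing.

The habitat is four housing compartments joined in a ring by tube-shaped
passages.  Each tube carries a pair of RFID antennas, one at each end, so a
completed crossing produces an origin-side read followed by a
destination-side read.  These types describe that static structure; the
event-level analysis lives in :mod:`habsoc.io` and :mod:`habsoc.occupancy`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

HOUR = 3600.0

GENOTYPES = ("WT", "HET", "MUT")
SEXES = ("M", "F")


class ApparatusError(ValueError):
    """Raised when an apparatus description violates the ring topology."""


@dataclass(frozen=True)
class Tube:
    """A passage joining two compartments; ``left``/``right`` name its ends."""

    id: int
    left: int
    right: int


@dataclass(frozen=True)
class Apparatus:
    """Four-compartment ring habitat with paired tube antennas.

    Parameters
    ----------
    compartments
        Compartment identifiers (canonically ``(1, 2, 3, 4)``).
    tubes
        Passages; the default ring joins 1–2, 2–3, 3–4, 4–1.
    antenna_map
        ``antenna id -> (tube id, side)`` with side in ``{"left", "right"}``.
    """

    compartments: tuple[int, ...] = (1, 2, 3, 4)
    tubes: tuple[Tube, ...] = (
        Tube(1, 1, 2),
        Tube(2, 2, 3),
        Tube(3, 3, 4),
        Tube(4, 4, 1),
    )
    antenna_map: Mapping[int, tuple[int, str]] = field(
        default_factory=lambda: {
            1: (1, "left"), 2: (1, "right"),
            3: (2, "left"), 4: (2, "right"),
            5: (3, "left"), 6: (3, "right"),
            7: (4, "left"), 8: (4, "right"),
        }
    )

    def __post_init__(self) -> None:
        self.validate()

    # -- structure queries -------------------------------------------------
    def tube_by_id(self, tube_id: int) -> Tube:
        for t in self.tubes:
            if t.id == tube_id:
                return t
        raise ApparatusError(f"unknown tube id {tube_id}")

    def antenna_compartment(self, antenna: int) -> int:
        """Compartment at the end of the tube where this antenna sits."""
        tube_id, side = self.antenna_map[antenna]
        tube = self.tube_by_id(tube_id)
        return tube.left if side == "left" else tube.right

    def antenna_for(self, tube_id: int, compartment: int) -> int:
        """Antenna on the ``compartment`` side of tube ``tube_id``."""
        tube = self.tube_by_id(tube_id)
        side = "left" if tube.left == compartment else "right"
        if (tube.left if side == "left" else tube.right) != compartment:
            raise ApparatusError(f"tube {tube_id} does not touch {compartment}")
        for antenna, (tid, s) in self.antenna_map.items():
            if tid == tube_id and s == side:
                return antenna
        raise ApparatusError(f"no antenna on side {side} of tube {tube_id}")

    def tube_between(self, a: int, b: int) -> Tube | None:
        for t in self.tubes:
            if {t.left, t.right} == {a, b}:
                return t
        return None

    def neighbors(self, compartment: int) -> tuple[int, ...]:
        out = []
        for t in self.tubes:
            if t.left == compartment:
                out.append(t.right)
            elif t.right == compartment:
                out.append(t.left)
        return tuple(sorted(out))

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        comp = set(self.compartments)
        for t in self.tubes:
            if t.left not in comp or t.right not in comp:
                raise ApparatusError(f"tube {t.id} touches unknown compartment")
        for c in self.compartments:
            deg = sum(c in (t.left, t.right) for t in self.tubes)
            if deg != 2:
                raise ApparatusError(
                    f"compartment {c} joins {deg} tubes; ring topology needs 2"
                )
        per_tube: dict[int, set[str]] = {}
        for antenna, (tube_id, side) in self.antenna_map.items():
            if side not in ("left", "right"):
                raise ApparatusError(f"antenna {antenna}: bad side {side!r}")
            self.tube_by_id(tube_id)
            sides = per_tube.setdefault(tube_id, set())
            if side in sides:
                raise ApparatusError(f"tube {tube_id} has two {side} antennas")
            sides.add(side)
        for t in self.tubes:
            if per_tube.get(t.id) != {"left", "right"}:
                raise ApparatusError(f"tube {t.id} lacks a full antenna pair")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "compartments": list(self.compartments),
            "tubes": [[t.id, t.left, t.right] for t in self.tubes],
            "antennas": {str(a): [tid, side] for a, (tid, side) in self.antenna_map.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Apparatus":
        return cls(
            compartments=tuple(d["compartments"]),
            tubes=tuple(Tube(*row) for row in d["tubes"]),
            antenna_map={int(a): (v[0], v[1]) for a, v in d["antennas"].items()},
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Apparatus":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class Animal:
    animal_id: str
    tag: str
    genotype: str = "WT"
    sex: str = "M"
    cohort: str = "cohort0"

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}")


class AnimalRegistry:
    """Maps RFID tag codes to animals (id, genotype, sex, cohort)."""

    def __init__(self, animals: Iterable[Animal]):
        self._by_tag: dict[str, Animal] = {}
        ids: set[tuple[str, str]] = set()
        for a in animals:
            if a.tag in self._by_tag:
                raise ValueError(f"duplicate tag {a.tag!r}")
            key = (a.cohort, a.animal_id)
            if key in ids:
                raise ValueError(f"duplicate animal id {a.animal_id!r} in {a.cohort!r}")
            ids.add(key)
            self._by_tag[a.tag] = a

    def __len__(self) -> int:
        return len(self._by_tag)

    def __contains__(self, tag: str) -> bool:
        return tag in self._by_tag

    def lookup(self, tag: str) -> Animal:
        return self._by_tag[tag]

    @property
    def animals(self) -> list[Animal]:
        return sorted(self._by_tag.values(), key=lambda a: (a.cohort, a.animal_id))

    @property
    def animal_ids(self) -> list[str]:
        return [a.animal_id for a in self.animals]

    def genotype_of(self, animal_id: str) -> str:
        for a in self.animals:
            if a.animal_id == animal_id:
                return a.genotype
        raise KeyError(animal_id)

    def to_json(self, path: str | Path) -> None:
        rows = [
            {"animal_id": a.animal_id, "tag": a.tag, "genotype": a.genotype,
             "sex": a.sex, "cohort": a.cohort}
            for a in self.animals
        ]
        Path(path).write_text(json.dumps(rows, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "AnimalRegistry":
        rows = json.loads(Path(path).read_text())
        return cls(Animal(**row) for row in rows)


@dataclass(frozen=True)
class ProtocolWindows:
    """Session phases and binning for the 84-h habitat protocol.

    The protocol is an adaptation phase (first 24 h) followed by the
    sociability testing phase (next 48 h); activity is binned in 12-h bins
    over the whole session.  Times are session-relative seconds; the
    wall-clock dark-phase onset is metadata used for phase labeling only.
    """

    adaptation_h: float = 24.0
    testing_h: float = 48.0
    bin_h: float = 12.0
    duration_h: float = 84.0
    dark_onset_h: float = 0.0  # hours after session start when dark begins

    def __post_init__(self) -> None:
        n = self.testing_h / self.bin_h
        if abs(n - round(n)) > 1e-9:
            raise ValueError("testing phase must be a whole number of bins")
        if self.duration_h < self.adaptation_h + self.testing_h:
            raise ValueError("protocol shorter than adaptation + testing")

    @property
    def duration_s(self) -> float:
        return self.duration_h * HOUR

    @property
    def n_bins(self) -> int:
        """Number of 12-h activity bins covering the full protocol."""
        import math

        return math.ceil(self.duration_h / self.bin_h - 1e-9)

    def bin_edges_s(self) -> list[float]:
        return [i * self.bin_h * HOUR for i in range(self.n_bins + 1)]

    def testing_windows_s(self) -> list[tuple[float, float]]:
        """Half-open 12-h windows tiling the testing phase, in seconds."""
        t0 = self.adaptation_h * HOUR
        n = int(round(self.testing_h / self.bin_h))
        w = self.bin_h * HOUR
        return [(t0 + i * w, t0 + (i + 1) * w) for i in range(n)]

    def testing_span_s(self) -> tuple[float, float]:
        t0 = self.adaptation_h * HOUR
        return (t0, t0 + self.testing_h * HOUR)

    def phase_at(self, t_s: float) -> str:
        """``"dark"`` or ``"light"``, alternating every 12 h from dark onset."""
        h = t_s / HOUR - self.dark_onset_h
        return "dark" if int(h // 12.0) % 2 == 0 else "light"
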