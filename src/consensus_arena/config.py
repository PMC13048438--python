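"""Trial configuration: arena geometry, candidate sites, kinematics, conditions.

Coordinate conventions used throughout the package: arena-centred Cartesian
coordinates in meters, x to the right and y up; time in seconds from trial
start; analysis bins are half-open ``[t, t+1)`` seconds.

The standard arena is a 150 m x 150 m square (half-extent 75 m) with four
circular candidate sites centred at (+/-40, +/-40).  Three sites share a
radius of 12 m; the correct (largest) site has radius 13, 14 or 15 m for the
hard, medium and easy difficulty levels respectively.  Avatars move at a
fixed forward speed of 8 m/s and rotate at pi rad/s, and a trial lasts at
most 100 s.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

SITE_LABELS = ("A", "B", "C", "D")
CONDITIONS = ("global", "local", "informed_minority")
DIFFICULTIES = ("easy", "medium", "hard")

#: correct-site radius (m) per difficulty level; incorrect sites are 12 m.
CORRECT_RADIUS = {"easy": 15.0, "medium": 14.0, "hard": 13.0}
INCORRECT_RADIUS = 12.0

#: standard site centres, in label order.
SITE_CENTERS = {
    "A": (-40.0, -40.0),
    "B": (-40.0, 40.0),
    "C": (40.0, -40.0),
    "D": (40.0, 40.0),
}


class ConfigError(ValueError):
    """Raised when a trial configuration violates its invariants."""


@dataclass(frozen=True)
class Site:
    """A circular candidate site."""

    id: str
    center: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.id not in SITE_LABELS:
            raise ConfigError(f"site id must be one of {SITE_LABELS}, got {self.id!r}")
        if not self.radius > 0:
            raise ConfigError(f"site {self.id}: radius must be > 0, got {self.radius}")

    def contains(self, x: float, y: float) -> bool:
        dx, dy = x - self.center[0], y - self.center[1]
        return dx * dx + dy * dy < self.radius * self.radius


@dataclass
class TrialConfig:
    """Geometry, condition and kinematic constants for one trial (or cell).

    Parameters
    ----------
    condition
        ``"global"`` (site sizes visible from anywhere), ``"local"`` (sizes
        visible only within ``local_visibility_radius`` of a site centre) or
        ``"informed_minority"`` (global visibility plus two participants told
        the correct site).
    difficulty
        ``"easy"``, ``"medium"`` or ``"hard"``; controls the correct site's
        radius via :data:`CORRECT_RADIUS` when using the standard geometry.
    """

    condition: str = "global"
    difficulty: str = "easy"
    correct_site: str = "D"
    n_participants: int = 8
    sites: list[Site] = field(default_factory=list)
    informed_ids: list[str] = field(default_factory=list)
    arena_half_extent: float = 75.0
    speed: float = 8.0
    rot_rate: float = math.pi
    time_limit: float = 100.0
    local_visibility_radius: float = 25.0
    start_radius: float = 20.0
    sample_rate: float = 10.0

    def __post_init__(self) -> None:
        if not self.sites:
            self.sites = standard_sites(self.difficulty, self.correct_site)
        if self.condition == "informed_minority" and not self.informed_ids:
            self.informed_ids = [participant_label(0), participant_label(1)]
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if self.condition not in CONDITIONS:
            raise ConfigError(f"unknown condition {self.condition!r}")
        if self.difficulty not in DIFFICULTIES:
            raise ConfigError(f"unknown difficulty {self.difficulty!r}")
        if not 7 <= self.n_participants <= 10:
            raise ConfigError(
                f"n_participants must be in 7..10, got {self.n_participants}"
            )
        labels = [s.id for s in self.sites]
        if sorted(labels) != list(SITE_LABELS):
            raise ConfigError(f"need exactly sites {SITE_LABELS}, got {labels}")
        if self.correct_site not in labels:
            raise ConfigError(f"correct_site {self.correct_site!r} not among sites")
        centers = {s.center for s in self.sites}
        if len(centers) != len(self.sites):
            raise ConfigError("site centers must be pairwise distinct")
        for s in self.sites:
            if max(abs(s.center[0]), abs(s.center[1])) > self.arena_half_extent:
                raise ConfigError(f"site {s.id} lies outside the arena")
        radii = self.radii()
        for lab in labels:
            if lab != self.correct_site and radii[lab] >= radii[self.correct_site]:
                raise ConfigError(
                    "correct site must be strictly largest "
                    f"({lab}={radii[lab]} >= {self.correct_site}="
                    f"{radii[self.correct_site]})"
                )
        if self.condition == "informed_minority":
            if len(self.informed_ids) != 2:
                raise ConfigError("informed_minority requires exactly 2 informed ids")
        elif self.informed_ids:
            raise ConfigError("informed_ids only allowed in informed_minority")
        known = set(self.participant_ids())
        if not set(self.informed_ids) <= known:
            raise ConfigError("informed_ids must be participant labels")
        for name, val in [
            ("speed", self.speed),
            ("rot_rate", self.rot_rate),
            ("time_limit", self.time_limit),
            ("sample_rate", self.sample_rate),
            ("local_visibility_radius", self.local_visibility_radius),
            ("start_radius", self.start_radius),
        ]:
            if not val > 0:
                raise ConfigError(f"{name} must be > 0, got {val}")

    # -- convenience --------------------------------------------------------

    def participant_ids(self) -> list[str]:
        return [participant_label(i) for i in range(self.n_participants)]

    def site(self, label: str) -> Site:
        for s in self.sites:
            if s.id == label:
                return s
        raise KeyError(label)

    def radii(self) -> dict[str, float]:
        return {s.id: s.radius for s in self.sites}

    def site_centers(self) -> dict[str, tuple[float, float]]:
        return {s.id: s.center for s in self.sites}

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sites"] = [
            {"id": s.id, "center": list(s.center), "radius": s.radius}
            for s in self.sites
        ]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "TrialConfig":
        d = dict(d)
        if "sites" in d and d["sites"]:
            d["sites"] = [
                Site(s["id"], tuple(s["center"]), float(s["radius"]))
                for s in d["sites"]
            ]
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "TrialConfig":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)


def participant_label(i: int) -> str:
    return f"p{i:02d}"


def standard_sites(difficulty: str, correct_site: str = "D") -> list[Site]:
    """The four standard sites with the correct radius set by difficulty."""
    if difficulty not in CORRECT_RADIUS:
        raise ConfigError(f"unknown difficulty {difficulty!r}")
    return [
        Site(
            lab,
            SITE_CENTERS[lab],
            CORRECT_RADIUS[difficulty] if lab == correct_site else INCORRECT_RADIUS,
        )
        for lab in SITE_LABELS
    ]


def relative_radius_excess(difficulty: str) -> float:
    """Fractional size advantage of the correct site over the others.

    E.g. ``0.25`` for easy (15 m vs 12 m) and ``0.0833...`` for hard
    (13 m vs 12 m).
    """
    return (CORRECT_RADIUS[difficulty] - INCORRECT_RADIUS) / INCORRECT_RADIUS


def design_cells(
    conditions: Sequence[str] = CONDITIONS,
    difficulties: Sequence[str] = DIFFICULTIES,
    n_participants: int = 8,
    **kwargs,
) -> list[TrialConfig]:
    """The full condition x difficulty factorial design as TrialConfigs."""
    return [
        TrialConfig(
            condition=c, difficulty=d, n_participants=n_participants, **kwargs
        )
        for c in conditions
        for d in difficulties
    ]
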