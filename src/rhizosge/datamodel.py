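"""Domain types and experimental design for two-strain co-inoculation experiments.

The experiment crosses a panel of rhizobium strains on a single legume host
genotype in a randomized complete block design.  Each strain exists as two
isogenic fluorescently marked variants (red / green) so that the two strains
sharing a pot can be told apart at the nodule.  Within every block the design
holds:

* one one-strain pot per (strain, marker) combination,
* two pots per unordered strain pair, reciprocally marked (A-red + B-green,
  and A-green + B-red),
* a fixed number of uninoculated control pots.

Nodule occupancy is scored per strain as ``singles + 0.5 * mixed``: a nodule
founded by one strain counts 1 for that strain, a mixed-colour nodule counts
0.5 for each co-occupant.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

MARKERS = ("red", "green")

TREATMENT_CONTROL = "control"
TREATMENT_ONE_STRAIN = "one_strain"
TREATMENT_TWO_STRAIN = "two_strain"


class DesignError(ValueError):
    """Raised when a requested design is impossible or inconsistent."""


class ConsistencyError(ValueError):
    """Raised when linked records disagree (e.g. tally names an uninoculated strain)."""


@dataclass(frozen=True)
class StrainLabel:
    """One fluorescently marked strain variant."""

    strain_id: str
    marker: str

    def __post_init__(self) -> None:
        if self.marker not in MARKERS:
            raise DesignError(f"unknown marker {self.marker!r}; expected one of {MARKERS}")


@dataclass(frozen=True)
class PlantUnit:
    """A single pot: block, treatment, inoculum labels and the host phenotype."""

    pot_id: str
    block: int
    treatment: str
    labels: tuple[StrainLabel, ...] = ()
    shoot_mass: Optional[float] = None

    def __post_init__(self) -> None:
        n = len(self.labels)
        expected = {TREATMENT_CONTROL: 0, TREATMENT_ONE_STRAIN: 1, TREATMENT_TWO_STRAIN: 2}
        if self.treatment not in expected:
            raise DesignError(f"unknown treatment {self.treatment!r}")
        if n != expected[self.treatment]:
            raise DesignError(
                f"pot {self.pot_id}: treatment {self.treatment} requires "
                f"{expected[self.treatment]} labels, got {n}"
            )
        if n == 2:
            a, b = self.labels
            if a.strain_id == b.strain_id:
                raise DesignError(f"pot {self.pot_id}: two-strain pot with duplicated strain")
            if a.marker == b.marker:
                raise DesignError(f"pot {self.pot_id}: two-strain pot with duplicated marker")
        if self.shoot_mass is not None and self.shoot_mass < 0:
            raise DesignError(f"pot {self.pot_id}: negative shoot mass")

    @property
    def strain_ids(self) -> tuple[str, ...]:
        return tuple(lab.strain_id for lab in self.labels)

    def marker_of(self, strain_id: str) -> str:
        for lab in self.labels:
            if lab.strain_id == strain_id:
                return lab.marker
        raise ConsistencyError(f"strain {strain_id} not inoculated in pot {self.pot_id}")


@dataclass
class NoduleTally:
    """Per-pot nodule colour counts: single-colour counts per strain, plus mixed."""

    pot_id: str
    singles: dict[str, int] = field(default_factory=dict)
    mixed: int = 0

    def __post_init__(self) -> None:
        if self.mixed < 0 or any(v < 0 for v in self.singles.values()):
            raise ConsistencyError(f"pot {self.pot_id}: negative nodule count")


@dataclass
class StrainPotObservation:
    """Dyadic record: one inoculated strain's nodulation outcome in one pot.

    ``nodule_score`` is the half-integer occupancy score; ``nodule_proportion``
    is the strain's share of the pot total, ``None`` when the pot set no nodules.
    """

    pot_id: str
    focal_strain: str
    competitor_strain: Optional[str]
    focal_marker: str
    nodule_score: float
    nodule_proportion: Optional[float]


@dataclass
class NoduleCFU:
    """Colony-forming-unit counts for one dissected nodule, per occupying strain."""

    pot_id: str
    nodule_id: str
    nodule_class: str  # "single_colour" | "mixed_colour"
    cfu: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.nodule_class not in ("single_colour", "mixed_colour"):
            raise ConsistencyError(f"unknown nodule class {self.nodule_class!r}")
        if any(v < 0 for v in self.cfu.values()):
            raise ConsistencyError(f"nodule {self.nodule_id}: negative CFU")


def strain_names(n_strains: int) -> list[str]:
    """Default strain registry: S1..Sn (zero-padded for lexicographic order)."""
    width = len(str(n_strains))
    return [f"S{i + 1:0{width}d}" for i in range(n_strains)]


def generate_design(
    n_strains: int,
    n_blocks: int,
    n_controls_per_block: int = 2,
    strains: Optional[Sequence[str]] = None,
) -> list[PlantUnit]:
    """Generate the full randomized-complete-block co-inoculation design.

    Per block: one one-strain pot per (strain, marker) combination, two
    reciprocally marked pots per unordered strain pair, and
    ``n_controls_per_block`` uninoculated controls.  Output order is
    deterministic (blocks, then controls / one-strain / pairs).

    With 8 strains, 8 blocks and 2 controls per block this yields
    8 * (16 + 56 + 2) = 592 pots and 28 distinct strain pairs.
    """
    if n_strains < 2:
        raise DesignError("need at least 2 strains to form pairs")
    if n_blocks < 1:
        raise DesignError("need at least 1 block")
    if n_controls_per_block < 0:
        raise DesignError("negative control count")
    if strains is None:
        strains = strain_names(n_strains)
    elif len(strains) != n_strains:
        raise DesignError("strain registry length disagrees with n_strains")

    units: list[PlantUnit] = []
    counter = itertools.count(1)
    for block in range(1, n_blocks + 1):
        for _ in range(n_controls_per_block):
            units.append(
                PlantUnit(pot_id=f"P{next(counter):04d}", block=block, treatment=TREATMENT_CONTROL)
            )
        for strain in strains:
            for marker in MARKERS:
                units.append(
                    PlantUnit(
                        pot_id=f"P{next(counter):04d}",
                        block=block,
                        treatment=TREATMENT_ONE_STRAIN,
                        labels=(StrainLabel(strain, marker),),
                    )
                )
        for a, b in itertools.combinations(strains, 2):
            for ma, mb in ((MARKERS[0], MARKERS[1]), (MARKERS[1], MARKERS[0])):
                units.append(
                    PlantUnit(
                        pot_id=f"P{next(counter):04d}",
                        block=block,
                        treatment=TREATMENT_TWO_STRAIN,
                        labels=(StrainLabel(a, ma), StrainLabel(b, mb)),
                    )
                )
    return units


def tally_to_observations(tally: NoduleTally, pot: PlantUnit) -> list[StrainPotObservation]:
    """Convert a pot's nodule colour tally into per-strain occupancy records.

    Each strain scores ``singles + 0.5 * mixed``; the proportion is the score
    over the pot total, undefined (None) when the pot formed no nodules.
    """
    inoculated = set(pot.strain_ids)
    extra = set(tally.singles) - inoculated
    if extra:
        raise ConsistencyError(
            f"pot {pot.pot_id}: tally names strain(s) {sorted(extra)} not inoculated"
        )
    if pot.treatment == TREATMENT_CONTROL:
        if tally.singles or tally.mixed:
            raise ConsistencyError(f"pot {pot.pot_id}: nodule tally on an uninoculated control")
        return []
    if tally.mixed and len(inoculated) < 2:
        raise ConsistencyError(f"pot {pot.pot_id}: mixed-colour nodules in a one-strain pot")

    scores = {s: tally.singles.get(s, 0) + 0.5 * tally.mixed for s in pot.strain_ids}
    total = sum(scores.values())
    obs = []
    for strain in pot.strain_ids:
        others = [s for s in pot.strain_ids if s != strain]
        obs.append(
            StrainPotObservation(
                pot_id=pot.pot_id,
                focal_strain=strain,
                competitor_strain=others[0] if others else None,
                focal_marker=pot.marker_of(strain),
                nodule_score=scores[strain],
                nodule_proportion=(scores[strain] / total) if total > 0 else None,
            )
        )
    return obs


def observations_for(
    units: Iterable[PlantUnit], tallies: Iterable[NoduleTally]
) -> list[StrainPotObservation]:
    """Vector form of :func:`tally_to_observations` over matched pots/tallies."""
    by_pot = {u.pot_id: u for u in units}
    out: list[StrainPotObservation] = []
    for tally in tallies:
        if tally.pot_id not in by_pot:
            raise ConsistencyError(f"tally references unknown pot {tally.pot_id}")
        out.extend(tally_to_observations(tally, by_pot[tally.pot_id]))
    return out
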