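"""Design generation and nodule-tally arithmetic."""

import itertools
from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhizosge.datamodel import (
    ConsistencyError,
    DesignError,
    NoduleTally,
    PlantUnit,
    StrainLabel,
    generate_design,
    tally_to_observations,
)


@pytest.mark.parametrize("n_strains,n_blocks,n_controls", [
    (2, 1, 2), (3, 2, 0), (5, 4, 1), (8, 8, 2), (10, 3, 3),
])
def test_design_count_formula(n_strains, n_blocks, n_controls):
    """Total pots = B * (2S + 2*C(S,2) + controls)."""
    units = generate_design(n_strains, n_blocks, n_controls)
    expected = n_blocks * (2 * n_strains + n_strains * (n_strains - 1) + n_controls)
    assert len(units) == expected
    assert len({u.pot_id for u in units}) == len(units)


def test_design_paper_scale():
    """8 strains x 8 blocks x 2 controls: 592 pots, 28 pairs, 74 per block."""
    units = generate_design(8, 8, 2)
    assert len(units) == 592
    pairs = {frozenset(u.strain_ids) for u in units if u.treatment == "two_strain"}
    assert len(pairs) == 28
    assert set(Counter(u.block for u in units).values()) == {74}


def test_design_reciprocal_markers_and_balance():
    units = generate_design(4, 2, 0)
    # each unordered pair appears twice per block with swapped markers
    for block in (1, 2):
        two = [u for u in units if u.block == block and u.treatment == "two_strain"]
        by_pair = {}
        for u in two:
            by_pair.setdefault(frozenset(u.strain_ids), []).append(
                tuple(sorted((lab.strain_id, lab.marker) for lab in u.labels)))
        for pair, markings in by_pair.items():
            assert len(markings) == 2 and markings[0] != markings[1]
        # every strain appears equally often per block
        focal_counts = Counter(s for u in two for s in u.strain_ids)
        assert len(set(focal_counts.values())) == 1


def test_design_small_example():
    """2 strains, 1 block, 2 controls: 4 one-strain + 2 pair pots + 2 controls."""
    units = generate_design(2, 1, 2)
    assert len(units) == 8
    assert Counter(u.treatment for u in units) == {
        "control": 2, "one_strain": 4, "two_strain": 2}


def test_design_errors():
    with pytest.raises(DesignError):
        generate_design(1, 4)
    with pytest.raises(DesignError):
        generate_design(4, 0)
    with pytest.raises(DesignError):
        generate_design(3, 2, strains=["a", "b"])


def _two_strain_pot(**kw):
    return PlantUnit(
        pot_id=kw.get("pot_id", "P1"), block=1, treatment="two_strain",
        labels=(StrainLabel("A", "red"), StrainLabel("B", "green")))


def test_plant_unit_invariants():
    with pytest.raises(DesignError):
        PlantUnit("P1", 1, "control", labels=(StrainLabel("A", "red"),))
    with pytest.raises(DesignError):
        PlantUnit("P1", 1, "two_strain",
                  labels=(StrainLabel("A", "red"), StrainLabel("B", "red")))
    with pytest.raises(DesignError):
        PlantUnit("P1", 1, "two_strain",
                  labels=(StrainLabel("A", "red"), StrainLabel("A", "green")))


@pytest.mark.parametrize("singles_a,singles_b,mixed,score_a,prop_a", [
    (3, 2, 1, 3.5, 3.5 / 6.0),   # mixed nodules split 0.5 / 0.5
    (0, 0, 0, 0.0, None),        # empty pot: proportion undefined
    (0, 0, 4, 2.0, 0.5),         # mixed-only pot splits evenly
])
def test_tally_scoring(singles_a, singles_b, mixed, score_a, prop_a):
    pot = _two_strain_pot()
    tally = NoduleTally("P1", {"A": singles_a, "B": singles_b}, mixed)
    obs = {o.focal_strain: o for o in tally_to_observations(tally, pot)}
    assert obs["A"].nodule_score == pytest.approx(score_a)
    if prop_a is None:
        assert obs["A"].nodule_proportion is None
        assert obs["B"].nodule_proportion is None
    else:
        assert obs["A"].nodule_proportion == pytest.approx(prop_a)
        assert obs["A"].nodule_proportion + obs["B"].nodule_proportion == pytest.approx(1.0)
    assert obs["A"].competitor_strain == "B"
    assert obs["A"].focal_marker == "red"


def test_tally_unknown_strain_rejected():
    with pytest.raises(ConsistencyError):
        tally_to_observations(NoduleTally("P1", {"C": 1}), _two_strain_pot())


@given(a=st.integers(0, 50), b=st.integers(0, 50), m=st.integers(0, 50))
@settings(max_examples=100, deadline=None)
def test_two_strain_scores_partition_total(a, b, m):
    """Scores sum to singles + mixed; proportions sum to exactly 1 when defined."""
    obs = tally_to_observations(NoduleTally("P1", {"A": a, "B": b}, m), _two_strain_pot())
    total = sum(o.nodule_score for o in obs)
    assert total == pytest.approx(a + b + m)
    props = [o.nodule_proportion for o in obs]
    if total > 0:
        assert sum(props) == pytest.approx(1.0, abs=1e-12)
    else:
        assert props == [None, None]
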