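"""Generate the co-inoculation design and score a nodule tally.

The design crosses 8 strains in all 28 pairs (reciprocally marked), plus
16 one-strain pots and 2 uninoculated controls per block, over 8 blocks.
"""

from collections import Counter

from rhizosge import generate_design, tally_to_observations
from rhizosge.datamodel import NoduleTally, PlantUnit, StrainLabel

units = generate_design(n_strains=8, n_blocks=8, n_controls_per_block=2)
print(f"total pots: {len(units)}")                  # 592
print(f"treatments: {dict(Counter(u.treatment for u in units))}")
pairs = {frozenset(u.strain_ids) for u in units if u.treatment == "two_strain"}
print(f"distinct strain pairs: {len(pairs)}")       # 28

# a two-strain pot with 3 red-only, 2 green-only and 1 mixed-colour nodule:
pot = PlantUnit("demo", 1, "two_strain",
                (StrainLabel("S1", "red"), StrainLabel("S2", "green")))
tally = NoduleTally("demo", {"S1": 3, "S2": 2}, mixed=1)
for obs in tally_to_observations(tally, pot):
    print(f"{obs.focal_strain}: score {obs.nodule_score} "
          f"(singles + half the mixed nodules), share {obs.nodule_proportion:.3f}")
# the two shares always sum to 1: each mixed nodule counts 0.5 for each strain
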