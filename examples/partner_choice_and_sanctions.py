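"""Partner-choice and sanctions regressions on strain genotypic means.

Each strain is summarized by its mean benefit (one-strain shoot mass) and its
mean nodulation / CFU outcomes; host discrimination appears as a positive
slope of success on benefit, tested with F(1, n_strains - 2).
"""

from rhizosge import SimulationConfig, discrimination_report, simulate_experiment

ds = simulate_experiment(SimulationConfig(seed=11))
report = discrimination_report(ds.data)
for name, r in report.results.items():
    print(f"{name:32s} slope {r.slope:10.3g}  F(1,{r.df2}) = {r.f_stat:7.2f}  "
          f"p = {r.p_value:.4g}")
# positive nodule_number / nodule_proportion slopes: partner choice (better
# strains found more nodules, alone and in competition); positive sanctions
# slopes: better strains also proliferate more inside nodules.
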