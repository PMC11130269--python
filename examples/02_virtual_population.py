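"""Simulate a virtual population and summarize its ventilation band.

Samples 50 virtual subjects (independent log-normal variation around the
shipped stand-in kinetic parameters), runs the rescue scenario for each,
and prints the population median and 95% band of fractional minute
ventilation at selected times.
"""

import numpy as np

from naloxsim import DosingScenario, SimConfig, simulate_subject
from naloxsim.evaluation import population_percentiles
from naloxsim.population import ParameterDistributionConfig, sample_population

scenario = DosingScenario(0.11, 1, 4.0, 0.25, 3.0)
config = SimConfig(output_step=60.0, rtol=1e-6, atol=1e-9)

population = sample_population(ParameterDistributionConfig(size=50, seed=7))
timecourses = [simulate_subject(s, scenario, config) for s in population]
summary = population_percentiles(timecourses)

print("time(min)  p2.5   median  p97.5")
for minute in (0, 5, 15, 30, 60):
    i = np.searchsorted(summary.times, minute * 60)
    print(f"{minute:8d}  {summary.p2_5[i]:.3f}  {summary.median[i]:.3f}"
          f"   {summary.p97_5[i]:.3f}")

# The band is tight at baseline, widest around the ventilation nadir where
# inter-subject kinetic variability matters most, and narrows again as
# naloxone rescue pulls the population back toward baseline.
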