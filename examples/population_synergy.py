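"""Monte Carlo population synergy of LY30 + TRAIL.

Simulates cell populations (normally distributed initial protein
levels, CV 0.4) for each single treatment and the combination, then
quantifies synergy as the excess of combination killing over the
additive expectation (the capped sum of the single-treatment death
fractions).  The study conditions use 10 000 cells; this example uses
300 to run in about a minute — death fractions agree within Monte
Carlo error.
"""

from apopsynergy import PopulationSpec, analyze, build_variant, run_population
from apopsynergy.network import default_grid

spec = PopulationSpec(n_cells=300, cv=0.4, seed=1)
grid = default_grid(24.0)

deaths = {}
for tag in ("ly30_only", "trail_only", "combination"):
    result = run_population(build_variant(tag), spec, grid)
    deaths[tag] = result.death_fraction_at(24.0)
    print(f"{tag:12s} 24 h death fraction: {deaths[tag]:.3f} "
          f"(viability {1 - deaths[tag]:.1%})")

report = analyze(deaths["ly30_only"], deaths["trail_only"],
                 deaths["combination"])
print(f"additive expectation : {report.additive_expectation:.3f}")
print(f"excess over additive : {report.excess_over_additive:.0f}%  "
      f"-> {report.classification}")
# An excess well above zero means the combination kills more cells
# than the two drugs would if their effects simply summed.
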