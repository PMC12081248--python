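"""Sample a virtual population and summarize exposure variability.

100 Japanese adults with 30% log-normal variability on CYP3A4 expression;
the spread in the day-2 cyclosporine trough mirrors the mean +/- SD
reporting convention of population PBPK studies.
"""

from hsctpbpk.physiology import PopulationSpec, population_to_frame, sample_population
from hsctpbpk.library import load_library
from hsctpbpk.scenarios import CourseSpec, Scenario, run_scenario

spec = PopulationSpec(
    n=100, seed=7, ethnicity="Japanese", variability={"CYP3A4.E0": 0.3}
)
population = sample_population(spec)
frame = population_to_frame(population)
print(frame[["weight", "CYP3A4.E0"]].describe().loc[["mean", "std"]])

# exposure spread on a small subsample (full n=100 runs in a few minutes)
scenario = Scenario(
    population=spec.model_copy(update={"n": 8}),
    victim=CourseSpec(
        drug="cyclosporine", dose=100, interval=12, start_day=0, end_day=2
    ),
    metric="Cmin",
    evaluation_day=2,
)
summary = run_scenario(scenario, load_library(), grid_dt=0.5)
print(
    f"day-2 trough: {summary.mean:.1f} +/- {summary.sd:.1f} ng/mL "
    f"(n={summary.n}, attainment {summary.attainment})"
)
# The SD comes entirely from the sampled enzyme expression; the attainment
# figure is the fraction of individuals inside the 200-400 ng/mL window.
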