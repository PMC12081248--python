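"""A classic post-transplant interaction: voriconazole raises cyclosporine.

Cyclosporine 100 mg bid for a week, alone and with voriconazole 200 mg bid
(a mechanism-based CYP3A4 inactivator). The day-6 trough ratio is the
quantity a TDM service would act on, stratified by CYP2C19 phenotype
because voriconazole's own exposure is CYP2C19-limited.
"""

from hsctpbpk.ddi import ddi_ratio
from hsctpbpk.library import load_library
from hsctpbpk.physiology import PopulationSpec
from hsctpbpk.scenarios import CourseSpec, Scenario, run_scenario

library = load_library()
pop = PopulationSpec(n=1, seed=1, ethnicity="Japanese")


def day6_trough(phenotype, with_vori):
    perpetrators = (
        [CourseSpec(drug="voriconazole", dose=200, interval=12, start_day=0, end_day=6)]
        if with_vori
        else []
    )
    scenario = Scenario(
        population=pop,
        victim=CourseSpec(
            drug="cyclosporine", dose=100, interval=12, start_day=0, end_day=6
        ),
        perpetrators=perpetrators,
        metric="Cmin",
        evaluation_day=6,
        phenotypes={"CYP2C19": phenotype},
    )
    return run_scenario(scenario, library, grid_dt=0.5).mean


alone = day6_trough("NM", with_vori=False)
print(f"cyclosporine day-6 trough alone : {alone:6.1f} ng/mL")
for phen in ("NM", "IM", "PM"):
    combo = day6_trough(phen, with_vori=True)
    print(
        f"  with voriconazole, CYP2C19 {phen}: {combo:6.1f} ng/mL "
        f"(ratio {ddi_ratio(combo, alone):.2f})"
    )
# Poor metabolizers accumulate more voriconazole, inactivate more CYP3A4,
# and push the cyclosporine trough higher - the genotype-dependent DDI.
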