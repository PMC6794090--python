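"""Morning/evening anticipation in a ramped vs ramp-free cohort.

A fly anticipating a light transition ramps its activity up over the hours
before it.  The index is (activity in the 3 h before the transition) /
(activity in the 6 h before); 0.5 means no anticipation.  Here one cohort
carries a morning anticipation ramp and the other does not -- the contrast
shows up in MAI and leaves EAI untouched.
"""

from flyclock import dam
from flyclock.anticipation import cohort_anticipation
from flyclock.dam import CohortTable, default_schedule
from flyclock.simulate import SyntheticCohortSpec, SyntheticFlyParams, simulate_cohort
from flyclock.stats import kruskal_dunn

sched = default_schedule(n_ld_days=0)
cohorts = {}
for name, ramp in (("ramped", "morning"), ("no_ramp", "none")):
    spec = SyntheticCohortSpec(
        n_flies=32,
        params=SyntheticFlyParams(anticipation_ramp=ramp, ramp_gain=1.5),
        n_ld_days=0,
        n_dd_days=9,
        group=name,
        master_seed=3,
    )
    cohorts[name] = [dam.bin_series(f, 60) for f in simulate_cohort(spec, sched)[name]]

table = cohort_anticipation(CohortTable(cohorts), spans=[("DD2", "DD", (2,))])
mai = {g: table[table.group == g]["mai"].dropna().to_numpy() for g in cohorts}
eai = {g: table[table.group == g]["eai"].dropna().to_numpy() for g in cohorts}

for g in cohorts:
    print(f"{g:8s}  MAI {mai[g].mean():.3f}  EAI {eai[g].mean():.3f}  (n={mai[g].size})")
print(f"MAI contrast (Kruskal-Wallis): p = {kruskal_dunn(mai).omnibus_p:.2g}")
print(f"EAI contrast (Kruskal-Wallis): p = {kruskal_dunn(eai).omnibus_p:.2g}")
# the ramped group's MAI sits clearly above the flat group's while the EAIs
# are statistically indistinguishable: the ramp is transition-specific.
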