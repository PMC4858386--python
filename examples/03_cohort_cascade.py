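"""The eligibility cascade and workplace-assignment bookkeeping.

Runs the fixed exclusion sequence on the deterministic fixture that
reproduces the reference stage counts, then summarises workplace-zone
assignment among employed women in a simulated cohort.
"""

from dbpexposure import (
    ScenarioConfig, apply_exclusions, exact_cascade_fixture,
    simulate_cohort, workplace_assignment_summary,
)

fixture = exact_cascade_fixture()
eligible, log = apply_exclusions(fixture, seed=2024)
print(log)
print(f"-> {log.n_final} babies eligible for analysis\n")

cohort = simulate_cohort(ScenarioConfig(seed=5, n_records=4000))
summary = workplace_assignment_summary(cohort)
print(f"employed: {summary['n_employed']}, workplace zone assigned: "
      f"{summary['n_assigned']} ({summary['assignment_rate_pct']:.1f}%)")
# women without an assignable workplace zone get residence-only exposure.
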