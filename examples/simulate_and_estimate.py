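"""Simulate the reference cohort and estimate its survival curves.

Draws the default four-entity design (430 subjects, three treatment
groups), fits a Kaplan-Meier curve per group and prints the estimated
survival at t = 35 together with the group sizes.  Group 3 contains the
embedded high-risk subset, so its curve sits below groups 1 and 2.
"""

import survfig as sf

ds = sf.simulate_dataset()  # default config, seed 0
print(f"simulated {ds.n_rows} subjects, variables: {ds.variable_names}")

roles = sf.RoleAssignment("timevar", "statusvar", "factorvar")
analysis = sf.assign_roles(ds, roles)

for level, times, status in analysis.groups():
    curve = sf.km_estimate(times, status, group_label=f"group {level:g}")
    s35 = sf.survival_at(curve, 35.0)
    print(f"{curve.group_label}: n = {curve.n_total}, "
          f"events = {curve.total_events}, S(35) = {s35:.3f}")

print("S(35) is the estimated probability of remaining event-free past "
      "t = 35; in expectation group 3 declines fastest (any single draw "
      "is noisy).")
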