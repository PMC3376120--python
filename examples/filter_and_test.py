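"""Subset a cohort with a filter string and run pairwise logrank tests.

Removing the high-risk subset with "filtervar<2" leaves three groups with
identically distributed event times, so the pairwise p-values should look
like draws from a null (no small p-values expected systematically).
"""

import survfig as sf
from survfig.pipeline import tests_for

ds = sf.simulate_dataset()
expr = sf.parse_filter("filtervar<2")
filtered, removed = sf.apply_filter(ds, expr)
print(f"filter {sf.unparse(expr)} removed {removed} of {ds.n_rows} rows")

analysis = sf.assign_roles(filtered, sf.RoleAssignment(
    "timevar", "statusvar", "factorvar"))
for res in tests_for(analysis, "pairwise"):
    print(f"{res.description}: chi2 = {res.statistic:.3f}, "
          f"p = {sf.format_p(res.p_value, 4)}")

print("Each line compares two groups' survival distributions; after "
      "filtering, all three comparisons are null comparisons.")
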