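"""Batch-render a list of saved plot specs.

Writes two specs (an unfiltered and a filtered variant of the same
analysis), then processes them as a queue into one output directory; the
log reports each spec in order and ends with the sentinel "Finished".
"""

import dataclasses
from pathlib import Path

import survfig as sf

out = Path("scratch_example")
out.mkdir(exist_ok=True)

ds = sf.simulate_dataset()
sf.write_table(ds, out / "example.dat")
roles = sf.RoleAssignment("timevar", "statusvar", "factorvar")
spec = sf.default_spec(sf.assign_roles(ds, roles), data_path="example.dat")
spec_filtered = dataclasses.replace(
    spec, filter_string="filtervar<2",
    y_axis=sf.AxisSpec(0, 100, 20, "Percent event-free"))  # percent mode

p1 = sf.save_spec(spec, out / "example.kmspec.json")
p2 = sf.save_spec(spec_filtered, out / "example_filtered.kmspec.json")

job = sf.QueueJob((str(p1), str(p2)), str(out / "figures"), "svg")
log = sf.run_queue(job)
for line in log.lines():
    print(line)
print(f"{log.n_ok} figure(s) written; a failing spec would be logged and "
      "skipped without stopping the batch.")
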