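"""Render aerial and ground counts comparable with class conversion factors.

A roan series counted mostly from the ground with two aerial censuses:
roan is a large light/brown species, so an aerial count must be multiplied
by 2.302 to be comparable with ground counts.
"""

import poptrend as pt

roan = pt.get_species_profile("roan")
print(f"roan: class={roan.species_class}, preferred method="
      f"{roan.preferred_field_method}, r_max={pt.get_rmax(roan)}")
entry = pt.get_conversion_factor(roan.species_class)
print(f"aerial->ground factor: {entry.factor} "
      f"[{entry.ci_low}, {entry.ci_high}]\n")

records = [
    pt.CountRecord("nazinga", "roan", 1998.0, "ground", "sample", 870.0,
                   precision_kind="ci95", precision_values=(600.0, 1140.0)),
    pt.CountRecord("nazinga", "roan", 2000.2, "aerial", "sample", 406.0,
                   precision_kind="ci95", precision_values=(300.0, 512.0)),
    pt.CountRecord("nazinga", "roan", 2003.0, "aerial", "sample", 440.0,
                   precision_kind="ci95", precision_values=(330.0, 550.0)),
    pt.CountRecord("nazinga", "roan", 2005.0, "ground", "sample", 1050.0,
                   precision_kind="ci95", precision_values=(760.0, 1340.0)),
]
series = pt.standardize_series(
    pt.CountSeries("nazinga", "roan", tuple(records)))

harmonized = pt.harmonize_series(series, roan, target="auto")
for before, after in zip(series.counts, harmonized.counts):
    tag = "converted" if after.scale != before.record.field_method else ""
    print(f"{before.date:7.1f} {before.record.field_method:6s} "
          f"{before.count:7.1f} -> {after.count:8.1f} "
          f"[{after.ci_low:7.1f}, {after.ci_high:7.1f}] {tag}")

# target='auto' resolves to ground (the preferred method for roan); the two
# aerial counts and their interval bounds are multiplied by 2.302, after
# which they align with the ground counts' scale.
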