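"""Standardize heterogeneous count precision to 95% intervals.

Four counts of the same population, each reported differently: a sample
count with a CI, one with a standard error, a total count with nothing,
and an expert guesstimate.  All are reduced to the common currency the
trend model consumes: a 95% interval and an observation sd.
"""

import poptrend as pt

records = [
    pt.CountRecord("zakouma", "tiang", 1986.0, "aerial", "sample", 2000.0,
                   precision_kind="ci95", precision_values=(1500.0, 2500.0)),
    pt.CountRecord("zakouma", "tiang", 1991.0, "aerial", "sample", 400.0,
                   precision_kind="se", precision_values=(250.0,)),
    pt.CountRecord("zakouma", "tiang", 2005.0, "aerial", "total", 1310.0),
    pt.CountRecord("zakouma", "tiang", 1970.0, "", "guesstimate", 3000.0),
]

for rec in records:
    sc = pt.standardize_ci(rec)
    rule = sc.notes[0] if sc.notes else "95% CI used as given"
    print(f"{rec.date:7.1f}  {rec.stat_method:11s} count {rec.count:6.0f}"
          f" -> CI [{sc.ci_low:7.1f}, {sc.ci_high:7.1f}], sigma"
          f" {sc.sigma:6.1f}   ({rule})")

# The sigma column is (CI width)/3.93 -- the sd of a normal whose central
# 95% mass spans the interval; precise counts get small sigmas and pull the
# fitted trajectory harder.  Note the floored lower bound for the 1991
# count: 400 - 1.96*250 would be negative.
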