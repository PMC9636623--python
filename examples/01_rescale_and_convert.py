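"""Rescale pain summaries to 0-100 and convert median-based reports.

A 0-10 numerical rating scale mean of 5.0 (SD 2.0) and a 0-3 verbal
rating scale mean of 1.5 (SD 0.9) both land at a mean of 50 on the common
0-100 scale -- the whole point of range-ratio rescaling.  Median-based
reports are first converted to mean/SD; a constant sample (min = median
= max) converts to SD 0 and is flagged, because such an arm cannot
contribute a mean-difference variance.
"""

from painrescale import (
    SCALE_0_100,
    ScaleDefinition,
    assign_numeric_values,
    convert_median_iqr,
    convert_median_range,
    rescale_summary,
)

nrs = ScaleDefinition("NRS-10", 0, 10)
labels = ["no pain", "mild pain", "moderate pain", "severe pain"]
print("verbal categories numbered:", dict(assign_numeric_values(labels)))
vrs = ScaleDefinition("VRS-4", 0, 3, labels=tuple(labels),
                      values_assigned_by="analyst")

for scale, mean, sd in ((nrs, 5.0, 2.0), (vrs, 1.5, 0.9)):
    m, s = rescale_summary(mean, sd, scale, SCALE_0_100)
    print(f"{scale.name}: mean {mean} (SD {sd}) -> {m:.1f} (SD {s:.1f}) on 0-100")

conv = convert_median_range(50.0, 0.0, 100.0, n=81)
print(f"median 50 (range 0-100, n=81) -> mean {conv.mean:.1f}, SD {conv.sd:.2f}")

conv = convert_median_iqr(3.0, 2.0, 4.0, n=120)
print(f"median 3 (IQR 2-4, n=120)    -> mean {conv.mean:.2f}, SD {conv.sd:.2f}")

degenerate = convert_median_range(1.0, 1.0, 1.0, n=46)
print(
    f"median 1 (range 1-1, n=46)   -> SD {degenerate.sd}, "
    f"degenerate={degenerate.degenerate} (pair will be excluded)"
)
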