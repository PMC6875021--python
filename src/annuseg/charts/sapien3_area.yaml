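# Edwards Sapien 3 sizing by annulus area (mm^2).
# Synthetic transcription based on the publicly available manufacturer
# sizing matrix, with band boundaries made contiguous and non-overlapping
# (boundary values fall into the larger size, half-open [lower, upper)
# convention).  Editable data, not clinical ground truth.
device_family: "Edwards Sapien 3"
parameter: area_mm2
bands:
  - {lower: 273.0, upper: 345.0, size: "20"}
  - {lower: 345.0, upper: 430.0, size: "23"}
  - {lower: 430.0, upper: 546.0, size: "26"}
  - {lower: 546.0, upper: 683.0, size: "29"}
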