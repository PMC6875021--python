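# Medtronic Evolut sizing by annulus perimeter (mm).
# Synthetic transcription: annulus-diameter windows 18-20 / 20-23 / 23-26 /
# 26-30 mm from the publicly available sizing guide, converted to perimeter
# by pi * diameter.  Half-open [lower, upper) bands; editable data, not
# clinical ground truth.
device_family: "Medtronic Evolut"
parameter: perimeter_mm
bands:
  - {lower: 56.5, upper: 62.8, size: "23"}
  - {lower: 62.8, upper: 72.3, size: "26"}
  - {lower: 72.3, upper: 81.7, size: "29"}
  - {lower: 81.7, upper: 94.2, size: "34"}
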