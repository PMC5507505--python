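# Published linear CFT estimators for deciduous central incisors.
# Each entry: intercept (days), slope (days per unit), unit of the predictor.
# These estimate TOTAL crown formation time (pre- + post-natal) unless noted.
estimators:
  mahoney_unworn:
    intercept: 122.980
    slope: 11.357
    unit: mm2
    provenance: "total CFT from labiolingual crown section area, unworn deciduous incisors"
  mahoney_worn:
    intercept: -236.268
    slope: 43.751
    unit: mm
    provenance: "total CFT from EDJ length, worn deciduous incisors with intact EDJ"
  birch_dean_incisor:
    intercept: 6.73
    slope: null
    unit: um
    provenance: "cumulative cross-striation count vs prism length, modern deciduous central incisors; slope not published, supply at call time"
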