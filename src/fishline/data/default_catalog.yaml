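# Default species catalog for Chilean pelagic landing lines.
#
# Length-weight parameters are the allometric coefficients of W = a L^b
# (W in grams, L in centimeters) fitted from laboratory measurements for
# the four target species; jumbo squid and snoek have no fitted parameters
# and yield length estimates only.
#
# Size rules encode the plausibility filter: sardine and anchovy longer
# than 20 cm, or jack mackerel / mackerel shorter than 20 cm, are discarded
# as abnormal detections.
#
# Display colors are distinct hues used both for rendering annotations and
# by the synthetic scene generator / reference detector.
classes:
  - name: anchovy
    display_color: [70, 130, 200]
    size_rule: {max_length_cm: 20.0}
    lw_params: {a: 0.003653, b: 3.23344}
  - name: jack_mackerel
    display_color: [220, 220, 60]
    size_rule: {min_length_cm: 20.0}
    lw_params: {a: 0.007921, b: 3.1085}
  - name: mackerel
    display_color: [200, 60, 60]
    size_rule: {min_length_cm: 20.0}
    lw_params: {a: 0.0090147, b: 3.1067}
  - name: sardine
    display_color: [60, 200, 200]
    size_rule: {max_length_cm: 20.0}
    lw_params: {a: 0.0064065, b: 3.1299}
  - name: jumbo_squid
    display_color: [230, 140, 40]
  - name: snoek
    display_color: [60, 180, 60]
calibration:
  cm_per_pixel: 0.05
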