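"""Re-derive the shipped Type-2 footprint-of-uncertainty widths.

The interval Type-2 membership functions are the Type-1 trapezoids widened
per feature by a FoU width.  The widths are not free parameters: they are
the smallest grid point (ascending total width, then lexicographic) at
which the Type-2 classifier labels every reference-cohort case correctly.
"""

from ibccad import calibrate_fou, classify_t2, default_type1_config, load_reference_cohort

cohort = load_reference_cohort()
config = calibrate_fou(cohort, default_type1_config())

print("calibrated FoU widths:", config.fou_widths)
correct = sum(classify_t2(c, config).label == c.label for c in cohort)
print(f"cohort classification: {correct}/{len(cohort)} correct")

# The mean-ratio feature needs the widest uncertainty band (0.25): the one
# Type-1 miss sits between the Low and Medium supports of f1.
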