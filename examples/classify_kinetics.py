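"""Classify CEM enhancement kinetics from ROI densities.

Uses the two published worked examples: mean recombined-image densities
2180 -> 2157 and 2148 -> 2113 between the ~2 min and ~8 min acquisitions.
A drop of more than 10 device units indicates washout, the curve type
most suggestive of malignancy.
"""

from kscem import ROIPair, classify_enhancement, curve_type_from_mri_kinetics

for initial, delayed in [(2180, 2157), (2148, 2113), (2000, 2006), (1500, 1540)]:
    roi = ROIPair(initial_mean=initial, delayed_mean=delayed)
    curve = classify_enhancement(roi)
    print(f"ROI {initial} -> {delayed} (delta {roi.delta:+.0f}): {curve}")

# the same vocabulary harmonizes with MRI time-intensity curve types
print("MRI type III curve corresponds to:", curve_type_from_mri_kinetics("typeIII"))
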