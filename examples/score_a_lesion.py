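"""Score a single lesion through the Kaiser flowchart.

Builds the descriptor vector of a textbook-suspicious lesion (spiculated,
washout kinetics, irregular margins, centripetal enhancement, no oedema)
and scores it with the shipped MRI flowchart.
"""

from kscem import LesionFeatures, load_builtin_tree, score_lesion

tree = load_builtin_tree("mri")
lesion = LesionFeatures(
    root_sign="present",
    delayed_phase="washout",
    margins="irregular",
    internal_enhancement="inhomogeneous_centripetal",
    oedema="absent",
)
ks = score_lesion(lesion, tree)

print(f"Kaiser score: {ks.value}")
print(f"biopsy recommended: {ks.biopsy_recommended}")
print(f"BI-RADS band (non-normative default mapping): {ks.birads_category}")
# A score above 4 puts the lesion in the biopsy region; this profile lands
# at 8, i.e. high suspicion of malignancy.
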