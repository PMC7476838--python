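"""Build the per-variant background error null from unmatched normals.

A known tumor mutation is genotyped in the buffy coats of the *other* patients
in the cohort; none of them carries it, so their VAFs measure the sequencing
error at exactly that variant. The case VAF must exceed the panel mean plus
2 SD to count as real signal.
"""

from rbliquid import AlleleCount, VariantKey, build_background, exceeds_background

variant = VariantKey("chr13", 48_941_648, "C", "T", label="p.Q736*")

# nine unmatched buffy coats: one shows a single error read at 1500x
panel = [
    AlleleCount(variant, f"PON{i}-buffy", "buffy_unmatched",
                depth=1500, alt_reads=(1 if i == 4 else 0),
                alt_fwd=(1 if i == 4 else 0))
    for i in range(9)
]
model = build_background(variant, panel, k=2)
print(f"panel mean VAF    {model.mean_vaf:.6f}")
print(f"panel SD          {model.sd_vaf:.6f}")
print(f"threshold (m+2SD) {model.threshold:.6f}")

for case_vaf in (0.0003, 0.0008, 0.007):
    verdict = "above" if exceeds_background(case_vaf, model) else "below"
    print(f"case VAF {case_vaf:.4f} is {verdict} the background threshold")

# A case VAF must clear ~0.052% here: one stray panel read already pushes the
# threshold well above the panel mean, which is what keeps false positives rare.
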