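"""Genotype known tumor mutations in a patient's plasma cfDNA.

Tumor-guided genotyping asks a narrow question -- is the exact mutation seen in
the tumor present in plasma? -- which is why it works down to a few supporting
reads: >=3 alt reads, cfDNA VAF above the matched buffy coat, and above the
unmatched-panel mean + 2 SD.
"""

from rbliquid import (
    AlleleCount,
    VariantKey,
    build_background,
    genotype_variant,
    theoretical_detection_limit,
    truncated_percent,
)

variant = VariantKey("chr13", 48_919_230, "C", "T", label="p.R320*")
panel = [
    AlleleCount(variant, f"PON{i}-buffy", "buffy_unmatched", depth=1500, alt_reads=0)
    for i in range(9)
]
model = build_background(variant, panel, k=2)
buffy = AlleleCount(variant, "P12-buffy", "buffy_matched", depth=1480, alt_reads=0)

for alt, depth in [(150, 1500), (5, 5666), (2, 2286)]:
    cfdna = AlleleCount(variant, "P12-cfdna", "cfdna", depth=depth,
                        alt_reads=alt, alt_fwd=alt // 2, alt_rev=alt - alt // 2)
    r = genotype_variant(variant, cfdna, buffy, model)
    print(
        f"{alt:>4}/{depth:<5} VAF {r.cfdna_vaf:.5f}  -> {r.status:<13}"
        f" (reads {r.pass_min_reads}, buffy {r.pass_buffy}, background {r.pass_background})"
        + ("  [subthreshold evidence]" if r.subthreshold_evidence else "")
    )

limit = theoretical_detection_limit(3, 1596)
print(f"\ntheoretical detection limit at 1596x: 3/1596 = {truncated_percent(limit)}%")
# 150/1500 is an unambiguous detection; 5/5666 still clears the 3-read floor;
# 2/2286 leaves evidence below the detection threshold and is reported as such.
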