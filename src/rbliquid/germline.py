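"""Germline vs somatic classification from the matched buffy coat.

An inherited variant is carried by every nucleated blood cell, so it appears
in the buffy coat near 50% VAF (heterozygous); a tumor-derived somatic variant
is absent from it. A variant at an intermediate buffy VAF may reflect
mosaicism (a subpopulation of cells carrying the mutation) and is deliberately
left ambiguous, never auto-resolved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from scipy.stats import binomtest

from .genotyping import DetectionResult
from .variants import AlleleCount, VariantKey, vaf


@dataclass(frozen=True)
class GermlineRule:
    """Concrete thresholds for the germline/somatic/ambiguous trichotomy.

    germline: an exact two-sided binomial test of the buffy alt count against
    a heterozygous p=0.5 is not rejected at ``alpha`` AND buffy VAF >=
    ``min_het_vaf``. somatic: buffy support at or below ``max_somatic_alt``
    reads, or buffy VAF < ``max_somatic_vaf``. Anything else: ambiguous.
    """

    alpha: float = 0.01
    min_het_vaf: float = 0.30
    max_somatic_vaf: float = 0.02
    max_somatic_alt: int = 3
    het_p: float = 0.5


@dataclass(frozen=True)
class GermlineCall:
    variant: VariantKey
    patient_id: str
    buffy_vaf: float
    cfdna_vaf: float
    verdict: str  # "germline" | "somatic" | "ambiguous"
    binomial_p: float


def classify_germline(
    variant: VariantKey,
    buffy: AlleleCount,
    cfdna: AlleleCount,
    rule: GermlineRule = GermlineRule(),
    patient_id: str = "",
) -> GermlineCall:
    """Classify one variant from its matched buffy coat observation.

    The cfDNA VAF is reporting context only and never influences the verdict:
    tumor shedding can push a germline variant's plasma VAF well off 50%.
    """
    if buffy.variant != variant or cfdna.variant != variant:
        raise ValueError(f"counts do not match variant {variant}")
    buffy_vaf = vaf(buffy)
    if buffy.depth > 0:
        p_value = binomtest(buffy.alt_reads, buffy.depth, rule.het_p).pvalue
    else:
        p_value = 1.0  # no evidence against heterozygosity, but no support either
    if p_value >= rule.alpha and buffy_vaf >= rule.min_het_vaf:
        verdict = "germline"
    elif buffy.alt_reads <= rule.max_somatic_alt or buffy_vaf < rule.max_somatic_vaf:
        verdict = "somatic"
    else:
        verdict = "ambiguous"
    return GermlineCall(
        variant=variant,
        patient_id=patient_id,
        buffy_vaf=buffy_vaf,
        cfdna_vaf=vaf(cfdna),
        verdict=verdict,
        binomial_p=float(p_value),
    )


def filter_germline(
    results: Sequence[DetectionResult],
    calls: Sequence[GermlineCall],
) -> tuple[list[DetectionResult], list[DetectionResult], dict[tuple[str, VariantKey], str]]:
    """Partition detection results into somatic-reported and germline-excluded.

    Results whose germline call is ``germline`` are excluded from the somatic
    report; ``ambiguous`` results stay in the report carrying their flag in
    the returned verdict map. Results with no matching call (e.g. no buffy
    support at all) are reported as somatic.
    """
    verdicts = {(c.patient_id, c.variant): c.verdict for c in calls}
    reported: list[DetectionResult] = []
    excluded: list[DetectionResult] = []
    for result in results:
        if verdicts.get((result.patient_id, result.variant)) == "germline":
            excluded.append(result)
        else:
            reported.append(result)
    return reported, excluded, verdicts
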