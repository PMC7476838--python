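"""Per-variant empirical background error null from unmatched buffy coats.

Each patient's known tumor mutations are also genotyped in the buffy coats of
the *other* patients in the cohort. Since those samples are not expected to
carry the mutation, the distribution of their VAFs is an empirical null for
the sequencing/library error at that exact variant, and a case VAF is only
trusted when it exceeds the panel mean plus ``k`` standard deviations
(default k=2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

from .variants import AlleleCount, VariantKey, vaf

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BackgroundModel:
    """Empirical null for one variant: panel VAFs, their mean/SD, threshold."""

    variant: VariantKey
    panel_vafs: tuple[float, ...]
    mean_vaf: float
    sd_vaf: float
    threshold: float
    n_panel: int


def build_background(
    variant: VariantKey,
    panel: Sequence[AlleleCount],
    k: float = 2.0,
) -> BackgroundModel:
    """Build the mean + k*SD null for ``variant`` from unmatched normals.

    The SD is the sample standard deviation (n-1 denominator), defined as 0
    for a single-sample panel. Panel samples with zero coverage at the site
    enter the average as VAF 0 (logged): an uncovered normal is weak but
    admissible evidence of a clean background.

    The caller is responsible for panel hygiene: no panel sample may come from
    the patient under test.
    """
    if not panel:
        raise ValueError(f"empty unmatched panel for {variant}: no null can be formed")
    for count in panel:
        if count.variant != variant:
            raise ValueError(
                f"panel count for {count.variant} does not match model variant {variant}"
            )
        if count.depth == 0:
            logger.warning(
                "panel sample %s has zero coverage at %s; included as VAF 0",
                count.sample_id, variant,
            )
    vafs = tuple(vaf(c) for c in panel)
    n = len(vafs)
    mean = math.fsum(vafs) / n
    if n > 1:
        sd = math.sqrt(math.fsum((x - mean) ** 2 for x in vafs) / (n - 1))
    else:
        sd = 0.0
    return BackgroundModel(
        variant=variant,
        panel_vafs=vafs,
        mean_vaf=mean,
        sd_vaf=sd,
        threshold=mean + k * sd,
        n_panel=n,
    )


def exceeds_background(case_vaf: float, model: BackgroundModel) -> bool:
    """Strict comparison: true iff the case VAF is greater than the threshold.

    Ties fail ("greater than" is read literally), so a case indistinguishable
    from the panel is never positive.
    """
    return case_vaf > model.threshold
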