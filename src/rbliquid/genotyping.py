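"""Tumor-guided genotyping of known mutations in plasma cfDNA.

A variant known from the patient's tumor is scored positive in cfDNA when it
has (a) at least 3 supporting reads, (b) a cfDNA VAF strictly above the VAF in
the patient's own buffy coat, and (c) a cfDNA VAF above the unmatched-panel
mean + 2 SD background threshold. A call with more than half of its alt reads
flagged as artifact is forced to not-detected regardless of (a)-(c).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from statistics import median
from typing import Iterable, Mapping, Sequence

from .background import BackgroundModel, build_background, exceeds_background
from .variants import AlleleCount, DetectionThresholds, VariantKey, vaf, zero_count

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionResult:
    """Per-variant verdict with one boolean per criterion.

    ``subthreshold_evidence`` marks variants with at least one supporting read
    that nevertheless fail the criteria -- reporting metadata only, never a
    detection (the study context: a patient whose two tumor mutations were
    seen at 2/2286 and 5/5666 reads, both below threshold).
    """

    variant: VariantKey
    patient_id: str
    sample_id: str
    track: str  # "tumor_guided" | "de_novo"
    cfdna_vaf: float
    buffy_vaf: float
    background_threshold: float
    pass_min_reads: bool
    pass_buffy: bool
    pass_background: bool
    pass_artifact: bool
    status: str  # "detected" | "not_detected"
    subthreshold_evidence: bool

    @property
    def detected(self) -> bool:
        return self.status == "detected"


def artifact_fraction_ok(count: AlleleCount, max_fraction: float) -> bool:
    """True unless more than ``max_fraction`` of alt reads are artifact-flagged.

    The fraction is computed over alt-supporting reads; zero alt reads passes
    vacuously.
    """
    if count.alt_reads == 0:
        return True
    return count.alt_artifact_reads <= max_fraction * count.alt_reads


def genotype_variant(
    variant: VariantKey,
    cfdna: AlleleCount,
    buffy_matched: AlleleCount,
    model: BackgroundModel,
    thresholds: DetectionThresholds = DetectionThresholds(),
    patient_id: str | None = None,
) -> DetectionResult:
    """Apply the tumor-guided criteria to one variant in one cfDNA sample."""
    for count in (cfdna, buffy_matched):
        if count.variant != variant:
            raise ValueError(f"count for {count.variant} does not match {variant}")
    if model.variant != variant:
        raise ValueError(f"background model for {model.variant} does not match {variant}")
    cf_vaf = vaf(cfdna)
    bc_vaf = vaf(buffy_matched)
    pass_min_reads = cfdna.alt_reads >= thresholds.min_alt_reads_genotyping
    pass_buffy = cf_vaf > bc_vaf
    pass_background = exceeds_background(cf_vaf, model)
    pass_artifact = artifact_fraction_ok(cfdna, thresholds.artifact_max_fraction)
    detected = pass_min_reads and pass_buffy and pass_background and pass_artifact
    return DetectionResult(
        variant=variant,
        patient_id=patient_id if patient_id is not None else patient_of(cfdna.sample_id),
        sample_id=cfdna.sample_id,
        track="tumor_guided",
        cfdna_vaf=cf_vaf,
        buffy_vaf=bc_vaf,
        background_threshold=model.threshold,
        pass_min_reads=pass_min_reads,
        pass_buffy=pass_buffy,
        pass_background=pass_background,
        pass_artifact=pass_artifact,
        status="detected" if detected else "not_detected",
        subthreshold_evidence=(not detected) and cfdna.alt_reads >= 1,
    )


def theoretical_detection_limit(min_reads: int, coverage: int) -> float:
    """Lowest genotypable VAF at a given unique coverage: min_reads / coverage.

    Example: 3 supporting reads at 1596x unique coverage gives 3/1596
    (~0.188%), the floor below which a known mutation cannot satisfy the
    read-count criterion.
    """
    if coverage < 1:
        raise ValueError("coverage must be >= 1")
    return min_reads / coverage


def truncated_percent(fraction: float, decimals: int = 2) -> str:
    """Format a fraction as a percentage truncated (not rounded) to ``decimals``."""
    scale = 10 ** decimals
    value = int(fraction * 100 * scale) / scale
    return f"{value:.{decimals}f}"


# ---------------------------------------------------------------------------
# Cohort-level genotyping


def patient_of(sample_id: str) -> str:
    """Patient identifier encoded as the sample-id prefix before the first '-'."""
    return sample_id.split("-")[0]


class CohortCounts:
    """Index of pileup observations by sample and variant for one cohort.

    Sample ids follow the ``<patient>-<type>[-repN]`` convention (for example
    ``P10-cfdna``, ``P10-cfdna-rep2``, ``P10-buffy``). Buffy-coat rows carry
    role ``buffy_matched`` relative to their own patient; rows with role
    ``buffy_unmatched`` belong to out-of-cohort donors and only ever enter
    background panels.
    """

    def __init__(self, counts: Iterable[AlleleCount]):
        self._by_key: dict[tuple[str, VariantKey], AlleleCount] = {}
        self._samples_by_role: dict[str, list[str]] = {}
        for count in counts:
            key = (count.sample_id, count.variant)
            if key in self._by_key:
                raise ValueError(f"duplicate pileup row for {count.sample_id} @ {count.variant}")
            self._by_key[key] = count
            bucket = self._samples_by_role.setdefault(count.role, [])
            if count.sample_id not in bucket:
                bucket.append(count.sample_id)

    def get(self, sample_id: str, variant: VariantKey, role: str) -> AlleleCount:
        """Observation for (sample, variant); depth-0 placeholder if absent."""
        count = self._by_key.get((sample_id, variant))
        if count is None:
            logger.warning("no pileup row for %s @ %s; treated as depth 0", sample_id, variant)
            return zero_count(variant, sample_id, role)
        return count

    def has(self, sample_id: str, variant: VariantKey) -> bool:
        return (sample_id, variant) in self._by_key

    def counts_for_sample(self, sample_id: str) -> list[AlleleCount]:
        return [c for (sid, _), c in self._by_key.items() if sid == sample_id]

    def cfdna_samples(self, patient_id: str) -> list[str]:
        """cfDNA samples of a patient, primary first (replicates sort after)."""
        return sorted(
            s for s in self._samples_by_role.get("cfdna", ()) if patient_of(s) == patient_id
        )

    def buffy_sample(self, patient_id: str) -> str | None:
        matches = [
            s for s in self._samples_by_role.get("buffy_matched", ())
            if patient_of(s) == patient_id
        ]
        return matches[0] if matches else None

    def patients(self) -> list[str]:
        return sorted({patient_of(s) for s in self._samples_by_role.get("cfdna", ())})

    def unmatched_panel(self, patient_id: str, variant: VariantKey) -> list[AlleleCount]:
        """Background panel for a patient: every other patient's buffy coat,
        plus any dedicated out-of-cohort normals."""
        panel = []
        for sample in self._samples_by_role.get("buffy_matched", ()):
            if patient_of(sample) != patient_id:
                panel.append(self.get(sample, variant, "buffy_matched"))
        for sample in self._samples_by_role.get("buffy_unmatched", ()):
            panel.append(self.get(sample, variant, "buffy_unmatched"))
        return panel

    def background_for(
        self, patient_id: str, variant: VariantKey, k: float
    ) -> BackgroundModel:
        return build_background(variant, self.unmatched_panel(patient_id, variant), k=k)


def summarize_detections(results: Sequence[DetectionResult]) -> dict:
    """Cohort summary over primary-sample results: counts and detected-VAF stats."""
    primary = [r for r in results if _is_primary(r, results)]
    detected = [r for r in primary if r.detected]
    patients = sorted({r.patient_id for r in primary})
    detected_patients = sorted({r.patient_id for r in detected})
    vafs = sorted(r.cfdna_vaf for r in detected)
    return {
        "mutations_detected": len(detected),
        "mutations_total": len(primary),
        "patients_detected": len(detected_patients),
        "patients_total": len(patients),
        "detected_patient_ids": detected_patients,
        "subthreshold_patient_ids": sorted(
            {r.patient_id for r in primary if r.subthreshold_evidence}
            - {r.patient_id for r in detected}
        ),
        "detected_vaf_median": median(vafs) if vafs else None,
        "detected_vaf_min": vafs[0] if vafs else None,
        "detected_vaf_max": vafs[-1] if vafs else None,
    }


def _is_primary(result: DetectionResult, results: Sequence[DetectionResult]) -> bool:
    """Keep one result per (patient, variant): the lexicographically first sample."""
    siblings = [
        r.sample_id
        for r in results
        if r.patient_id == result.patient_id and r.variant == result.variant
    ]
    return result.sample_id == min(siblings)


def genotype_cohort(
    tumor_variants: Mapping[str, Sequence[VariantKey]],
    cohort: CohortCounts,
    thresholds: DetectionThresholds = DetectionThresholds(),
) -> tuple[list[DetectionResult], dict]:
    """Genotype every patient's known tumor variants in all their cfDNA samples.

    Patients present in the tumor-variant map but absent from the pileups are
    logged and reported as not-detected at depth 0. Returns per-(patient,
    variant, sample) results plus a cohort summary computed over primary
    samples.
    """
    results: list[DetectionResult] = []
    for patient_id in sorted(tumor_variants):
        variants = tumor_variants[patient_id]
        cf_samples = cohort.cfdna_samples(patient_id)
        buffy = cohort.buffy_sample(patient_id)
        if not cf_samples:
            logger.warning("patient %s has no cfDNA sample; all variants not detected", patient_id)
            cf_samples = [f"{patient_id}-cfdna"]
        if buffy is None:
            raise ValueError(
                f"patient {patient_id} has no matched buffy coat; "
                "the buffy-comparison criterion is undefined without one"
            )
        for variant in variants:
            model = cohort.background_for(patient_id, variant, k=thresholds.background_k)
            buffy_count = cohort.get(buffy, variant, "buffy_matched")
            for sample in cf_samples:
                cf_count = cohort.get(sample, variant, "cfdna")
                results.append(
                    genotype_variant(
                        variant, cf_count, buffy_count, model, thresholds,
                        patient_id=patient_id,
                    )
                )
    return results, summarize_detections(results)
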