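"""De novo discovery of low-VAF variants across the targeted panel.

Without tumor knowledge, every panel site with any alt-supporting read is a
candidate, and a stricter cascade decides whether it is called: VAF > 0.5%
with at least 10 mutant reads, cfDNA VAF at least 2x the matched buffy coat,
cfDNA VAF above the unmatched-panel mean + 2 SD threshold, at most 50% of alt
reads artifact-flagged, and no gross one-strand support. The artifact and
strand-bias guards are automated surrogates for manual review of alignments;
they are tuned to act only on unambiguous technical artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam
from intervaltree import IntervalTree
from scipy.stats import fisher_exact

from .background import BackgroundModel, exceeds_background
from .genotyping import CohortCounts, artifact_fraction_ok, patient_of
from .variants import AlleleCount, DetectionThresholds, PanelRegion, VariantKey, vaf

logger = logging.getLogger(__name__)

FILTER_NAMES = ("low_vaf", "low_alt_reads", "buffy_ratio", "background", "artifact", "strand_bias")

_FILTER_DESCRIPTIONS = {
    "low_vaf": "cfDNA VAF not above the de novo VAF floor",
    "low_alt_reads": "fewer mutant allele reads than the de novo floor",
    "buffy_ratio": "cfDNA VAF below the required multiple of the matched buffy coat VAF",
    "background": "cfDNA VAF not above the unmatched-normal mean + k*SD threshold",
    "artifact": "more than the allowed fraction of alt reads flagged as artifact",
    "strand_bias": "alt support confined to one strand with extreme exact-test p",
}


@dataclass(frozen=True)
class CandidateVariant:
    """A candidate site/allele with its strand-bias p-value and failed filters."""

    variant: VariantKey
    cfdna_count: AlleleCount
    strand_bias_p: float
    filters_failed: frozenset[str] = frozenset()

    @property
    def called(self) -> bool:
        return not self.filters_failed

    @property
    def vaf(self) -> float:
        return vaf(self.cfdna_count)


def strand_bias_pvalue(count: AlleleCount) -> float:
    """Two-sided Fisher exact p for alt strand counts against reference reads.

    The pileup dialect does not carry a strand split for reference reads, so
    the reference reads are apportioned evenly between strands; with the
    filter gated on all-one-strand alt support this is conservative.
    """
    if count.alt_reads == 0:
        return 1.0
    ref_reads = count.depth - count.alt_reads
    table = [
        [count.alt_fwd, count.alt_rev],
        [(ref_reads + 1) // 2, ref_reads // 2],
    ]
    return float(fisher_exact(table, alternative="two-sided")[1])


def _region_tree(regions: Iterable[PanelRegion]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for region in regions:
        trees.setdefault(region.chrom, IntervalTree()).addi(region.start, region.end, region.name)
    return trees


def in_panel(variant: VariantKey, trees: dict[str, IntervalTree]) -> bool:
    tree = trees.get(variant.chrom)
    return bool(tree and tree.overlaps(variant.pos - 1))


def scan_candidates(
    pileups: Sequence[AlleleCount],
    regions: Sequence[PanelRegion],
) -> list[CandidateVariant]:
    """Every (site, alt allele) with >=1 alt read inside the panel, sorted."""
    trees = _region_tree(regions)
    candidates = [
        CandidateVariant(
            variant=count.variant,
            cfdna_count=count,
            strand_bias_p=strand_bias_pvalue(count),
        )
        for count in pileups
        if count.alt_reads >= 1 and in_panel(count.variant, trees)
    ]
    candidates.sort(key=lambda c: (c.variant.chrom, c.variant.pos, c.variant.alt))
    return candidates


def filter_denovo(
    candidate: CandidateVariant,
    buffy_matched: AlleleCount,
    model: BackgroundModel,
    thresholds: DetectionThresholds = DetectionThresholds(),
) -> CandidateVariant:
    """Annotate a candidate with the de novo filter cascade.

    Floors are strict where the criteria say "greater than" (VAF floor,
    background) and inclusive where they say "at least" (read counts, the 2x
    buffy-coat ratio: exactly 2x passes).
    """
    if buffy_matched.variant != candidate.variant or model.variant != candidate.variant:
        raise ValueError(f"mismatched inputs for candidate {candidate.variant}")
    count = candidate.cfdna_count
    cf_vaf = vaf(count)
    failed = set()
    if not cf_vaf > thresholds.denovo_min_vaf:
        failed.add("low_vaf")
    if count.alt_reads < thresholds.denovo_min_alt_reads:
        failed.add("low_alt_reads")
    if cf_vaf < thresholds.denovo_buffy_ratio * vaf(buffy_matched):
        failed.add("buffy_ratio")
    if not exceeds_background(cf_vaf, model):
        failed.add("background")
    if not artifact_fraction_ok(count, thresholds.artifact_max_fraction):
        failed.add("artifact")
    if (
        count.alt_reads >= thresholds.strand_bias_min_alt
        and min(count.alt_fwd, count.alt_rev) == 0
        and candidate.strand_bias_p < thresholds.strand_bias_p
    ):
        failed.add("strand_bias")
    return replace(candidate, filters_failed=frozenset(failed))


def call_denovo_sample(
    sample_id: str,
    cohort: CohortCounts,
    regions: Sequence[PanelRegion],
    thresholds: DetectionThresholds = DetectionThresholds(),
) -> list[CandidateVariant]:
    """Scan and filter all candidates in one cfDNA sample."""
    patient = patient_of(sample_id)
    buffy = cohort.buffy_sample(patient)
    if buffy is None:
        raise ValueError(f"patient {patient} has no matched buffy coat")
    annotated = []
    for candidate in scan_candidates(cohort.counts_for_sample(sample_id), regions):
        model = cohort.background_for(patient, candidate.variant, k=thresholds.background_k)
        buffy_count = cohort.get(buffy, candidate.variant, "buffy_matched")
        annotated.append(filter_denovo(candidate, buffy_count, model, thresholds))
    return annotated


def call_denovo_cohort(
    cohort: CohortCounts,
    regions: Sequence[PanelRegion],
    thresholds: DetectionThresholds = DetectionThresholds(),
    tumor_variants: Mapping[str, Sequence[VariantKey]] | None = None,
) -> tuple[dict[str, list[CandidateVariant]], list[dict]]:
    """De novo candidates for every cfDNA sample plus a concordance table.

    Returns annotated candidates keyed by sample id, and -- when the known
    tumor variants are supplied -- one concordance row per primary-sample call
    or missed tumor variant, classed as ``concordant``, ``cfdna_only`` or
    ``tumor_only``.
    """
    per_sample: dict[str, list[CandidateVariant]] = {}
    for patient in cohort.patients():
        for sample in cohort.cfdna_samples(patient):
            per_sample[sample] = call_denovo_sample(sample, cohort, regions, thresholds)

    concordance: list[dict] = []
    if tumor_variants is not None:
        for patient in sorted(set(cohort.patients()) | set(tumor_variants)):
            known = list(tumor_variants.get(patient, ()))
            samples = cohort.cfdna_samples(patient)
            primary = samples[0] if samples else None
            calls = [c for c in per_sample.get(primary, ()) if c.called] if primary else []
            called_keys = {c.variant for c in calls}
            for call in calls:
                concordance.append(
                    {
                        "patient_id": patient,
                        "variant": call.variant,
                        "vaf": call.vaf,
                        "class": "concordant" if call.variant in known else "cfdna_only",
                    }
                )
            for variant in known:
                if variant not in called_keys:
                    concordance.append(
                        {"patient_id": patient, "variant": variant, "vaf": None,
                         "class": "tumor_only"}
                    )
    return per_sample, concordance


def write_denovo_vcf(
    calls: Sequence[CandidateVariant],
    path: str | Path,
    models: Mapping[VariantKey, BackgroundModel] | None = None,
    passing_only: bool = True,
) -> None:
    """Write de novo calls as VCF 4.2 with filter annotations and VAF/ALTREADS/BGTHRESH info."""
    header = pysam.VariantHeader()
    for name in FILTER_NAMES:
        header.filters.add(name, None, None, _FILTER_DESCRIPTIONS[name])
    header.info.add("VAF", 1, "Float", "Variant allele frequency in cfDNA")
    header.info.add("ALTREADS", 1, "Integer", "Alt-supporting reads in cfDNA")
    header.info.add("BGTHRESH", 1, "Float", "Unmatched-normal background threshold (mean + k*SD)")
    records = [c for c in calls if c.called] if passing_only else list(calls)
    for chrom in dict.fromkeys(c.variant.chrom for c in records):
        header.contigs.add(chrom)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for cand in records:
            v = cand.variant
            record = out.new_record(
                contig=v.chrom,
                start=v.pos - 1,
                stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, v.alt),
            )
            if cand.filters_failed:
                for name in sorted(cand.filters_failed):
                    record.filter.add(name)
            else:
                record.filter.add("PASS")
            record.info["VAF"] = cand.vaf
            record.info["ALTREADS"] = cand.cfdna_count.alt_reads
            if models and v in models:
                record.info["BGTHRESH"] = models[v].threshold
            out.write(record)
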