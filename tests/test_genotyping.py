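import statistics

import numpy as np
import pytest

from rbliquid.background import build_background
from rbliquid.genotyping import (
    CohortCounts,
    genotype_cohort,
    genotype_variant,
    summarize_detections,
    theoretical_detection_limit,
    truncated_percent,
)
from rbliquid.variants import DetectionThresholds, VariantKey

from conftest import SNV, make_count


def build_model(panel_vafs, k=2.0, depth=6000):
    counts = []
    for i, v in enumerate(panel_vafs):
        alt = round(v * depth)
        assert alt == v * depth, f"panel VAF {v} not exactly representable at depth {depth}"
        counts.append(make_count(alt, depth, sample_id=f"PON{i}-buffy", role="buffy_unmatched"))
    return build_background(SNV, counts, k=k)


def oracle_verdict(alt, depth, artifact, buffy_alt, buffy_depth, panel_vafs, k=2.0):
    """Literal re-statement of the genotyping criteria, independent of the library."""
    cf_vaf = alt / depth if depth else 0.0
    bc_vaf = buffy_alt / buffy_depth if buffy_depth else 0.0
    mean = statistics.mean(panel_vafs)
    sd = statistics.stdev(panel_vafs) if len(panel_vafs) > 1 else 0.0
    crit_a = alt >= 3
    crit_b = cf_vaf > bc_vaf
    crit_c = cf_vaf > mean + k * sd
    artifact_ok = True if alt == 0 else artifact <= 0.5 * alt
    return crit_a and crit_b and crit_c and artifact_ok


CONFIGS = [
    # (buffy_alt, buffy_depth, panel_vafs)
    (0, 1500, [0.0] * 9),
    (5, 1500, [0.0] * 9),
    (0, 0, [0.001, 0.001, 0.001]),
    (2, 1000, [0.0, 0.0, 0.003]),
    (1, 2000, [0.0005] * 9),
]


@pytest.mark.parametrize("buffy_alt, buffy_depth, panel_vafs", CONFIGS)
def test_verdicts_match_exhaustive_enumeration(buffy_alt, buffy_depth, panel_vafs):
    """All (alt, depth) up to depth 30, with artifact extremes, against brute force."""
    model = build_model(panel_vafs)
    buffy = make_count(buffy_alt, buffy_depth, sample_id="P07-buffy", role="buffy_matched")
    for depth in range(0, 31):
        for alt in range(0, depth + 1):
            for artifact in {0, alt // 2, alt}:
                cf = make_count(alt, depth, sample_id="P07-cfdna", artifact=artifact)
                result = genotype_variant(SNV, cf, buffy, model)
                expected = oracle_verdict(
                    alt, depth, artifact, buffy_alt, buffy_depth, panel_vafs
                )
                assert result.detected == expected, (alt, depth, artifact)
                assert result.subthreshold_evidence == (alt >= 1 and not expected)


def test_two_supporting_reads_is_subthreshold_evidence():
    # 2/2286: passes everything except the 3-read floor
    result = genotype_variant(
        SNV,
        make_count(2, 2286, sample_id="P16-cfdna"),
        make_count(0, 1500, sample_id="P16-buffy", role="buffy_matched"),
        build_model([0.0] * 9),
    )
    assert not result.detected
    assert not result.pass_min_reads and result.pass_buffy and result.pass_background
    assert result.subthreshold_evidence


def test_five_reads_pass_the_read_floor():
    result = genotype_variant(
        SNV,
        make_count(5, 5666, sample_id="P16-cfdna"),
        make_count(0, 1500, sample_id="P16-buffy", role="buffy_matched"),
        build_model([0.0] * 9),
    )
    assert result.pass_min_reads and result.detected


def test_clear_positive_is_detected():
    result = genotype_variant(
        SNV,
        make_count(100, 1500, sample_id="P01-cfdna"),
        make_count(0, 1500, sample_id="P01-buffy", role="buffy_matched"),
        build_model([0.0] * 9),
    )
    assert result.detected and result.cfdna_vaf == pytest.approx(100 / 1500)


def test_artifact_majority_forces_not_detected():
    result = genotype_variant(
        SNV,
        make_count(8, 1500, sample_id="P01-cfdna", artifact=5),  # 62.5% flagged
        make_count(0, 1500, sample_id="P01-buffy", role="buffy_matched"),
        build_model([0.0] * 9),
    )
    assert not result.detected and not result.pass_artifact
    # exactly 50% flagged is allowed
    ok = genotype_variant(
        SNV,
        make_count(8, 1500, sample_id="P01-cfdna", artifact=4),
        make_count(0, 1500, sample_id="P01-buffy", role="buffy_matched"),
        build_model([0.0] * 9),
    )
    assert ok.detected


def test_zero_depth_fails_everything_but_artifact():
    result = genotype_variant(
        SNV,
        make_count(0, 0, sample_id="P19-cfdna"),
        make_count(0, 1500, sample_id="P19-buffy", role="buffy_matched"),
        build_model([0.0] * 9),
    )
    assert result.status == "not_detected"
    assert not result.pass_min_reads and not result.pass_buffy and not result.pass_background
    assert result.pass_artifact and not result.subthreshold_evidence


def test_detection_monotone_in_alt_reads():
    buffy = make_count(1, 1500, sample_id="P07-buffy", role="buffy_matched")
    model = build_model([0.0, 0.0, 0.001])
    depth, artifact = 400, 1
    detected_prev = False
    for alt in range(1, depth + 1, 3):
        r = genotype_variant(
            SNV, make_count(alt, depth, sample_id="P07-cfdna", artifact=artifact), buffy, model
        )
        assert not (detected_prev and not r.detected), f"flip at alt={alt}"
        detected_prev = r.detected
    assert detected_prev  # top of the range is clearly positive


def test_mismatched_variant_is_an_error(snv):
    other = VariantKey("chr13", 1, "A", "G")
    with pytest.raises(ValueError, match="does not match"):
        genotype_variant(
            snv,
            make_count(5, 100, variant=other),
            make_count(0, 100, role="buffy_matched"),
            build_model([0.0] * 3),
        )


# ---------------------------------------------------------------------------
# Detection limit


def test_theoretical_detection_limit():
    assert theoretical_detection_limit(3, 1596) == pytest.approx(3 / 1596)
    assert truncated_percent(theoretical_detection_limit(3, 1596)) == "0.18"
    assert theoretical_detection_limit(3, 3) == 1.0
    assert theoretical_detection_limit(10, 2000) == 0.005
    with pytest.raises(ValueError):
        theoretical_detection_limit(3, 0)


# ---------------------------------------------------------------------------
# Cohort genotyping


def variant_at(pos):
    return VariantKey("chr13", pos, "C", "T")


def cohort_counts(patients, depth=1500, alts=None):
    """A minimal cohort: one variant per patient, clean buffy coats."""
    counts = []
    for pid, variant in patients.items():
        alt = (alts or {}).get(pid, 150)
        counts.append(make_count(alt, depth, sample_id=f"{pid}-cfdna", variant=variant))
        for other in patients:  # every buffy coat observed at every site
            counts.append(
                make_count(
                    0, depth, sample_id=f"{other}-buffy", role="buffy_matched", variant=variant
                )
            )
    return CohortCounts(counts)


def test_cohort_all_strong_variants_detected():
    patients = {f"P{i:02d}": variant_at(1000 + i) for i in range(1, 6)}
    cohort = cohort_counts(patients)
    tumor = {pid: [v] for pid, v in patients.items()}
    results, summary = genotype_cohort(tumor, cohort)
    assert summary["mutations_detected"] == summary["mutations_total"] == 5
    assert summary["patients_detected"] == 5
    assert summary["detected_vaf_median"] == pytest.approx(0.1)


def test_missing_pileup_patient_reports_not_detected(caplog):
    patients = {"P01": variant_at(1001), "P02": variant_at(1002)}
    cohort = cohort_counts(patients)
    tumor = {pid: [v] for pid, v in patients.items()}
    tumor["P03"] = [variant_at(1003)]  # absent from the pileups entirely
    with pytest.raises(ValueError, match="buffy"):
        genotype_cohort(tumor, cohort)


def test_summary_counts_primary_sample_only():
    v = variant_at(1001)
    counts = [
        make_count(150, 1500, sample_id="P01-cfdna", variant=v),
        make_count(2, 1500, sample_id="P01-cfdna-rep2", variant=v),  # replicate missed it
        make_count(0, 1500, sample_id="P01-buffy", role="buffy_matched", variant=v),
        make_count(0, 1500, sample_id="P02-buffy", role="buffy_matched", variant=v),
    ]
    cohort = CohortCounts(counts)
    results, summary = genotype_cohort({"P01": [v]}, cohort)
    assert len(results) == 2  # both captures analyzed separately
    assert summary["mutations_detected"] == 1  # but counted once, on the primary
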