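import random

import numpy as np
import pytest
from scipy.stats import hypergeom

from rbliquid.background import build_background
from rbliquid.denovo import (
    CandidateVariant,
    call_denovo_cohort,
    filter_denovo,
    scan_candidates,
    strand_bias_pvalue,
    write_denovo_vcf,
)
from rbliquid.genotyping import CohortCounts, genotype_variant
from rbliquid.simulate import paper_like_fixture, rb1_panel, simulate_cohort
from rbliquid.variants import PanelRegion, VariantKey, read_variants

from conftest import SNV, make_count

EXON = PanelRegion("chr13", SNV.pos - 10, SNV.pos + 10, "exon")


def build_model(panel_vafs, depth=6000, k=2.0):
    counts = []
    for i, v in enumerate(panel_vafs):
        alt = round(v * depth)
        assert alt == v * depth, f"panel VAF {v} not exactly representable at depth {depth}"
        counts.append(make_count(alt, depth, sample_id=f"PON{i}-buffy", role="buffy_unmatched"))
    return build_background(SNV, counts, k=k)


def oracle_fisher(alt_fwd, alt_rev, ref_fwd, ref_rev):
    """Two-sided Fisher exact p by hypergeometric enumeration."""
    n = alt_fwd + alt_rev + ref_fwd + ref_rev
    row = alt_fwd + alt_rev
    col = alt_fwd + ref_fwd
    dist = hypergeom(n, row, col)
    p_obs = dist.pmf(alt_fwd)
    support = range(max(0, row + col - n), min(row, col) + 1)
    return float(sum(dist.pmf(k) for k in support if dist.pmf(k) <= p_obs * (1 + 1e-9)))


def oracle_filters(alt, depth, artifact, fwd, buffy_vaf, panel_vafs):
    """Literal six-filter evaluation, independent of the library path."""
    import statistics

    cf_vaf = alt / depth if depth else 0.0
    failed = set()
    if not cf_vaf > 0.005:
        failed.add("low_vaf")
    if alt < 10:
        failed.add("low_alt_reads")
    if cf_vaf < 2 * buffy_vaf:
        failed.add("buffy_ratio")
    mean = statistics.mean(panel_vafs)
    sd = statistics.stdev(panel_vafs) if len(panel_vafs) > 1 else 0.0
    if not cf_vaf > mean + 2 * sd:
        failed.add("background")
    if alt > 0 and artifact > 0.5 * alt:
        failed.add("artifact")
    rev = alt - fwd
    ref = depth - alt
    if alt >= 10 and min(fwd, rev) == 0:
        if oracle_fisher(fwd, rev, (ref + 1) // 2, ref // 2) < 0.005:
            failed.add("strand_bias")
    return failed


def annotate(alt, depth, artifact=0, fwd=None, buffy_vaf=0.0, panel_vafs=(0.0,) * 9):
    count = make_count(alt, depth, artifact=artifact, fwd=fwd)
    candidate = CandidateVariant(SNV, count, strand_bias_pvalue(count))
    buffy_depth = 2000
    buffy = make_count(
        round(buffy_vaf * buffy_depth), buffy_depth, sample_id="P99-buffy", role="buffy_matched"
    )
    return filter_denovo(candidate, buffy, build_model(list(panel_vafs)))


# ---------------------------------------------------------------------------
# Candidate scanning


def test_scan_keeps_panel_sites_only():
    inside = make_count(15, 1400)
    outside = make_count(
        20, 1400, variant=VariantKey("chr13", SNV.pos + 5000, "G", "A")
    )
    candidates = scan_candidates([inside, outside], [EXON])
    assert [c.variant for c in candidates] == [SNV]


def test_scan_matches_brute_force_row_count():
    rng = np.random.default_rng(7)
    regions = rb1_panel()
    counts = []
    positions = rng.choice(200_000, size=300, replace=False)
    for i, offset in enumerate(positions):
        pos = regions[0].start - 1000 + int(offset)
        depth = int(rng.integers(500, 2000))
        alt = int(rng.integers(0, 5))
        counts.append(
            make_count(alt, depth, variant=VariantKey("chr13", max(pos, 1), "C", "A"))
        )
    expected = sum(
        1
        for c in counts
        if c.alt_reads >= 1
        and any(r.contains(c.variant.chrom, c.variant.pos) for r in regions)
    )
    assert len(scan_candidates(counts, regions)) == expected


def test_scan_order_is_canonical_and_input_order_free():
    counts = [
        make_count(3, 1000, variant=VariantKey("chr13", SNV.pos + 2, "C", "G")),
        make_count(3, 1000, variant=SNV),
        make_count(3, 1000, variant=VariantKey("chr13", SNV.pos, "C", "G")),
    ]
    expected = [(SNV.pos, "G"), (SNV.pos, "T"), (SNV.pos + 2, "G")]
    for seed in range(3):
        random.Random(seed).shuffle(counts)
        got = [(c.variant.pos, c.variant.alt) for c in scan_candidates(counts, [EXON])]
        assert got == expected


# ---------------------------------------------------------------------------
# Filter cascade


def test_filter_grid_matches_brute_force():
    depths = [500, 1000, 2000, 3000]
    buffy_vafs = [0.0, 0.001, 0.004, 0.01, 0.03]
    panels = [(0.0,) * 9, (0.0, 0.0, 0.003), (0.001,) * 3]
    for depth in depths:
        for alt in range(0, 41, 2):
            for buffy_vaf in buffy_vafs:
                for panel in panels:
                    got = annotate(alt, depth, buffy_vaf=buffy_vaf, panel_vafs=panel)
                    expected = oracle_filters(
                        alt, depth, 0, alt // 2, buffy_vaf, list(panel)
                    )
                    assert got.filters_failed == expected, (alt, depth, buffy_vaf, panel)


@pytest.mark.parametrize(
    "alt, depth, failed",
    [
        (10, 1000, set()),  # 1.0% VAF with 10 mutant reads: called
        (9, 1000, {"low_alt_reads"}),  # count floor binds regardless of VAF
        (12, 3000, {"low_vaf"}),  # 0.4% <= 0.5% VAF floor
        (10, 2000, {"low_vaf"}),  # exactly 0.5% fails the strict floor
    ],
)
def test_floor_examples(alt, depth, failed):
    got = annotate(alt, depth)
    assert got.filters_failed == failed
    assert got.called == (not failed)


def test_exact_double_buffy_vaf_passes_ratio():
    # cfDNA at exactly 2x the buffy VAF: "at least 2 times" is inclusive
    got = annotate(20, 1000, buffy_vaf=0.01)  # cf 2.0% vs buffy 1.0%
    assert "buffy_ratio" not in got.filters_failed
    got = annotate(19, 1000, buffy_vaf=0.01)  # 1.9% < 2x
    assert "buffy_ratio" in got.filters_failed


def test_zero_buffy_vaf_never_fails_ratio():
    assert "buffy_ratio" not in annotate(20, 1000, buffy_vaf=0.0).filters_failed


def test_artifact_fraction_filter():
    assert "artifact" in annotate(20, 1000, artifact=11).filters_failed
    assert "artifact" not in annotate(20, 1000, artifact=10).filters_failed


def test_strand_bias_filter_fires_on_one_strand_support_only():
    biased = annotate(15, 1500, fwd=15)
    assert "strand_bias" in biased.filters_failed
    balanced = annotate(15, 1500, fwd=8)
    assert "strand_bias" not in balanced.filters_failed
    few = annotate(5, 1500, fwd=5)  # below the read floor the guard stays quiet
    assert "strand_bias" not in few.filters_failed


def test_strand_bias_p_matches_hypergeometric_oracle():
    for alt, depth, fwd in [(15, 1500, 15), (12, 800, 0), (20, 2000, 10), (4, 100, 1)]:
        count = make_count(alt, depth, fwd=fwd)
        ref = depth - alt
        assert strand_bias_pvalue(count) == pytest.approx(
            oracle_fisher(fwd, alt - fwd, (ref + 1) // 2, ref // 2), rel=1e-6
        )


def test_filter_mismatched_inputs_error():
    count = make_count(15, 1000)
    candidate = CandidateVariant(SNV, count, 1.0)
    other = VariantKey("chr13", 5, "A", "C")
    with pytest.raises(ValueError, match="mismatched"):
        filter_denovo(
            candidate,
            make_count(0, 1000, role="buffy_matched", variant=other),
            build_model([0.0] * 9),
        )


# ---------------------------------------------------------------------------
# Cohort-level calling and the strictness ordering


def test_every_denovo_call_is_also_genotype_detected():
    """The de novo cascade is uniformly stricter than tumor-guided genotyping."""
    truth = paper_like_fixture(include_unexplained=True)
    sim = simulate_cohort(truth, seed=5)
    cohort = CohortCounts(sim.counts)
    per_sample, _ = call_denovo_cohort(cohort, rb1_panel())
    checked = 0
    for sample_id, candidates in per_sample.items():
        patient = sample_id.split("-")[0]
        buffy = cohort.buffy_sample(patient)
        for cand in candidates:
            if not cand.called:
                continue
            model = cohort.background_for(patient, cand.variant, k=2.0)
            result = genotype_variant(
                cand.variant,
                cand.cfdna_count,
                cohort.get(buffy, cand.variant, "buffy_matched"),
                model,
            )
            assert result.detected, (sample_id, cand.variant)
            checked += 1
    assert checked >= 7  # the fixture guarantees real calls were exercised


def test_denovo_vcf_round_trips_through_the_variant_reader(tmp_path):
    variants = [
        VariantKey("chr13", SNV.pos, "C", "T"),
        VariantKey("chr13", SNV.pos + 3, "G", "GA"),
    ]
    calls = []
    for v in variants:
        count = make_count(25, 1200, variant=v)
        calls.append(CandidateVariant(v, count, strand_bias_pvalue(count)))
    path = tmp_path / "calls.vcf"
    write_denovo_vcf(calls, path)
    assert read_variants(path) == variants
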