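"""End-to-end orchestration: dataset layout, configuration, reports.

A dataset directory (as written by :func:`run_simulate`) contains::

    pileups.tsv        all samples' allele counts (pileup dialect)
    panel.bed          targeted capture regions
    tumor/<PID>.vcf    per-patient tumor mutation lists
    truth.json         generator ground truth (synthetic datasets only)

``run_genotype`` and ``run_denovo`` consume such a directory and write report
bundles; ``run_score`` compares reports against the truth. Every run echoes
its effective configuration into the output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import denovo as denovo_mod
from .genotyping import (
    CohortCounts,
    DetectionResult,
    genotype_cohort,
    summarize_detections,
)
from .germline import GermlineCall, GermlineRule, classify_germline, filter_germline
from .simulate import CohortTruth, SimulatedCohort, paper_like_fixture, rb1_panel, score_pipeline, simulate_cohort
from .variants import (
    DetectionThresholds,
    read_panel_bed,
    read_pileup_table,
    read_variants,
    write_panel_bed,
    write_pileup_table,
    write_variants,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Serializable run configuration; all thresholds live here, none hard-coded."""

    data_dir: str = "."
    out_dir: str = "out"
    seed: int = 13
    replicate_handling: str = "separate"  # or "merged": sum replicate counts
    thresholds: DetectionThresholds = field(default_factory=DetectionThresholds)
    germline_rule: GermlineRule = field(default_factory=GermlineRule)

    def __post_init__(self) -> None:
        if self.replicate_handling not in ("separate", "merged"):
            raise ValueError("replicate_handling must be 'separate' or 'merged'")

    def to_dict(self) -> dict:
        return {
            "data_dir": str(self.data_dir),
            "out_dir": str(self.out_dir),
            "seed": self.seed,
            "replicate_handling": self.replicate_handling,
            "thresholds": dataclasses.asdict(self.thresholds),
            "germline_rule": dataclasses.asdict(self.germline_rule),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return cls(
            data_dir=data.get("data_dir", "."),
            out_dir=data.get("out_dir", "out"),
            seed=data.get("seed", 13),
            replicate_handling=data.get("replicate_handling", "separate"),
            thresholds=DetectionThresholds(**data.get("thresholds", {})),
            germline_rule=GermlineRule(**data.get("germline_rule", {})),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle) or {})

    def echo(self, out_dir: Path) -> None:
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "config.yaml", "w") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=False)


# ---------------------------------------------------------------------------
# Dataset IO


def write_dataset(sim: SimulatedCohort, out_dir: str | Path) -> Path:
    """Write a simulated cohort as a dataset directory (deterministic layout)."""
    out = Path(out_dir)
    (out / "tumor").mkdir(parents=True, exist_ok=True)
    write_pileup_table(sim.counts, out / "pileups.tsv")
    write_panel_bed(rb1_panel(), out / "panel.bed")
    for patient_id, variants in sorted(sim.tumor_variants.items()):
        write_variants(variants, out / "tumor" / f"{patient_id}.vcf")
    sim.truth.to_json(out / "truth.json")
    return out


@dataclass
class Dataset:
    cohort: CohortCounts
    tumor_variants: dict
    regions: list
    truth: CohortTruth | None


def load_dataset(data_dir: str | Path, replicate_handling: str = "separate") -> Dataset:
    data = Path(data_dir)
    pileup_path = data / "pileups.tsv"
    if not pileup_path.exists():
        raise FileNotFoundError(f"missing pileup table: {pileup_path}")
    counts = read_pileup_table(pileup_path)
    if replicate_handling == "merged":
        counts = merge_replicates(counts)
    tumor_dir = data / "tumor"
    tumor_variants = {}
    if tumor_dir.is_dir():
        for vcf in sorted(tumor_dir.glob("*.vcf")):
            tumor_variants[vcf.stem] = read_variants(vcf)
    panel_path = data / "panel.bed"
    regions = read_panel_bed(panel_path) if panel_path.exists() else []
    truth_path = data / "truth.json"
    truth = CohortTruth.from_json(truth_path) if truth_path.exists() else None
    return Dataset(CohortCounts(counts), tumor_variants, regions, truth)


def merge_replicates(counts):
    """Sum technical-replicate cfDNA counts into the patient's primary sample."""
    from .variants import AlleleCount
    from .genotyping import patient_of

    merged: dict[tuple[str, object], AlleleCount] = {}
    for c in counts:
        sid = c.sample_id
        if c.role == "cfdna":
            sid = f"{patient_of(sid)}-cfdna"
        key = (sid, c.variant)
        if key in merged:
            prev = merged[key]
            merged[key] = AlleleCount(
                variant=c.variant,
                sample_id=sid,
                role=c.role,
                depth=prev.depth + c.depth,
                alt_reads=prev.alt_reads + c.alt_reads,
                alt_artifact_reads=prev.alt_artifact_reads + c.alt_artifact_reads,
                alt_fwd=prev.alt_fwd + c.alt_fwd,
                alt_rev=prev.alt_rev + c.alt_rev,
            )
        else:
            merged[key] = dataclasses.replace(c, sample_id=sid)
    return list(merged.values())


# ---------------------------------------------------------------------------
# Subcommand bodies


def run_simulate(
    out_dir: str | Path,
    seed: int | None = None,
    truth: CohortTruth | None = None,
    paper_like: bool = False,
    include_unexplained: bool = False,
) -> Path:
    """Generate a dataset directory from a truth (or the study-like fixture)."""
    if truth is None:
        if not paper_like:
            raise ValueError("provide a truth JSON or pass paper_like=True")
        truth = paper_like_fixture(include_unexplained=include_unexplained)
    sim = simulate_cohort(truth, seed=seed)
    return write_dataset(sim, out_dir)


def _results_frame(results: list[DetectionResult], verdicts: dict) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "patient_id": r.patient_id,
                "sample_id": r.sample_id,
                "chrom": r.variant.chrom,
                "pos": r.variant.pos,
                "ref": r.variant.ref,
                "alt": r.variant.alt,
                "label": r.variant.label or "",
                "track": r.track,
                "cfdna_vaf": r.cfdna_vaf,
                "buffy_vaf": r.buffy_vaf,
                "background_threshold": r.background_threshold,
                "pass_min_reads": r.pass_min_reads,
                "pass_buffy": r.pass_buffy,
                "pass_background": r.pass_background,
                "pass_artifact": r.pass_artifact,
                "status": r.status,
                "subthreshold_evidence": r.subthreshold_evidence,
                "germline_verdict": verdicts.get((r.patient_id, r.variant), "somatic"),
            }
        )
    return pd.DataFrame(rows)


def _classify_tumor_variants(ds: Dataset, rule: GermlineRule) -> list[GermlineCall]:
    """Germline/somatic calls for every known tumor variant with a matched buffy."""
    calls: list[GermlineCall] = []
    for patient_id, variants in sorted(ds.tumor_variants.items()):
        buffy = ds.cohort.buffy_sample(patient_id)
        cf_samples = ds.cohort.cfdna_samples(patient_id)
        if buffy is None or not cf_samples:
            continue
        for variant in variants:
            calls.append(
                classify_germline(
                    variant,
                    ds.cohort.get(buffy, variant, "buffy_matched"),
                    ds.cohort.get(cf_samples[0], variant, "cfdna"),
                    rule=rule,
                    patient_id=patient_id,
                )
            )
    return calls


def run_genotype(config: RunConfig) -> dict:
    """Tumor-guided genotyping over a dataset; writes the report bundle.

    Outputs: ``detections.tsv`` (every result, with per-criterion booleans and
    germline verdicts), ``summary.json`` (cohort counts over the somatic
    report), ``germline.tsv``, ``background.tsv``.
    """
    out = Path(config.out_dir)
    ds = load_dataset(config.data_dir, config.replicate_handling)
    config.echo(out)
    results, _ = genotype_cohort(ds.tumor_variants, ds.cohort, config.thresholds)

    calls = _classify_tumor_variants(ds, config.germline_rule)
    reported, excluded, verdicts = filter_germline(results, calls)
    summary = summarize_detections(reported)
    summary["germline_excluded"] = len({(r.patient_id, r.variant) for r in excluded})
    summary["ambiguous_flagged"] = sorted(
        {f"{pid}:{v}" for (pid, v), verdict in verdicts.items() if verdict == "ambiguous"}
    )

    _results_frame(results, verdicts).to_csv(out / "detections.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "patient_id": c.patient_id,
                "chrom": c.variant.chrom,
                "pos": c.variant.pos,
                "ref": c.variant.ref,
                "alt": c.variant.alt,
                "buffy_vaf": c.buffy_vaf,
                "cfdna_vaf": c.cfdna_vaf,
                "binomial_p": c.binomial_p,
                "verdict": c.verdict,
            }
            for c in calls
        ]
    ).to_csv(out / "germline.tsv", sep="\t", index=False)

    bg_rows = []
    for patient_id, variants in sorted(ds.tumor_variants.items()):
        for variant in variants:
            model = ds.cohort.background_for(patient_id, variant, config.thresholds.background_k)
            bg_rows.append(
                {
                    "patient_id": patient_id,
                    "chrom": variant.chrom,
                    "pos": variant.pos,
                    "ref": variant.ref,
                    "alt": variant.alt,
                    "n_panel": model.n_panel,
                    "mean_vaf": model.mean_vaf,
                    "sd_vaf": model.sd_vaf,
                    "threshold": model.threshold,
                }
            )
    pd.DataFrame(bg_rows).to_csv(out / "background.tsv", sep="\t", index=False)
    with open(out / "summary.json", "w") as handle:
        json.dump(summary, handle, indent=1)
    logger.info(
        "genotyping: %s/%s mutations detected in %s/%s patients",
        summary["mutations_detected"], summary["mutations_total"],
        summary["patients_detected"], summary["patients_total"],
    )
    return summary


def run_denovo(config: RunConfig) -> dict:
    """De novo calling over a dataset; writes per-patient VCFs + concordance table."""
    out = Path(config.out_dir)
    ds = load_dataset(config.data_dir, config.replicate_handling)
    config.echo(out)
    if not ds.regions:
        raise FileNotFoundError(f"missing panel.bed in {config.data_dir}")
    per_sample, concordance = denovo_mod.call_denovo_cohort(
        ds.cohort, ds.regions, config.thresholds, tumor_variants=ds.tumor_variants
    )
    # Germline variants are filtered from the somatic comparison: a known
    # heterozygote missed by the somatic caller is not a missed somatic mutation.
    germline_keys = {
        (c.patient_id, c.variant)
        for c in _classify_tumor_variants(ds, config.germline_rule)
        if c.verdict == "germline"
    }
    concordance = [
        row for row in concordance
        if (row["patient_id"], row["variant"]) not in germline_keys
    ]
    vcf_dir = out / "denovo"
    vcf_dir.mkdir(parents=True, exist_ok=True)
    for sample_id, candidates in sorted(per_sample.items()):
        for cand in candidates:
            if not cand.called:
                logger.info(
                    "%s: %s filtered by %s", sample_id, cand.variant,
                    ",".join(sorted(cand.filters_failed)),
                )
        models = {
            c.variant: ds.cohort.background_for(
                sample_id.split("-")[0], c.variant, config.thresholds.background_k
            )
            for c in candidates
        }
        denovo_mod.write_denovo_vcf(candidates, vcf_dir / f"{sample_id}.vcf", models=models)

    pd.DataFrame(
        [
            {
                "patient_id": row["patient_id"],
                "chrom": row["variant"].chrom,
                "pos": row["variant"].pos,
                "ref": row["variant"].ref,
                "alt": row["variant"].alt,
                "vaf": row["vaf"],
                "class": row["class"],
            }
            for row in concordance
        ]
    ).to_csv(out / "concordance.tsv", sep="\t", index=False)

    primary_calls = {
        s: [c for c in cands if c.called]
        for s, cands in per_sample.items()
        if s.endswith("-cfdna")
    }
    called_pv = {
        (s.split("-")[0], c.variant) for s, cands in primary_calls.items() for c in cands
    }
    concordant = [r for r in concordance if r["class"] == "concordant"]
    summary = {
        "mutations_called": len(concordant),
        "mutations_expected": len(concordant)
        + sum(1 for r in concordance if r["class"] == "tumor_only"),
        "patients_with_call": len({pid for pid, _ in called_pv}),
        "patients_total": len(ds.cohort.patients()),
        "cfdna_only_calls": sum(1 for r in concordance if r["class"] == "cfdna_only"),
    }
    with open(out / "denovo_summary.json", "w") as handle:
        json.dump(summary, handle, indent=1)
    logger.info(
        "de novo: %s/%s known mutations called in %s/%s patients (%s cfDNA-only)",
        summary["mutations_called"], summary["mutations_expected"],
        summary["patients_with_call"], summary["patients_total"],
        summary["cfdna_only_calls"],
    )
    return summary


def run_score(config: RunConfig) -> dict:
    """Re-run both tracks in memory and score them against the dataset truth."""
    ds = load_dataset(config.data_dir, config.replicate_handling)
    if ds.truth is None:
        raise FileNotFoundError(f"no truth.json in {config.data_dir}; cannot score")
    results, _ = genotype_cohort(ds.tumor_variants, ds.cohort, config.thresholds)
    per_sample, _ = denovo_mod.call_denovo_cohort(
        ds.cohort, ds.regions, config.thresholds, tumor_variants=ds.tumor_variants
    )
    metrics = score_pipeline(ds.truth, results, denovo_calls=per_sample)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "score.json", "w") as handle:
        json.dump(metrics, handle, indent=1)
    return metrics
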