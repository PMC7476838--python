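"""Synthetic cohorts with the statistical structure the detection method assumes.

The generator produces per-patient tumor variant lists, matched buffy coats,
and plasma cfDNA allele counts at every variant site, at the count level:
depth is drawn from a (mildly overdispersed) negative binomial around the
sample's mean unique coverage, alt reads from Binomial(depth, q) with
q = v*(1-3e) + (1-v)*e for a true variant fraction v and per-allele error e,
strands split Binomial(alt, 1/2), and artifact flags applied to error-origin
reads only. Error hotspots (elevated per-site error), artifact-prone sites,
per-library error multipliers and strand-locked artifact loci can be seeded
per variant to exercise every filter in the cascade. Ground truth is retained
for scoring sensitivity, specificity, VAF recovery and technical-replicate
concordance.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import pearsonr

from .genotyping import DetectionResult
from .variants import AlleleCount, PanelRegion, VariantKey

SEEDED_BELOW = ("none", "genotyping_floor", "background", "artifact")


@dataclass(frozen=True)
class TruthVariant:
    """Ground truth for one variant in one patient.

    ``site_error_rate`` (per-allele) overrides the cohort base error at this
    locus in every sample, modelling an error hotspot; ``site_artifact_rate``
    overrides the flagging probability for error-origin reads there.
    ``seeded_below`` records, for bookkeeping, which detection criterion the
    variant was constructed to fail. ``in_tumor`` is False for spike-ins that
    the tumor assay did not report (plasma-only variants of unknown origin).
    """

    variant: VariantKey
    true_cfdna_vaf: float
    is_germline: bool = False
    seeded_below: str = "none"
    site_error_rate: float | None = None
    site_artifact_rate: float | None = None
    strand_biased: bool = False
    in_tumor: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_cfdna_vaf <= 1.0:
            raise ValueError(f"true_cfdna_vaf out of [0,1]: {self.true_cfdna_vaf}")
        if self.is_germline and self.true_cfdna_vaf != 0.5:
            raise ValueError("germline variants must have true VAF 0.5")
        if self.seeded_below not in SEEDED_BELOW:
            raise ValueError(f"unknown seeded_below {self.seeded_below!r}")


@dataclass(frozen=True)
class TruthPatient:
    patient_id: str
    variants: tuple[TruthVariant, ...]
    cfdna_depth_mean: float | None = None  # cohort default when None
    error_multiplier: float = 1.0  # per-library error-rate scaling
    replicate: bool = False  # emit a second, independent cfDNA capture

    def __post_init__(self) -> None:
        if self.error_multiplier <= 0:
            raise ValueError("error_multiplier must be positive")


@dataclass(frozen=True)
class CohortTruth:
    """Full generative description of a cohort plus the master seed."""

    patients: tuple[TruthPatient, ...]
    error_rate: float = 5e-4  # per-base substitution error (any alt)
    depth_mean: float = 1530.0  # average unique coverage
    depth_dispersion: float | None = 200.0  # NB size; None = constant depth
    artifact_rate: float = 0.05  # P(flag | error-origin alt read)
    seed: int = 13

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate out of range")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if not 0 <= self.artifact_rate <= 1:
            raise ValueError("artifact_rate out of [0,1]")
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate patient ids")

    @property
    def n_unmatched_panel(self) -> int:
        """Panel size seen by each patient: every other patient's buffy coat."""
        return max(len(self.patients) - 1, 0)

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            json.dump(self.to_dict(), handle, indent=1)

    @classmethod
    def from_dict(cls, data: Mapping) -> "CohortTruth":
        patients = tuple(
            TruthPatient(
                patient_id=p["patient_id"],
                variants=tuple(
                    TruthVariant(variant=VariantKey(**tv.pop("variant")), **tv)
                    for tv in [dict(v) for v in p["variants"]]
                ),
                cfdna_depth_mean=p.get("cfdna_depth_mean"),
                error_multiplier=p.get("error_multiplier", 1.0),
                replicate=p.get("replicate", False),
            )
            for p in data["patients"]
        )
        return cls(
            patients=patients,
            error_rate=data["error_rate"],
            depth_mean=data["depth_mean"],
            depth_dispersion=data["depth_dispersion"],
            artifact_rate=data["artifact_rate"],
            seed=data["seed"],
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortTruth":
        with open(path) as handle:
            return cls.from_dict(json.load(handle))


@dataclass(frozen=True)
class SimulatedCohort:
    truth: CohortTruth
    counts: tuple[AlleleCount, ...]
    tumor_variants: dict[str, list[VariantKey]]
    seed: int


def _draw_depth(rng: np.random.Generator, mean: float, dispersion: float | None) -> int:
    if dispersion is None:
        return int(round(mean))
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def simulate_cohort(truth: CohortTruth, seed: int | None = None) -> SimulatedCohort:
    """Draw one cohort's pileup counts and tumor variant lists from the truth.

    Every sample (cfDNA, optional technical replicate, buffy coat) receives a
    row at every variant site in the cohort, so backgrounds and de novo scans
    see the full site-by-sample grid. Deterministic given (truth, seed); the
    truth's own seed is used when none is passed.
    """
    used_seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(used_seed)
    sites: list[tuple[str, TruthVariant]] = [
        (patient.patient_id, tv) for patient in truth.patients for tv in patient.variants
    ]
    seen = set()
    for owner, tv in sites:
        if tv.variant in seen:
            raise ValueError(f"variant {tv.variant} seeded in more than one patient")
        seen.add(tv.variant)

    counts: list[AlleleCount] = []
    for patient in truth.patients:
        pid = patient.patient_id
        cf_mean = patient.cfdna_depth_mean or truth.depth_mean
        samples = [(f"{pid}-cfdna", "cfdna", cf_mean)]
        if patient.replicate:
            samples.append((f"{pid}-cfdna-rep2", "cfdna", cf_mean))
        samples.append((f"{pid}-buffy", "buffy_matched", truth.depth_mean))
        for sample_id, role, depth_mean in samples:
            for owner, tv in sites:
                if owner == pid:
                    if tv.is_germline:
                        v = 0.5
                    else:
                        v = 0.0 if role == "buffy_matched" else tv.true_cfdna_vaf
                else:
                    v = 0.0
                e_allele = (
                    tv.site_error_rate if tv.site_error_rate is not None
                    else truth.error_rate / 3.0
                ) * patient.error_multiplier
                q = min(max(v * (1.0 - 3.0 * e_allele) + (1.0 - v) * e_allele, 0.0), 1.0)
                depth = _draw_depth(rng, depth_mean, truth.depth_dispersion)
                alt = int(rng.binomial(depth, q)) if depth > 0 else 0
                err_share = ((1.0 - v) * e_allele / q) if q > 0 else 0.0
                n_error = int(rng.binomial(alt, min(err_share, 1.0)))
                art_rate = (
                    tv.site_artifact_rate if tv.site_artifact_rate is not None
                    else truth.artifact_rate
                )
                artifact = int(rng.binomial(n_error, art_rate))
                fwd = alt if tv.strand_biased else int(rng.binomial(alt, 0.5))
                counts.append(
                    AlleleCount(
                        variant=tv.variant,
                        sample_id=sample_id,
                        role=role,
                        depth=depth,
                        alt_reads=alt,
                        alt_artifact_reads=artifact,
                        alt_fwd=fwd,
                        alt_rev=alt - fwd,
                    )
                )
    tumor = {
        patient.patient_id: [tv.variant for tv in patient.variants if tv.in_tumor]
        for patient in truth.patients
    }
    return SimulatedCohort(truth=truth, counts=tuple(counts), tumor_variants=tumor, seed=used_seed)


# ---------------------------------------------------------------------------
# The versioned study-like fixture


_RB1_PANEL_START = 48_877_882  # synthetic approximation of the RB1 locus (chr13)


def rb1_panel() -> list[PanelRegion]:
    """A 27-exon targeted panel on chr13 (synthetic exon coordinates).

    Interval sizes and spacing approximate a capture design over the RB1 gene
    body; they are versioned constants, not the true annotation.
    """
    regions = []
    for i in range(27):
        start = _RB1_PANEL_START + i * 6_610
        length = 120 + (i * 53) % 180
        regions.append(PanelRegion("chr13", start, start + length, f"RB1_exon_{i + 1:02d}"))
    return regions


def _exon_pos(exon_index: int, offset: int = 50) -> int:
    """1-based position ``offset`` bases into a panel exon (0-based index)."""
    return _RB1_PANEL_START + exon_index * 6_610 + offset


def paper_like_fixture(include_unexplained: bool = False) -> CohortTruth:
    """A fixed 10-patient cohort truth emulating the published study design.

    13 somatic mutations across 10 patients. Ten are seeded detectable by
    tumor-guided genotyping (8 patients), of which exactly seven also clear
    the stricter de novo floors; the remaining three sit at 0.26-0.30% true
    VAF under ~7000x coverage, robustly genotypable yet robustly below the
    0.5% de novo VAF floor. One patient (P16 analogue) carries two variants
    seeded below the detection threshold -- an error hotspot that fails the
    background null and an artifact-dominated locus -- leaving subthreshold
    evidence only. One patient (P19 analogue, treated with chemotherapy before
    blood draw) sheds nothing: true plasma VAF 0. P01 additionally carries a
    germline heterozygote next to its somatic hit. Five patients have
    technical replicates for concordance analysis. Median detectable VAF is
    0.049. With ``include_unexplained`` two plasma-only spike-ins of unknown
    origin (1.56% and 0.99% VAF, absent from the tumor lists) are added.

    Every constant here is versioned: repeated calls are identical.
    """
    V = VariantKey
    patients = [
        TruthPatient(
            "P01",
            variants=(
                TruthVariant(V("chr13", _exon_pos(2), "C", "T", label="p.R255*"), 0.012),
                TruthVariant(
                    V("chr13", _exon_pos(16), "C", "T", label="p.R661W"), 0.5, is_germline=True
                ),
            ),
            cfdna_depth_mean=2500.0,
        ),
        TruthPatient(
            "P10",
            variants=(
                TruthVariant(V("chr13", _exon_pos(7), "C", "A", label="p.Q217*"), 0.126),
                TruthVariant(V("chr13", _exon_pos(13), "G", "T", label="p.R455*"), 0.048),
            ),
            replicate=True,
            error_multiplier=1.05,
        ),
        TruthPatient(
            "P12",
            variants=(TruthVariant(V("chr13", _exon_pos(9), "C", "T", label="p.R320*"), 0.10),),
            replicate=True,
            error_multiplier=0.95,
        ),
        TruthPatient(
            "P14",
            variants=(TruthVariant(V("chr13", _exon_pos(17), "G", "A", label="p.E748*"), 0.08),),
            replicate=True,
            error_multiplier=1.1,
        ),
        TruthPatient(
            "P16",
            variants=(
                TruthVariant(
                    V("chr13", _exon_pos(20), "C", "T", label="p.Q736*"),
                    0.0002,
                    seeded_below="background",
                    site_error_rate=0.0015,
                ),
                TruthVariant(
                    V("chr13", _exon_pos(18), "G", "A", label="X702_splice"),
                    0.0,
                    seeded_below="artifact",
                    site_error_rate=0.001,
                    site_artifact_rate=0.9,
                ),
            ),
            cfdna_depth_mean=4000.0,
            error_multiplier=0.7,
        ),
        TruthPatient(
            "P19",
            variants=(TruthVariant(V("chr13", _exon_pos(8), "G", "T", label="p.W99*"), 0.0),),
            cfdna_depth_mean=1596.0,
            error_multiplier=1.05,
        ),
        TruthPatient(
            "P22",
            variants=(TruthVariant(V("chr13", _exon_pos(19), "C", "G", label="p.R787*"), 0.065),)
            + (
                (
                    TruthVariant(
                        V("chr13", _exon_pos(4), "G", "A", label="p.G509E"),
                        0.0156,
                        in_tumor=False,
                    ),
                )
                if include_unexplained
                else ()
            ),
            replicate=True,
            error_multiplier=1.2,
        ),
        TruthPatient(
            "P24",
            variants=(TruthVariant(V("chr13", _exon_pos(10), "A", "T", label="p.E323*"), 0.050),),
            replicate=True,
            error_multiplier=0.9,
        ),
        TruthPatient(
            "P26",
            variants=(
                TruthVariant(V("chr13", _exon_pos(1), "C", "T", label="p.Q35*"), 0.0026),
                TruthVariant(V("chr13", _exon_pos(21), "A", "G", label="c.2325+2A>G"), 0.0028),
            )
            + (
                (
                    TruthVariant(
                        V("chr13", _exon_pos(15), "C", "A", label="p.P781Q"),
                        0.0099,
                        in_tumor=False,
                    ),
                )
                if include_unexplained
                else ()
            ),
            cfdna_depth_mean=7000.0,
        ),
        TruthPatient(
            "P28",
            variants=(TruthVariant(V("chr13", _exon_pos(5), "G", "C", label="p.L128*"), 0.0030),),
            cfdna_depth_mean=7000.0,
            error_multiplier=1.15,
        ),
    ]
    return CohortTruth(patients=tuple(patients), seed=13)


# ---------------------------------------------------------------------------
# Scoring against ground truth


def score_pipeline(
    truth: CohortTruth,
    results: Sequence[DetectionResult],
    denovo_calls: Mapping[str, Sequence] | None = None,
) -> dict:
    """Score pipeline output against the truth it was generated from.

    Sensitivity/specificity are computed over somatic truth records on primary
    samples; VAF recovery (bias and mean absolute error) over detected true
    positives; replicate concordance as Pearson r-squared on VAF pairs of
    variants detected in both technical replicates.
    """
    truth_map = {
        (p.patient_id, tv.variant): tv for p in truth.patients for tv in p.variants
    }
    patient_ids = {p.patient_id for p in truth.patients}
    for result in results:
        if result.patient_id not in patient_ids:
            raise ValueError(f"result patient {result.patient_id} not in truth cohort")

    by_pv: dict[tuple[str, VariantKey], list[DetectionResult]] = {}
    for result in results:
        by_pv.setdefault((result.patient_id, result.variant), []).append(result)
    for group in by_pv.values():
        group.sort(key=lambda r: r.sample_id)

    tp = fp = fn = tn = 0
    errors: list[float] = []
    pairs: list[tuple[float, float]] = []
    for (pid, variant), group in by_pv.items():
        tv = truth_map.get((pid, variant))
        if tv is None or tv.is_germline:
            continue
        primary = group[0]
        positive = tv.true_cfdna_vaf > 0
        if primary.detected:
            if positive:
                tp += 1
                errors.append(primary.cfdna_vaf - tv.true_cfdna_vaf)
            else:
                fp += 1
        else:
            if positive:
                fn += 1
            else:
                tn += 1
        if len(group) >= 2 and group[0].detected and group[1].detected:
            pairs.append((group[0].cfdna_vaf, group[1].cfdna_vaf))

    metrics: dict = {
        "n_true_positive_sites": tp + fn,
        "n_true_negative_sites": fp + tn,
        "sensitivity": tp / (tp + fn) if tp + fn else None,
        "specificity": tn / (tn + fp) if tn + fp else None,
        "vaf_bias": float(np.mean(errors)) if errors else None,
        "vaf_mae": float(np.mean(np.abs(errors))) if errors else None,
        "n_replicate_pairs": len(pairs),
        "replicate_r2": None,
    }
    if len(pairs) >= 2:
        x, y = zip(*pairs)
        if np.std(x) > 0 and np.std(y) > 0:
            metrics["replicate_r2"] = float(pearsonr(x, y).statistic ** 2)

    if denovo_calls is not None:
        called: set[tuple[str, VariantKey]] = set()
        cfdna_only = 0
        for sample_id, candidates in denovo_calls.items():
            pid = sample_id.split("-")[0]
            if not sample_id.endswith("-cfdna"):
                continue  # primary captures only
            for cand in candidates:
                if not cand.called:
                    continue
                tv = truth_map.get((pid, cand.variant))
                if tv is not None and not tv.is_germline and tv.in_tumor:
                    called.add((pid, cand.variant))
                else:
                    cfdna_only += 1
        expected = [
            (p.patient_id, tv)
            for p in truth.patients
            for tv in p.variants
            if not tv.is_germline and tv.in_tumor and tv.true_cfdna_vaf > 0
        ]
        metrics["denovo_sensitivity"] = (
            len(called) / len(expected) if expected else None
        )
        metrics["denovo_concordant_calls"] = len(called)
        metrics["denovo_cfdna_only_calls"] = cfdna_only
    return metrics
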