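"""Core data types and readers/writers for variants, panel regions and allele counts.

Coordinate conventions: :class:`VariantKey` is 1-based (VCF); :class:`PanelRegion`
is 0-based half-open (BED). All conversions between the two live in this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

_DNA = frozenset("ACGT")

#: Column order of the pileup table dialect.
PILEUP_COLUMNS = (
    "sample_id",
    "role",
    "chrom",
    "pos",
    "ref",
    "alt",
    "depth",
    "alt_reads",
    "alt_artifact_reads",
    "alt_fwd",
    "alt_rev",
)

#: Valid values of the pileup ``role`` column. A buffy coat row is
#: ``buffy_matched`` relative to its own patient; ``buffy_unmatched`` marks
#: normals from donors outside the cohort that only ever serve in the
#: background panel.
ROLES = frozenset({"cfdna", "buffy_matched", "buffy_unmatched", "tumor"})


class PileupFormatError(ValueError):
    """Raised when a pileup table violates the dialect or its invariants."""


class VcfFormatError(ValueError):
    """Raised when a variant file cannot be parsed."""


def normalize_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim shared leading/trailing bases so the allele pair is parsimonious.

    Trailing bases are removed first, then leading bases (advancing ``pos``),
    always keeping at least one base on each allele so indels retain their
    anchor. The operation is idempotent. Full left-alignment through repeat
    tracts would additionally need the reference sequence, which this pipeline
    deliberately does not require; trimming is sufficient for the targeted
    panel, where each variant is observed at a single reported locus.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


@dataclass(frozen=True, order=True)
class VariantKey:
    """A normalized genomic variant; identity is (chrom, pos, ref, alt).

    ``label`` carries an optional human-readable annotation such as a protein
    change ("p.Q736*") or splice notation; it never participates in equality.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    label: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if set(self.ref) - _DNA or set(self.alt) - _DNA:
            raise ValueError(f"alleles must be uppercase A/C/G/T: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if normalize_alleles(self.pos, self.ref, self.alt) != (self.pos, self.ref, self.alt):
            raise ValueError(
                f"alleles not parsimonious: {self.chrom}:{self.pos} {self.ref}>{self.alt}"
            )

    @classmethod
    def build(cls, chrom: str, pos: int, ref: str, alt: str, label: str | None = None) -> "VariantKey":
        """Construct a key, normalizing the allele representation first."""
        pos, ref, alt = normalize_alleles(pos, ref.upper(), alt.upper())
        return cls(chrom, pos, ref, alt, label)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        tag = f" ({self.label})" if self.label else ""
        return f"{self.chrom}:{self.pos} {self.ref}>{self.alt}{tag}"


@dataclass(frozen=True, order=True)
class PanelRegion:
    """A targeted-capture interval in BED coordinates (0-based half-open)."""

    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid region {self.chrom}:{self.start}-{self.end}")

    def contains(self, chrom: str, pos: int) -> bool:
        """Whether a 1-based position falls inside this region."""
        return chrom == self.chrom and self.start < pos <= self.end


def merge_regions(regions: Iterable[PanelRegion]) -> list[PanelRegion]:
    """Sort and merge overlapping/adjacent regions per chromosome."""
    merged: list[PanelRegion] = []
    for region in sorted(regions):
        if merged and region.chrom == merged[-1].chrom and region.start <= merged[-1].end:
            prev = merged.pop()
            merged.append(
                PanelRegion(prev.chrom, prev.start, max(prev.end, region.end), prev.name)
            )
        else:
            merged.append(region)
    return merged


@dataclass(frozen=True)
class AlleleCount:
    """Per-sample read-count observation at one variant.

    ``depth`` counts qualifying reads only; the pileup producer (the synthetic
    generator, or an adapter from aligned reads) is responsible for any
    base-/mapping-quality floors and duplicate removal, so counts here are
    taken as given. ``alt_artifact_reads`` counts alt-supporting reads flagged
    as likely technical artifacts by the producer.
    """

    variant: VariantKey
    sample_id: str
    role: str
    depth: int
    alt_reads: int
    alt_artifact_reads: int = 0
    alt_fwd: int = 0
    alt_rev: int = 0

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for sample {self.sample_id}")
        if self.depth < 0 or self.alt_reads < 0 or self.alt_artifact_reads < 0:
            raise ValueError("counts must be non-negative")
        if self.alt_reads > self.depth:
            raise ValueError(
                f"alt_reads {self.alt_reads} > depth {self.depth} "
                f"({self.sample_id} @ {self.variant})"
            )
        if self.alt_artifact_reads > self.alt_reads:
            raise ValueError("alt_artifact_reads exceeds alt_reads")
        if self.alt_fwd < 0 or self.alt_rev < 0 or self.alt_fwd + self.alt_rev != self.alt_reads:
            raise ValueError("alt_fwd + alt_rev must equal alt_reads")

    @property
    def vaf(self) -> float:
        return vaf(self)


def vaf(count: AlleleCount) -> float:
    """Variant allele frequency: alt reads over depth; 0 at zero depth.

    Zero depth maps to VAF 0 (not NaN) so that every downstream strict
    inequality fails naturally -- an uncovered site can never be detected.
    """
    if count.depth == 0:
        return 0.0
    return count.alt_reads / count.depth


def zero_count(variant: VariantKey, sample_id: str, role: str) -> AlleleCount:
    """A depth-0 placeholder for a sample with no observation at a site."""
    return AlleleCount(variant, sample_id, role, 0, 0, 0, 0, 0)


@dataclass(frozen=True)
class DetectionThresholds:
    """All numeric criteria used by the two detection tracks.

    Defaults are the published criteria: >=3 supporting reads for genotyping a
    known tumor mutation; background threshold at the unmatched-panel mean VAF
    plus 2 SD; de novo floors of VAF > 0.5% with >=10 mutant reads and cfDNA
    VAF at least 2x the matched buffy coat; calls with more than 50% of alt
    reads flagged as artifact are rejected. The strand-bias guard is this
    package's automated surrogate for manual review of gross one-strand
    artifacts and only ever acts on all-one-strand support.
    """

    min_alt_reads_genotyping: int = 3
    background_k: float = 2.0
    denovo_min_vaf: float = 0.005
    denovo_min_alt_reads: int = 10
    denovo_buffy_ratio: float = 2.0
    artifact_max_fraction: float = 0.5
    germline_vaf_center: float = 0.5
    strand_bias_p: float = 0.005
    strand_bias_min_alt: int = 10

    def __post_init__(self) -> None:
        if self.min_alt_reads_genotyping < 1 or self.denovo_min_alt_reads < 1:
            raise ValueError("read-count thresholds must be >= 1")
        if self.background_k < 0:
            raise ValueError("background_k must be >= 0")
        for name in ("denovo_min_vaf", "artifact_max_fraction", "germline_vaf_center", "strand_bias_p"):
            value = getattr(self, name)
            if not 0 < value <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {value}")
        if self.denovo_buffy_ratio < 1:
            raise ValueError("denovo_buffy_ratio must be >= 1")


# ---------------------------------------------------------------------------
# Variant (VCF) IO


def read_variants(path: str | Path) -> list[VariantKey]:
    """Read a VCF into normalized :class:`VariantKey` objects.

    Multi-allelic records are split into one key per alt allele. Records whose
    REF contains non-ACGT characters, and symbolic/breakend alts, are skipped
    with a logged warning. Order is preserved; exact duplicates (after
    normalization) are collapsed to the first occurrence.
    """
    path = Path(path)
    keys: list[VariantKey] = []
    seen: set[VariantKey] = set()
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfFormatError(f"cannot parse VCF {path}: {exc}") from exc
    with vcf:
        for record in vcf:
            ref = (record.ref or "").upper()
            if not ref or set(ref) - _DNA:
                logger.warning(
                    "%s: skipping record at %s:%s with non-ACGT ref %r",
                    path.name, record.chrom, record.pos, record.ref,
                )
                continue
            label = record.id if record.id not in (None, ".") else None
            for alt in record.alts or ():
                alt = (alt or "").upper()
                if not alt or set(alt) - _DNA:
                    logger.warning(
                        "%s: skipping non-sequence alt %r at %s:%s",
                        path.name, alt, record.chrom, record.pos,
                    )
                    continue
                key = VariantKey.build(record.chrom, record.pos, ref, alt, label=label)
                if key not in seen:
                    seen.add(key)
                    keys.append(key)
    return keys


def write_variants(variants: Sequence[VariantKey], path: str | Path) -> None:
    """Write variant keys as a minimal sites-only VCF 4.2 file."""
    header = pysam.VariantHeader()
    for chrom in dict.fromkeys(v.chrom for v in variants):
        header.contigs.add(chrom)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in variants:
            record = out.new_record(
                contig=v.chrom,
                start=v.pos - 1,
                stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, v.alt),
                id=v.label,
            )
            out.write(record)


# ---------------------------------------------------------------------------
# Panel (BED) IO


def read_panel_bed(path: str | Path) -> list[PanelRegion]:
    """Read a BED3/BED4 file into merged, non-overlapping panel regions."""
    regions: list[PanelRegion] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >=3 BED columns")
            name = parts[3] if len(parts) > 3 else ""
            regions.append(PanelRegion(parts[0], int(parts[1]), int(parts[2]), name))
    return merge_regions(regions)


def write_panel_bed(regions: Sequence[PanelRegion], path: str | Path) -> None:
    with open(path, "w") as handle:
        for region in regions:
            handle.write(f"{region.chrom}\t{region.start}\t{region.end}\t{region.name}\n")


# ---------------------------------------------------------------------------
# Pileup table IO


def read_pileup_table(path: str | Path) -> list[AlleleCount]:
    """Read the tab-separated allele-count table into validated counts.

    The dialect is a header row with columns exactly :data:`PILEUP_COLUMNS`;
    ``#``-prefixed lines are ignored. Any invariant violation (alt_reads >
    depth, unknown role, strand counts not summing) is a hard error naming the
    offending row.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    if list(frame.columns) != list(PILEUP_COLUMNS):
        raise PileupFormatError(
            f"{path}: expected columns {list(PILEUP_COLUMNS)}, found {list(frame.columns)}"
        )
    counts: list[AlleleCount] = []
    for idx, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            variant = VariantKey(str(row.chrom), int(row.pos), str(row.ref), str(row.alt))
            counts.append(
                AlleleCount(
                    variant=variant,
                    sample_id=str(row.sample_id),
                    role=str(row.role),
                    depth=int(row.depth),
                    alt_reads=int(row.alt_reads),
                    alt_artifact_reads=int(row.alt_artifact_reads),
                    alt_fwd=int(row.alt_fwd),
                    alt_rev=int(row.alt_rev),
                )
            )
        except ValueError as exc:
            raise PileupFormatError(f"{path}: row {idx}: {exc}") from exc
    return counts


def write_pileup_table(counts: Iterable[AlleleCount], path: str | Path) -> None:
    """Write counts in the pileup TSV dialect (round-trips exactly)."""
    rows = [
        (
            c.sample_id, c.role, c.variant.chrom, c.variant.pos, c.variant.ref,
            c.variant.alt, c.depth, c.alt_reads, c.alt_artifact_reads, c.alt_fwd, c.alt_rev,
        )
        for c in counts
    ]
    frame = pd.DataFrame(rows, columns=list(PILEUP_COLUMNS))
    frame.to_csv(path, sep="\t", index=False)


def relabel(count: AlleleCount, role: str) -> AlleleCount:
    """Return the same observation with a different relational role."""
    return replace(count, role=role)
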