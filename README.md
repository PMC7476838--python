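# rbliquid

Detection of somatic *RB1* mutations in plasma cell-free DNA (cfDNA) from
targeted-panel sequencing, for retinoblastoma liquid-biopsy analysis.

Most children with unilateral retinoblastoma do not undergo biopsy, and when a
germline *RB1* test is negative the somatic *RB1* status remains formally
unknown. Deep targeted sequencing of plasma cfDNA can recover the tumor's
*RB1* mutations non-invasively — but at variant allele frequencies (VAF) of a
percent or less, where sequencing error competes with signal. This package
implements, tests and benchmarks the complete analysis layer of such an assay:

- **Tumor-guided genotyping.** A mutation known from the tumor is *detected*
  in cfDNA iff (a) it has ≥ 3 supporting reads, (b) its cfDNA VAF exceeds the
  VAF in the patient's own buffy coat (the white-cell fraction, serving as the
  germline/hematopoietic reference), and (c) its cfDNA VAF exceeds
  `mean + 2·SD` of the VAFs of the same variant genotyped in the *other*
  patients' buffy coats — an empirical per-variant error null. Calls with
  more than 50% of alt reads flagged as artifact are rejected. Variants with
  ≥ 1 supporting read that still fail are reported as *subthreshold evidence*.
- **De novo calling.** Without tumor knowledge, every panel site with alt
  support is a candidate, passed through stricter floors: VAF > 0.5% with
  ≥ 10 mutant reads, cfDNA VAF ≥ 2× the matched buffy coat, the same
  background threshold, plus automated artifact-fraction and strand-bias
  guards standing in for manual alignment review.
- **Germline filtering.** Inherited variants sit near 50% VAF in the buffy
  coat; an exact binomial test against the heterozygous model (with VAF
  guards) classifies buffy observations as germline / somatic / ambiguous,
  and germline variants are excluded from the somatic report. Intermediate
  VAFs (possible mosaicism) stay flagged, never auto-resolved.
- **Synthetic cohorts.** A generator reproduces the statistical structure the
  method assumes — ~10 patients, 1–2 somatic *RB1* mutations each, plasma
  VAFs from fractions of a percent to ~13%, ~1500× unique coverage,
  per-base error, error/artifact hotspots, germline heterozygotes, technical
  replicates — with full ground truth for scoring sensitivity, specificity,
  VAF recovery and replicate concordance (Pearson r²).

## Worked example

```python
from rbliquid import (AlleleCount, VariantKey, build_background,
                      genotype_variant, theoretical_detection_limit, truncated_percent)

variant = VariantKey("chr13", 48_919_230, "C", "T", label="p.R320*")
panel = [AlleleCount(variant, f"PON{i}-buffy", "buffy_unmatched", depth=1500, alt_reads=0)
         for i in range(9)]
model = build_background(variant, panel, k=2)
buffy = AlleleCount(variant, "P12-buffy", "buffy_matched", depth=1480, alt_reads=0)

for alt, depth in [(150, 1500), (5, 5666), (2, 2286)]:
    cfdna = AlleleCount(variant, "P12-cfdna", "cfdna", depth=depth, alt_reads=alt,
                        alt_fwd=alt // 2, alt_rev=alt - alt // 2)
    r = genotype_variant(variant, cfdna, buffy, model)
    print(alt, depth, f"VAF {r.cfdna_vaf:.5f}", r.status, r.subthreshold_evidence)

print(truncated_percent(theoretical_detection_limit(3, 1596)), "%")
```

prints

```
150 1500 VAF 0.10000 detected False
5 5666 VAF 0.00088 detected False
2 2286 VAF 0.00087 not_detected True
```

— 150 reads at 10% VAF is an unambiguous detection; 5 reads at 0.088% still
clears the 3-read floor against a clean background; 2 reads fall below it and
are surfaced as subthreshold evidence rather than a detection. The last line,
`0.18 %`, is the theoretical detection limit of the 3-read criterion at 1596×
unique coverage (3/1596 ≈ 0.188%, truncated to printed precision).

More in `examples/`: the background null (01), genotyping (02), de novo
calling (03), a full simulate→genotype→denovo→score loop on the bundled
10-patient study-like cohort (04), and replicate concordance (05). Each is a
short narrative script that prints what it computes.

A thin CLI wraps the same functions:

```bash
rbliquid simulate --out data --paper-like --seed 13
rbliquid genotype --data data --out reports
rbliquid denovo   --data data --out reports
rbliquid score    --data data --out reports
```

## Data model and formats

Variant lists are VCF 4.2 (read/written with pysam; multi-allelic records are
split and alleles trimmed to parsimonious form). Panel regions are BED.
Allele counts travel as a tab-separated pileup table with columns
`sample_id role chrom pos ref alt depth alt_reads alt_artifact_reads alt_fwd
alt_rev`; sample ids follow `<patient>-<type>[-repN]` (e.g. `P10-cfdna`,
`P10-cfdna-rep2`, `P10-buffy`). The pileup producer is responsible for
quality floors and duplicate removal; this package treats depth as unique,
qualifying coverage. See `docs/methods.md` for the model, parameter defaults
and design choices.

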