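# File formats

All internal coordinates are **1-based, half-open** `[start, end)`.
Conversions happen at the file boundary and nowhere else.

## Imputed / truth VCF

Read with cyvcf2; written as plain uncompressed VCF 4.2.

- `GT` (truth/array callsets): diploid genotypes coded 0/1/2; `./.` reads
  as missing (−1).
- `DS` (imputed): dosage in [0, 2], written to 3 decimals. When `DS` is
  absent but `GP` is present, dosage is derived as `GP1 + 2·GP2`.
- `GP`: posterior triple. On read, triples are renormalised when their sum
  is within 1e-3 of 1 and set to missing otherwise. On write, the third
  component is emitted as `1 − GP0 − GP1` so rounded triples sum to 1.000
  exactly.
- Per-site `INFO` fields used: `AF` (alternate-allele frequency) and
  `INFO` (imputation quality in [0, 1]; may be absent).
- Multi-allelic records are skipped with a warning; sites are keyed by
  (chrom, pos, ref, alt).

## Local-ancestry tracts (`msp.tsv` dialect)

RFMix2-style. Two header lines:

```
#Subpopulation order/codes: AFR=0	EUR=1
#chm	spos	epos	sgpos	egpos	n snps	S0.0	S0.1	S1.0	S1.1
```

then one row per window with integer ancestry codes per haplotype column
(two columns per sample, `<sample>.0` and `<sample>.1`). `spos`/`epos` are
1-based half-open physical positions. Consecutive windows with identical
codes are merged into tracts on read.

## Intervals

- **BED** (`.bed`): 0-based half-open; converted to 1-based half-open on
  read. Three columns: chrom, start, end.
- **interval_list**: 1-based **closed**; `@`-prefixed header lines are
  skipped. Converted to half-open by adding 1 to the end.

Overlapping and abutting intervals are merged on read; intervals with
`end <= start` are rejected with the offending line number.

## CNV call table (TSV)

Columns, in order:

| column | type | notes |
|---|---|---|
| sample | str | carrier sample ID |
| chrom | str | |
| start | int | 1-based half-open |
| end | int | must exceed start |
| type | str | `DEL` or `DUP` |
| qs | float | caller quality score |

## Pedigree (PED-like TSV)

Columns: `family`, `sample`, `father`, `mother`, `sex`, `phenotype`.
Founders use `0` for both parents. The de novo screen considers children
whose two parents are both present in the table.

## QC metrics table (TSV, consumed by `bge-eval qc`)

Required columns: `exome_fraction_10x`, `wgs_coverage`, `chimera_rate`,
`contamination_rate`. Optional: `sample` (echoed in the report),
`stratum` (grouping for MAD outlier filtering; one global stratum when
absent), and any of the metric columns `n_singletons`, `n_insertions`,
`n_deletions`, `n_transitions`, `n_transversions`, `het_ratio`,
`titv_ratio`, `insdel_ratio` (each present column is screened for
|x − mean| > 4·MAD outliers within its stratum).

Output columns: `coverage_pass`, `coverage_reasons` (semicolon-joined
failure reasons among `exome_fraction`, `wgs_coverage`, `chimera`,
`contamination`), `metric_outlier_pass`, `passed`.
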