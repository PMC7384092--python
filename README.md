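# lohmap

Chromosome-arm LOH mapping for multifocal tumors: from tumor/normal allelic
read depths, identify LOH-informative SNPs on a target chromosome, assign
the retained parental allele per SNP per tumor, and classify the cross-tumor
pattern of parental-allele loss. Ships with a simplified binned log2-ratio
hemizygous-loss screen and a synthetic-cohort simulator with planted ground
truth.

## Method

Given per-sample ref/alt read counts at biallelic SNP sites:

1. **Germline het SNPs** — kept if normal-sample depth > 10 and VAF in
   [0.4, 0.6] (bounds configurable).
2. **Informative-SNP selection** — per tumor, het SNPs with tumor depth > 10
   are tested with an exact two-sided binomial test against 0.5;
   Benjamini–Hochberg adjustment is applied per tumor and SNPs with
   q < 0.1 are LOH-informative. A tumor is retained if it has ≥ 1000 (WGS)
   or ≥ 100 (WES) informative SNPs.
3. **Retained allele** — the majority allele at each informative SNP.
4. **Pattern classification** — pairwise retained-allele concordance over
   shared informative SNPs, overall and per chromosome arm; tumors are then
   2-colored on a signed agreement graph per arm. Patient-level calls:
   `SAME_ALLELE`, `OPPOSITE_ALLELES`, `ARM_DISCORDANT` (a tumor groups
   differently on the p and q arms), or `UNDETERMINED`. Haplotype groups are
   identified only up to relabeling (no trio phasing).
5. **CNV screen** (optional) — median per-chromosome/arm log2 ratio of
   library-normalized binned read counts; hemizygous loss is called when the
   median is < −0.1. For purity ρ the expected signal of a one-copy loss is
   log2(1 − ρ/2), so the criterion detects losses down to ρ ≈ 0.134.

## CLI

```sh
# simulate a cohort with a planted pattern
lohmap simulate --seed 7 --pattern ARM_DISCORDANT --n-tumors 6 \
    --n-snps 4000 --purity 0.7 --out-dir sim/

# run the full pipeline (VCF with per-sample AD, or the flat depth TSV)
lohmap map-loh --input sim/cohort.vcf --normal normal \
    --tumor T1 --tumor T2 --tumor T3 --tumor T4 --tumor T5 --tumor T6 \
    --bins sim/bins.tsv --out-dir results/

# three-patient demo (simulate + map-loh, one cohort per pattern)
lohmap demo --seed 1 --out-dir demo/

# standalone pattern re-classification / CNV screen
lohmap classify --informative results/informative_snps.tsv --out pattern.json
lohmap cnv --bins sim/bins.tsv --tumor-col T1_count --out calls.tsv
```

Outputs are deterministic, byte-stable TSV/JSON: `informative_snps.tsv`,
`tumor_profiles.tsv`, `pair_concordance.tsv`, `patient_pattern.json`,
`run_summary.json` (thresholds, per-stage counts, config hash), and
`cnv_calls.tsv` when bin counts are given. Exit codes: 0 success (including
UNDETERMINED), 2 configuration error, 3 data error.

Input formats: VCF v4.x with per-sample `AD` (multiallelic and indel lines
are skipped and counted), or a TSV with columns
`chrom, pos, ref, alt, <sample>_ref, <sample>_alt`. Arm boundaries come from
a UCSC-style cytoband file, a 3-column `chrom p_end q_start` table, or the
built-in hg19 default (chr18: p ends at 15,400,000; q starts at 19,000,001).

## Limitations

The CNV screen is an intentionally simplified stand-in for full
allele-specific copy-number callers: no segmentation, no GC/mappability
correction, no absolute copy-number or ploidy estimation. The simulator does
not model read-level artifacts (alignment, mapping bias) — depths are
negative-binomial and allele counts binomial given depth.
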