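# retprio

Variant prioritization for inherited retinal disease (IRD) WGS cohorts.
Given per-sample small-variant and structural-variant (SV) calls, gene
models with retinal transcript expression, reference population panels and
pedigrees, the package reproduces a complete diagnostic workflow:

1. **Genotype/site QC** — hard filters on DP, GQ and allele balance, plus
   site-level filters (low-complexity regions, inbreeding coefficient,
   Hardy-Weinberg, VQSR flag). Failing genotypes become missing; sites are
   dropped only when empty. SV records bypass these filters.
2. **Dual-population rarity** — SVs are matched across call sets by >80%
   reciprocal overlap and assigned the allele frequency of the
   best-matching panel record; a variant is rare only when AF < 1% in
   *every* configured panel.
3. **Likely-pathogenic classification** — seven SNV/indel categories
   (stop gain/loss, frameshift, canonical splice, damaging missense,
   deep-intronic and non-canonical splice by the 100 bp nearest-exon rule)
   and two SV categories (exonic DEL/DUP; exonic inversion not spanning
   the whole gene), driven by externally computed CADD/SpliceAI/EVE
   annotations.
4. **Transcript disruption ratio (TDR)** — the TPM-weighted fraction of a
   gene's retinal expression carried by transcripts an SV disrupts; SVs
   below 20% are excluded as likely benign.
5. **Segregation and diagnosis** — dominant, recessive/compound-het (with
   trio phasing) and X-linked checks against the pedigree, producing
   per-patient diagnosis reports and cohort summaries.

A fully synthetic cohort simulator (`retprio.synthetic_cohort`) plants
causal variants under seven inheritance modes together with decoys that
each fail exactly one stage, and writes/reads complete cohorts as plain
text (VCF, PED, GTF, TSV, JSON). The curated variant and per-patient
diagnosis-mode tables from a published IRD WGS study are bundled as
fixtures for the summary operations.

## Command line

```bash
retprio simulate --out cohort/ --seed 1 --n-families 30   # synthetic cohort + truth manifest
retprio qc        --cohort cohort/ --out qc.json
retprio rarity    --cohort cohort/ --out rarity.tsv
retprio classify  --cohort cohort/ --out classes.tsv
retprio tdr       --cohort cohort/ --out tdr.tsv
retprio diagnose  --cohort cohort/ --out reports/          # full pipeline
retprio summarize --cohort cohort/ --out summary.json
retprio run-all   --out run/ --seed 1 --n-families 30      # simulate + diagnose
retprio fixtures  --out fixtures/                          # curated study tables
```

Thresholds live in a single `ThresholdConfig`; pass overrides as JSON via
`--config`. All randomness is controlled by `--seed`.

## Library use

```python
from retprio import (
    SimulationConfig, simulate_cohort, run_pipeline, summarize_run,
)

cohort = simulate_cohort(SimulationConfig(n_families=30, seed=7))
result = run_pipeline(cohort)
print(summarize_run(result, cohort).as_dict())
```

## Layout

```
src/retprio/
  genome_model.py           intervals, transcripts, gene-model loading (GTF/TSV)
  variant_qc.py             ThresholdConfig, genotype/site hard filters
  population_freq.py        SV matching, panel AFs, rarity, benign SV sets
  pathogenicity.py          category rules, TDR, SV size comparison
  segregation_diagnosis.py  pedigrees, segregation checks, diagnoses, summaries
  synthetic_cohort.py       simulator and curated study fixtures
  pipeline.py               stage orchestration
  io.py                     VCF/PED/GTF/TSV round trip
  cli.py                    click CLI
tests/                      unit, property and acceptance suites
scripts/acceptance.py       acceptance report
```
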