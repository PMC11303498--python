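# updscreen

Batch screening for uniparental disomy (UPD) in exome/genome cohorts from
per-individual VCFs. For every (sample, autosome) pair the tool computes

* the **ROH fraction** — the proportion of the chromosome covered by runs of
  homozygosity called from the sample's variant sites, and
* the **inheritance ratio (IR)** — the imbalance between child variants carried
  exclusively by the mother vs. exclusively by the father (duo/trio setups),

then tags both against fixed cutoffs (ROH: low < 0.2, high-mixed 0.2–0.7,
high > 0.7; IR high: > 2 in duos, > 5 in trios) to nominate candidates:

| ROH tag      | IR tag | call                       |
|--------------|--------|----------------------------|
| high         | any    | `iUPD_candidate`           |
| high_mixed   | low    | `segmental_iUPD_candidate` |
| high_mixed   | high   | `mixed_UPD_candidate`      |
| low          | high   | `hUPD_candidate`           |

Samples whose ROH pattern looks consanguine (≥ 3 elevated autosomes or a high
genome-wide ROH fraction) are flagged, and their ROH-driven candidate calls are
downgraded to `none` (the raw call is kept in the `raw_upd_call` column).

A built-in simulator generates synthetic single/duo/trio cohorts with
Mendelian transmission, binomial read noise, a low-allele-fraction artifact
band (alt fraction ≈ 0.2 on every chromosome), injected whole-chromosome and
segmental iso-/heterodisomies, and consanguine background — so the entire
pipeline is testable without any external data.

## CLI

```sh
# synthetic cohort: one VCF per individual + manifest.tsv + truth.tsv
updscreen simulate --out sim/ --seed 7 --families 20 \
    --n-iupd 2 --n-hupd 2 --n-segupd 1 --n-consanguinity 1

# screen a cohort described by a manifest (sample_id, role, family_id, path)
updscreen batch --manifest sim/manifest.tsv --out results/ --truth sim/truth.tsv

# one family from individual VCFs
updscreen run --child child.vcf --mother mom.vcf --father dad.vcf --out fam/

# re-render the cohort scatter from a saved table
updscreen plot --table results/cohort_table.tsv --out scatter.png
```

`batch` writes `cohort_table.tsv`/`.json` (one row per sample × autosome with
all metrics, tags and candidate calls), `summary.json`, a cohort ROH-vs-IR
scatter with threshold shading, and per-candidate allele-fraction plots
(alt fraction vs. position colored by parental origin, with an ROH track and
relative-IR/ROH side bars). All thresholds, filters, ROH-caller parameters and
the genome build (GRCh37/GRCh38) are configurable via `--config config.yaml`
(sections: `filters`, `roh`, `inheritance`, `thresholds`, `consanguinity`,
`plot`, `genome_build`); every table carries a provenance header with the
package version and config hash, and outputs are byte-deterministic for a
fixed seed and config.

Cohort table columns: `family, sample, setup, chrom, roh_fraction,
n_sites_used, maternal_only, paternal_only, biparental, neither, ir,
ir_direction, relative_ir, roh_tag, ir_tag, upd_call, raw_upd_call,
upd_parent, consanguinity_flag`.

## Method notes

* Variant sites are decomposed per alt allele and matched across family
  members on (chrom, pos, ref, alt) after chr-prefix normalization. A child
  variant absent from a sequenced parent's VCF counts as *not carried* (exome
  VCFs emit variant sites only).
* Default site filters: depth ≥ 10; het calls kept only at alt fraction
  0.25–0.75 (this removes the ≈ 0.2 artifact band); hom-alt calls require
  alt fraction ≥ 0.85.
* The ROH caller is a rule-based scanner: runs of ≥ 15 homozygous sites,
  tolerating ≤ 1 het interruption, broken at gaps > 3 Mb; the fraction
  denominator is the full build chromosome length.
* IR = (max(m, p) + 1) / (min(m, p) + 1) over exclusively-maternal (m) and
  exclusively-paternal (p) counts; chromosomes with < 10 informative sites
  are reported as uninformative. `relative_ir` = m / (m + p).
* X/Y are excluded from screening (hemizygosity mimics ROH); only autosomes
  1–22 are tagged.

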