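# organellotype

Polymorphism, haplotype and heteroplasmy analysis for circular organelle
genomes (chloroplast and mitochondrial), built around multi-sample VCFs with
per-sample allele depths.

The toolkit covers the full chain used in organelle resequencing panels:

- **`synthdata`** — synthetic references, accession panels and VCFs with
  fully known planted truth (skewed haplotype frequencies,
  species-partitioned haplotype sharing, designated heteroplasmic sites,
  Poisson depth + sequencing-error AD model).
- **`repeatmask`** — duplicated-region detection by ungapped seed-and-extend
  self-comparison on both strands (circular genomes handled at the origin),
  mask construction, and VCF filtering of variants inside repeats.
- **`variantstats`** — SNP/InDel/MNP and bi-/multi-allelic classification,
  Ts/Tv ratio, and a self-contained coding-effect predictor
  (synonymous/missense/nonsense/frameshift/inframe, with a fixed impact
  ladder) against GFF3 gene models.
- **`haplotyper`** — tag-site selection by perfect linkage (sites inducing
  identical accession partitions are collapsed, transitively), haplotype
  assignment, frequency-ranked naming (CT1, CT2, ... / MT1, ...),
  minimum-spanning haplotype networks with equal-length alternative edges,
  and average-linkage haplotype groups (CTG/MTG).
- **`cytoplasm`** — joint CT/MT cytoplasm types, distribution tables by
  country/region/province with half-up percentage rounding, wild/cultivated
  haplotype sharing, and unbiased haplotype diversity.
- **`heterozygosity`** — per-accession reference-allele frequencies (RAF)
  from AD at designated sites, heteroplasmy profiles, and Wilcoxon rank-sum
  comparisons between accession strata.
- **`cli`** — subcommands plus an `all` pipeline with a flat config file,
  derived per-stage seeds, and a checksummed output manifest.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: worked-example
percentage checks, and property-based oracle equivalences (brute-force
repeat finder, linkage closure, MST weight, whole-protein translation diff,
binomial RAF recovery, Ts/Tv recovery). The supplementary-table checks are
skipped unless `tests/data/table_s4.tsv` has been downloaded manually.

## CLI

```sh
organellotype simulate --out-dir run --seed 1 --n-accessions 300
organellotype mask --fasta run/chl.fasta --vcf run/chl.vcf \
    --out-bed run/chl.bed --out-vcf run/chl_masked.vcf --circular
organellotype stats --vcf run/chl_masked.vcf --gff run/chl.gff3 \
    --fasta run/chl.fasta --out run/chl_stats.tsv
organellotype haplotype --vcf run/chl_masked.vcf --meta run/metadata.tsv \
    --prefix CT --groups 4 --out-dir run
organellotype cytoplasm --assignments run/cytoplasm_assignment.tsv \
    --by country --level joint --out run/by_country.tsv
organellotype raf --vcf run/mit.vcf --sites sites.tsv --min-depth 10 \
    --band 0.05,0.95 --meta run/metadata.tsv --strata species --out run/raf.tsv
```

End-to-end (synthesize, mask, classify, haplotype both organelles, join
cytoplasm types, analyze RAF, verify recovery against planted truth):

```sh
python - <<'PY'
from organellotype.cli import RunConfig
RunConfig(out_dir="run", seed=1).to_file("run.cfg")
PY
organellotype all --config run.cfg
```

Exit codes: 0 ok, 1 input/config error, 2 stage failure. Rerunning with the
same config and seed reproduces byte-identical outputs (checksums in
`run/manifest.json`).

## Conventions

- Coordinates are 0-based half-open internally; 1-based at VCF/GFF
  interfaces. BED output is 0-based half-open.
- Organelle genotypes are treated as haploid; mixed (diploid-style) GT calls
  are collapsed to the majority allele by AD (ties become missing), and
  sites that are heteroplasmic in most accessions are excluded from
  haplotyping and analyzed through the RAF module instead.
- Unassigned accessions (missing tag calls) are reported, never imputed.
- Percentages print half-up at one decimal.
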