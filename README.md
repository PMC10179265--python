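# pedvar

Pedigree-aware rare-variant prioritization for familial cancer studies.

The package implements, as a tested reusable pipeline, the analysis used
to prioritize candidate susceptibility variants in a multiplex family:

- **Germline filter cascade** — shared-carrier intersection, public
  database allele-frequency screen (<1% in 1KG/EVS/ExAC/gnomAD),
  internal-cohort screen, and familial segregation, with an auditable
  `FilterTrace` of per-stage counts.
- **Segregation engine** — compatibility of each variant with dominant
  (optionally incomplete-penetrance) and recessive (optionally
  pseudo-dominant) inheritance, listing non-penetrant carriers and
  violators; Mendelian trio checking.
- **Annotation tiering** — splice-benign exclusion (spliceAI +
  dbscSNV-Ada) and thyroid-expression (TPM) prioritization into
  primary/secondary candidates.
- **Two-point linkage** — exact pedigree likelihood of a variant versus
  the disease phenotype under a penetrance model, computed by
  sum-product peeling (variable elimination) that handles
  consanguineous loops; LOD(θ) = log10 L(θ) − log10 L(0.5).
- **Somatic subtraction** — tumor-minus-germline calls, <5% frequency
  screen, restriction to a somatic/susceptibility gene panel, and a
  per-gene second-hit scan (homozygous, heterozygous, compound-het
  pairs).
- **Interaction paths** — bounded-length simple-path search linking
  candidate genes to known disease genes over a supplied edge list.
- **Simulator** — multi-branch pedigree construction, gene-dropping
  with a planted dominant variant and configurable penetrance, tumor
  spiking, and a complete plain-text fixture suite, all
  seed-deterministic.

A bundled worked example (`pedvar.examples`) transcribes the study's
published genotype matrix, candidate annotations, somatic candidate
pair, and interaction neighbourhood, and is used throughout the tests.

## CLI

```sh
pedvar simulate --out fixtures --seed 1          # write a synthetic input suite
pedvar germline --vcf fixtures/example_genotypes.vcf \
    --ped fixtures/example.ped \
    --annotations fixtures/example_annotations.tsv \
    --internal-freqs fixtures/example_internal_freqs.tsv \
    --carriers III8,III10,IVA5,XFIII4,XFIII5 --out germline.tsv
pedvar segregate --vcf ... --ped ... --model dominant --incomplete-penetrance --out seg.tsv
pedvar lod --vcf ... --ped ... --variant 5:73048875:A:G --penetrance 0.9
pedvar somatic --tumor-vcf ... --germline-vcf ... --annotations ... \
    --somatic-panel fixtures/somatic_panel.txt --out somatic.tsv
pedvar ppi --edges fixtures/interactions.tsv --sources ARHGEF28,FBXW10,SLC47A1 \
    --target-panel fixtures/somatic_panel.txt
pedvar full --config config.yaml --out results/
```

`full` runs germline → segregation → tiering → interaction paths and
(when a tumor VCF is configured) the somatic cascade, from a single
YAML config. Reports are TSV with a JSON filter-trace sidecar.

## File formats

6(+2)-column whitespace PED (phenotype 0 = unknown, optional sequenced
and sampled flag columns), VCFv4.2 with GT (multi-allelic sites are
split and normalized to minimal representation; GRCh37, 1-based),
header-bearing TSVs for annotations (`freq_<db>` / `score_<name>` /
`expression_tpm` columns; empty cells mean "not observed", distinct
from 0), long-format frequency tables, one-gene-per-line panels, and
`gene_a  gene_b  evidence` edge lists.
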