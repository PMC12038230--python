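# panhap

Downstream analysis toolkit for haplotype-resolved (super-)pangenomes:

- **pangenome** — gene-family occupancy matrices (orthogroups TSV dialect),
  classification into core / softcore / dispensable / private families,
  pan/core saturation (rarefaction) curves, per-genome gene compositions,
  singleton genes, and cross-tabulation of external gene lists.
- **sv** — SyRI-dialect alignment/variant table parsing, extraction of the
  six SV categories (INS, DEL, INV, TRANS, DUP, CNV) longer than 50 bp,
  length histograms, SV+/SV− gene screening (gene body and strand-aware
  upstream 2 kb), highly-diverged-region (HDR) detection, and Welch t-test
  group comparisons.
- **ase** — allele pairing across haplotypes via collinearity anchors,
  per-condition allele-specific-expression calls (TPM ≥ 2, |log2FC| ≥ 2 by
  default), cross-condition consistency classification, chromosome bias,
  and overlap with SV gene sets.
- **dup** — unique duplication-mode assignment from per-mode pair lists with
  priority WGD > TD > PD > TRD > DSD, plus the proximal-distance rule.
- **survey** — canonical k-mer spectra, genome-size estimation via
  `G = N (L − k + 1) / F`, and LTR insertion dating `T = K / (2r)`.
- **simulate** — synthetic inputs with planted ground truth for every stage
  (family matrices, SyRI-style SV tables + gene models, paired-allele TPM
  matrices, error-free/error-bearing reads), making the whole pipeline
  testable without external data.
- **report** — YAML-configured pipeline driver with machine-readable summary
  reports and internal arithmetic checks.

## Tests

```sh
python -m pytest -q
```

The suite includes unit tests per module, hypothesis property tests, and
`tests/test_acceptance.py` with oracle-backed end-to-end criteria (brute-force
saturation enumeration, O(n·m) overlap scans, closed-form Welch statistics,
planted-truth recovery).

## CLI

```sh
panhap simulate pangenome --n-genomes 14 --n-families 1000 --seed 1 --out-dir sim/
panhap pangenome classify sim/orthogroups.tsv
panhap pangenome saturate sim/orthogroups.tsv --n-samples 100 --seed 1 --out curve.tsv

panhap simulate sv --seed 1 --out-dir sim/
panhap sv extract sim/syri.out --min-len 50 --out svs.tsv
panhap sv genes sim/syri.out sim/genes.gff3 --region body --out-prefix out/genes
panhap sv hdr sim/syri.out --window 100000 --threshold 0.5 --out hdr.bed

panhap simulate ase --n-pairs 200 --seed 1 --out-dir sim/
panhap ase classify sim/anchors.tsv sim/tpm.tsv --tpm-min 2 --lfc-min 2

panhap simulate reads --genome-length 100000 --coverage 20 --seed 1 --out-dir sim/
panhap survey size sim/reads.fastq --k 21
panhap survey ltr-age divergences.tsv --rate 3.39e-9

panhap dup assign genes.txt --wgd wgd.tsv --td td.tsv
panhap run --config config.yaml
```

A pipeline config looks like:

```yaml
stages: [pangenome, sv, ase, survey]
seed: 123
out_dir: out/
synthetic:
  pangenome: {n_genomes: 14, n_families: 1000}
  sv: {genome_length: 1000000, gene_count: 30}
  ase: {n_pairs: 200, n_consistent: 40, n_inconsistent: 40}
  reads: {genome_length: 100000, coverage: 20}
```

Replace `synthetic` with an `inputs:` section (orthogroups/syri/genes/anchors/
tpm/reads paths) to run on real files.

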