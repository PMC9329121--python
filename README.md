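# mutlineage

Clone-lineage somatic mutation analysis: a tested, reusable pipeline for
measuring de novo deaminase (APOBEC3-style) mutagenesis in parent/daughter
clone experiments.

The package covers:

- **`genome`** — reference FASTA handling and genome-wide availability of
  pyrimidine-strand trinucleotide (32) and pentanucleotide (512) mutation
  target contexts.
- **`catalog`** — SBS call records (with ASMD/CLPM/read-direction quality
  fields) and classification into the 6 / 96 / 288 / 1536 sequence-context
  channel systems, with sample × channel count matrices.
- **`lineage`** — the two-step, six-filter derivation of de novo mutations:
  panel-of-normals PASS, ASMD > 130, CLPM == 0, reference-sample coverage
  ≥ 16 reads, both read directions, absence from the reference sample, and
  presence in ≤ 50% of clones from other parental lineages; plus bulk-proxy
  accumulation, shared-daughter flagging (> 30% shared), and a VAF
  clonality (unimodality) diagnostic.
- **`enrichment`** — fold-enrichment E = (Mut_motif/Con_motif)/(Mut_C/Con_C)
  of C>T and C>G mutations at TCN, TCA, YTCA and RTCA motifs.
- **`clustered`** — clustered-SBS detection calibrated by a
  context-preserving background simulation (100 replicates preserving each
  mutation's ±1 bp context and per-chromosome burden), a sample-dependent
  IMD cutoff (90% purity, empirical q < 0.01), a 10-Mb mutation-rich-window
  correction, VAF-consistency (< 0.10), and classification into kataegis /
  omikli / doublet / multibase / other with an APOBEC3 (cytosine at TCN)
  partition and clustered TMB.
- **`signatures`** — penalized sparse NNLS refitting of 96-channel
  catalogues onto a reference signature set (lowered penalties 0.005/0.001
  by default, conservative 0.05/0.01 available) and decomposition of de
  novo signatures with cosine thresholds (> 0.97 decomposed, < 0.95 novel).
- **`stats`** — one/two-tailed Mann–Whitney U (exact for small tie-free
  groups) and Benjamini–Hochberg FDR over caller-declared families.
- **`simulate`** — fully synthetic clone-lineage studies with per-mutation
  ground truth: signature-mixture spectra sampled channel-first, episodic
  per-daughter bursts, injected strand-coordinated clusters, germline /
  parental / bulk-shared variants, binomial read sampling, and a
  configurable artifact fraction.
- **`pipeline` / `cli`** — YAML-configured orchestration of the whole
  analysis with deterministic, seed-scoped randomness.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end property checks (exact
context/filter oracles, enrichment calibration on a 10-Mb genome, cluster
null/recovery on a 100-Mb genome, attribution recovery, statistics
exactness, full round trip); it takes a few minutes.

## CLI

Every stage is a subcommand of `mutlineage`:

```sh
# generate a synthetic study with ground truth
mutlineage simulate --config sim.yaml --seed 1 --out-dir study/

# individual stages
mutlineage contexts  --genome study/genome.fa --flank 2 --out penta.tsv
mutlineage matrix    --genome study/genome.fa --table study/mutations.tsv --system 96 --out m96.tsv
mutlineage filter    --table study/mutations.tsv --manifest study/manifest.yaml \
                     --genotypes study/genotypes.tsv --clone D1.1 --out-prefix d11
mutlineage enrich    --genome study/genome.fa --table d11.de_novo.tsv \
                     --tri-inventory tri.tsv --penta-inventory penta.tsv --out enr.tsv
mutlineage clusters  --genome study/genome.fa --table study/mutations.tsv \
                     --sample D1.1 --out-prefix d11
mutlineage attribute --genome study/genome.fa --table study/mutations.tsv \
                     --signatures study/signatures.tsv --out activities.tsv
mutlineage compare   --values values.tsv --group-a WT --group-b KO --tail one_less

# full pipeline from one YAML run config
mutlineage run --config run.yaml
```

## File formats

- Mutation tables: TSV with columns `sample_id chrom pos ref alt mut_fwd
  mut_rev depth ref_sample_depth ref_sample_mut asmd clpm pass_flag`
  (1-based positions). A minimal single-sample VCF reader is also provided
  (INFO `ASMD`,`CLPM`,`RDP`,`RMUT`; FORMAT `DP`,`MF`,`MR`).
- Clone manifests and run/simulation configs: YAML.
- Genotyping counts: long TSV (`chrom pos ref alt clone mut_reads total_reads`).
- Context inventories: two-column TSV with a JSON header line.
- Signature sets: COSMIC-style TSV (channel label column + one column per
  signature, `A[C>A]A` naming); activities as sample × signature TSV.
- Cluster events: BED-like TSV plus rainfall-plot export (position,
  log10 IMD, class).
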