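# holostrain

Strain-level metagenomics of low-complexity holobionts (host + heritable
bacterial symbionts), from multi-sample allele counts to phylogenies and
host–symbiont cophylogeny tests.

Stages:

1. **Coverage screening** — per-sample/per-symbiont depth summaries and
   presence calls (absent < 1×, analysable > 10× with homogeneous coverage,
   present-low in between), assembled into a presence matrix.
2. **Variant filtering** — a four-rule cascade over a multi-sample
   allele-count matrix read from VCF (AD or DPR): per-sample rare-allele
   removal (< 4 reads or < 10% frequency), low/high extreme-coverage site
   masks relative to per-sample median variant depth (≥ 75% of samples below
   the median, or ≥ 5× above it), and an externally computed homology mask
   (BED).
3. **Strain profiles** — per-sample most-abundant-allele genotypes (ties
   keep the reference and are flagged; samples with > 5% tied sites are
   excluded), deduplication of identical profiles, and synthesis of
   per-sample gene sequences from a reference FASTA + GFF3 for external
   alignment/ML.
4. **Profile phylogeny** — pairwise profile distances (differences divided
   by the total variant count), neighbor joining with site-resampling
   bootstrap, outgroup rooting, Grafen ultrametrization and Robinson–Foulds
   comparison.
5. **Coinfection detection** — 1- vs 2-component Poisson mixture (EM) on
   the depths of intra-sample polymorphic alleles; a bimodal fit with
   ΔBIC ≥ 10 and mean ratio ≥ 2 calls a two-strain sample, whose haplotypes
   are then phased by depth.
6. **Cophylogeny** — exact duplication–transfer–loss event-cost
   reconciliation of each symbiont tree onto the host tree (default costs:
   cospeciation 0, all other events 1) with a tip-mapping permutation test
   for cospeciation signal.
7. **Simulation** — a ground-truthed holobiont generator (Yule host tree,
   symbiont histories with host switches and losses, Jukes–Cantor + indel
   mutations, Poisson depths, miscall errors, pooled and coinfected
   samples) used to verify every stage.

## Test

```bash
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, which checks oracle
equivalence of the filter cascade and reconciliation DP, NJ recovery of
additive matrices, permutation-test calibration/power, coinfection
operating characteristics, and end-to-end recovery of simulated truth.

## CLI

```bash
holostrain simulate --n-hosts 12 --genome-length 200000 --seed 1 --out-dir sim/
holostrain coverage --depth-dir sim/depths --length 200000 --out presence.tsv
holostrain filter --vcf sim/calls.vcf --out filtered.vcf --report report.tsv
holostrain profile --vcf filtered.vcf --out profiles.tsv
holostrain consensus --ref sim/ref.fa --gff sim/genes.gff3 \
    --profiles profiles.tsv --out genes_by_sample.fa
holostrain tree --profiles profiles.tsv --bootstrap 1000 --seed 42 \
    --out tree.nwk --distances dist.tsv
holostrain coinfect --vcf filtered.vcf --sample host_001 --out coinf.json
holostrain reconcile --host host.nwk --symbiont symb.nwk --mapping tips.tsv \
    --n-perm 500 --seed 7 --out recon.json
holostrain run --config run.toml --out-dir results/
```

`holostrain run` wires all stages from a TOML config with one
`[symbionts.<name>]` table per symbiont (keys: `vcf`, `depth_dir`,
`genome_length`, optional `ref`, `gff`, `mask`, `outgroup`); when no
`host_tree` is given, the `primary` symbiont's NJ tree serves as the host
proxy for the reconciliations.

## Formats

VCF 4.x (AD/DPR per-allele depths), samtools-depth TSV tracks, FASTA,
GFF3, BED (0-based half-open), Newick, tip-mapping TSV. Internal
coordinates are 0-based half-open; conversion happens only at I/O
boundaries. All writers emit deterministic, byte-stable output.
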