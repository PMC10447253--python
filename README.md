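# wheatscan

Windowed population-genomic scans for wheat-scale genomes, built around
synthetic data with planted ground truth:

- **simgen** — synthetic ancestors, diversity panels on a fixed
  ((α),(β,dom),(γ)) population tree with planted γ-introgression blocks,
  RIL populations observed at skim coverage, EMS mutant bulks, and
  diverged LTR pairs — all with machine-readable truth files.
- **vcfops** — biallelic SNP hard filters (SNP clusters, mean-depth
  bounds) and windowed statistics: nucleotide diversity (π), per-pair
  diversity, Weir–Cockerham F_ST, SNP density.
- **introgression_pi** — introgression calling from pairwise-diversity
  tracks using three criteria (≥10 Mb continuous reduction, no reduction
  against a control accession, not explained by missing data), plus
  genome-fraction summaries.
- **kmer_map** — species-specific canonical k-mer sets (k = 51 default),
  exact full-length no-mismatch genome scanning, 1 Mb coverage windows
  and segment calling (donor coverage ≥ 5, 1 Mb merge rule).
- **kmer_var** — identity-by-state variation scores per 50 kb window
  (k = 31), IBS segments at the ≤ 30 cutoff, minimum-consensus tracks and
  donor-group assignment.
- **binmap** — parental marker discovery, 1 Mb bin genotyping of
  low-coverage RILs with the 0.7 consensus rule, crossover breakpoint
  intervals, and marker-matrix filtering/deduplication.
- **mutmap** — bulked-segregant SNP-index mapping: bulk variant filters,
  varietal-SNP removal, EMS-type (G/C→A/T) selection, 100 kb window
  averaging and candidate-interval extraction.
- **centromere_clock** — centromere boundaries from enrichment-peak
  density at 100 kb resolution, and LTR retrotransposon insertion ages
  from LTR–LTR divergence (Jukes–Cantor, age = K / 2r).

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the slow end-to-end recovery suite
(k-mer boundary recovery on a 10 Mb genome, 20-seed panel/RIL/bulk
recoveries); the rest of the suite runs in seconds.

## CLI

Everything is exposed under a single `wheatscan` entry point; every
threshold default notes its provenance in `--help`:

```bash
# synthetic dataset with planted truth
wheatscan simulate --config sim.yaml --outdir sim/

# windowed statistics from a VCF
wheatscan stats pi      --vcf panel.vcf --window 10000  --out pi.tsv
wheatscan stats pairdiv --vcf panel.vcf --sample-x dom1 --sample-y gamma1 --out pd.tsv
wheatscan stats fst     --vcf panel.vcf --group1 a1,a2 --group2 b1,b2 --out fst.tsv

# diversity-reduction introgression scan
wheatscan introgression pi-scan --target pd.tsv --control ctl.tsv --out segs.bed

# k-mer mapping approach
wheatscan kmer count --fasta donor.fasta -k 51 --out donor.kmers
wheatscan kmer diff  --a donor.kmers --b other.kmers --out specific.kmers
wheatscan kmer scan  --genome wheat.fasta --kmers specific.kmers --out cov.tsv
wheatscan kmer call  --donor cov.tsv --other other_cov.tsv --out segs.bed

# identity-by-state variation scans
wheatscan ibs scan --reference wheat.fasta --kmers acc.kmers --out var.tsv
wheatscan ibs consensus --track a.tsv --track b.tsv --out min.tsv
wheatscan ibs segments --track var.tsv --cutoff 30 --out ibs.bed

# RIL bin genotyping
wheatscan binmap genotype --observations obs.tsv --markers markers.tsv \
    --chrom-lengths lengths.tsv --out bins.tsv

# MutMap
wheatscan mutmap index --bulk bulk.tsv --out-records rec.tsv --out-windows win.tsv
wheatscan mutmap candidates --records rec.tsv --windows win.tsv --out interval.bed

# centromeres and LTR dating
wheatscan centromere density --peaks peaks.bed --chrom-lengths lengths.tsv --out d.tsv
wheatscan centromere call --density d.tsv --out centromeres.bed
wheatscan ltr age --pairs ltr_pairs.fasta --rate 1.3e-8 --out ages.tsv
```

Each invocation writes a JSON run manifest (inputs, parameters, seed,
sha256 checksums of outputs) next to its outputs.

## Conventions

Internal coordinates are 0-based half-open; VCF positions are 1-based;
BED output is 0-based half-open. Genotypes are haploid-coded for inbred
material (0 = ref, 1 = alt, het available behind explicit flags). All
randomness derives from a single integer seed.
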