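# sexscan

Coverage-based discovery of sex-specific (hemizygous) genomic regions from
sexed whole-genome read-depth data, and in-silico design of a one-reaction
PCR sexing assay.

Given per-base depth tables for a cohort of phenotypically sexed
individuals, the pipeline:

1. **scans** every position with Welch's t-test plus presence/absence rules
   (group mean depth ≥ 5 in the carrying sex, depth ≤ 0 in every individual
   of the other sex) and merges qualifying runs into regions larger than
   50 bp (`coverage_scan`);
2. **verifies hemizygosity** by the depth-ratio argument — a single-copy
   region sits at ~0.5× the genome-wide mean of the carrying sex and ~0 in
   the other (`ploidy_assessment`);
3. **locates and aligns the diploid paralog** of each called region with a
   seeded k-mer search and a Gotoh affine-gap global aligner, and
   inventories the deletions separating the two copies
   (`paralog_alignment`);
4. **designs a single primer pair** in alignment windows conserved between
   the paralogs, so one reaction co-amplifies both loci; the deletion-bearing
   copy yields a shorter product, and the gel banding pattern (two bands =
   ZW female, one band = ZZ male) reads out genetic sex (`marker_design`);
5. ties everything together behind a CLI with a **synthetic-data module**
   that plants a ground-truth hemizygous region for end-to-end validation
   (`synthetic_data`, `pipeline_cli`).

## Test

```sh
python -m pytest -q tests/
```

The suite includes property tests (hypothesis) and an acceptance module
(`tests/test_acceptance.py`) checking coordinate arithmetic, oracle
equivalence of the Welch test / region merger / aligner against independent
brute-force implementations, planted-region recovery across seeds, and the
end-to-end pipeline.

## CLI

```sh
# synthetic cohort with a planted 598 bp hemizygous region
sexscan simulate --seed 1 --out fixture/

# scan depth tables for female-specific regions
sexscan scan --depth fixture/depth.tsv --samples fixture/samples.tsv \
             --out scanout/ --min-depth 5 --p 1e-4 --min-len 51 --target-sex F

# full pipeline on simulated inputs (scan -> ploidy -> paralog -> primers -> PCR)
sexscan run-all --seed 1 --out run/

# in-silico PCR and banding-based sex calls
sexscan pcr --forward CGTGTGTTGATTGGCTGA --reverse TGGCGATGAGAGCCGAGT --templates ref.fa
sexscan sex-call --bands 569,339 --shared-size 569 --w-size 339   # -> ZW
```

`run-all` writes `regions.bed`, `regions.tsv`, `coverage.tsv`,
`ploidy.json`, `alignment.txt`, `gaps.tsv`, `primers.tsv`,
`amplicons.fasta` and `summary.json` into the run directory. Exit codes:
0 ok, 2 precondition failure, 3 stage failure.

## File formats

* depth tables: samtools-depth style TSV (`contig  pos  d1 … dn`), 1-based,
  with an optional `#contig  pos  s1 … sn` header fixing sample order;
  missing positions are densified to zero depth by default;
* sample sheet: TSV `sample  sex` with sex in {F, M} (case-insensitive);
* intervals are 1-based inclusive internally; BED output is 0-based
  half-open;
* FASTA via biopython; gene tables as `gene_id  contig  start  end  strand`.

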