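# markercompare

Tools for comparing a dominant presence/absence fingerprint dataset
(AFLP-style 0/1 band tables) with a SNP dosage dataset (RADseq-style
matrices) over the same individuals:

- **Replicate-guided locus denoising** — a single sequential pass that drops a
  locus iff removing it strictly lowers the sum of p-distances between blind
  replicate pairs, with a full decision log.
- **Ordination outlier screen** — per primer combination, Jaccard distances →
  2-d non-metric MDS → per-region 90% coverage ellipses; individuals outside
  their ellipse in >50% of combinations, or combinations with >10% outside
  individuals, are flagged.
- **Dissimilarities** — p-distance, Jaccard (binary bands), Gower (dosages
  with pairwise deletion of missing calls and per-locus range scaling).
- **Statistics from first principles** — ANOSIM Global R, the Mantel test
  (Pearson, joint row/column permutation) and NMDS (Kruskal stress-1,
  isotonic regression + Guttman majorization), all with seeded permutation
  p-values using the add-one convention.
- **Locus rarefaction** — repeated random locus subsets in fixed steps, with
  Global R and Mantel-r-vs-full-matrix per replicate, per-step mean ± SD,
  explicit not-applicable records for degenerate draws, and an overlay of the
  fingerprint dataset's statistics at its matched locus count.
- **Synthetic paired data** — a Balding–Nichols style F-model generator that
  produces matched fingerprint and SNP datasets with known regional
  structure, replicate scoring noise and missing-at-random dropout, so the
  whole pipeline is testable end to end.

## CLI

```sh
markercompare simulate --regions 5 --per-region 3 --aflp-loci 500 \
    --snp-loci 5000 -F 0.3 --epsilon 0.05 --missing 0.2 --replicates 3 \
    --seed 1 --out-prefix sim

markercompare qc --aflp sim_aflp.tsv --meta sim_meta.csv --out-prefix qc \
    [--per-combo] [--iterate] [--seed 1]

markercompare distance --input qc_filtered.tsv --type aflp --out d_aflp.csv
markercompare distance --input sim_snp.csv   --type snp  --out d_snp.csv

markercompare anosim --dist d_snp.csv --meta sim_meta.csv --perms 9999 --seed 1
markercompare mantel --d1 d_aflp.csv --d2 d_snp.csv --perms 9999 --seed 1
markercompare nmds   --dist d_aflp.csv -k 2 --out coords.csv

markercompare rarefy --snp sim_snp.csv --meta sim_meta.csv --aflp qc_filtered.tsv \
    --step 50 --reps 50 --perms 999 --seed 1 --out rarefaction.json [--plot rf.svg]

markercompare compare --config run.yaml --out-dir out/
```

`compare` reads a YAML config (`aflp: {table, meta}`, `snp: {table, format,
max_missing}`, `stats: {permutations}`, `rarefaction: {...}`, `seed`) and
writes `summary.json` / `summary.txt` plus all per-stage artifacts; the
summary embeds a manifest from which the run is exactly reproducible.

## File formats

- **Binary marker table**: delimited text (tab/comma/semicolon sniffed),
  header of locus ids (`comboTag:locusName` optional), leading sample-id
  column, cells 0/1.
- **Genotype matrix**: dosage CSV (`0/1/2/NA`) or the two-rows-per-individual
  STRUCTURE dialect (integer allele codes, `-9` missing; collapsed to dosage
  of the lowest observed allele code per locus).
- **Metadata**: CSV with columns `sample, region, replicate_of, match_key`.
- **Distance matrix**: full square CSV with labels.

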