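# meatseq

Identification of animal-derived components in meat products from
mitochondrial sequencing reads. The toolkit builds a category-curated
mitochondrial genome database, defines marker amplicons by in-silico PCR with
universal primers (CYTB / COI / D-loop presets), maps amplicon or shotgun
reads with an internal seed-and-extend mapper (or ingests an external SAM),
assigns each read to exactly one meat category by the unique-read rule —
reads whose alignments span more than one category are discarded — and
reports per-category read counts, percentages, differences against a target
composition, qualitative presence calls, concordance with a reference
method, and subsampling precision (mean / SD / RSD).

A fully deterministic synthetic-data generator (divergent multi-species
"mitogenomes" grouped into categories, implanted primer cassettes, conserved
cross-category blocks, error-bearing mixed reads) makes every stage testable
with no external downloads.

## Package layout

| module | role |
| --- | --- |
| `meatseq.reference_db` | genome records, category map, filtering, both-strand k-mer index, persistence |
| `meatseq.insilico_pcr` | primer-site search (IUPAC-aware, ungapped), amplicon extraction, marker panel |
| `meatseq.read_classifier` | internal mapper, unique-read rule, FASTQ/SAM tallies |
| `meatseq.mixture_report` | proportions, target comparisons, presence calls, concordance, depth, CSV output |
| `meatseq.subsampling` | seeded exact-count / Bernoulli FASTQ subsampling, RSD study |
| `meatseq.phylo_marker` | p-distance / Jukes–Cantor, center-star alignment, neighbor joining, category coherence |
| `meatseq.synth_fixtures` | deterministic synthetic worlds and read simulation |

## CLI

All commands are subcommands of `meatseq`:

```sh
# generate a synthetic six-category sample plus its reference world
meatseq simulate --preset h1 --seed 7 --n-reads 30000 \
    --out reads.fq --truth truth.csv --world-out ref.fa,categories.cfg

# build and persist the reference database
meatseq build-db --fasta ref.fa --categories categories.cfg --k 21 --out db/

# slice the CYTB marker panel
meatseq insilico-pcr --db db/ --preset cytb --max-mismatch 3 \
    --out amplicons.fa --skips skips.txt

# classify reads and report proportions
meatseq classify --db db/ --fastq reads.fq --out result.csv
meatseq report --counts result.csv --out report.csv --calls-out calls.csv

# external alignments instead of the internal mapper
meatseq classify --db db/ --sam aln.sam --out result.csv

# subsampling and the throughput/precision study
meatseq subsample --fastq reads.fq --ratio 0.005 --seed 7 --out sub.fq
meatseq rsd-study --fastq reads.fq --db db/ \
    --ratios 0.001,0.005,0.025,0.125,0.625 --reps 4 --seed 7 --out rsd.csv

# marker phylogeny and category coherence
meatseq tree --amplicons amplicons.fa --model p --out tree.nwk \
    --coherence coherence.csv

# concordance of +/- calls against a reference method
meatseq concordance --test ngs_calls.csv --ref qpcr_calls.csv --out conc.csv
```

Category maps are plain text, one category per line:

```
Pork: Sus
Beef: Bos, Bubalus, Bison
Mutton: Capra, Ovis, Pseudois
```

## Notes on defaults

- Coordinates are 0-based, half-open throughout.
- Mapper: k = 21 seeds, ungapped extension, min identity 0.90 over ≥ 0.80 of
  the read; one best hit per genome; quality strings ignored; reads < 50 bp
  counted unmapped.
- In-silico PCR: ungapped primer matching, ≤ 3 mismatches with the final two
  3′ bases exact; templates circular by default; products 100–1000 bp
  (250–500 bp for the CYTB preset).
- Subsampling default is exact-count (`floor(N·ratio)` without replacement);
  percentages round half-up to 2 decimals at presentation only.
- Presence calls default to a 0.5% threshold of mapped unique reads.
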