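# ogmapper

Orthology-based functional annotation of (meta)genomic sequences against a
compact, plain-text reference-database bundle.

The pipeline mirrors the classic four-stage annotation workflow:

1. **Gene prediction** — deterministic ORF calling from assembled contigs
   (six-frame, table-aware, start codons normalized to M).
2. **Search** — seed-and-extend Smith–Waterman alignment of queries against
   the reference proteins, with `fast` / `sensitive` / `iterative`
   sensitivity presets, blastx-like mode for nucleotide reads, and a total,
   documented hit ranking (evalue, bit score, target id).
3. **Orthology** — the best hit (seed ortholog) is resolved to an
   orthologous group at a taxonomic scope (automatic or lineage-fixed); the
   pairwise-orthology relation is expanded into a typed transfer set
   (one2one / one2many / many2one / many2many) with in-paralogs excluded.
4. **Transfer & reporting** — functional terms (GO, KEGG, EC, BiGG, CAZy,
   names, COG categories, descriptions) are aggregated across the ortholog
   set (union or majority policy); protein domains are annotated in three
   modes (transfer from the seed, realignment refinement under gathering
   thresholds, or full de novo PSSM scanning with clan disambiguation);
   results are written as annotation/ortholog/domain TSVs and optionally as
   functionally decorated GFF3.

A first-class simulator (`ogmapper.simdata`) generates ground-truth
benchmarks — species taxonomy, duplication–loss gene families, sequence
evolution with branch-rate heterogeneity, paralog-divergent functional
labels and planted domains — and emits a valid reference database plus
held-out queries with an answer key, so the whole pipeline is testable
offline.

## Command line

```sh
# generate a ground-truth benchmark (database + queries + answer key)
ogmapper simulate --seed 1 --out bench --n-species 16 --n-families 100

# annotate protein queries end to end
ogmapper annotate --db bench/db --queries bench/queries.faa --out run \
    --preset iterative --domain-mode refine

# contigs: ORF prediction first, plus decorated GFF output
ogmapper annotate --db bench/db --queries contigs.fa --itype contigs --out run

# reads: blastx-like six-frame search
ogmapper annotate --db bench/db --queries reads.fa --itype reads --out run

# taxon-restricted database
ogmapper subset-db --db bench/db --taxon 3 --out bench/db_clade3

# decorate an arbitrary GFF3 with a previous annotation report
ogmapper decorate-gff --gff genes.gff --annotations run.annotations.tsv \
    --out genes.decorated.gff

# gene prediction only
ogmapper orfs --contigs contigs.fa --out-proteins p.faa --out-gff genes.gff
```

Outputs: `<out>.annotations.tsv` (fixed 17-column layout),
`<out>.orthologs.tsv` (one row per query/ortholog with pair type),
`<out>.domains.tsv`, `<out>.hits.tsv` (12-column tabular alignments),
`<out>.unmatched.txt`, and for contig input `<out>.proteins.faa` plus
`<out>.genes(.decorated).gff`. `--no-header-metadata` suppresses the `##`
run-metadata lines for byte-reproducible comparisons.

## Reference database layout

One directory of diffable text files: `proteins.faa` (record ids carry a
`tax=<id>` tag), `taxonomy.tsv`, `ogs.tsv`, `orthologs.tsv`,
`annotations.tsv`, `domain_models.tsv` + `domain_pssms.tsv`,
`domain_annotations.tsv`. Loading validates referential integrity,
per-level OG membership and hierarchical OG nesting.

## Acceptance

`tests/test_acceptance.py` implements the acceptance criteria (aligner and
LCA oracle equivalence, gene-tree ground-truth recovery, the
orthology-vs-best-hit precision experiment with its no-divergence control,
domain-mode precision/recall ordering, subset-database byte-identity,
iterative-search dominance, ORF-finder oracle equivalence and round-trips).

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The build contract defines no numeric acceptance targets (the original
evaluation numbers require external databases), so the script writes an
empty JSON report and prints condensed property-based self-checks.
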