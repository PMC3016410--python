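# petals-network

Mine "petal" subnetworks that connect a mutated driver gene to candidate
partner genes through a refined protein–protein interaction (PPI)
network, then rank those petals against a proteomic target list using a
bimodality statistic on activity-weighted coexpression, with a
permutation null.

## Pipeline

1. **refine** — a logistic regression over four edge features
   (observation count, coexpression, mean endpoint clustering
   coefficient, subcellular-localization overlap) scores every PPI edge;
   edges below an optimized probability cutoff are removed, and missing
   edges are imputed wherever at least one observed edge joins the two
   proteins' families.
2. **blossom** — for each candidate gene, all simple paths from the
   driver within a shortest-path diameter bound (computed on the raw
   network, falling back to the imputed network on disconnection) are
   enumerated in the imputed network. Paths are kept when their mean
   absolute coexpression is at least `gamma` (default 0.6) and their GO
   association-rule support is significant against same-length random
   paths (`p < 0.05`); survivors merge into one petal per candidate.
3. **rank** — each petal's activity-weighted coexpression to the target
   list (the sample) is compared with its coexpression to the whole
   array (the background) via `beta`, minus half the difference of the
   two second moments; a negative `beta` means coordinated positive
   *and* negative coexpression with the targets. Significance comes
   from random target sets of the same size (default 10 000 draws).

## Command line

Generate a fully synthetic input bundle with known ground truth, run
the whole pipeline on it, and inspect the ranking:

```bash
petals simulate --out fixture/ --seed 7
petals -v run --config config.yaml          # see below
cat out/ranking.tsv
```

Minimal `config.yaml` (flags on `petals run` override config keys;
every stage is also available standalone as `petals refine`,
`petals blossom`, and `petals rank`):

```yaml
network: fixture/network.tsv
expression: fixture/expression.tsv
groups: fixture/groups.tsv
gaf: fixture/annotations.gaf
obo: fixture/go.obo
gmt: fixture/pathways.gmt
targets: fixture/targets.txt
candidates: fixture/candidates.txt
families: fixture/families.tsv
localization: fixture/localization.tsv
positives: fixture/positives.tsv   # omit to skip the reliability filter
driver: g0000
out_dir: out
seed: 1
```

Outputs: one petal JSON per candidate (GraphML/SIF also supported),
`blossom_summary.json`, `ranking.tsv`/`ranking.json` (with a clearly
supplementary Benjamini–Hochberg column), and a `manifest.json`
recording config, seeds, input checksums, and stage counters. Re-running
with the same inputs and seed reproduces byte-identical output.

## Input formats

Tab-separated edge lists (`geneA geneB [count [provenance]]`), a genes ×
samples expression TSV with a `sample → WT|MT` sidecar, GAF 2.x
annotations (biological-process aspect), an OBO 1.2 GO graph, GMT
pathway sets, two-column gene→family and gene→compartment maps, and
one-gene-per-line target/candidate lists. All inputs share one
case-sensitive identifier namespace; no ID mapping is performed.

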