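# famdomevo

Comparative phylogenomics of protein families and protein domains:
which lineages gained or lost families, which gained or lost domains,
how member copies duplicated and disappeared, and what that implies
about domain shuffling and adaptation.

The package is aimed at researchers studying proteome evolution across
a fixed species phylogeny — here, nine metazoans spanning vertebrates
(Hsa, Mmu, Gga), arthropods (Dme, Aae, Bmo) and nematodes (Cel, Cbr,
Tsp) with yeast (Sce) and choanoflagellate (Mbr) outgroups.  It
implements the full analysis chain:

1. **Families** — Markov clustering (MCL, inflation 2.0) of a weighted
   protein similarity graph; multi-member clusters are families.
2. **Domains** — per-protein profile-hit tables become ordered domain
   architectures and per-accession domain groups.
3. **Birth/death** — each family or domain is a presence/absence
   character; Dollo parsimony places one gain (on the branch above the
   LCA of the carriers) and a minimal set of losses per character.
4. **Duplication/deletion** — per-family neighbor-joining gene trees,
   rooted by minimum duplication+loss cost, reconciled against the
   species tree by LCA mapping: a gene node mapping to the same
   species node as one of its children is a duplication; skipped
   species nodes charge losses to the branches they bypass.
5. **Rates and indices** — counts divided by branch length *l*
   (substitutions/site), summarized per lineage by
   the family change index log2(B_fam/D_fam), the domain change index
   log2(B_dom/D_dom), the domain shuffling index log2(B_fam/B_dom),
   and the adaptation index AI = log2(B/l) + log2(D/l);
   cross-event Pearson correlations with Student-t significance.
6. **Enrichment** — family-level hypergeometric term
   enrichment/depletion with elim-style refinement and a permutation
   FDR (selection: p < 0.001 and FDR < 0.1).
7. **Simulation** — a forward generator of family/domain evolution
   along the species tree that emits every input the pipeline reads
   (edge list, domain hits, distance matrices, annotations, ontology,
   tree) with per-branch ground-truth event counts for validation.

A packaged fixture ships the species tree and the published
per-lineage event counts for the 17 metazoan lineages, so the
rate/index/correlation layer can be exercised without any external
data.

## Worked example

Recompute the per-lineage indices and cross-event correlations from
the packaged event table:

```
$ famdom-evo reproduce-tables
# Per-lineage indices
  lineage  fam_change  dom_change  shuffling  adaptation
      Hsa        0.46       -0.11       2.18       23.12
      Mmu        0.14       -0.83       1.97       21.43
      ...
      Tsp        0.22       -5.36       6.18       21.33
      ...
      Gga       -3.02       -3.83       1.32       20.95

# Cross-event correlations (rates, 17 lineages)
  event_a   event_b      r     p  n  published_r  agrees_2dp
fam_birth fam_death -0.589 0.013 17        -0.58        True
fam_birth dom_birth  0.596 0.012 17         0.59        True
...

# Duplications per analyzed universal family
metazoa_dup_per_universal_family     2.23
vertebrate_dup_per_universal_family  1.95
```

Reading the output: the human terminal lineage gained family
complexity (fam_change 0.46 > 0) while chicken lost it sharply
(−3.02); the shuffling index is highest in the *T. spiralis* lineage
(6.18) and lowest in chicken (1.32), the signature of domain shuffling
contributing more to new families in nematodes than in birds.  Family
birth and death *rates* are negatively correlated (r = −0.589,
p = 0.013 over the 17 lineages), and the two duplication bursts at the
metazoan and vertebrate LCAs average 2.23 and 1.95 duplications per
universal family.

The same machinery runs on your own data or on simulated data:

```
famdom-evo simulate --seed 42 --out simdir/
famdom-evo cluster --graph simdir/edges.abc --inflation 2.0 --out families.tsv
famdom-evo dollo --families families.tsv --tree simdir/species_tree.nwk --out events.tsv
famdom-evo correlate --events my_events.tsv
```

or end-to-end from a YAML config (`famdom-evo run-all --config cfg.yaml`),
which writes one TSV per stage plus a checksum manifest.

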