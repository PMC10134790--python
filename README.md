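# solomine

Mining and classification of **LuxR solos** — orphan quorum-sensing
receptors — in annotated proteobacterial genomes.

Canonical acyl-homoserine-lactone (AHL) quorum sensing couples a LuxI-family
signal synthase to a LuxR-family receptor, with the two genes genetically
linked (typically < 3,000 bp apart, in tandem or convergent arrangement).
Many proteobacteria additionally carry *LuxR solos*: proteins with the
autoinducer-binding domain (Pfam **PF03472**) and the helix-turn-helix
DNA-binding domain, but no cognate AHL synthase (Pfam **PF00765**) nearby.
Solos listen in on foreign AHLs, plant compounds, pyrones and
dialkylresorcinols, or nothing at all, and are of broad interest in
interspecies and interkingdom signalling. `solomine` is for computational
microbiologists who want to survey them systematically.

## What the pipeline does

1. **Solo detection** — a protein with PF03472 is a solo iff none of the
   surrounding 8 genes (4 up- and 4 downstream in gene-rank order on the
   same replicon) encodes PF00765. Complete luxI/luxR pairs are classified
   geometrically (tandem / convergent / divergent / complex, linkage
   < 3,000 bp).
2. **Sequence clustering** — greedy incremental clustering of solo proteins
   at ≥ 80% identity with ≥ 80% bidirectional coverage against
   representatives (Needleman–Wunsch, match +1 / mismatch 0 / gap −1;
   identity counted over the shorter sequence).
3. **Context subgrouping** — for clusters with > 50 members, the fraction of
   members carrying each Pfam in their neighborhood is computed, accessions
   below 5% prevalence are dropped, profiles are embedded in 3 dimensions
   (deterministic PCA by default, seeded UMAP optionally) and
   density-clustered with DBSCAN (eps 0.5, min_samples 10; noise = −1).
4. **Ligand-class hints** — queries are numbered by global alignment to a
   TraR-like anchor and scored at the nine conserved residues W57, Y61,
   D70, P71, W85, G113 (ligand-binding cavity) and E178, L182, G188 (HTH).
   The W57M/Y61W substitution plus an adjacent proline-iminopeptidase
   (*pip*) gene flags plant-associated-bacteria (PAB) solos; TYDQCS /
   TYDQYI motifs in place of the canonical WYDPWG residue set flag
   pyrone/dialkylresorcinol (PluR/PauR-like) receptors; full conservation
   yields an AHL-type hint. Hints are sequence/context heuristics, never
   functional claims.
5. **Phylogeny & report** — neighbor-joining tree of cluster representatives
   on 1 − identity distances, annotated Newick output, and the per-genome
   solo-count distribution (percent of genomes with zero / one / multiple
   solos).

A seeded synthetic-corpus generator plants luxI/luxR pairs, solos with
designed sequence and neighborhood signatures, and decoy genes, and emits a
machine-readable truth table, so the entire pipeline is testable with no
external downloads.

## Worked example

```sh
solo-mine simulate --out demo/corpus --seed 7
solo-mine run --input demo/corpus --out demo/out --seed 7
```

prints

```
wrote 30 genome files and demo/corpus/truth.tsv
genomes: 10  solo hits: 9  zero/one/multi: 20.0/70.0/10.0 %
outputs: clusters.tsv, context_profiles.tsv, ligand_classes.tsv, solos.tsv,
subgroups.tsv, summary.json, tree.nwk, tree_annotations.tsv
```

i.e. of the 10 synthetic genomes, 2 carry no solo, 7 carry exactly one and
1 carries several; the 9 solo hits collapse into 5 sequence clusters
(`summary.json` → `"n_clusters": 5`), whose class hints split into 6
AHL-type, 2 PAB-type and 1 pyrone/DAR-type (`"class_counts"`), matching the
planted truth table. `solos.tsv` records, per LuxR call, the solo verdict,
the blocking luxI protein (if any) and the window's Pfam content:

```
genome_id  replicon_id  protein_id   is_solo  blocking_luxI  window_genes          luxr_length_ok
G0001      G0001_rep0   G0001_p0005  True                    PF03466;;;;PF00196,... True
G0001      G0001_rep0   G0001_p0024  False    G0001_p0023    ...;PF00765;...        True
```

The same run is available stage by stage (`solo-mine detect|cluster|
subgroup|classify|tree`), and `solo-mine report --out demo/out` reprints
the distribution summary of a finished run. Everything is deterministic
given `--seed`: rerunning produces byte-identical outputs.

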