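# metasecretome

Prediction, functional annotation and gastrointestinal biogeography of the
**metasecretome** — the collection of proteins that the members of a
microbial community secrete out of the cytoplasm — from collections of
metagenome-assembled genomes (MAGs).

Gut bacteria export digestive enzymes (notably carbohydrate-active
enzymes, CAZymes) into the lumen and mucus layer, where they shape
cross-feeding and host nutrition. This package implements, as a tested and
reusable library + CLI, the computational pipeline for mapping that
secreted proteome:

1. **Gene handling** — ingest Prodigal-style protein FASTA (or call ORFs on
   synthetic genomes), require ≥ 482 genes per MAG, reduce to one MAG per
   species-level OTU.
2. **Clustering** — greedy centroid clustering of all proteins at 95%
   amino-acid identity (BLOSUM62, affine gaps, identity excluding
   terminal-gap columns), keeping clusters with ≥ 5 members.
3. **Secretion calling** — parse SignalP 5.0 and TMHMM 2.0 output for the
   cluster centroids; a protein is *secreted* iff it carries a Sec/SPI or
   Tat signal peptide and no transmembrane helix (lipoprotein tags are
   excluded); labels propagate from centroid to cluster members.
4. **Annotation** — HMMER3 domain tables filtered dbCAN-style (HMM
   coverage ≥ 0.35, E ≤ 1e-15, overlap resolution) for CAZyme families and
   best-hit (E ≤ 0.001) for orthologous groups / COG categories / EC
   numbers.
5. **Ordination** — MAG × (CAZyme family × secretion status) count
   matrices, Spearman-correlation distances (d = 1 − ρ), principal
   coordinates, single-linkage row ordering, and group profiles with a −25
   pseudovalue for MAGs lacking a family.
6. **Biogeography** — unique metagenomic reads mapped to secreted ORFs,
   per EC function, converted to a pseudo-RPKM

   ```
   pseudo-RPKM(EC, sample) = reads(EC, sample) /
       ( mean ORF length of the EC [kb] × library size [10⁶ reads] )
   ```

   averaged per GI (site, compartment), filtered at > 50 RPKM prevalence,
   max-normalized per EC, and summarized as mucosa/lumen ratios.
7. **Statistics** — Mann-Whitney U (exact for small tie-free samples),
   Kruskal-Wallis with tie correction, Bonferroni, and the > 50-MAG
   major-phylum rule.

A fully ledgered **synthetic-community generator**
(`metasecretome.simulate`) stands in for real MAG catalogs so that every
stage admits parameter-recovery tests at desk scale: planted per-phylum
secretion fractions (0.30/0.25/0.10), longer secreted proteins (482 vs
329 aa on average), a shared Bacteroidetes/Verrucomicrobia-like CAZyme
repertoire, and site/compartment-specific EC enrichment in read data.

## Worked example

Simulate a desk-scale community and run the whole pipeline:

```bash
metasecretome run-all --seed 7 --outdir out/
```

which writes, under `out/`: `proteins.faa`, `clusters.tsv`,
`secretion.tsv`, `annotations.tsv`, `cazyme_matrix.tsv`,
`pcoa_coordinates.tsv`, `rpkm_raw.tsv`, `rpkm_normalized.tsv`,
`rpkm_ratio.tsv`, `phylum_stats.tsv` — each with a provenance header
recording the config hash, seed and thresholds. The same stages are
available individually (`simulate`, `call-orfs`, `cluster`, `classify`,
`annotate`, `ordinate`, `biogeo`, `stats`) and as library functions.

Or in Python:

```python
from metasecretome.simulate import small_community_config, generate_community
from metasecretome.cluster import greedy_cluster, filter_clusters_by_size

community = generate_community(small_community_config(seed=1))
clusters = greedy_cluster(community.protein_records(), threshold=0.95)
print(len(clusters))                                   # 146
big = filter_clusters_by_size(clusters, 5)
```

The 880-protein community collapses to its 146 planted base proteins —
the greedy partition recovers the ground-truth clusters exactly on this
fixture (`tests/test_simulate.py`, `tests/test_acceptance.py`).

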