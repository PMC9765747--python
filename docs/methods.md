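# Methods

This note documents the models, rules and numerical choices behind
`metasecretome`, in the spirit of the methods documentation that simulation
and statistics packages ship alongside their APIs. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The analysis in one paragraph

Given a collection of genome bins (MAGs) with called protein-coding genes,
the pipeline (i) clusters all proteins greedily at 95% amino-acid identity,
(ii) calls secretion on cluster centroids only — a protein is *secreted*
when it carries a Sec/SPI or Tat signal peptide and no predicted
transmembrane helix; lipoprotein (Sec/SPII) tags are excluded because the
mature protein stays membrane-anchored — and propagates each centroid's
label to all cluster members, (iii) annotates proteins with CAZyme
families, orthologous groups, COG categories and EC numbers from HMMER3
domain tables, and (iv) maps metagenomic reads from gastrointestinal
samples onto secreted proteins to quantify where along the gut each
secreted function is abundant, using a pseudo-RPKM statistic.

## Gene calling and genome-level filters

The built-in ORF caller reports, in all six reading frames, the maximal
open reading frame per stop codon: from the most upstream ATG/GTG/TTG
following the previous in-frame stop through the first in-frame stop,
inclusive. The minimum length is 15 nt counted start-through-stop, i.e.
deliberately permissive toward very short genes. This caller exists so
synthetic genomes can be processed end to end; real gene-caller output
(Prodigal protein FASTA) is ingested directly through its headers, and no
attempt is made to reproduce Prodigal's coding-potential scoring, partial
genes at contig edges, or its single-vs-metagenome modes.

Genome bins are required to carry at least 482 called genes — the gene
count of the smallest known bacterial genome — and collections are reduced
to one genome per species-level OTU, drawn uniformly with a fixed seed.
The draw depends only on the OTU membership and the seed, never on input
order.

## Pairwise identity and greedy clustering

Identity between two proteins is computed from one deterministic optimal
global alignment: BLOSUM62 substitution scores, affine internal gap
penalties (open 10, extend 1 on the integer score scale), and terminal
gaps priced at 1 per residue. Identity is matching columns divided by
alignment columns *excluding* terminal-gap columns; internal gap columns
count as mismatches. Among co-optimal alignments the one with the most
matching columns, then the fewest counted columns, is used, which makes
the reported identity a well-defined function of the sequence pair.

Terminal gaps must carry a small, nonzero cost. If they were free, the
maximum-score alignment of two *unrelated* proteins would collapse to a
tiny perfect overlap — a single shared residue yields "100% identity" —
and greedy clustering at any threshold would merge unrelated sequences.
The 1-per-residue terminal price mirrors the cheap-but-nonzero terminal
gap defaults of greedy centroid clusterers (USEARCH family) while keeping
fragment-to-full-length matches possible: a 95%-identical fragment nested
in a longer protein still aligns positively and clusters.

Clustering is greedy and centroid-based: sequences are processed in
decreasing length (ties broken lexicographically by id); each sequence
joins the first existing centroid reaching the identity threshold (default
0.95), else founds a new cluster. No k-mer prefilter or heuristic
shortcut is applied, so the partition is exactly the one this definition
implies; the cost is that clustering is quadratic in practice, which is
why the default end-to-end community is sized at ~900 proteins (below).
The cluster-size floor is ≥ 5 members by default, with a strict (> 5)
variant available, reflecting the two readings of that rule.

## Secretion calling

The SignalP 5.0 summary classes map to four signal-peptide classes
(Sec/SPI, Tat/SPI, lipoprotein Sec/SPII, none); TMHMM 2.0 short-format
lines supply the predicted helix count. The final call is the strict truth
table: secreted iff class ∈ {Sec/SPI, Tat} and helices = 0. Any predicted
helix disqualifies a protein, *including* a helix overlapping the signal
peptide itself — the known confound between hydrophobic signal peptides
and N-terminal helix predictions is deliberately left in by default, with
an opt-in flag that discounts helices lying entirely within the first 60
residues (using topology spans when present). Proteins missing from a
prediction file are treated as unlabelled (no tag, no helices) with a
logged warning, so partial tool output degrades gracefully rather than
aborting. Proteins that never reach secretion calling (members of clusters
below the size floor) count as nonsecreted in downstream summaries, which
slightly underestimates the secretome — the same bias the centroid-only
annotation strategy accepts by design.

Biosynthetic cost summaries use the Akashi–Gojobori per-residue costs in
high-energy phosphate-bond equivalents, shipped as an editable two-column
table; any residue not in the table is skipped with a warning (or raises,
configurably).

## Functional annotation

Domain tables are HMMER3 `--domtblout` files in hmmscan orientation; the
independent (i-)E-value of each domain is used. CAZyme hits pass a
dbCAN-style filter: per protein, hits are admitted best-E-value-first and
a hit overlapping an already-admitted hit by more than half the shorter
alignment is discarded; survivors must cover ≥ 0.35 of the HMM at E-value
≤ 1e-15. Admission ordering (E-value, then family id, then coordinates)
makes the survivor set independent of input order. Orthologous-group
searches keep the best hit per protein at E ≤ 0.001, ties broken
lexicographically. Throughout, a filter phrased as a "minimum e-value" is
interpreted as an upper bound on the E-value — the standard meaning of
these thresholds; the literal reading would discard every good hit.

CAZyme family → representative EC and → broad substrate class (animal
carbohydrate, plant cell wall, starch/glycogen, peptidoglycan,
sucrose/fructan) ship as an editable seed table covering the common gut
GH/PL families; users with richer mappings can substitute their own file.

## Ordination of CAZyme repertoires

The repertoire matrix counts ORFs per genome per (family × secretion
status) column — a family observed both secreted and nonsecreted becomes
two columns, so secretion status is part of the repertoire. Distance
between genomes is `1 − ρ` with Spearman's rank correlation of their count
profiles (average ranks on ties; constant profiles are an error naming the
offending genome). The simple `1 − ρ` form is used rather than
`√(1 − ρ)` or `(1 − ρ)/2`; the choice is recorded in output metadata.
Because rank correlation is scale-free, counts are not normalized per
genome first.

PCoA is classical metric scaling: Gower double-centering of `−D²/2`,
eigendecomposition, coordinates scaled by the square root of positive
eigenvalues. Correlation distances need not be Euclidean, so negative
eigenvalues can occur; they are reported in the eigenvalue output but
their axes are dropped, without a Cailliez correction — the information is
surfaced, not hidden. Heatmap row ordering uses single-linkage
agglomeration on Euclidean row distances with a deterministic,
input-order-independent leaf order. Families present in only one genome
can be dropped before ordering (flag), matching heatmap practice; the
PCoA matrix keeps them by default. Group-level family profiles average
per-genome secreted percentages with a pseudovalue of −25 for genomes not
encoding the family, so non-encoders pull a group's mean down instead of
silently vanishing.

## Gastrointestinal biogeography

Read→ORF assignments come from SAM (primary alignments, MAPQ ≥ 10 by
default) or a three-column table; a read with more than one primary target
is discarded entirely ("unique reads"). For each EC function,

pseudo-RPKM = reads assigned to the EC /
              ((mean ORF length of the EC in kb) × (library size / 10⁶))

where the mean nucleotide length is computed once over all representative
secreted ORFs carrying that EC — a property of the gene catalog, not of
each sample. The library-size denominator defaults to the QC-passed read
count from the sample metadata, with a flag to use mapped-read totals
instead (the two readings of an ambiguous convention; the default is
recorded in output provenance). ORFs with several ECs contribute their
reads to each EC, and each EC's length denominator is computed over its
own ORFs.

Samples from the same (site, compartment) are averaged arithmetically;
stool is a single undivided habitat. EC rows are kept only when some
habitat strictly exceeds 50 pseudo-RPKM. Two derived views are produced:
each row divided by its maximum (so every retained EC attains exactly 1.0
at its best habitat — this max-normalization is sometimes loosely called a
z-score; a true per-row z-score view is provided under that name), and the
mucosa/lumen ratio per site, with zero-lumen cells marked undefined (NaN)
unless an epsilon stabilizer is requested.

## Rank statistics

Mann-Whitney U uses exact enumeration of all group labelings when both
groups have ≤ 8 observations and the pooled data are tie-free, otherwise
the normal approximation with tie and continuity corrections; the
formulas reproduce the standard scientific-Python defaults so results are
comparable with analyses run through that stack, and the suite pins this
with a cross-implementation check. Kruskal-Wallis uses the tie-corrected H
with a χ² reference. Bonferroni is `min(1, m·p)`. "Major" phyla are those
with strictly more than 50 genomes; per-phylum plots additionally use a
≥ 5-genome inclusion floor, kept as a separate threshold.

## The synthetic community generator

The generator plants, per phylum: a secretion fraction (defaults 0.30 /
0.25 / 0.10 for the Bacteroidetes-like, Verrucomicrobia-like and
Firmicutes-like phyla), lognormal protein lengths with means 482 aa
(secreted) and 329 aa (nonsecreted) at shape σ = 0.35, a CAZyme family
profile (the Bacteroidetes- and Verrucomicrobia-like phyla share one
profile rich in mucin/host-glycan hydrolases so their repertoires
co-cluster; the Firmicutes-like profile centres on GH1/GH4/GH18-style
families), a per-phylum secreted-CAZyme fraction (0.20 / 0.18 / 0.03),
and COG category rates. Each phylum's proteins derive from a pool of
"base" proteins copied into genomes with 1% per-residue substitution, so
true clusters exist comfortably above the 95% identity threshold and the
ground-truth ledger records every ORF's cluster, labels and lengths.
Secreted proteins receive a planted N-terminal export tag (Sec-like or
twin-arginine-like); prediction files (SignalP 5 summary, TMHMM short,
HMMER3 domtblout) are emitted from the ledger with independent
class-flip and false-helix corruption at configurable rates, plus decoy
domain hits that must fail the downstream filters.

Read simulation draws, per sample, a phylum by habitat-specific abundance
(Firmicutes-like dominating the upper GI, Bacteroidetes-like the lower,
minor phyla mucosa-leaning, stool mirroring the colonic lumen), then an
ORF with probability proportional to nucleotide length times any EC
enrichment multiplier for that habitat; the default design plants a 4×
colon-lumen enrichment of beta-galactosidase (EC 3.2.1.23). Every draw is
ledgered. All outputs are byte-reproducible for a fixed seed.

What the generator does *not* emulate: realistic sequence evolution
(substitutions are i.i.d.; no indels within clusters), sequencing error
or quality strings, assembly/binning artifacts, inter-phylum homology,
genuine signal-peptide sequence statistics (predictions are emitted from
the ledger, not recomputed from sequence), or correlated annotation
errors. Passing recovery tests therefore demonstrates that the pipeline's
logic is faithful — not that the upstream predictors are accurate on real
data.

## Problem sizes and runtime choices

Exact, prefilter-free alignment makes greedy clustering the one expensive
stage, so the package uses two community scales: a full-size default
(3 × 20 genomes × 250 ORFs = 15,000 proteins) for parameter-recovery
analyses that operate on centroids and ledger clusters without
re-clustering, and a desk-scale community (8/6/8 genomes × 40 ORFs ≈ 900
proteins, redundancy 6 so typical clusters clear the ≥ 5 floor) for runs
that include clustering; the latter completes end to end in about two
minutes on one CPU. Recovery checks under label noise re-corrupt the
prediction files of one fixed community across seeds, since the noise
process — not community assembly — is the randomness under test. Read
simulations use 10⁵ reads per sample, at which the planted 4× enrichment
is recovered with large margin.

## Known limitations

* Identity is defined through one tie-broken optimal alignment; a
  different but co-optimal alignment path could justify a different
  identity value, and other tools' identities will differ in the third
  decimal for gappy pairs.
* The greedy partition depends on the processing order (length, then id),
  as in all centroid clusterers; it is deterministic, not canonical.
* Secretion calls inherit every limitation of the upstream predictors;
  periplasmic proteins and proteins exported by non-Sec/Tat routes are
  out of reach by construction.
* Per-EC pseudo-RPKM inherits the catalog's mean-length estimate; ECs
  carried by few ORFs have noisy denominators.
* The mucosa/lumen ratio is undefined where the luminal signal is zero;
  the epsilon-stabilized variant trades that honesty for plottability.
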