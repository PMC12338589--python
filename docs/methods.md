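# Methods

This note documents the statistical model behind `epoclib`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate.

## Inference model

A gene family is a protein alignment and a tree over eukaryotic and
prokaryotic sequences, each sequence carrying a curated class-level taxon
label (e.g. Asgard, Alphaproteobacteria, Metazoa). The quantity of interest
is the prokaryotic clade most likely to be the sister group of the
eukaryotic clade — a proxy for the gene's prokaryotic donor lineage.

Rather than trusting the single estimated topology, each nearby prokaryotic
clade defines a constrained hypothesis: "the eukaryotic clade is this
candidate's sibling; everything else retains its arrangement". The
constrained topology is produced by pruning the eukaryotic subtree and
regrafting it onto the midpoint of the candidate's stem; branch lengths are
then re-optimised on the fixed topology. This coordinate-wise re-optimisation
(bounded golden-section per edge against exact inside/outside partial
likelihoods, two sweeps, tolerance 1e-4) is the desk-scale analogue of a
constrained maximum-likelihood tree search: the topological constraint is
what the hypothesis asserts, and branch lengths are nuisance parameters.

Support is quantified with Expected Likelihood Weights estimated by RELL:
per-site log-likelihoods are computed once per hypothesis (Felsenstein
pruning; gaps and ambiguous residues are missing data with partial
likelihood 1 in every state; per-node per-site rescaling prevents
underflow); each of 1000 bootstrap replicates resamples site indices with
replacement, totals the fixed per-site values, and converts the totals to
normalised likelihood weights; the ELW of a hypothesis is its mean weight.
ELWs are in [0, 1] and sum to 1 over the candidate set. RELL avoids
re-optimising branch lengths per replicate; this is accurate when the
resampled optimum stays close to the full-data optimum, which holds for the
alignment sizes used here (hundreds of columns).

Assumptions worth stating: sites are independent and identically distributed
given the tree (no rate heterogeneity across sites by default); the
substitution process is reversible and homogeneous across the tree; the
candidate set contains the true sister (it is restricted to the 12
topologically closest prokaryotic clades, distance counted as non-root
internal nodes on the connecting path, ties broken by larger clade then
lexical label).

## Substitution models

The default `eq20` model is a 20-state equal-rates chain with uniform
stationary frequencies, the amino-acid analogue of Jukes–Cantor. It was
chosen as the default because it admits closed forms
(P_same(t) = 1/20 + (19/20)·e^(−20t/19)) against which both the simulator
and the pruning likelihood are verified exactly. An `empirical` option
provides realistic exchangeabilities derived at run time from the BLOSUM62
log-odds matrix: exponentiating the half-bit entries recovers the
target/background odds ratios O, background frequencies consistent with a
joint q_ij = p_i p_j O_ij are the solution of the linear system O·p = 1,
and O (zero diagonal) serves as the symmetric exchangeability matrix. Both
models are normalised to one expected substitution per site per unit branch
length and applied via symmetric eigendecomposition.

## Preprocessing

- **Taxonomy-aware subsampling** (caps: 30 eukaryotes, 70 prokaryotes).
  Same-label sibling leaf pairs are collapsed, closest pair first, keeping
  the leaf nearest the root and accumulating a pruned-relative count on the
  survivor; if no same-label cherry remains above target, leaves with the
  fewest pruned relatives (isolated singletons first) are deleted. When one
  domain is capped, the other domain's leaves are protected. The result
  approximates a maximum-diversity representation.
- **Information trimming** (0.15 bits for tree alignments, 0.2 for profile
  construction). Column information is log2(20) minus the Shannon entropy
  of the amino-acid distribution among non-gap residues; no pseudocounts,
  0·log 0 ≡ 0; non-standard residues (B, Z, X, U, O, J) count as gaps;
  all-gap columns score 0 and are always removed. Retention is strict
  (> threshold), so trimming is idempotent and monotone in the threshold.
- **Outlier pruning** (99.5% one-sided quantile). A log-normal is fitted by
  maximum likelihood (mean/sd of logs) to all positive branch lengths —
  terminal and internal by default; a terminal-only switch exists because
  either reading of "stem" is defensible — and every subtree whose stem
  exceeds the quantile is removed, deleting long terminal branches and
  diverged clades in one pass. Zero-length branches are excluded from the
  fit and never pruned; a degenerate fit (log-sd < 1e-8) prunes nothing and
  is flagged. Families are discarded when pruning would remove the whole
  eukaryotic clade or more than 30% of leaves.
- **Weighted midpoint rooting**. The root is placed on the edge and offset
  minimising the absolute difference of total branch length on the two
  sides; within an edge the balance point is linear and clamped; ties
  between edges break by preorder index. When the balance point is
  interior, the two sides agree to machine precision. This is a data
  convention, not a phylogenetic rooting.

## Clade detection

Eukaryotic clades are detected at domain level (one label, "Eukaryota",
spanning all eukaryotic class labels); prokaryotic clades per class label.
For every label, each ancestor of each maximal monophyletic group is scored
with (n_label/size)·(n_label/total_label) — purity times scope — and
candidates are accepted greedily by score, skipping overlaps within a
label. The score tolerates single intruding leaves (local topology error or
within-tree transfer) without abandoning the clade. Validity is decided
only by size (≥ 3 prokaryotic / ≥ 5 eukaryotic label-bearing sequences) and
strict purity > 0.8; the score itself is metadata. Labels are processed
independently, so calls of different labels may nest; downstream stages use
the eukaryotic call(s) and the prokaryotic calls as given. Families with no
valid eukaryotic clade, no valid prokaryotic clade, or more than 3
eukaryotic clades (high paraphyly) are rejected with the reason recorded.

## Aggregation and core filtering

Reliable assignments are ELW strictly inside (0.4, 0.99). The upper cut
guards against sister sequences that are effectively eukaryotic — late
transfers back into the family — which present as near-certain assignments;
a configurable exception re-admits ELW = 1 for annotation categories where
near-certainty is biologically expected rather than artefactual. Families
must carry at least one functional annotation, and their eukaryotic clade
must span more than 5 distinct class labels including both deep supergroups
(Amorphea and Diaphoretickes), the criterion for plausibly predating the
LECA. aELW is the arithmetic mean of core ELWs per (category, donor taxon),
with categories under 20 families flagged.

## Stem lengths

SL is the path length from the node joining the eukaryotic clade and its
top-ELW sister (FECA) to the eukaryotic clade root (LECA), measured on the
preprocessed master tree; the normalisation is the median over eukaryotic
leaves of the LECA-to-leaf path length (read as path lengths, not
individual edges, since the intent is the clade's typical amount of
post-LECA evolution). NSL = SL / median BL.

Cohorts are compared per donor group: Gaussian KDE (Scott bandwidth,
configurable), 5th/25th/50th percentiles, empirical CDF and 200 bootstrap
CDF replicates on a 200-point grid spanning [0, pooled 99th percentile].
Three Mann–Whitney families are reported per group pair:

- `grid_pvalues`: at each grid point, the two groups' bootstrap CDF-value
  samples compared directly. This mirrors the bootstrap envelope but is
  **anti-conservative under the null**: the two bootstrap distributions
  concentrate (sd ≈ √(F(1−F)/n)) around each group's own empirical CDF,
  and the between-group ECDF difference has that same scale, so even
  identical generating distributions yield many significant grid points.
  It is kept as a descriptive band, not a calibrated test.
- `threshold_pvalues`: at each grid value t, the groups' NSL values below t
  compared — the running generalisation of the split analysis; calibrated
  under the null (about 5% of grid points significant for identical
  distributions).
- `split_tests`: below/above comparisons at the configured split points
  (defaults 0.3 and 0.35).

Groups with fewer than 5 records are excluded with a warning. Note that a
pure location shift of a non-negative distribution leaves only the shifted
group's lower tail below a small split, so below-split power at moderate n
is intrinsically limited; power statements in the test suite therefore
summarise over replicate cohorts.

## Synthetic data

The generator emulates one gene family: pure-birth (Yule) within-clade
topologies scaled to a target depth with mild log-normal branch jitter
(sd 0.25) so trees are not exactly ultrametric; prokaryotic clades joined
along a randomly ordered backbone (stems 0.15, backbone edges 0.2
substitutions/site); the eukaryotic clade (depth 0.4) attached to the
midpoint of the true sister's stem by a stem of 0.3; alignments of 300
columns evolved under the chosen model. Defaults give 36 leaves (10
eukaryotes, prokaryotic clades of 7/7/6/6). Eukaryotic leaves cycle through
8 class labels covering both deep supergroups, so simulated clades pass the
LECA scope check. Optional noise: terminal-branch inflation by a fixed
factor (long-branch outliers), relabelling prokaryotic leaves with an
off-clade label (transfer-like taxonomic incongruence), and extra planted
eukaryotic clades (paraphyly). All draws flow from one seed through
independent child streams, so enabling noise does not perturb the base
tree, and identical seeds give bit-identical output.

What the simulator does **not** emulate — and hence what passing tests do
not show about real data: indels and alignment error (alignments are true,
gap-free and exactly homologous), rate heterogeneity across sites and
lineages beyond branch jitter, model misspecification (inference uses the
generating model), deep non-tree-like signal, taxon-sampling bias, and
clustering artefacts upstream of the tree. Recovery rates measured on
simulations are upper bounds on real-data performance.

Stem cohorts are sampled directly from named NSL distributions (normal,
lognormal, uniform, exponential, gamma), clipped at 0 because stem lengths
are non-negative.

## Numerical choices and degenerate inputs

Natural logs throughout the likelihood machinery; branch-length bounds
[1e-9, 15] in optimisation; per-node per-site rescaling of partials; edge
updates are accepted only if they do not decrease the likelihood.
Supercluster partitioning embeds the patristic distance matrix (rows as
feature vectors, Euclidean metric, 50 neighbours capped at n−1, min_dist
0.3, fixed random state) and clusters with HDBSCAN allowing single-cluster
output; noise points join the nearest cluster centroid; trees with fewer
than 8 leaves fall back to one partition. The acceptance surface for this
stage is planted-partition recovery, not any particular embedding.
Pipeline stages derive their seeds by hashing the global seed with the
stage name, so independent stages can be reordered without changing
results.

## Problem sizes in the test suite

The suite and the acceptance script run at desk scale by design: 50
simulated families for sister-recovery, 100 for clade detection, 200 trees
for pruning calibration, cohorts of 500–1000 stems, 1000 RELL replicates
and 200 stem bootstraps. These sizes give comfortable statistical margins
for every property checked while keeping a full run to a few minutes on one
CPU.

## Known limitations

- Constrained hypotheses re-use the master tree's internal arrangement;
  only the eukaryotic attachment point varies. Genuinely different
  arrangements of the non-sister remainder are not explored.
- ELW is computed by RELL over full-alignment site likelihoods; windowed
  slices of the alignment are a config hook, not a default.
- The empirical model is a BLOSUM62-derived exchangeability matrix, not a
  maximum-likelihood amino-acid replacement model; for model-sensitive
  questions users should verify conclusions under both provided models.
- The soft-LCA greedy overlap resolution is per label; pathological trees
  where high-scoring clades of different labels interleave may produce
  nested calls that downstream consumers must interpret.
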