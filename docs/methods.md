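# Methods

This note documents the models and conventions implemented in `evotrek`,
the defaults and why they were chosen, and what the synthetic validation
does and does not establish.

## Species trees

Trees are rooted, with non-negative branch lengths in expected
substitutions per site and uniquely named leaves. The Newick dialect is
deliberately minimal — unquoted labels, optional branch lengths and
internal labels, no quoted strings or comments on input — and
serialization is canonical (children in stored order, lengths printed
with `%.12g`), so parse→write→parse is a fixed point. Event-annotated
output attaches `[&events=...]` comments to branches; these are an output
format only.

The distance-based tree builder is standard neighbor joining
(Saitou–Nei Q criterion) on Jukes–Cantor distances,
`d = −(3/4)·ln(1 − 4p/3)` with pairwise deletion of gap/ambiguity
columns. NJ resolves Q ties toward the lowest index pair in the working
order, making output deterministic; negative estimated branch lengths are
clamped to zero with a warning (they cannot occur on additive inputs, on
which NJ is exact). Saturated distances (p ≥ 0.75) are NaN — explicitly
undefined, never silently zero — and NJ refuses matrices containing them.
Outgroup rooting suppresses a degree-2 root, then places the new root at
the midpoint of the outgroup's pendant edge; leaf path lengths are
preserved exactly. NJ here is a desk-scale stand-in for likelihood-based
phylogenetics: when a curated tree exists, ingest it instead (the
pipeline reads any rooted Newick).

## Gene inventory

Homology is established by exact Smith–Waterman local alignment with
affine gaps (BLOSUM62, gap open 11, extend 1 — the de facto protein
search defaults; a gap of length k costs open + k·extend). `X` is
tolerated and scored 0. Raw scores are converted to a bit-like scale with
the gapped BLOSUM62/11/1 Karlin–Altschul parameters (λ = 0.267,
K = 0.041): `bits = (λS − ln K)/ln 2`. An E-value cutoff presupposes a
database size, so filtering instead uses database-size-free thresholds:
bit score ≥ 50 AND query coverage ≥ 0.5 (both configurable). Families
are connected components of the hit graph (single linkage) — inclusive
by design, matching the field's practice of calling related paralogs one
family; genes without hits become singletons. Paralogy is preserved in a
separate copy-number table and surfaces as a `duplication` annotation;
the parsimony matrix itself is binary.

## Parsimony event mapping

Per family, ancestral presence/absence is reconstructed by Sankoff
parsimony with transition costs `c_gain` (0→1) and `c_loss` (1→0); the
root state is free, so the outgroup's observed state polarizes gains
against losses. Polytomies are accepted. Defaults are `c_gain = 2`,
`c_loss = 1`: acquiring a gene (typically by horizontal transfer) is
treated as rarer than losing one; unit costs reproduce Fitch parsimony
(the `fitch` routine itself is restricted to binary trees, where the
union/intersection recurrence is cost-exact).

All cost-optimal labelings are enumerated by backtracking, capped at 64
per family with an overflow flag, and converted to per-branch event
scenarios. One canonical scenario is chosen deterministically for
summary tables — fewest gains, then events closest to the tips
(DELTRAN-like), then a fixed serialization — but the full co-optimal set
is always reported: ingroup-stem-gain vs outgroup-loss ambiguity is real
biology, not a tie to be hidden. Every reported scenario is replayed
from its root state down the tree at run time and must reproduce the
observed leaf states exactly.

Interpretation caveats: parsimony recovers the true history only when
events are sparse; a history that is strictly less parsimonious than an
alternative (e.g. independent losses on two sister clades, which a
single parental loss explains more cheaply) is unrecoverable in
principle. Events on the outgroup's own pendant branch are never
polarizable against the ingroup stem without a second outgroup.

## Selection (NG86 dN/dS)

The Nei–Gojobori (1986) counting variant is pinned as follows, chosen to
be fully oracle-testable:

* **Sites.** Each of a codon's nine single-nucleotide neighbors carries
  weight 1/3 toward its synonymous or nonsynonymous site count; neighbors
  that are stop codons are dropped, so a stop-adjacent codon contributes
  slightly fewer than 3 sites (S + N = 3 − stops/3). Pair counts average
  the two codons.
* **Differences.** For codons differing at k positions, all k! orderings
  of the changes are enumerated with equal weights; pathways passing
  through a stop codon are excluded and the remainder averaged. (If every
  pathway were blocked — impossible for sense endpoints under the
  standard code — all pathways would be used with stops treated as a
  21st amino acid.)
* **Correction and ratio.** p_S = S_d/S and p_N = N_d/N are Jukes–Cantor
  corrected; ω = dN/dS is *undefined* when dS = 0, when p ≥ 0.75, or when
  no codon columns survive pairwise deletion (gap or ambiguity in either
  row skips the column). Undefined ratios are flagged and counted, never
  coerced to 0 or ∞, and excluded from family means.
* **Family statistic.** The arithmetic mean of defined pairwise ratios
  (not the ratio of mean dN to mean dS). Classification: ω > 1 positive,
  ω < 1 purifying, |ω − 1| ≤ 1e−9 boundary.

Only the standard genetic code (NCBI table 1) is supported — the target
organisms are bacteria. `backtranslate` threads unaligned CDS onto a
protein alignment PAL2NAL-style (protein gaps become `---` codons, CDS
must translate exactly to the ungapped row, trailing stop tolerated).
The synthetic pipeline stacks within-family CDS directly — the simulator
produces no indels, so they are already aligned; real data with indels
should come through `backtranslate` from an external protein aligner.

## Identity clustering

Percent identity is matches / compared columns × 100 with columns
containing a gap or ambiguity in either row excluded from both numerator
and denominator, so 100% means "no observed difference". Clusters at a
threshold are single-linkage components; partitions are nested in the
threshold (lowering it never splits a cluster). The identity matrices are
emitted as TSV; an optional matplotlib heat map orders members by their
100% cluster.

## Mobile-element context

GFF3 `gene` and `mobile_element` features are read (1-based inclusive on
disk, 0-based half-open internally). A target gene is flagged when any
mobile element on its contig lies within `window_genes` intervening genes
OR `window_bp` base pairs edge-to-edge; strand is ignored (a divergently
oriented transposase is still evidence). Defaults: 3 genes / 5,000 bp —
the notion of "associated with" mobile elements has no standard number,
so these are explicit, configurable choices. The reported nearest element
minimizes bp distance, ties broken by id. A context flag is *evidence*
consistent with horizontal acquisition, not a demonstration: vertically
inherited genes can sit near mobile elements, and old transfers lose
their flanking elements.

## The simulator

`simulate_dataset` generates the study system the inference stages are
validated against:

* **Tree.** A Yule (pure-birth) ingroup rescaled so the root-to-tip
  height equals `tree_height` (default 0.1 substitutions/site, i.e. up to
  ~0.2 between leaves — within the regime where protein homology
  detection is trivially reliable), plus an outgroup on a pendant branch
  of 1.5 × height attached at the root (a distant relative, as a
  different genus would be). Defaults: 13 leaves = 12 ingroup + `OUT`.
* **Gene content.** Per family, a two-state continuous-time process along
  each branch (Gillespie): gains fire on absent lineages at `gain_rate`
  per unit branch length, losses on present lineages at `loss_rate`
  (defaults 1.0/1.0; root presence probability 0.5). The truth log
  records the *net* transition per branch — what any branch-resolved
  inference could possibly see. Dollo mode suppresses second gains. A
  family whose presence originates from a gain inside the tree is flagged
  HGT, and every genome copy gets a `mobile_element` feature planted in
  the adjacent intergenic spacer at emission.
* **Sequences.** Root codons uniform over the 61 sense codons; evolution
  by single-nucleotide proposals — Poisson(t·L) proposals per branch of
  length t over L nucleotide sites — accepted with probability 1 if
  synonymous and ω if nonsynonymous; stop-creating proposals are
  resampled without consuming time. Branch length therefore equals
  expected *accepted* substitutions per site at ω = 1, directly
  comparable to the Jukes–Cantor scale used downstream. Per-family ω is
  drawn 50/50 from {0.05, 1.0} by default — the strong-purifying vs
  neutral contrast the selection stage must resolve.
* **Layout.** Genes head-to-tail on one contig per genome, forward
  strand, fixed 100 bp spacers — the simplest geometry that exercises
  GFF3 parsing and window logic.
* **Reproducibility.** One master seed spawns named substreams
  (tree/content/sequences); identical configs give byte-identical output
  files.

What the simulator does **not** emulate: indels and rearrangements,
operon structure and strand variation, rate heterogeneity across sites or
lineages, sequence-divergent xenologs (a horizontally gained family's
sequence still evolves along the species tree), gene fusion, and
annotation error. Passing recovery tests therefore demonstrates the
inference machinery is correct and calibrated on clean data of realistic
shape — not that it is robust to the full messiness of real genomes.

## Validation experiments (problem sizes)

The acceptance suite fixes these experiment sizes, chosen to give each
statistic enough events to be meaningful while staying desk-scale:

* Sankoff vs exhaustive enumeration over all internal labelings: 200
  random instances, 4–8 leaves, random columns and costs; minimum cost
  and the complete optimal-labeling set must match.
* Event recovery: six replicates of 13 leaves × 50 families at
  gain = loss = 0.3 events per unit branch length (≈0.3 events/family —
  sparse enough that true histories are parsimony-identifiable),
  reconstructed with matching unit costs. A true event is recovered when
  a reported co-optimal scenario places it on its branch; families with
  no ingroup carrier are excluded (a genus-seeded inventory cannot
  contain them). Requirement: ≥ 90% aggregated across replicates.
* NG86 vs pathway-enumeration oracle: every ordered sense-codon pair
  differing at ≤ 2 positions (2,094 pairs), exact agreement.
* ω recovery: 100 replicate pairs of 300 codons at total divergence 0.3;
  median estimate must fall in [0, 0.15] at true ω = 0.05 and [0.7, 1.3]
  at ω = 1.0, strictly ordered.
* NJ exactness: 100 random trees of 6–10 taxa; the path-length matrix of
  the NJ tree must equal the additive input to 1e−9 (which pins both
  topology and branch lengths).
* End-to-end: 13 genomes × 24 families at default thresholds; recovered
  families and presence patterns must equal the truth exactly for every
  family with a surviving copy, and ≥ 95% of true-HGT families must be
  context-flagged.
* Identity: a three-leaf clade simulated at zero internal divergence must
  form exactly one 100%-identity cluster equal to the clade.

`scripts/acceptance.py --seed N --out results/acceptance.json` recomputes
all of these from scratch under a caller-supplied seed and writes the
measured values; the pytest acceptance tests assert the same properties
at fixed seeds.

## Known limitations

* All-vs-all exact Smith–Waterman is O(n²) in gene count — appropriate
  for tens of genomes × tens of families, not for full proteomes.
* Branch-resolved duplication and fusion inference (gene-tree/species-tree
  reconciliation) is out of scope; duplications surface only as
  copy-number annotations, fusions only as user-supplied annotations.
* The family mean of pairwise ω treats pairs as independent, which they
  are not (shared phylogeny); it is a summary statistic, not an estimator
  with known sampling theory.
* Fitch is binary-tree-only; use Sankoff (unit costs) on polytomies.
* Co-optimal scenario enumeration caps at 64 per family (flagged), which
  pathological phyletic patterns can exceed.
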