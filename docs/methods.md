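# Methods

## Orthology model

Orthologous groups are built from **best reciprocal hits** (BRH): protein
`a` in genome `A` and `b` in genome `B` are candidate orthologs when `b` is
the highest-scoring local alignment of `a` among all proteins of `B` and
vice versa. Local search uses exact Smith–Waterman over the whole target
proteome (no heuristic seeding); ties on score break to the
lexicographically smallest protein id so tables are deterministic. A raw
local score below `min_score` (default 50, BLOSUM62 scale) disqualifies a
hit; because best-hit tables keep only each query's maximum, this cutoff
mainly bounds computation.

Candidate edges are vetted with a **composition-preserved randomization
test**: the global Needleman–Wunsch score of the pair is compared with the
scores of the first sequence against `n_shuffles = 50` uniform residue
permutations of the second. With null mean `μ` and sample (n−1) standard
deviation `σ`, `Z = (S_obs − μ)/σ` and the reported confidence is the
one-sided normal probability `Φ(Z)`. Edges need confidence above 0.999999
(`Z ≥ 4.7534`) to survive. When `σ = 0` (degenerate compositions such as
homopolymers) the call is: observed above the null mean → confidence 1,
otherwise → 0 (observed equal to the null mean reports `Z = 0`).
Only the second sequence is shuffled, matching the 50-randomized-sequence
design; the Z-statistic is close to symmetric in practice because scoring
matrices are symmetric.

Clusters are the **connected components** of the validated BRH graph with
members from at least two genomes. Components subsume the classical
triangle-merging construction and, importantly, admit two-genome clusters,
which dominate real occupancy distributions. Filtering happens per edge;
components are re-derived afterwards, so proteins attached only through a
failed edge drop out. Multiple members per genome can enter one cluster
through transitive BRH links (co-orthologs); occupancy counts distinct
genomes. Cluster ids (`HOG0001`, …) are assigned in order of each
component's smallest member protein id, making numbering independent of
genome input order; per-pair shuffle RNGs are seeded from a CRC of the
sorted protein ids plus the run seed for the same reason.

## Classification and the signature screen

With base genomes `G` (|G| = N): occupancy `N` → **core** (cHOG), else
**accessory** (aHOG). A cluster is associated with a reference ortholog
tier (prokaryotic / eukaryotic / archaeal, i.e. COG/KOG/arCOG-style tables)
iff at least one of its members from the designated reference genome maps
into that tier. Core clusters with neither a prokaryotic- nor a
eukaryotic-tier association are unique candidates (**ucHOGs**).

The sequential screen then runs in a fixed order:

1. **Added-genome screen** (cluster confidence, 99.9999%): for every core
   cluster and every later-added ingroup genome, some added protein's best
   local hit among the cluster members must pass the randomized
   significance test; failing clusters are relabeled accessory and take no
   further part. Applying this step before the outgroup screen reproduces
   the bookkeeping convention in which a cluster removed here is not also
   counted as having outgroup homologs.
2. **Outgroup screen** (homolog confidence, 99.0%): every member of each
   surviving ucHOG is locally aligned against the outgroup database;
   database proteins scoring at least `outgroup_min_score` against some
   member are candidates, and each candidate is re-tested with the global
   randomization test against *every* member. One confirmed
   (member, outgroup) pair makes the cluster **nearly unique** (nucHOG);
   none leaves it **truly unique** (tucHOG) — a clade signature family.
   Per-cluster confirmed-hit counts are recorded.

`outgroup_min_score` defaults to 80, deliberately stricter than the
best-hit `min_score`: the outgroup screen keeps *every* pair above
threshold rather than per-query maxima, so a candidate must be individually
meaningful at database scale. At BLOSUM62 11/1, raw 50–55 against a
database of hundreds of proteins is expected by chance about once per
screened family, and a fraction of such chance candidates will also clear
the 99% confirmation (which tolerates 1% false positives per pair by
construction); raw 80 pushes the chance-candidate expectation below ~10⁻²
per family while any genuine homolog at ≥ 40% identity over ≥ 80 residues
scores well above 150. The confirmation threshold itself is never touched.

Bookkeeping compares the labelling before and after the screens per
category (core, association subcategories, unique, truly/nearly unique,
accessory and its subcategories) as initial/removed/added/final counts and
enforces `final = initial − removed + added` and
`core + accessory = all clusters` on every run, along with the partition
identities `tucHOG ⊎ nucHOG = ucHOG ⊆ cHOG` and `cHOG ⊎ aHOG = all`.

## Alignment engine and scoring

Global and local affine-gap alignment run on Biopython's `PairwiseAligner`
(C implementation) behind the package's `ScoringScheme`/`AlignmentResult`
types; score-only calls are used in the all-vs-all and shuffle loops. A gap
of length `k` costs `gap_open + k·gap_extend` (BLAST convention; the first
gapped residue costs open + extend). Defaults: BLOSUM62, open 11, extend 1,
for both modes — the classical protein-search defaults, configurable per
run, including matrices in NCBI text format. The ambiguity residue X scores
0 against everything (B/Z/U/J/O are mapped to X on load, with a warning);
trailing `*` stop characters are stripped and internal stops are hard
errors. Percent identity uses all aligned columns including gap columns
(terminal gaps included in global mode) — stated explicitly because
identity ranges are denominator-sensitive. The test suite checks both
aligners against an exhaustive enumeration of alignments on short
sequences, and the local/global dominance, symmetry and round-trip
invariants.

## Confidence thresholds

The two confidence levels map to one-sided normal quantiles: 99.9999% ⇔
`Z ≥ 4.7534` (cluster membership), 99.0% ⇔ `Z ≥ 2.3263` (outgroup
homology). Reading the shuffle null through a Z-test is the natural
interpretation of reporting mean and standard deviation of randomized
scores. Calibration is part of acceptance: across 1,000 unrelated
random-protein pairs the 99.9999% criterion fires in ≤ 0.1% of trials,
while self-alignments of diverse sequences always pass.

## Synthetic pan-genomes

The generator emulates a family-level pan-proteome study design. Defaults
(the package's standard desk-scale study conditions): 5 base + 2 added
genomes; 60 core families present in every genome including added ones; 40
accessory families with occupancy drawn from a bimodal law (P(2) = 0.35,
P(3) = 0.20, remainder uniform above); 12 clade-unique core families, 8
truly unique and 4 decoys carrying a planted outgroup homolog at 45–55%
identity; 15 singletons per genome; a 200-protein unrelated outgroup
database; family lengths uniform on 80–300 residues; amino acids drawn from
Robinson–Robinson background frequencies.

Family members are independent descendants of a random ancestor with
i.i.d. position substitutions and no indels, so the identity target is
exact and recovery is interpretable. The configured identity range
(default 0.30–0.80) is interpreted as the expected *pairwise* identity
within a family: a family-level target `t` is drawn from the range and each
member is mutated to ancestor identity `√t`, putting sibling pairwise
identity at `t` plus a small chance-match excess — spanning roughly the
20–85% band seen between real within-cluster orthologs. Unique families
are chromosomal with probability 0.9 (other families 0.85); each genome has
one chromosome and one megaplasmid replicon. Coding sequences are produced
by back-translation under the standard genetic code with an exponentially
GC-tilted synonymous-codon choice, the tilt solved once per configuration
so mean coding G+C hits the configured target (default 0.62, a
halophile-like value). Reference associations are planted for ordinary
core families (60% dual-tier, 40% prokaryotic-only) and for 15% of
accessory families, so unique candidates emerge from the association step
exactly as in a real run. A deletion plan can remove chosen core families
from chosen added genomes to exercise the added-genome screen.

What the simulator does **not** emulate: phylogenetic correlation (no tree,
no rate heterogeneity), indels, domain shuffling, paralog families,
composition bias differences between genomes, and real functional-category
structure. Passing recovery tests therefore demonstrates correctness of
the clustering/screening machinery under clean 1:1 orthology, not
performance on real proteomes with promiscuous domains or heavy
paralogy.

## Physicochemical statistics

Isoelectric point solves net-charge(pH) = 0 by bisection to 1e-4 pH units
on the Henderson–Hasselbalch charge curve with an EMBOSS-style pKa set
(N-term 8.6, C-term 3.6, C 8.5, D 3.9, E 4.1, H 6.5, K 10.8, R 12.5,
Y 10.1), configurable. Molecular weight sums average residue masses plus
one water, reported in kDa (X uses the mean residue mass). Gene G+C is
percent G+C of the coding sequence. Class-level averages are computed per
protein and then averaged unweighted, so large clusters do not dominate.
Reported percentages round half away from zero at the printed precision
(one decimal for per-genome tables, integers for prose fractions).

## Bundled survey tallies

`panhog.datasets` ships the published per-genome counts, functional matrix
and nine-to-thirteen-genome accounting of the haloarchaeal core-proteome
survey as plain constants; they validate the report arithmetic (the
pipeline itself is validated on simulations). One printed cell is
internally inconsistent — the *Haloarcula marismortui* core percentage is
printed as 23.1% while its own printed counts give 893/4240 = 21.1% — and
is recorded as such (`PRINTED_PCT_INCONSISTENCIES`); the arithmetic checks
assert the value the counts imply. The functional matrix is
multi-counted (a cluster mapping to k categories increments k cells), so
column sums may exceed cluster counts; distinct-cluster prose fractions are
a separate statistic and are not forced to match the matrix.

## Problem sizes and runtime

The acceptance runs use the default simulation above (~570 ingroup
proteins, ~350,000 local and ~50,000 global alignments end to end), 520
oracle pairs of length ≤ 6, and 1,000 + 200 calibration pairs; the full
pipeline completes in a few minutes on one CPU. The exact local search is
quadratic in proteome size and meant for desk-scale databases — plugging a
seeded heuristic search in place of `best_hits` is the natural extension
for genome-scale inputs.

## Known limitations

- Connected components can chain distinct families through a single
  spurious validated edge; at the significance threshold used this is rare
  but not impossible in large runs.
- The added-genome screen tests candidates in descending best-score order
  and accepts the first significant one; a genome whose only homolog is
  highly diverged costs one significance test per candidate until found.
- Per-edge removal after significance filtering may split a cluster the
  way manual curation would not; whole-cluster rejection is a documented
  alternative not implemented.
- The one-sided shuffle design conditions on the realized arrangement of
  the unshuffled partner; sequences whose realized arrangement is
  atypically alignable inflate Z slightly against all partners. The
  stricter outgroup candidacy threshold absorbs this in practice.
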