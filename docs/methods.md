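# Methods

This note documents the models and procedures implemented in `microvinet`,
the parameters that matter, the synthetic data the package tests itself on,
and the numerical choices made where the design was genuinely open.

## The classification model

Microvirus taxonomy is built here from a two-tier protein-sharing network.
All protein products of curated genomes are compared all-vs-all by local
alignment; pairs passing a significance gate and a coverage/identity gate
become edges; single-linkage clusters of proteins (connected components of
the edge graph) are the shared-protein groups that connect genomes in a
bipartite genome–protein graph. Two tiers are built from the same hit
table:

- **Family tier** — identity ≥ 30 % AAI over ≥ 80 % coverage, all proteins.
- **Genus tier** — identity ≥ 50 % AAI over ≥ 80 % coverage, restricted to
  the universally conserved core triad (VP1 major capsid, VP2 DNA pilot,
  VP4 replication initiator). Short optional hallmarks (VP5/VP8, ~50–60 aa)
  and accessory peptides carry enough sampling variance in their identities
  that they occasionally bridge distinct genera at the 50 % threshold; the
  core triad, being long and always present, does not. Genus-level
  relatedness is therefore judged on the conserved proteins.

Because the tiers share one hit table and the genus gates are strictly
stronger, genus-tier edges are a subset of family-tier edges and genus-tier
clusters nest within family-tier clusters by construction.

**Families** anchor on VP1: every family-tier VP1-majority cluster with at
least two member proteins defines a family, and a genome belongs to the
family whose VP1 cluster contains its own VP1 gene. A VP1 cluster of size
one defines nothing — otherwise every orphan capsid would found a
family-of-one and the singleton category could never occur. Genomes without
such a connection fall back to their map-equation module: a module of more
than five such genomes becomes a provisional (VP1-less) family, anything
smaller is a singleton.

**Genera** are the map-equation modules of the genus-tier network, refined
by two checks: all members must share the circular order of the core
hallmarks read 5'→3' from VP1 (synteny), and members must hold together at
≥ 50 % pairwise nucleotide identity. The nucleotide check takes the
connected components of the pairwise ≥ 50 %-identity graph within each
synteny group rather than a per-member average: when two cohesive subgroups
are bridged by a spurious protein-level edge, each member's average is
dominated by its own subgroup, so an average can never separate them while
component linkage does. Finally, any genus spanning several families is
split per family, so the genus partition always refines the family
partition.

### The map equation

Genome modules minimize the two-level map equation

    L(M) = q H(Q) + Σ_i p_i H(P_i)

over the undirected bipartite graph with uniform edge weights, where node
visit rates are degree-proportional, q_i is module i's exit probability and
the entropies price the index and module codebooks of a random walk.
Two operational choices matter:

- The flow graph contains only protein clusters with **≥ 2 members**.
  Singleton clusters carry no sharing information; as leaf nodes they
  dilute module visit rates enough that the codelength objective itself
  (not merely a greedy optimizer) starts preferring to split genuine
  genera. This was verified numerically before the choice was made.
- The optimizer is greedy: seeded local node moves to adjacent modules,
  followed by pairwise module merges, iterated to a fixed point, with
  deterministic tie-breaking. On every graph of ≤ 8 nodes in the test suite
  it attains the exhaustive set-partition optimum; no optimality guarantee
  is claimed beyond that scale. The partition is run on the bipartite graph
  directly (not on a genome–genome projection); module membership is then
  restricted to the genome nodes, and isolated genomes get their own
  modules.

## Pairwise alignment and significance

Protein pairs are aligned by Smith–Waterman with BLOSUM62 and affine gaps
(first gap column 11, each further column 1). Identity is the percentage of
identical residues over *all* alignment columns, gap columns included.
Coverage is the fraction of the **shorter** protein's residues inside the
alignment — the symmetric choice, and one that cannot exceed 1 (a raw
column count can, once the alignment contains gaps). Co-optimal alignments
are resolved deterministically: the best cell is the smallest (i, j)
maximum, traceback prefers diagonal over up (query-consuming gap) over
left, and closing a gap beats extending it on ties. The pair is internally
sorted before aligning, so identity and coverage are exactly symmetric.
These conventions are frozen because the test suite holds the implementation
to exact agreement with an independently written dynamic-programming oracle.

Hit significance is calibrated empirically: Smith–Waterman scores of
shuffled-protein decoy pairs are fitted with a Gumbel extreme-value
distribution and converted to E-values, E(s) = N·exp(−(s−μ)/β) for N
candidate pairs; hits enter the network at E ≤ 0.001. This replaces the
analytic calibration of accelerated search tools and requires no external
binaries.

## Profile HMMs and hallmark labeling

Hallmark detection uses profile hidden Markov models estimated from seed
alignments: columns with ≤ 50 % gaps become match states; emissions and
state transitions are Laplace-smoothed counts (pseudocount 1, 20-letter
alphabet, uniform background by default). Scoring is the full forward
algorithm in log space, reported as a log-odds bit score against an i.i.d.
background null; residues outside the 20-letter alphabet score as
background. The N-/C-terminal flank insert states use a fixed 0.99
self-loop (glocal semantics, as in standard search tools) instead of
seed-derived estimates: called ORFs routinely overshoot the seeded domain
(an upstream in-frame start extends the protein), and seed-estimated flank
loops would price every flanking residue at ~1.6 bits.

E-values come from decoy calibration as above, but the exponential tail is
fitted by peaks-over-threshold (mean exceedance over the 90th percentile of
decoy scores): forward scores *sum* over paths rather than maximize, their
null is lighter-tailed than a Gumbel, and a full-distribution fit
miscalibrates exactly the tail that E-values live in. The fitted law is
self-consistent: scoring fresh decoys at the fitted parameters yields about
one sequence with E ≤ 1 per database-size worth of decoys.

Iterative (jackhmmer-style) search admits database proteins at E ≤ 0.05,
realigns the hit set to the profile by Viterbi (match-column projection;
inserts dropped, so the column count stays fixed at the seed's), rebuilds
the profile and repeats until the hit set stops growing; the set is
monotone non-decreasing by construction. Genes take the label of their
best-scoring profile at E ≤ 0.05; at most one gene per genome may carry
VP1 (best score wins, then lowest coordinate; demoted copies are labeled
`VP1-duplicate`).

## Curation and gene order

ORFs are called as maximal open reading frames (start codons ATG/GTG/TTG;
stops per translation table 11, or table 4 where TGA reads as tryptophan)
on both strands, with origin-spanning ORFs found by scanning the doubled
sequence — an ORF may only open after a stop has been seen in its frame, and
wrapped copies are deduplicated modulo the genome length, which makes the
ORF set rotation-invariant. An `auto` mode retries table 4 when table 11
yields fewer than three ORFs of ≥ 33 aa. Unlabeled ORFs overlapping a kept
gene on the same strand are pruned longest-first; overprinted genes are
deliberately not modeled.

Curation enforces the microvirus single-strand rule: genes antisense to VP1
are removed; genomes lacking VP1 or VP4 are rejected with a structured
reason (`missing:VP4`); a genome with VP1+VP4 but no recognizable VP2 is
kept with a "Suborder II candidate" warning by default (one suborder is
defined by the absence of a recognizable DNA pilot protein) and rejected
only under `require_vp2`. Accepted genomes are strand-normalized (reverse
complemented if VP1 lies on '−') and rotated so VP1 starts at coordinate 0;
every downstream result is therefore invariant to the rotation and strand
of the input contig.

The gene-order label reads the hallmarks 5'→3' from VP1 on the circle. For
the core triad there are exactly two circular classes (VP1–VP2–VP4 and
VP1–VP4–VP2); additional observed variation comes from the placement of the
optional hallmarks, which the label includes when present. The genus
synteny check compares the core order only, because optional-hallmark
detection on 50–90 aa proteins is not reliable enough to define synteny.

Exact tandem concatemers (assembly artifacts presenting a circular genome
as k ≥ 2 identical copies) are collapsed to their smallest repeat unit and
flagged circular; near-identical tandem copies are left untouched and
logged for manual review.

## Nucleotide identity and recombination scanning

Genome-pair nucleotide identity uses the edit-distance-optimal global
alignment (edlib), VP1-anchored on both sides, identity = matches /
alignment columns with terminal gaps trimmed. A caveat documented here
deliberately: unit-cost global alignment buys matches with cheap gaps, so
*unrelated* genome pairs measure ~55–60 % — the 50 % genus floor is
therefore permissive rather than discriminating under this aligner, and the
discriminating genus-level signal is the conserved-protein AAI tier (the
nucleotide gate still separates within-genus pairs, ~80 %, from everything
else).

Recombination scanning slides a 99-nt window in 33-nt steps over the
columns of one global alignment (gaps count as mismatches, keeping the two
genomes' coordinates synchronized). Tracts are maximal runs of windows
exceeding the track median by ≥ 4 robust z-units (MAD-scaled, with the
scale floored at one identity point so a near-constant backbone cannot
inflate noise); runs use hysteresis — seeded at z ≥ 4, extended while
z ≥ 2, touching runs merged — because a long tract's interior windows
fluctuate around any hard threshold. Reported boundaries are refined to
single-column resolution by a change-point scan of the match indicator
against the midpoint of backbone and tract identity, then mapped to
genome-A coordinates. On the planted 700-nt / 72 %-vs-38 % scenario the
recovered boundaries fall within a few nucleotides of truth, well inside
one window step.

## Read recruitment and abundance

The recruiter is a seed-and-extend mapper: exact 13-mers index the genome
database (circular genomes extended by 300 nt so origin-spanning reads
seed); k-mers occurring more than 10 times are masked, standard repeat
masking without which low-complexity seeds let random reads through. A read
is extended only where at least 5 seeds agree on one diagonal band (±15),
then aligned infix (whole read against the banded window) and accepted at
≥ 50 % identity over the read. Reads at that floor carry on the order of a
hundred exact seeds, so the gate costs no sensitivity at the simulated
error rates; sensitivity to *much* more diverged reads (≲ 75 % identity) is
limited by exact seeding, a known property of this mapper family. The best
genome wins; exact ties split fractionally in equal shares (configurable to
drop), so per-genome counts sum to the mapped-read total exactly. Abundance
profiles sum counts per family and divide by total mapped reads.

## The synthetic-data generator

The generator plants a three-level taxonomy (families → genera → genomes)
whose observable envelope mirrors curated microvirus collections: circular
genomes of 3,500–8,300 nt, GC targets drawn in 0.26–0.65, all genes on one
strand, hallmark complement VP1/VP2/VP4 always plus optional VP3/VP5/VP8
and accessory peptidases/methyltransferases, canonical VP1–VP2–VP4 order
with optional per-genus permutation, and stop-codon-rich intergenic spacers
and filler so no spurious long ORFs arise.

Divergence is applied in amino-acid space along the family → genus → genome
tree and then back-translated with synonymous-codon choice weighted toward
the family GC target. Branch substitution fractions are exact counts
(round(d·L) positions drawn without replacement), not per-residue
Bernoulli, so the configured identity bands hold tightly even for short
proteins. Defaults: genus branch 0.30 from the family ancestor, genome
branch 0.13 from the genus ancestor, families drawn independently. Two
genomes whose lineages retain fractions r₁, r₂ of sites show pairwise
identity ≈ r₁·r₂ plus a ~1/19 coincidence term, giving within-genus VP1
identity ≈ 77 %, within-family ≈ 40 % (the 35–45 % band), and between
families no coverage-passing alignment at all. Each genus carries one
nucleotide template (gene codons, spacers, filler, total length); member
genomes mutate it at the genome branch rate, so within-genus nucleotide
identity stays at the ~80 % typical of genus-level clusters. Seed
alignments for the profile search are the per-family genus-ancestor
proteins (equal-length, gapless rows), mirroring the per-family capsid
alignments a curator would bootstrap from.

Optional plants: a peptidase shared between two families at ~74 % AAI
(branch rates 0.08/0.04/0.03) while their capsids remain unrelated — the
cross-family shared-protein scenario; and recombinant tracts, where the
acceptor genome is rebuilt as a positionally homologous mutant of the donor
at the backbone rate (default 38 % identity) with one or more tracts
mutated at the tract rate (default 72 %, 700 nt). The acceptor emulates a
distantly related *syntenic* genome: splicing a tract into an unrelated
genome at arbitrary coordinates is undetectable by global-alignment window
identity, because nothing makes the aligner co-align the tract. Reads are
drawn proportional to weight × genome length with uniform (wrapping) starts
and i.i.d. substitution errors.

What the generator does **not** emulate: insertions/deletions within genes
(protein divergence is substitution-only), codon-usage or selection
structure, overprinted genes, frameshift assembly errors, chimeric contigs,
sequencing indels and quality variation, and uneven taxon sampling. Passing
tests therefore demonstrate correctness of the pipeline's logic and its
rotation/strand invariances under controlled divergence — not robustness to
every artifact of real MAG data.

## Default parameters

| Parameter | Default | Meaning |
|---|---|---|
| `family_identity` | 30 % | AAI floor, family tier |
| `genus_identity` | 50 % | AAI floor, genus tier (core hallmarks) |
| `min_coverage` | 0.80 | aligned fraction of the shorter protein |
| `hit_e_max` | 0.001 | all-vs-all significance gate |
| `hallmark_e_max` | 0.05 | profile-search inclusion gate |
| `min_family_size` | 6 | VP1-less provisional family needs > 5 genomes |
| `nt_identity_min` | 50 % | genus nucleotide-identity floor |
| `min_contig_length` | 4,000 nt | metagenome screening floor |
| `min_orf_aa` | 33 aa | smallest called ORF |
| `window`, `step` | 99, 33 nt | recombination scan windows |
| `z_min` | 4 | robust z threshold for elevated tracts |
| `read_min_identity` | 50 % | read-recruitment floor |
| `read_kmer` | 13 | recruitment seed size |
| `map_seed` | 42 | partitioner / calibration seed |

## Problem sizes

The default test and acceptance conditions are desk-scale by design: the
planted taxonomy runs 5 families × 3 genera × 4 genomes (60 genomes,
~300 proteins, ~45,000 alignment pairs), profile search uses 15–25
profiles calibrated on 300 decoys each, the recombination scenario is one
genome pair, and abundance uses 5,000 reads of 150 nt over three genomes.
Exhaustive oracles (path enumeration, set-partition enumeration, brute-force
DP) run on instances small enough to be checked completely: profiles of
≤ 4 match states × sequences of ≤ 6 residues, graphs of ≤ 8 nodes, peptides
of ≤ 30 residues.

## Known limitations

- The family/genus thresholds are operational, not phylogenetic; no
  monophyly claim is made or checked (tree building is out of scope).
- The nucleotide-identity floor is permissive under edit-distance
  alignment (see above).
- Exact-seed recruitment under-detects reads far below ~75 % identity.
- Concatemer collapsing requires exact repeats; diverged tandem copies are
  only logged.
- The greedy map-equation optimizer is exact only where exhaustively
  verified (small graphs); large-graph partitions are heuristic, as in all
  practical community-detection tools.
- `classify_new` re-clusters the pooled protein set, so reference
  assignments can in principle shift when contigs are added; contig labels
  are mapped back to fitted reference families/genera by majority.
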