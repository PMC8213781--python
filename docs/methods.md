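# Methods

This note documents the models, rules and numerical choices implemented in
`ecisminer`, and what the synthetic test surface does and does not show.

## Conventions

Coordinates are 1-based and inclusive at both ends (the convention of both
IMG-style exports and GFF3); half-open arithmetic never appears in any
record or file. The distance between two genes is the number of bases
strictly between their nearest boundaries, `max(0, start_b − end_a − 1)`,
strand-ignored; overlapping or abutting genes are at distance 0. Every
physical-linkage threshold (operon chaining at 12,000 bp, contamination
window at 10,000 bp) uses this one definition and compares inclusively
("within" read as ≤). Non-coding features are parsed and retained but
excluded from all gene counting.

## Locus detection model

The detector encodes the biology of the eCIS operon — a compact cassette
of core structural genes — as a chain of falsifiable rules:

1. **Seeds.** Protein-coding genes whose pfam annotations intersect the
   eCIS pfam→role map. The shipped map covers the classical particle
   domains (tube Phage_T4_gp19, sheath Phage_sheath_1, baseplate
   Baseplate_J/Phage_GPD/GPW_gp25, spike PAAR_motif, AAA ATPase, cap
   DUF4255) and is deliberately user-extensible: annotation pipelines
   differ, and most role evidence in a real run comes from the Afp1–16
   HMM profiles rather than the map.
2. **Chaining.** Single-linkage within 12,000 bp per scaffold. The gap is
   measured from the rightmost boundary reached so far, so a long gene
   bridges neighbours even when a short gene nests inside it.
3. **Seed filter.** ≥ 4 members, ≥ 3 distinct eCIS pfams. This kills
   isolated domain hits and tandem repeats of a single family.
4. **Contamination screens.** Because eCIS share ancestry with phage
   tails and T6SS, a candidate near phage-marker pfams (capsid, portal,
   terminase) or T6SS-marker COGs (TssM and companions) is discarded
   outright — stringency is preferred to sensitivity. The whole scaffold
   is scanned for blocklisted genes within 10,000 bp of any group member;
   a member carrying the marker itself is contamination. The blocklists
   are configuration, not code.
5. **Expansion and merging.** ± 10 protein-coding genes, truncated at
   scaffold ends; non-coding features are skipped without consuming the
   budget. Candidates whose expanded spans overlap on one scaffold are
   merged before finalization, so one physical locus split by a large
   internal gap is never double-reported. (How overlapping candidates
   should be resolved is genuinely open; merging is the choice that
   cannot double-count.)
6. **Core census.** Roles are the union of pfam-map roles and surviving
   HMM hits. "At least ten core genes" counts genes carrying ≥ 1 role,
   with gene multiplicity: core genes frequently occur in paralogous
   copies, and counting distinct roles would paradoxically reject such
   loci. A configuration switch (`count_core_roles_distinct`) provides
   the stricter reading. At least one eCIS-specific core (afp12, afp13,
   afp14, afp16) is required, which is the rule that excludes R-type
   pyocins — contractile particles lacking the inner-tube/fiber/cap
   families.
7. **Boundaries.** Four protein-coding genes beyond the extreme core
   genes, clipped at scaffold ends. Operon edges are inherently fuzzy
   (3′ toxin cargo is hypervariable), so the flank is an explicit,
   reproducible convention rather than a biological claim.

### HMM bitscore percentile filter

hmmsearch hits are rank-filtered per profile: the top
`ceil(keep_fraction · n)` by bitscore survive (default ½; ¼ for the
fiber analysis), and hits tied with the last kept score are also kept —
equal evidence is never discarded by rank arbitrariness, and a lone hit
always survives. Ranking is per profile over the whole input batch, not
per genome: profiles differ hugely in score scale, and per-genome
percentiles would be unstable for rare profiles. A switch
(`percentile_per_profile=False`) gives one global ranking. E-values are
carried through but not thresholded at this stage.

## Enrichment statistics

Pfam enrichment is computed at gene granularity: a gene either carries a
domain or it does not, and repeated copies within one gene (typically
repeat domains) count once, preventing repeat expansions from inflating
counts. Each pfam seen inside ≥ 1 locus gets the 2×2 table (in-locus
with / in-locus without / background with / background without) over the
supplied gene universe — the background is whatever universe the run
declares, and is recorded in output metadata. The odds ratio everywhere
is the unconditional sample OR `ad/bc` with conventions `0/x = 0`,
`x/0 = ∞`, `0/0 = NA`; exact zero and exact infinity are meaningful
summaries of degenerate tables (total depletion, total presence) that the
conditional MLE cannot produce. The two-sided Fisher p follows the
probability-at-most-observed rule. Benjamini–Hochberg q-values that
underflow to exactly 0 in floating point are clamped to 1e-250 so they
survive a −log10 plotting axis. Phylum spread classifies domains core
(> 10 phyla) / shell (4–10) / cloud (< 4); genomes without a phylum
mapping count as the single pseudo-phylum "unclassified" and are flagged.

## The contrasting-pairs test

Genus- or trait-level Fisher tests are confounded by phylogeny: a trait
fixed in one locus-rich clade produces a spectacular odds ratio from a
single evolutionary event. The pairwise-comparison test (Read & Nee;
popularised by Scoary) counts *independent* events instead: pairs of tree
tips that differ in genotype **and** in phenotype, with no tip shared and
no tree edge used by two pairs' connecting paths. A pair *supports* the
association when the contrasts agree in direction (the genotype-1 tip is
the phenotype-1 tip) and *opposes* it otherwise. Requiring contrast in
both variables is what makes the binomial reference exact: under the
no-association null each pair supports with probability ½, so the count
of supporting pairs among `max_pairs` trials is Binomial(max_pairs, ½).
Pairs differing in genotype alone carry no directional information and
are not counted as trials — including them would make the test severely
conservative (their support probability is ¼, not ½).

The implementation is an exact post-order dynamic program. Each subtree
is summarised by, for each "dangling" state (no reserved tip, or one
reserved tip of joint state (g, p)), the maximum pair count and the
best/worst support achievable at that maximum. Children fold through a
dangle-count-vector accumulator, so polytomies are handled exactly:
several pairs may cross one multifurcation as long as no edge is reused.
Because a maximum matching at a node splits into disjoint supporting
((1,1)×(0,0)) and opposing ((1,0)×(0,1)) channels, its support
contribution is forced; best/worst freedom arises only from which dangles
the children present, which the DP enumerates. Both the best-case and
worst-case supporting counts over all maximum pairings are reported with
their upper-tail binomial probabilities (`p_best`, `p_worst`); which of
the two a study should emphasise is a reporting decision, so both are
emitted. `max_pairs = 0` yields NA p-values. Tips missing either trait
are pruned per trait, not globally; trait-table entries absent from the
tree are pruned with a warning.

The DP is validated against exhaustive search over all edge-disjoint
contrasting pairings on 500 random trees of ≤ 10 tips, and its null
calibration is checked by simulation (1,000 independent-trait trees of 32
tips; the observed rejection rate at 0.05 must sit within three binomial
standard errors of 0.05).

## Tail-fiber classification

Fiber genes are the afp13-profile hits in the top quarter of bitscores
(same rank rule as above). Per gene, the best hit from each of the two
databases is taken after discarding hits with E-value ≥ 10⁻³ (BLAST
tabular output reports E-values; the threshold is configurable). A
best-bitscore difference strictly greater than 15 bits decides the call;
a difference of exactly 15 or less is inconclusive. When only one
database yields a surviving hit the call follows that database — the
two-score comparison degenerates naturally. Raw bitscores are compared,
not length-normalised ones. Classification provably depends only on each
database's maximum surviving bitscore.

## Synthetic data: what it emulates and what it does not

The generator produces annotation-level genomes: gene coordinates,
strands, pfam/COG sets, HMM and BLAST hit tables — no nucleotide or
protein sequences beyond format placeholders, since the pipeline's logic
never reads sequence. Planted operons use core gene lengths of
300–4,500 bp and intergenic gaps of 5–500 bp (comfortably inside the
12 kb rule); mapped-pfam seed genes are interleaved with HMM-only core
genes so a planted operon always chains into one seed group. Each decoy
kind violates exactly one rule: pyocin-like plants carry 12 cores but no
specific core; undersized plants carry 9; phage decoys add a capsid-pfam
gene exactly 8 kb (nearest-boundary) from the last seed gene — inside
the 10 kb window, with 11 kb used in tests to probe the clean side;
T6SS decoys put the marker COG on an operon member. Planted HMM hits are
drawn from 120–200 bits against a matched one-per-hit decoy population at
10–60 bits, so the top-half filter keeps exactly the planted cores by
construction. The background pfam vocabulary (PF9xxxx) is disjoint from
the eCIS map and both blocklists, keeping truth labels exact. Trees are
random rooted binary trees from recursive splits; the clade-confounded
scenario forces an even root split so the confounded clade is exactly
half the tips.

Consequently, passing tests demonstrate that the *rules as stated* are
implemented correctly and are sound/complete against their own
definitions. They do not demonstrate robustness to real annotation noise:
mis-annotated pfams, profile cross-hits between eCIS and T6SS families,
fragmented scaffolds, or operons whose geometry violates the planted
ranges. Scale is also modest by design — the default test surface uses a
few hundred scaffolds and 32-tip trees, sizes chosen so the full suite
runs in about a minute and a half while still exercising every rule
boundary.

## Degenerate inputs and tie-breaking

Empty genomes, empty hit lists, scaffold-edge operons, groups at exactly
the linkage/window thresholds, single-hit profiles, monomorphic traits
(`max_pairs = 0` → NA), 0/0 odds ratios (NA) and empty locus sets (empty
tables with a warning) are all defined behaviour with tests. Gene
ordering is canonicalised as (scaffold, start, end, gene_id); hit
filtering preserves input order; BH adjustment preserves input order and
is permutation-equivariant. All generators use integer-seeded PCG64
state, and every pipeline output embeds the tool version, a configuration
hash and the seed, so identical configurations produce byte-identical
outputs.

## Parameter defaults

| parameter | default | unit | role |
|---|---|---|---|
| linkage_gap_bp | 12,000 | bp | seed chaining window (inclusive) |
| contamination_window_bp | 10,000 | bp | phage/T6SS exclusion window (inclusive) |
| min_seed_genes | 4 | genes | seed-group size floor |
| min_distinct_seed_pfams | 3 | pfams | seed-group diversity floor |
| expansion_genes | 10 | genes | coding-gene expansion per side |
| min_core_genes | 10 | genes | core census floor (multiplicity) |
| boundary_flank_genes | 4 | genes | reported locus flank |
| hmm_keep_fraction | 0.5 | — | per-profile bitscore rank cut |
| fiber_select_fraction | 0.25 | — | afp13 rank cut for fiber analysis |
| fiber_evalue_cut | 1e-3 | — | BLAST hit significance |
| fiber_bitscore_delta | 15 | bits | decision margin (strict >) |
| plasmid_score_cut | 0.7 | — | threshold for joining precomputed plasmid scores |

These defaults are the operating point of the genome survey this pipeline
reimplements; all live in `CoreConfig`, serialisable to YAML, never in
code.

## Known limitations

Plasmid prediction itself is out of scope (the pipeline only thresholds a
precomputed score column at ≥ 0.7), as are multiple sequence alignment
and tree building (trees are consumed as newick), accessory-gene
clustering (cluster assignments are consumed as tables) and any
subtype I/II classification. The default pfam→role map is intentionally
minimal and should be extended with an organisation's own curated table
for production use.
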