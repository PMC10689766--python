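# Methods

This document records the model behind each stage, the parameters with
their defaults and rationale, the numerical choices that matter, and what
the test suite does and does not demonstrate.

## 1. Detection model

**Signal.** A spontaneously induced prophage excises, circularises (joining
*attL* and *attR*) and packages its DNA into virions. A DNase-treated
virion library mapped to the lysogen assembly yields (a) a coverage island
over the integrated prophage against a near-zero chromosomal background,
and (b) junction evidence at the att sites: fragments crossing the circular
junction map as outward-facing discordant pairs (the attL-side mate on the
minus strand, the attR-side mate on the plus strand), and reads crossing
the junction themselves map soft-clipped with the clip boundary exactly on
an att site.

**Island segmentation** (`detection.segment_islands`). Alignments with
MAPQ ≥ 1 (primary only) are piled into per-base depth. Thresholding
happens on 1 kb window-mean depth, not per-base depth: virion-library
backgrounds sit well below 1×, where per-base Poisson noise crosses any
small multiple of the background, while 1 kb window means separate cleanly.
Windows with mean ≥ `min_fold` × background are kept, runs merged across
gaps ≤ `merge_gap_bp`, and runs shorter than `min_len_bp` dropped.
Junction refinement restores base-exact boundaries afterwards, so the
window-granular island edges cost nothing.

**Background estimation.** The initial background is the *median* of 1 kb
window-mean depths over the whole genome, robust while islands cover a
minority of it. Once an island set exists, the background is re-estimated
as the plain *mean* depth outside the islands and the segmentation repeated
until stable (cap 5 rounds; non-convergence keeps the last set and warns).
The outside mean, not the outside median, is deliberate: at sub-1×
backgrounds the window-mean distribution is discrete and skewed, and the
median jumps between levels (0, 0.15, 0.3 … for 150 bp reads) as windows
are excluded — an earlier median-based implementation could feed back into
a collapsing threshold on occasional datasets. The mean is stable, and with
the islands already excluded it no longer needs to resist contamination.
With a zero background but nonzero depth (a strictly virion-only library)
every covered per-base run becomes a candidate, with a warning.

**Junction evidence** (`detection.collect_junction_evidence`). Within
`search_window_bp` of each island edge the caller collects (a) outward
discordant pairs — one mate near each edge; wrong orientations are recorded
but never count as support — and (b) alignments clipped by ≥ `min_clip_bp`
whose clip boundary lies near an edge. Pairs that are themselves clipped
are counted once, as splits.

**Boundary refinement** (`detection.refine_boundaries`). A boundary pair
(b_l, b_r) is scored by the number of orientation-consistent pairs it
explains — both mates inside, implied circular insert
(b_r − right_start) + (left_end − b_l) in (0, `max_insert_bp`] — plus the
number of split reads whose clip position equals a boundary exactly. Ties
break by (1) more split support, (2) shorter interval, (3) leftmost start.
The search is restricted to a candidate grid: observed pair anchors, clip
positions, the island edges, and the search-window extremes nearest the
island interior. The grid is exact: at an optimum, each boundary is a pair
anchor, a clip position, or — when one edge has no constraining evidence,
so the score is flat and the shorter-interval tie-break pushes it outward —
the window extreme. A brute-force enumeration over all integer pairs is
kept as a test oracle and agrees (hypothesis property test plus acceptance
criterion). With fewer than `min_support` supporting observations the call
falls back to the island edges, flagged `coverage_only`.

Pairs alone only bracket boundaries (they constrain b_l from above and b_r
from below); *exact* single-base recovery requires split reads at the att
sites. The acceptance study therefore conditions exactness on split
evidence being present on both edges, and also checks that this holds in
≥ 95% of replicates at study depth (observed ≈ 100%).

**Flanking enrichment** (`detection.flanking_enrichment`). Lateral
transduction by headful packaging elevates coverage on one flank with a
step/decay profile. Per flank the caller reports mean depth, enrichment
over background, and the least-squares slope of log(depth + 1) against
distance from the prophage edge. Known limitation: a strong lateral
gradient can extend the coverage island beyond the true att site on that
flank before refinement; when junction evidence is sparse the
coverage-only boundary on that side is unreliable, and enrichment should
be assessed from the refined (junction-supported) interval.

### Detection parameters

| parameter | default | rationale |
|---|---|---|
| `min_fold` | 5 | islands are ≥ 10–100× background in practice; 5× is permissive while excluding noise |
| `min_len_bp` | 5 000 | smallest induced prophages are ~16 kb; 5 kb keeps partial islands |
| `merge_gap_bp` | 2 000 | bridges short low-coverage dips inside one prophage |
| `search_window_bp` | 2 000 | island edges are window-granular; atts lie within ~1 kb of them |
| `max_insert_bp` | 1 500 | upper bound on sequencing fragment length |
| `min_support` | 2 | two independent junction observations guard against chimeras |
| `min_clip_bp` | 20 | shorter clips are common alignment noise |
| MAPQ | ≥ 1 | drops multi-mapping reads whose position is uninformative |

## 2. Quantification model

titre = m_DNA · N_A / (M_nt · L) · (r_pp / r_tot), with
N_A = 6.02214076 × 10²³ /mol and M_nt = 617.96 g/mol/bp. m_DNA is the
eluted DNA mass per 1 mL of overnight culture (ng in the interfaces,
converted internally); r_pp counts retained reads whose leftmost mapped
base lies in the call interval (leftmost-position binning keeps per-call
counts exactly multinomial in fragment origins; calls must be disjoint).

**Detection limit.** The smallest measurable total eluted mass is the
per-aliquot assay limit scaled by elution/assay volume (the aliquot is a
measurement, not a consumption). Spread over the supernatant volume,
pushed through the titre formula at r_pp/r_tot = 1 for an average-length
prophage, and inflated for virions lost during concentration:
0.1 ng × (24/5) / 30 mL, L = 41 kb, 47% loss → 7.2 × 10⁵ virions/mL.

**Induction rate.** titre / (CFU/mL × burst size); at the detection-limit
titre with 2.9 × 10⁹ CFU/mL and burst 150 this is 2 × 10⁻⁶ per cell.

**Mass conservation.** Inverting the formula gives each prophage's implied
DNA mass share; shares plus the unassigned-read share reproduce m_DNA to
machine precision (tested).

**Known small bias.** If residual chromosomal background reads fall inside
a prophage interval they inflate r_pp slightly (by background_fraction ×
L/G in expectation). This mirrors reality — DNase treatment minimises but
cannot eliminate background. The unbiasedness property is therefore stated,
and tested, under the model's own terms: multinomial read counts from true
titres and m_DNA derived from true genome-copy masses.

## 3. Benchmarking

Per active prophage: nucleotide precision |pred ∩ active| / |pred| and
recall |pred ∩ active| / |active| of the best single prediction; an active
prophage counts as *predicted* only if one prediction alone has recall
strictly > 0.75 (never aggregated across partial predictions). Active
prophage recall is the matched fraction. `category_rates` tabulates
activity across the four structural-gene × insertion-sequence annotation
cells, with NaN (not 0) for empty cells and an `unknown` row for
unresolved flags.

## 4. Phagotypes and protection

Active prophages are clustered from a symmetric percent-similarity matrix
by single linkage (connected components of the ≥ threshold graph; 95% ≈
species, 70% ≈ genus). Clusters at a higher threshold provably nest inside
clusters at a lower one (tested on random matrices). A strain's phagotype
is its frozenset of prophage clusters; the empty set is a valid phagotype.

`protection_statistic` compares plaquing among ordered strain pairs whose
cluster sets stand in a chosen relation (`equal`, `subset_either`,
`donor_subset_of_recipient`; default `subset_either`, since a strain
carrying a superset of the donor's phages is expected to be immune) against
all ordered pairs, excluding self-pairs. `include_empty` controls whether
prophage-free strains join within-group pairs (the empty set is a subset of
everything). Significance is a seeded permutation test shuffling cluster
sets across strains, p = (1 + #{permuted rate ≤ observed}) / (1 + N); note
the attainable p-value floor is the fraction of permutations preserving the
partition, so small strain panels cannot reach small p.

## 5. Simulator

`simulate.simulate(cfg)` builds a random host genome with prophages of
specified length, GC and titre inserted at specified positions (truth
intervals reported in final coordinates), then draws read pairs: pool
proportions are the prophages' mass shares (titre × length) plus a
configurable background fraction; per-prophage counts are multinomial;
fragments are uniform on the *circular* excised genome, so pairs crossing
the wrap map as outward discordant pairs and reads crossing it are
soft-clipped exactly at the att sites (the longer piece is the primary
alignment). m_DNA is derived from the configured titres
(Σ titre·L·M_nt/N_A, scaled by 1/(1 − background fraction)), making titre
recovery a closed loop. Optional lateral transduction adds Poisson extra
pairs per headful step with a geometric-like decay away from one edge.
Outputs: FASTA, truth SAM (deterministic bytes for a given seed), BED
truth intervals, metadata TSV, optional FASTQ. Three independent RNG
streams (genome, reads, lateral) are derived from one seed.

The simulator is an *oracle with known geometry*, not a read-error model:
no sequencing errors, no alignment ambiguity, no repeat-induced
multi-mapping. Passing tests therefore demonstrate correctness of the
statistical and geometric logic (segmentation, refinement optimality,
multinomial quantification), not robustness to aligner artefacts on real
libraries.

## 6. Test-suite design and problem sizes

Problem sizes in the tests and acceptance studies (60–260 kb genomes,
16–40 kb prophages, 10³–10⁴ read pairs) are the package's own choice: they
keep ~140 tests plus two 100-replicate studies under a minute while every
statistical assertion uses an explicit oracle — Lander–Waterman 3σ depth
checks, binomial/multinomial 3σ count checks, brute-force enumeration for
the boundary search and clustering, algebraic identities for mass
conservation. Statistical tests are seeded and derandomized; tolerance
bounds are 3σ under the tested model, not tuned margins.
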