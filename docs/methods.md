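# Methods

This note documents the models, parameter choices and numerical conventions
behind notchkit, and what its synthetic benchmark does and does not show
about real data.

## Curation model

Curation is a fixed three-stage filter; a record is charged to the *first*
stage it fails, so the report's counts partition the input exactly.

1. **Keyword screen.** Case-insensitive regular expressions over the
   defline description. Defaults: `strawberry notch`, `hypothetical`,
   `partial`, `low quality`, `predicted`, `synthetic construct`. These are
   defline conventions of public protein databases; `flag_patterns` can
   additionally mark (without removing) records.
2. **Reference screen.** Smith–Waterman local alignment (Gonnet matrix,
   affine gaps 10/0.5) of each record against a small set of family
   exemplars. The score is normalised by the self-score of the *aligned
   reference segment*; the record is kept if its best ratio reaches
   `min_norm_score` (default **0.3**). The default was chosen for the wide
   empirical separation between true homologs and chance similarity:
   shuffled or random sequences peak near 0.15–0.21 while a copy with 10%
   substitutions scores ≈ 0.88.
3. **Duplicate sweep.** Records are visited in descending length (ties:
   lexicographic id) and removed when global-alignment identity to an
   already-kept record reaches `identity_threshold` (default **0.95**).
   Identity is matches over *all alignment columns* (a pairwise alignment
   has no dual-gap column), which deliberately penalises length-discordant
   partial sequences. Identity is bounded by the length ratio, so
   length-discordant pairs are skipped without aligning. By default the
   sweep runs within each organism ("per species"); a global mode exists
   because database duplicates occasionally cross records of the same
   species labelled differently.

## Alignment model

Pairwise and profile alignment share one affine-gap dynamic-programming
engine (numba-compiled): three states, gap of length *k* costs
`gap_open + (k-1)·gap_extend` with defaults **10 / 0.5** on the Gonnet-250
score scale (the matrix is named by the source method; penalties are this
package's choice, as none are published with it). Traceback ties resolve
diagonal > up > left, making every alignment deterministic.

The progressive MSA follows the classic recipe: raw p-distances from
all-pairs global alignments ("the differences between each pair"), a
neighbor-joining guide tree (Q-criterion, negative branch lengths clamped
to zero, midpoint-rooted to order merges), then post-order profile–profile
alignment. Profile columns are scored by the frequency-weighted average
substitution score with gap and ambiguity (`X`) symbols contributing zero;
gaps once inserted are never removed and there is no iterative refinement.
Guide-tree distances are deliberately *uncorrected* p-distances, while the
downstream phylogeny uses corrected distances — two distinct distance
recipes for two distinct roles.

Consensus: per column, if the gap fraction exceeds `gap_rule_threshold`
(default 0.5) the column is omitted; otherwise the modal gap-excluded
residue wins, ties broken alphabetically (deterministic and documented; no
biological claim attaches to tie order).

## Distance correction and clustering

Observed difference fractions *p* (pairwise deletion: only columns where
neither row is gapped are compared) are corrected with the 20-state
Jukes–Cantor formula

    d = -(19/20) · ln(1 - 20 p / 19),

undefined at the saturation bound p ≥ 19/20. Saturated pairs raise by
default; `clamp_saturated` caps them at the largest finite corrected entry
(logged). Pairwise deletion is essential here because family members differ
~25-fold in length; complete deletion would leave no columns.

UPGMA merges the closest pair at height d/2 with size-weighted average
update; ties take the smallest (i, j) in the current cluster ordering and
the merged cluster inherits position i. Average linkage is monotone, so the
tree is exactly ultrametric. Cluster extraction cuts the tree at a height;
since no numeric threshold is published for the family's eight clusters,
the automatic threshold is the midpoint of the largest gap between
consecutive sorted merge heights — a deterministic, scale-free surrogate
that exactly recovers planted partitions whenever within-clade merge
heights and between-clade merge heights are separated by a gap larger than
any gap inside either regime.

Bootstrap supports resample alignment columns with replacement; replicate
*r* draws from a generator seeded `seed + r`, and a replicate that leaves
some pair with no comparable column is redrawn (at most 10 times, logged).
Support compares *rooted* clades (leaf sets), matching UPGMA's rooted
output. The consensus-level ("specialized") phylogeny bootstraps the
consensus alignment it is built from.

## Motif grammar and repeat calling

Patterns are PROSITE-flavoured: fixed residues, wildcard `X`, classes
`[FY]`, bounded spacers `x(m,n)`; `-` separators are cosmetic. An input
ambiguity character `X` satisfies wildcards and spacers but never a fixed
position or class. Scanning reports either all distinct occurrences or
non-overlapping leftmost matches; in non-overlapping mode each match takes
its *shortest* extent, which is what makes tandem EGF repeats come out one
per unit rather than bridging across units through intervening cysteines.

EGF-like repeats are called by the cysteine-spacing grammar
`C-x(2,14)-C-x(1,10)-C-x(1,6)-C-x(2,14)-C-x(1,8)-C`. The spacing bounds are
configuration constants chosen to accept the canonical unit and typical
EGF spacing; no published spacing numbers exist for this family's
annotation. The six anchored cysteines are reported with the canonical
disulfide pairing (1–3, 2–4, 5–6). Calcium-binding classification is a
documented surrogate: the five residues N-terminal of the repeat's first
cysteine must contain `[DN]-x-[DN]-[EQ]` (the published description names
only an asparagine/aspartate residue; this consensus makes the call exact
and testable). A repeat starting with fewer than four flank residues is
classified non-binding and logged. The digital signature is then the N→C
string of these bits, one per called repeat.

Motifs C, D and E (LNR-core and NOD/NODP patterns) are shipped as *named
configurable patterns with synthetic defaults* matched to this package's
domain templates and flagged experimental: their exact residues are not
legible from the source figures.

**Discovery.** Per alignment column: fixed residue if the modal
gap-excluded frequency ≥ `invariant_tau` (0.95), else a two-residue class
if the top-2 cumulative frequency ≥ `class_tau` (0.95), else wildcard;
columns gapped in > 50% of rows are wildcards. Maximal windows of length ≥
`min_len` (7) that start and end on non-wildcard columns and contain no
wildcard run longer than `max_wildcard_run` (2) become pattern strings.
With these defaults the EGF panel yields exactly `CXNGGXC` and
`CXCXXG[FY]XG`.

## Synthetic benchmark

The generator's purpose is a dataset whose every property is known, so the
pipeline can be scored exactly.

- **Architectures.** Eight clade specs: bacteria (110 aa, one EGF-like
  unit plus the NOD motif-D fragment), plants (400 aa), protist (600 aa),
  invertebrate (2,700 aa), Notch1–4 (2,627 / 2,471 / 2,321 / 2,059 aa).
  Notch1–3 carry the canonical 36 EGF repeats, 3 LNRs and 7 ANKs; Notch4 a
  reduced array of 29 EGFs (its real counterpart is likewise the shortest).
  Domain templates are synthetic stand-ins reproducing grammar-level
  features only; cysteines occur exclusively where a grammar needs them
  (linkers are cysteine-free; LNR cysteines sit in adjacent pairs that
  cannot seed the EGF chain), so repeat calls on generated sequences are
  truth-exact. The calcium plan marks every fourth repeat non-binding.
- **Divergence ladder.** One family master evolves down a planted
  ultrametric ladder (heights in expected substitutions per unprotected
  site): Notch2/Notch3 split last (0.30), then Notch1 (0.36), Notch4
  (0.42), the GLP-1/LIN-12-like outgroups (pair 0.30, joining outside the
  paralogs at 0.50), invertebrates (0.55), protist (0.60), plants (0.65),
  bacteria (0.70); clade members hang at 0.02. The ladder was designed so
  that after correction the within-clade and between-clade merge heights
  are separated by a gap several-fold larger than any gap inside either
  regime — the separation regime the clustering method presumes — and so
  that the sister structure (Notch2–Notch3 closest; outgroups outside the
  paralog clade) is unambiguous.
- **Substitution model.** Per-branch substitution probability follows the
  Jukes–Cantor expectation, replacements uniform — so corrected distances
  recover planted path lengths in expectation and test expectations stay
  analytic. Within the family simulation, replacements are drawn from the
  cysteine-free alphabet so planted cysteine architectures stay exact in
  every descendant; the public `evolve_clade` operation keeps the plain
  uniform-over-19 model. Motif-invariant template positions are protected
  from substitution; indels (geometric lengths) are restricted to linker
  segments, so planted domain *coordinates* remain exact in the truth
  table even with indels.
- **Noise and duplicates.** Noise flavors cycle through shuffled
  "strawberry notch homolog" / "LOW QUALITY" / "PREDICTED" records, random
  "hypothetical" and "synthetic construct" sequences, truncated "partial"
  copies, and one *unrelated* flavor with an innocuous defline that only
  the reference screen can catch. Duplicates are 1.5%-substituted, 1%-
  truncated copies of clean members (global identity ≈ 0.97–0.98, same
  organism, shorter than their source).
- **What it does not emulate.** No realistic rate matrix (WAG/LG), no
  rate heterogeneity, no domain gain/loss within clades, no alignment-
  ambiguous repeat expansion, no taxonomy beyond the organism string.
  Passing on this benchmark demonstrates the pipeline's correctness under
  its stated assumptions, not performance on raw database downloads.

## Problem sizes and runtime

The default benchmark (8 clades × 6 members plus outgroups, noise,
duplicates; sequences up to ~2,700 aa) runs the full pipeline in ~25 s on
one core; the dominant cost is the all-pairs guide-tree alignment
(O(n²L²)). Parameter-recovery studies use the equal-length partition
benchmark (K ≤ 8 clades, 1,000 aa, within 0.04 vs between 0.12 — the 3×
separation regime), where sequence length was set so binomial sampling
noise is small against the planted gap. The motif-discovery panel uses 24
rows, enough that a random column cannot reach the 0.95 conservation
thresholds by chance.

## Known limitations

- The largest-gap threshold assumes one dominant scale separation; on data
  with a continuum of divergences it will still cut *somewhere*, and the
  explicit `cut_height` override exists for that case.
- The reference-screen normalisation can in principle favour short perfect
  segments; empirically the Smith–Waterman optimum for unrelated sequences
  is a longer, weaker alignment and the 0.3 threshold separates cleanly,
  but adversarial inputs (e.g. low-complexity repeats) are not modelled.
- Progressive alignment is greedy: its sum-of-pairs score can fall below a
  star alignment on *unrelated* sequences; the guide tree only guarantees
  sensible merge order when the inputs are genuinely homologous.
- Very short members (the 110-aa bacterial miniature) contribute few
  comparable columns, so their distances are the noisiest; in compact test
  rosters mid-size clades are preferred for this reason.
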