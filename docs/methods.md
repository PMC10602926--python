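# Methods

This note documents the models, defaults and numerical choices behind
`lretools`, and what the synthetic-data tests do and do not demonstrate
about real data.

## The LRE model

An LRE (LIN-41 Response Element) is modelled as a tri-loop hairpin: a
contiguous stem of `k` base pairs closing a loop of exactly 3
nucleotides, with two structural constraints — the third loop base is a
purine (A or G), and the loop-closing pair, read with the 5′-strand base
first, is U–A or C–G. "First stem base pair" is interpreted as the
loop-closing pair with the 5′ base named first; both the orientation and
the allowed pair set are configurable if a different reading is wanted.

### Enumeration

The scanner slides over every possible loop position and extends the
stem outwards from the closing pair while pairs are allowed: canonical
Watson–Crick pairs always, G–U/U–G wobble only when `allow_wobble` is on
and never at the closing position. Each loop position therefore yields
at most one hairpin — the maximal-stem one, capped at `max_stem` — and a
hairpin is emitted only if the stem reaches `min_stem`. Defaults
`min_stem = 3`, `max_stem = 8`, wobble on: these are package choices
(short stems below 3 bp are rarely stable; beyond 8 bp additional pairs
carry little extra binding information and would inflate spans). No
bulges are modelled.

Local enumeration deliberately replaces full secondary-structure
prediction: it is deterministic, engine-independent and exactly testable
against a brute-force oracle. For a folding-based scan,
`hairpins_from_dotbracket` imports externally computed dot-bracket
structures (e.g. from an MFE folder) and extracts tri-loop helices into
the same classification layer, truncating stems at the first bulge or
disallowed pair.

### Scoring

Site scores are additive over scored positions: the three loop bases,
the closing pair and each non-closing stem pair. The original
position-specific binding-strength model is not publicly available, so
the shipped table is an explicit stand-in that rewards the known
determinants (purine identity at loop position 3, closing-pair identity,
stem-stabilising pairs, small bonuses for favourable loop bases). It is
calibrated so that a bare minimally valid LRE scores exactly at the
lowest threshold (0.225) and a fully optimal one scores ≥ 1.8, i.e. the
four categories are all reachable; both properties are asserted at
import time. Every weight, threshold and structural parameter can be
replaced through the YAML config without touching code. Scores are in
arbitrary model units; only their thresholds give them meaning.

### Categories

The four categories (minimal, weak, medium, strong) start at 0.225,
0.45, 0.9 and 1.8 — twofold steps. Lower bounds are inclusive: this is
forced by the requirement that four printed thresholds define four
categories (a score of exactly 0.225 must fall somewhere, and "minimal"
is the only consistent choice). A corollary used as a test invariant:
doubling any score in [0.225, 1.8) advances the category by exactly one.

### Overlap resolution

Overlapping classified sites on one UTR are resolved greedily — accept
by descending score, ties broken by leftmost start, discard anything
overlapping an accepted site. Greedy resolution is deterministic and
order-independent; nothing in the underlying biology dictates a
particular de-duplication, so the simplest reproducible rule is used.

## Per-mRNA binding score and the RIP scatter

The predicted binding score of an mRNA is the weighted sum of its site
scores, with per-UTR weights (`utr_weights`, both 1.0 by default). This
is the simplest aggregation consistent with binding strength depending
on the number of LREs and their UTR location; a counts-by-category score
is the special case where each site contributes its category midpoint.
No saturation cap is applied — if binding saturates with many sites, a
cap can be layered on top, but none is assumed.

`rip_scatter` filters to mRNAs with log2 enrichment ≥ log2(min_fold)
(default 4-fold), then reports both Pearson and Spearman coefficients:
the relationship is not assumed linear, and reporting both makes the
choice immaterial. Degenerate inputs (fewer than two points, or a
constant column) yield NaN correlations rather than an error.

## The discovery funnel

Four filters, each a pure set predicate: RIP enrichment ≥ min_rip_fold;
germline-expressed; ≥ min_lre_count LREs across both UTRs (default 2 —
repression requires at least two elements; all four categories count by
default, restrictable via `counted_categories`); not OMA-RIP-enriched.
The germline and OMA sets are opaque user-supplied lists; no
significance recomputation is attempted on them. Because the filters are
pure, they commute — a property test permutes their order. Every input
transcript keeps its flag row, so funnel counts are auditable after the
fact.

## Validation statistics

* **2^(−ΔΔCq)**: per matched replicate, ΔCq = Cq(target) − Cq(reference);
  ΔΔCq is the difference of condition means; significance from an
  unpaired t-test on per-replicate ΔCq values. Welch's (unequal
  variance) form is the default since equality of variances is rarely
  defensible for 3-replicate qPCR; `equal_var=True` gives the pooled
  form. Zero within-condition variance is handled explicitly (t = 0 or
  ±∞) instead of tripping numerical warnings. The method is invariant
  to adding a constant to every Cq.
* **Standard curve**: ordinary least squares of Cq on log10
  concentration; quantification inverts the fitted line; efficiency is
  10^(−1/slope) − 1 (slope −1/log10 2 ≈ −3.3219 at 100%). Slopes below
  1e-9 in magnitude raise a degenerate-curve error.
* **Condition ratios**: ratio of group means, SD by first-order error
  propagation, and a t-test of per-replicate ratios (a_i / mean(b))
  against 1 — matching the convention of plotting mutant/wild-type
  ratios against a reference line at 1. Raw ratios, not log-ratios, are
  tested.
* **Hypergeometric overlap**: upper tail P(X ≥ k) summed from
  log-gamma-space pmf terms via logsumexp. Plain factorial arithmetic
  overflows and naive pmf products underflow long before the
  transcriptome-scale universes (N ~ 2×10⁴) and 1e-33-scale p-values
  this test must handle; the log-space path agrees with brute-force
  enumeration to 1e-14 on all universes N ≤ 20.
* **Rank-sum test**: statistic W = rank sum of the first sample over
  pooled midranks. When C(n+m, n) ≤ 20 000 the two-sided p is exact by
  full enumeration of rank splits (|W − E[W]| ≥ observed, which also
  handles ties correctly); otherwise a tie-corrected normal
  approximation with continuity correction is used, and the result
  reports which path ran. All-tied input returns p = 1 with a warning.
* **Fluorescence ratios**: per animal, mean oocyte-nucleus intensity
  over mean distal-gonad intensity (the distal gonad lacks the
  repressor, making it an internal normaliser). `exclude_last` drops the
  final oocyte entry — the ovulating (−1) oocyte, where the repressor is
  degraded — and expects oocyte values ordered distal-to-proximal.
  Groups are compared with the rank-sum test.

## Synthetic data: what it emulates, what it does not

`make_lre_sequence` searches loop/closing/stem-pair combinations under
the active weight table for a construct landing in the requested
category interval, then *verifies the construct by scanning it* —
a fragment is only emitted if exactly one site with the intended span,
score and category is recovered. Fragments carry AA…CC flanks, which
cannot pair, so context can never extend a planted stem.

`make_cohort` draws background UTRs i.i.d. uniform over A/C/G/U
(configurable, e.g. to AT-rich compositions; uniform keeps chance-
hairpin rates analytically estimable). Targets receive ≥ 2 planted
3′-UTR LREs, ≥ 5 nt from the record edges and ≥ 40 nt apart — more than
twice the maximal hairpin span, so no chance site can displace two
planted sites at once, which guarantees the LRE-count filter under
greedy overlap resolution. Enrichment is Normal(3.0, σ) on the log2
scale for the enriched subset (targets plus a background slice that is
deliberately forced to fail the germline or OMA filter) and
Normal(0, σ) otherwise; σ defaults to 0, the noiseless regime in which
the planted targets are provably the unique funnel survivors. Default
cohort size 500 transcripts / 20 targets keeps a full scan-and-filter
cycle around a second.

Passing the planted-truth tests shows the pipeline's logic is correct
and self-consistent; it does not show that the stand-in weight table
matches the physical binding model, that real UTR base composition or
secondary structure behaves like the i.i.d. background, or that real
RIP enrichment is Gaussian on the log2 scale. Conclusions about real
transcriptomes require the real weight table and annotations.

Other generators: `make_cq_table` writes Cq = baseline − log2(abundance)
+ Normal(0, sd) with the reference gene pinned at fold change 1, so the
noiseless table inverts exactly and the noisy table supports calibration
simulations (type-I error of the t-test is checked against its binomial
interval). `make_overlap_sets` hits a configured expected overlap
`fold × |A||B|/N` by drawing the in-A membership count binomially —
infeasible folds are rejected rather than clipped silently.

## Conventions and limitations

* Coordinates are 0-based half-open internally, in the site TSV and in
  BED output; BED scores are model scores ×1000, rounded.
* T is transliterated to U and case is normalised on load; scanning a
  DNA-alphabet file yields the identical site set.
* Determinism: all generators are pure functions of seed and
  parameters; identical runs produce byte-identical tables, and run
  manifests record seed, config hash and input checksums
  (`--deterministic` suppresses the timestamp).
* Known limitations: no bulged or multi-loop structures; no
  thermodynamic stability term; no saturation in the per-mRNA score;
  the OMA motif (UAA/U repeats) is not scanned as a scored class —
  OMA-enrichment is delegated to the supplied gene list; gene-level
  multiple-testing correction is out of scope (per-gene tests only).
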