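# lretools

Discovery and validation statistics for mRNAs regulated through **LIN-41
Response Elements (LREs)** — tri-loop RNA hairpins recognised by the
*C. elegans* TRIM-NHL protein LIN-41.

In the germline, LIN-41 represses specific mRNAs during the
oocyte-to-embryo transition. Some of that regulation is direct: LIN-41's
NHL domain binds tri-loop stem–loops in the 5′ or 3′ UTRs of target
mRNAs. `lretools` implements the computational side of finding such
targets and the numeric layer of validating them, for anyone who wants
to run the same analysis on their own UTR annotations, RIP-seq tables
and qPCR data — or on fully synthetic data with known ground truth.

## What it computes

**LRE scanning** (`lretools.scan`). An LRE is a tri-loop hairpin — a
stem of paired bases closed by a 3-nt loop — in which the third loop
nucleotide is a purine (A/G) and the loop-closing stem pair, 5′ base
first, is U–A or C–G. The scanner enumerates, per loop position, the
maximal-stem tri-loop hairpin (canonical pairs always, G–U wobble
optionally in non-closing positions), scores each site with an additive
position-weight table and assigns one of four categories with twofold
threshold steps:

```
minimal: 0.225 <= s < 0.45    weak: 0.45 <= s < 0.9
medium:  0.9   <= s < 1.8     strong: s >= 1.8
```

Overlapping sites are resolved greedily (highest score, then leftmost).

**Binding scores vs RIP-seq** (`lretools.binding`). The predicted
per-mRNA binding score is the UTR-weighted sum of its site scores,
`B(m) = Σ_sites w_utr(site) · s(site)`. `rip_scatter` joins scores with
log2 RIP enrichment, restricts to mRNAs enriched ≥ 4-fold and reports
Pearson and Spearman correlations.

**Candidate funnel** (`lretools.pipeline`). Four auditable filters:
RIP enrichment ≥ 4-fold → germline-expressed → ≥ 2 LREs in the UTRs →
not enriched in OMA RIP (which would indicate indirect, OMA-mediated
association). Every input transcript keeps per-filter pass/fail flags.

**Validation statistics** (`lretools.stats`). qPCR fold changes by the
2^(−ΔΔCq) method with an unpaired t-test (Welch's by default);
standard-curve quantification with amplification efficiency
10^(−1/slope) − 1; mutant/wild-type condition ratios compared to 1;
upper-tail hypergeometric gene-set overlap computed in log-gamma space
(transcriptome-scale universes, p-values down to the 1e-33 scale and
beyond); exact/approximate Wilcoxon rank-sum; and oocyte/distal-gonad
fluorescence-ratio normalisation with the ovulating (−1) oocyte
optionally excluded.

**Synthetic data** (`lretools.simulate`). Generators for every input —
UTRs with planted LREs of a requested category, cohorts whose planted
targets are provably the unique funnel survivors in the noiseless
regime, Cq tables with known fold changes, gene sets with a configured
overlap enrichment — each a pure function of its seed, shipping
machine-readable truth.

## Worked example

`examples/discover_candidates.py` simulates 200 transcripts (10 planted
targets) and runs the funnel:

```
funnel (transcripts surviving each filter, applied in order):
  input           200
  pass_rip        29
  pass_germline   18
  pass_lre        15
  pass_not_oma    10

candidates: ['tx0000', 'tx0001', ..., 'tx0009']
exact recovery: True
```

Each filter narrows the cohort (29 RIP-enriched, 18 of those
germline-expressed, 15 with ≥ 2 LREs, 10 outside the OMA set), and the
final candidates coincide exactly with the planted targets.
`examples/scan_utrs.py` shows the site table itself:

```
seq_id    utr_kind  start  end  stem_len loop  score category
  demo three_prime     12   27         6  UGG   1.90   strong
  demo three_prime     76   85         3  AUA   0.85     weak
```

Coordinates are 0-based half-open on the UTR. The other examples cover
qPCR analysis (`qpcr_analysis.py`), gene-set overlap
(`gene_set_overlap.py`) and reporter-fluorescence ratios
(`reporter_ratios.py`).

A command-line pipeline mirrors the library:

```sh
lretools simulate --seed 7 --outdir cohort/
lretools all --run-config run.yaml     # scan -> score -> candidates
lretools qpcr --cq cq.tsv --target cfp-1 --ref act-1 \
         --control wild_type --test mutant
```

## A note on the scoring weights

The per-position weight table that defines how strongly a given LRE is
bound is not publicly available from the original binding model, so the
shipped default (`DEFAULT_POSITION_WEIGHTS`) is a documented stand-in
calibrated to span all four categories. Any user-supplied table can be
loaded via the YAML model config (`lretools.io.load_model_config`), and
externally folded structures can replace the local hairpin enumeration
through `hairpins_from_dotbracket`. See `docs/methods.md` for the full
modelling account.
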