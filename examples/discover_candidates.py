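"""Run the candidate-discovery funnel on a simulated cohort.

Generates 200 transcripts of which 10 are planted targets (>= 2 LREs in
the 3' UTR, 8-fold RIP enrichment), then applies the four filters:
RIP enrichment >= 4-fold, germline expression, >= 2 LREs, and absence
from the OMA-RIP-enriched set.  In this noiseless setting the funnel
recovers exactly the planted targets.
"""

from lretools import ScoringModel, discover_candidates, make_cohort, scan_transcript
from lretools.io import pair_utrs

model = ScoringModel()
cohort = make_cohort(n_transcripts=200, n_targets=10, seed=7)

paired = pair_utrs(cohort.utr5 + cohort.utr3)
profiles = [
    scan_transcript(v.get("five_prime"), v.get("three_prime"), model)
    for _, v in sorted(paired.items())
]

table = discover_candidates(
    profiles, cohort.rip, cohort.germline, cohort.oma_enriched, model=model
)

print("funnel (transcripts surviving each filter, applied in order):")
for name, count in table.funnel_counts().items():
    print(f"  {name:<15} {count}")
print()
print("candidates:", table.candidates)
print("planted targets:", cohort.truth.targets)
print("exact recovery:", set(table.candidates) == set(cohort.truth.targets))
# The funnel counts show how each filter narrows the cohort; the final
# candidate list coincides with the planted ground truth.
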