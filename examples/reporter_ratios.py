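"""Reporter-fluorescence quantification: oocyte/distal-gonad ratios.

Each animal contributes oocyte-nucleus intensities (ordered
distal-to-proximal; the last entry is the ovulating -1 oocyte, which is
excluded because the repressor is degraded there) and distal-gonad
intensities used for normalisation.  Per-animal ratios are compared
between a repressed wild-type reporter and a de-repressed mutant
reporter with the unpaired two-sample Wilcoxon rank-sum test.
"""

from lretools import fluorescence_ratio

# (oocyte intensities, distal-gonad intensities) per animal
wild_type = [
    ([310, 290, 305, 880], [600, 640]),
    ([280, 300, 295, 910], [610, 590]),
    ([320, 310, 300, 850], [620, 600]),
    ([290, 285, 310, 900], [580, 620]),
]
lre_mutant = [
    ([980, 1010, 990, 1020], [600, 610]),
    ([1005, 995, 1010, 1000], [590, 600]),
    ([960, 990, 1000, 1010], [620, 600]),
    ([1000, 1020, 980, 995], [610, 590]),
]

res = fluorescence_ratio(wild_type, lre_mutant, exclude_last=True)
print("wild-type reporter ratios: ",
      [f"{r:.3f}" for r in res.ratios_a])
print("LRE-mutant reporter ratios:",
      [f"{r:.3f}" for r in res.ratios_b])
print(f"rank-sum W = {res.rank_sum.statistic:.0f}, "
      f"p = {res.rank_sum.p_value:.4g} ({res.rank_sum.method})")
# Ratios ~0.5 mean oocyte expression is half the distal gonad's
# (repression by LIN-41); the mutant reporter's ratios ~1.65 show
# de-repression, and the exact rank-sum p-value quantifies the contrast.
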