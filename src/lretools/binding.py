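"""Per-mRNA predicted binding scores and their relation to RIP-seq enrichment.

The predicted binding score of an mRNA aggregates its retained LRE sites:
the weighted sum of per-site scores, where the weight depends on whether
the site lies in the 5' or 3' UTR.  Aggregation is additive, so the score
grows with the number of LREs; counts-by-category summaries are the
special case where each site contributes its category midpoint.

:func:`rip_scatter` joins the scores with RNA-immunoprecipitation
enrichment values (log2 IP over input), restricts to mRNAs enriched at
least ``min_fold``-fold, and reports both Pearson and Spearman
correlations with two-sided p-values together with a plotting-ready table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Sequence

import pandas as pd
from scipy import stats

from .errors import InputError
from .model import ScoringModel
from .scan import TranscriptLreProfile


@dataclass(frozen=True)
class BindingScore:
    transcript_id: str
    value: float


@dataclass(frozen=True)
class RipRecord:
    """One RIP-seq record: log2 enrichment of IP over input for a transcript."""

    transcript_id: str
    log2_enrichment: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.log2_enrichment):
            raise InputError(
                f"{self.transcript_id}: log2_enrichment must be finite"
            )


def predicted_binding_score(
    profile: TranscriptLreProfile, model: ScoringModel
) -> BindingScore:
    """Weighted sum of per-site scores over both UTRs.

    value = sum over sites of site.score * utr_weights[site's UTR kind];
    an mRNA without sites scores exactly 0.
    """
    value = sum(
        site.score * model.utr_weights[kind] for kind, site in profile.all_sites()
    )
    return BindingScore(transcript_id=profile.transcript_id, value=value)


@dataclass
class ScatterResult:
    """Joined (binding score, log2 enrichment) table plus correlations."""

    table: pd.DataFrame
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    min_fold: float

    @property
    def n(self) -> int:
        return len(self.table)


def rip_scatter(
    scores: Sequence[BindingScore],
    rip: Iterable[RipRecord],
    min_fold: float = 4.0,
) -> ScatterResult:
    """Relate predicted binding scores to RIP-seq enrichment.

    Restricts to transcripts whose enrichment is at least ``min_fold``
    (i.e. log2 enrichment >= log2(min_fold)), inner-joins on transcript
    id and computes Pearson and Spearman correlations.  Raises
    :class:`InputError` when no transcript passes the filter and join.
    """
    if min_fold <= 0:
        raise InputError(f"min_fold must be > 0, got {min_fold}")
    score_df = pd.DataFrame(
        {
            "transcript_id": [s.transcript_id for s in scores],
            "binding_score": [s.value for s in scores],
        }
    )
    rip_df = pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in rip],
            "log2_enrichment": [r.log2_enrichment for r in rip],
        }
    )
    for name, df in (("scores", score_df), ("rip", rip_df)):
        dup = df["transcript_id"].duplicated()
        if dup.any():
            raise InputError(
                f"duplicate transcript ids in {name}: "
                f"{sorted(df.loc[dup, 'transcript_id'].unique())[:5]}"
            )
    cutoff = math.log2(min_fold)
    rip_df = rip_df[rip_df["log2_enrichment"] >= cutoff]
    table = score_df.merge(rip_df, on="transcript_id", how="inner")
    if table.empty:
        raise InputError("no transcripts pass the enrichment filter")
    table = table.sort_values("transcript_id", ignore_index=True)
    if len(table) >= 2 and table["binding_score"].nunique() > 1 \
            and table["log2_enrichment"].nunique() > 1:
        pr = stats.pearsonr(table["binding_score"], table["log2_enrichment"])
        sr = stats.spearmanr(table["binding_score"], table["log2_enrichment"])
        pearson_r, pearson_p = float(pr.statistic), float(pr.pvalue)
        spearman_rho, spearman_p = float(sr.statistic), float(sr.pvalue)
    else:
        pearson_r = pearson_p = spearman_rho = spearman_p = float("nan")
    return ScatterResult(
        table=table,
        pearson_r=pearson_r,
        pearson_p=pearson_p,
        spearman_rho=spearman_rho,
        spearman_p=spearman_p,
        min_fold=min_fold,
    )


def plot_scatter(result: ScatterResult, path: str) -> None:
    """Write the enrichment-vs-score scatter to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(
        result.table["binding_score"],
        result.table["log2_enrichment"],
        s=10,
        alpha=0.6,
        edgecolors="none",
    )
    ax.set_xlabel("predicted binding score")
    ax.set_ylabel("RIP log2 enrichment")
    ax.set_title(
        f"n={result.n}, Spearman rho={result.spearman_rho:.3f}"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def scores_from_profiles(
    profiles: Sequence[TranscriptLreProfile], model: ScoringModel
) -> List[BindingScore]:
    """Convenience: predicted binding score for every profile."""
    return [predicted_binding_score(p, model) for p in profiles]
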