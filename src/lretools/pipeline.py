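"""Candidate-discovery funnel for LRE-regulated germline mRNAs.

Starting from RIP-seq-enriched mRNAs, the pipeline applies four filters
in order:

1. RIP enrichment of at least ``min_rip_fold`` (default 4-fold);
2. membership in the germline-expressed gene set;
3. at least ``min_lre_count`` LREs (default 2) across both UTRs, since
   LRE-mediated regulation requires at least two elements;
4. absence from the OMA-RIP-enriched set, excluding mRNAs whose
   association is likely indirect (OMA-dependent).

Every input transcript keeps a per-filter pass/fail flag, so the funnel
is fully auditable; a candidate is a row passing all four.  The filters
are pure set operations and therefore commute.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set

import pandas as pd

from .binding import RipRecord, predicted_binding_score
from .errors import InputError
from .model import CATEGORY_NAMES, ScoringModel
from .scan import TranscriptLreProfile

FILTER_NAMES = ("pass_rip", "pass_germline", "pass_lre", "pass_not_oma")


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene/transcript identifiers."""

    name: str
    members: FrozenSet[str]

    @classmethod
    def from_iterable(cls, name: str, members: Iterable[str]) -> "GeneSet":
        return cls(name=name, members=frozenset(members))

    def __contains__(self, item: str) -> bool:
        return item in self.members

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds of the discovery funnel.

    ``counted_categories`` restricts which site categories count toward
    ``min_lre_count``; by default all four count, since the requirement
    of at least two LREs is not category-restricted.
    """

    min_rip_fold: float = 4.0
    min_lre_count: int = 2
    counted_categories: FrozenSet[str] = field(
        default_factory=lambda: frozenset(CATEGORY_NAMES)
    )

    def __post_init__(self) -> None:
        if self.min_rip_fold <= 0:
            raise InputError("min_rip_fold must be > 0")
        if self.min_lre_count < 1:
            raise InputError("min_lre_count must be >= 1")
        unknown = set(self.counted_categories) - set(CATEGORY_NAMES)
        if unknown:
            raise InputError(f"unknown categories: {sorted(unknown)}")


@dataclass
class CandidateTable:
    """Audit-trail output of :func:`discover_candidates`.

    ``frame`` holds one row per input transcript with LRE counts, the
    binding score, log2 enrichment, the four filter flags and the final
    ``is_candidate`` flag.
    """

    frame: pd.DataFrame
    config: PipelineConfig

    @property
    def candidates(self) -> List[str]:
        mask = self.frame["is_candidate"]
        return self.frame.loc[mask, "transcript_id"].tolist()

    def funnel_counts(self) -> Dict[str, int]:
        """Transcripts surviving each filter applied cumulatively in order."""
        counts: Dict[str, int] = {"input": len(self.frame)}
        mask = pd.Series(True, index=self.frame.index)
        for name in FILTER_NAMES:
            mask &= self.frame[name]
            counts[name] = int(mask.sum())
        return counts


def discover_candidates(
    profiles: Sequence[TranscriptLreProfile],
    rip: Iterable[RipRecord],
    germline: GeneSet,
    oma_enriched: GeneSet,
    cfg: Optional[PipelineConfig] = None,
    model: Optional[ScoringModel] = None,
) -> CandidateTable:
    """Run the four-filter discovery funnel over all input transcripts.

    Transcripts appearing in either the profiles or the RIP table are
    audited; a transcript missing from the RIP table has unknown
    enrichment and fails the RIP filter, one without a profile has zero
    LREs.  Raises :class:`InputError` on duplicated transcript ids or an
    empty germline set.
    """
    cfg = cfg or PipelineConfig()
    model = model or ScoringModel()
    if len(germline) == 0:
        raise InputError("germline gene set is empty")

    seen: Set[str] = set()
    for p in profiles:
        if p.transcript_id in seen:
            raise InputError(f"duplicate transcript id in profiles: {p.transcript_id}")
        seen.add(p.transcript_id)
    profile_map = {p.transcript_id: p for p in profiles}

    rip_map: Dict[str, float] = {}
    for r in rip:
        if r.transcript_id in rip_map:
            raise InputError(f"duplicate transcript id in RIP table: {r.transcript_id}")
        rip_map[r.transcript_id] = r.log2_enrichment

    import math

    cutoff = math.log2(cfg.min_rip_fold)
    cats = sorted(cfg.counted_categories)
    rows = []
    for tid in sorted(set(profile_map) | set(rip_map)):
        profile = profile_map.get(tid)
        n5 = profile.n_sites("five_prime", cats) if profile else 0
        n3 = profile.n_sites("three_prime", cats) if profile else 0
        score = predicted_binding_score(profile, model).value if profile else 0.0
        log2_enr = rip_map.get(tid, float("nan"))
        pass_rip = (tid in rip_map) and log2_enr >= cutoff
        pass_germline = tid in germline
        pass_lre = (n5 + n3) >= cfg.min_lre_count
        pass_not_oma = tid not in oma_enriched
        rows.append(
            {
                "transcript_id": tid,
                "n_lre_5utr": n5,
                "n_lre_3utr": n3,
                "binding_score": score,
                "log2_enrichment": log2_enr,
                "pass_rip": pass_rip,
                "pass_germline": pass_germline,
                "pass_lre": pass_lre,
                "pass_not_oma": pass_not_oma,
                "is_candidate": pass_rip and pass_germline and pass_lre and pass_not_oma,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "n_lre_5utr", "n_lre_3utr", "binding_score",
            "log2_enrichment", *FILTER_NAMES, "is_candidate",
        ],
    )
    return CandidateTable(frame=frame, config=cfg)


def utr_localization_report(table: CandidateTable) -> pd.DataFrame:
    """Per-candidate UTR localisation of LREs plus a cohort summary row.

    Localisation is ``3utr_only``, ``5utr_only``, ``both`` or ``none``
    based on the counted LRE tallies.  The returned frame has one row per
    candidate; the fraction of candidates whose LREs are exclusively in
    the 3' UTR is stored in ``frame.attrs['fraction_3utr_only']``.
    """
    cand = table.frame[table.frame["is_candidate"]].copy()

    def _loc(row) -> str:
        if row.n_lre_3utr > 0 and row.n_lre_5utr == 0:
            return "3utr_only"
        if row.n_lre_5utr > 0 and row.n_lre_3utr == 0:
            return "5utr_only"
        if row.n_lre_5utr > 0 and row.n_lre_3utr > 0:
            return "both"
        return "none"

    cand["utr_localization"] = [_loc(r) for r in cand.itertuples()]
    out = cand[
        ["transcript_id", "n_lre_5utr", "n_lre_3utr", "utr_localization"]
    ].reset_index(drop=True)
    n = len(out)
    out.attrs["fraction_3utr_only"] = (
        float((out["utr_localization"] == "3utr_only").mean()) if n else float("nan")
    )
    return out
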