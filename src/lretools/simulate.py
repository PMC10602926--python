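"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes:

* UTR sequences with LRE hairpins planted at known positions and of a
  requested category (``make_lre_sequence``);
* a transcript cohort with a designated target subset carrying >= 2
  planted 3'-UTR LREs, log-normal-style RIP enrichment (normal on the
  log2 scale) for an enriched subset, and germline/OMA gene sets built
  so that, in the noiseless configuration, the planted targets are
  exactly the transcripts surviving the discovery funnel
  (``make_cohort``);
* qPCR Cq tables with configurable true fold changes and replicate
  noise (``make_cq_table``);
* overlapping gene sets with a configured enrichment factor
  (``make_overlap_sets``).

Every generator is a pure function of its seed and parameters, and every
cohort ships machine-readable truth so that "pipeline output equals
planted truth" is a checkable statement.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .binding import RipRecord
from .errors import ConfigurationError, GenerationError
from .model import CATEGORY_NAMES, LRE_CLOSING_PAIRS, ScoringModel
from .pipeline import GeneSet
from .scan import RnaSequence, scan_sequence

ALPHABET = "ACGU"

#: Flanks guaranteed not to extend a planted stem: A cannot pair with C.
_LEFT_FLANK = "AA"
_RIGHT_FLANK = "CC"


@dataclass(frozen=True)
class LreFragment:
    """A planted hairpin-forming fragment with its expected score/category."""

    seq: str
    score: float
    category: str
    hairpin_start: int  # offset of stem5_start within the fragment
    stem_len: int

    @property
    def hairpin_span(self) -> Tuple[int, int]:
        return (self.hairpin_start, self.hairpin_start + 2 * self.stem_len + 3)


def _category_interval(category: str, model: ScoringModel) -> Tuple[float, float]:
    if category not in model.category_names:
        raise ConfigurationError(f"unknown category {category!r}")
    i = model.category_names.index(category)
    lo = model.thresholds[i]
    hi = model.thresholds[i + 1] if i + 1 < len(model.thresholds) else float("inf")
    return lo, hi


def _fragment_score(
    model: ScoringModel,
    loop: str,
    closing: Tuple[str, str],
    stem_pairs: Sequence[Tuple[str, str]],
) -> float:
    total = sum(model.loop_weight(i + 1, loop[i]) for i in range(3))
    total += model.closing_weight(*closing)
    total += sum(model.stem_weight(*p) for p in stem_pairs)
    return total


def make_lre_sequence(
    category: str,
    model: Optional[ScoringModel] = None,
    rng: Optional[np.random.Generator] = None,
) -> LreFragment:
    """Construct a fragment whose single LRE scores inside ``category``.

    The search enumerates loop compositions, closing pairs and
    non-closing stem-pair multisets under the model's pairing policy,
    takes combinations whose additive score lands in the category's
    interval, and verifies the construct by scanning it: the fragment is
    only emitted if the scanner recovers exactly one site with the
    expected span, score and category.  The flanks (AA ... CC) cannot
    pair, so the planted stem cannot be extended by context.  Raises
    :class:`GenerationError` when the category is unreachable under the
    supplied weight table.
    """
    model = model or ScoringModel()
    rng = rng or np.random.default_rng(0)
    lo, hi = _category_interval(category, model)
    stem_options = model.allowed_pairs(closing=False)

    candidates: List[Tuple[str, Tuple[str, str], Tuple[Tuple[str, str], ...]]] = []
    for stem_len in range(model.min_stem, model.max_stem + 1):
        for closing in sorted(LRE_CLOSING_PAIRS):
            for loop3 in "AG":
                for loop1 in ALPHABET:
                    for loop2 in ALPHABET:
                        loop = loop1 + loop2 + loop3
                        base = _fragment_score(model, loop, closing, [])
                        for combo in itertools.combinations_with_replacement(
                            stem_options, stem_len - 1
                        ):
                            score = base + sum(
                                model.stem_weight(*p) for p in combo
                            )
                            if lo <= score < hi:
                                candidates.append((loop, closing, combo))
                        if len(candidates) >= 200:
                            break
                    if len(candidates) >= 200:
                        break
                if len(candidates) >= 200:
                    break
            if len(candidates) >= 200:
                break
        if len(candidates) >= 200:
            break
    if not candidates:
        raise GenerationError(
            f"category {category!r} is unreachable under the supplied weight table"
        )

    order = rng.permutation(len(candidates))
    for idx in order[: min(len(order), 50)]:
        loop, closing, combo = candidates[idx]
        stem_pairs = list(combo)
        rng.shuffle(stem_pairs)
        # outermost -> closing; stem5 reads 5'->3', stem3 is reversed
        pairs = stem_pairs + [closing]
        stem5 = "".join(p[0] for p in pairs)
        stem3 = "".join(p[1] for p in reversed(pairs))
        core = stem5 + loop + stem3
        frag = _LEFT_FLANK + core + _RIGHT_FLANK
        expected_score = _fragment_score(model, loop, closing, stem_pairs)
        # closed-loop verification through the scanner
        seq = RnaSequence(id="fragment", utr_kind="three_prime", seq=frag)
        sites = scan_sequence(seq, model)
        span = (len(_LEFT_FLANK), len(_LEFT_FLANK) + len(core))
        match = [
            s for s in sites
            if s.span == span and abs(s.score - expected_score) < 1e-9
            and s.category == category
        ]
        if len(sites) == 1 and match:
            return LreFragment(
                seq=frag,
                score=expected_score,
                category=category,
                hairpin_start=len(_LEFT_FLANK),
                stem_len=len(pairs),
            )
    raise GenerationError(
        f"could not realise a clean {category!r} fragment; "
        "the weight table may make planted hairpins ambiguous"
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantSpec:
    """Provenance of one planted LRE site within a cohort UTR."""

    transcript_id: str
    utr_kind: str
    position: int  # 0-based offset of the hairpin's stem5_start in the UTR
    category: str
    stem_len: int
    score: float


@dataclass
class CohortTruth:
    """Ground truth sufficient to predict the noiseless candidate set."""

    frame: pd.DataFrame  # per transcript: is_target, is_germline, is_oma, log2
    planted: List[PlantSpec]
    seed: int

    @property
    def targets(self) -> List[str]:
        mask = self.frame["is_target"]
        return self.frame.loc[mask, "transcript_id"].tolist()


@dataclass
class Cohort:
    """A generated cohort: sequences, RIP table, gene sets and truth."""

    utr5: List[RnaSequence]
    utr3: List[RnaSequence]
    rip: List[RipRecord]
    germline: GeneSet
    oma_enriched: GeneSet
    truth: CohortTruth
    params: Dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        """Emit the cohort in the formats the pipeline reads, plus truth."""
        from . import io as lio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        lio.write_utr_fasta(self.utr5, outdir / "utr5.fasta")
        lio.write_utr_fasta(self.utr3, outdir / "utr3.fasta")
        lio.write_rip_table(self.rip, outdir / "rip.tsv")
        lio.write_gene_list(self.germline, outdir / "germline.txt")
        lio.write_gene_list(self.oma_enriched, outdir / "oma_enriched.txt")
        self.truth.frame.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        pd.DataFrame([vars(p) for p in self.truth.planted]).to_csv(
            outdir / "planted_sites.tsv", sep="\t", index=False
        )
        manifest = {
            "seed": self.truth.seed,
            "parameters": self.params,
            "n_transcripts": len(self.utr3),
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )


def _random_seq(rng: np.random.Generator, length: int,
                probs: Optional[Sequence[float]] = None) -> str:
    bases = rng.choice(list(ALPHABET), size=length, p=probs)
    return "".join(bases)


#: Minimum gap between planted hairpin spans within one UTR.  A tri-loop
#: hairpin spans at most 2*max_stem + 3 = 19 nt under the default model;
#: 40 nt keeps any single chance site from touching two planted sites.
_PLANT_GAP = 40
_EDGE_MARGIN = 5


def make_cohort(
    n_transcripts: int = 500,
    n_targets: int = 20,
    utr3_length_range: Tuple[int, int] = (120, 250),
    utr5_length_range: Tuple[int, int] = (30, 120),
    seed: int = 0,
    model: Optional[ScoringModel] = None,
    n_planted_per_target: int = 2,
    planted_categories: Optional[Sequence[str]] = None,
    mu_enriched: float = 3.0,
    rip_sigma: float = 0.0,
    germline_background_fraction: float = 0.5,
    oma_background_fraction: float = 0.2,
    enriched_background_fraction: float = 0.1,
    base_probs: Optional[Sequence[float]] = None,
    targets_in_oma: bool = False,
) -> Cohort:
    """Generate a full discovery-pipeline input cohort with planted truth.

    ``n_targets`` transcripts receive ``n_planted_per_target`` (>= 2 by
    default) non-overlapping LREs in their 3' UTR and a log2 RIP
    enrichment of Normal(``mu_enriched``, ``rip_sigma``); background
    transcripts draw Normal(0, ``rip_sigma``).  The germline set holds
    all targets plus a background fraction; the OMA-enriched set is
    background-only.  A background fraction is also made RIP-enriched
    for funnel realism, but each such transcript is forced to fail the
    germline or OMA filter, so with ``rip_sigma = 0`` the funnel's
    survivors are exactly the planted targets.  All randomness derives
    from ``seed``.
    """
    if n_targets > n_transcripts:
        raise ConfigurationError("n_targets cannot exceed n_transcripts")
    if n_planted_per_target < 1:
        raise ConfigurationError("n_planted_per_target must be >= 1")
    if targets_in_oma:
        raise ConfigurationError(
            "targets_in_oma contradicts the truth guarantee that planted "
            "targets survive the funnel; add targets to the OMA set on the "
            "caller side to probe that scenario"
        )
    if rip_sigma < 0:
        raise ConfigurationError("rip_sigma must be >= 0")
    model = model or ScoringModel()
    rng = np.random.default_rng(seed)
    cats = list(planted_categories) if planted_categories else list(CATEGORY_NAMES)

    ids = [f"tx{i:04d}" for i in range(n_transcripts)]
    target_ids = ids[:n_targets]
    background_ids = ids[n_targets:]

    # pre-build one fragment per category (search is deterministic per rng)
    utr5, utr3 = [], []
    planted: List[PlantSpec] = []
    for tid in ids:
        len5 = int(rng.integers(utr5_length_range[0], utr5_length_range[1] + 1))
        len3 = int(rng.integers(utr3_length_range[0], utr3_length_range[1] + 1))
        utr5.append(
            RnaSequence(id=tid, utr_kind="five_prime",
                        seq=_random_seq(rng, len5, base_probs))
        )
        if tid in target_ids:
            frags = [
                make_lre_sequence(str(rng.choice(cats)), model, rng)
                for _ in range(n_planted_per_target)
            ]
            needed = sum(len(f.seq) for f in frags) \
                + _PLANT_GAP * (len(frags) - 1) + 2 * _EDGE_MARGIN
            length = max(len3, needed)
            seq3 = list(_random_seq(rng, length, base_probs))
            slack = length - needed
            # distribute leftover length randomly between the planted blocks
            cuts = np.sort(rng.integers(0, slack + 1, size=len(frags)))
            pos = _EDGE_MARGIN
            prev_cut = 0
            for f, cut in zip(frags, cuts):
                pos += int(cut) - prev_cut
                prev_cut = int(cut)
                seq3[pos : pos + len(f.seq)] = list(f.seq)
                planted.append(
                    PlantSpec(
                        transcript_id=tid,
                        utr_kind="three_prime",
                        position=pos + f.hairpin_start,
                        category=f.category,
                        stem_len=f.stem_len,
                        score=f.score,
                    )
                )
                pos += len(f.seq) + _PLANT_GAP
            utr3.append(
                RnaSequence(id=tid, utr_kind="three_prime", seq="".join(seq3))
            )
        else:
            utr3.append(
                RnaSequence(id=tid, utr_kind="three_prime",
                            seq=_random_seq(rng, len3, base_probs))
            )

    # gene sets
    n_bg = len(background_ids)
    germline_bg = set(
        rng.choice(background_ids,
                   size=int(round(germline_background_fraction * n_bg)),
                   replace=False)
    ) if n_bg else set()
    oma = set(
        rng.choice(background_ids,
                   size=int(round(oma_background_fraction * n_bg)),
                   replace=False)
    ) if n_bg else set()
    germline = set(target_ids) | germline_bg

    # RIP enrichment: targets high; a slice of background too, but forced
    # to fail another filter so noiseless truth stays exact
    enriched_bg = list(
        rng.choice(background_ids,
                   size=int(round(enriched_background_fraction * n_bg)),
                   replace=False)
    ) if n_bg else []
    for tid in enriched_bg:
        if tid in germline and tid not in oma:
            oma.add(tid)
    enriched = set(target_ids) | set(enriched_bg)
    log2 = {
        tid: float(
            (mu_enriched if tid in enriched else 0.0)
            + (rng.normal(0.0, rip_sigma) if rip_sigma > 0 else 0.0)
        )
        for tid in ids
    }
    rip = [RipRecord(tid, log2[tid]) for tid in ids]

    truth_frame = pd.DataFrame(
        {
            "transcript_id": ids,
            "is_target": [tid in set(target_ids) for tid in ids],
            "is_germline": [tid in germline for tid in ids],
            "is_oma_enriched": [tid in oma for tid in ids],
            "is_rip_enriched": [tid in enriched for tid in ids],
            "true_log2_enrichment": [log2[tid] for tid in ids],
            "n_planted": [
                sum(1 for p in planted if p.transcript_id == tid) for tid in ids
            ],
        }
    )
    params = {
        "n_transcripts": n_transcripts,
        "n_targets": n_targets,
        "n_planted_per_target": n_planted_per_target,
        "mu_enriched": mu_enriched,
        "rip_sigma": rip_sigma,
        "germline_background_fraction": germline_background_fraction,
        "oma_background_fraction": oma_background_fraction,
        "enriched_background_fraction": enriched_background_fraction,
        "utr3_length_range": list(utr3_length_range),
        "utr5_length_range": list(utr5_length_range),
    }
    return Cohort(
        utr5=utr5,
        utr3=utr3,
        rip=rip,
        germline=GeneSet.from_iterable("germline", germline),
        oma_enriched=GeneSet.from_iterable("oma_enriched", oma),
        truth=CohortTruth(frame=truth_frame, planted=planted, seed=seed),
        params=params,
    )


# ---------------------------------------------------------------------------
# qPCR Cq tables
# ---------------------------------------------------------------------------


def make_cq_table(
    genes: Sequence[str],
    fold_changes: Dict[str, float],
    ref_gene: str,
    sd: float = 0.0,
    replicates: int = 3,
    seed: int = 0,
    conditions: Tuple[str, str] = ("control", "test"),
    priming: str = "total",
    baseline_range: Tuple[float, float] = (18.0, 26.0),
) -> pd.DataFrame:
    """Simulate a Cq table with known true fold changes.

    Per gene, the control-condition abundance is 1 and the test-condition
    abundance is the gene's true fold change; Cq = baseline - log2(abundance)
    + Normal(0, sd).  The reference gene is pinned at fold change 1, so
    the 2^(-ddCq) analysis of a noiseless table returns each gene's true
    fold change exactly.
    """
    if sd < 0:
        raise ConfigurationError("sd must be >= 0")
    if replicates < 2:
        raise ConfigurationError("replicates must be >= 2")
    if ref_gene not in genes:
        raise ConfigurationError(f"ref_gene {ref_gene!r} must be among genes")
    rng = np.random.default_rng(seed)
    baselines = {
        g: float(rng.uniform(*baseline_range)) for g in genes
    }
    fc = dict(fold_changes)
    fc[ref_gene] = 1.0
    rows = []
    for g in genes:
        if g not in fc:
            raise ConfigurationError(f"no fold change specified for gene {g!r}")
        if fc[g] <= 0:
            raise ConfigurationError(f"fold change for {g!r} must be > 0")
        for cond, abundance in zip(conditions, (1.0, fc[g])):
            for rep in range(1, replicates + 1):
                noise = float(rng.normal(0.0, sd)) if sd > 0 else 0.0
                rows.append(
                    {
                        "gene": g,
                        "condition": cond,
                        "replicate": rep,
                        "priming": priming,
                        "cq": baselines[g] - np.log2(abundance) + noise,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Overlapping gene sets
# ---------------------------------------------------------------------------


def make_overlap_sets(
    universe_size: int,
    a_size: int,
    b_size: int,
    fold_enrichment: float = 1.0,
    seed: int = 0,
) -> Tuple[GeneSet, GeneSet, GeneSet]:
    """Sample two gene sets with a configured expected overlap enrichment.

    The expected overlap is fold_enrichment * a_size * b_size / universe_size:
    each member of B is drawn from A with the matching probability
    (binomial count, clipped to the feasible range), the rest from
    outside A.  Returns (universe, set_a, set_b).
    """
    if a_size > universe_size or b_size > universe_size:
        raise ConfigurationError("set sizes cannot exceed the universe")
    if fold_enrichment < 0:
        raise ConfigurationError("fold_enrichment must be >= 0")
    expected = fold_enrichment * a_size * b_size / universe_size
    if expected > min(a_size, b_size) + 1e-9:
        raise ConfigurationError(
            f"expected overlap {expected:.2f} exceeds min(set sizes); "
            "fold_enrichment is infeasible"
        )
    p_in = expected / b_size if b_size else 0.0
    if p_in > 1.0 + 1e-12:
        raise ConfigurationError("fold_enrichment is infeasible for these sizes")
    rng = np.random.default_rng(seed)
    ids = [f"g{i:05d}" for i in range(universe_size)]
    a_members = rng.choice(ids, size=a_size, replace=False)
    outside = sorted(set(ids) - set(a_members))
    k = int(rng.binomial(b_size, min(1.0, p_in)))
    k = int(np.clip(k, max(0, b_size - len(outside)), min(a_size, b_size)))
    b_members = list(rng.choice(a_members, size=k, replace=False)) + list(
        rng.choice(outside, size=b_size - k, replace=False)
    )
    return (
        GeneSet.from_iterable("universe", ids),
        GeneSet.from_iterable("set_a", a_members),
        GeneSet.from_iterable("set_b", b_members),
    )
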