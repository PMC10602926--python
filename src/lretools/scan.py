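"""Tri-loop hairpin enumeration and LRE classification on UTR sequences.

The scan works per UTR: enumerate every maximal-stem tri-loop hairpin,
keep those that satisfy the LRE structural predicates (purine at loop
position 3; loop-closing pair U–A or C–G with the 5'-strand base first),
score them with the model's additive weight table, assign the category,
and finally resolve overlapping sites greedily (highest score first, ties
broken by leftmost start).

All coordinates are 0-based half-open on the UTR sequence.  An import
path for externally computed secondary structures is provided by
:func:`hairpins_from_dotbracket`, so a folding-based scan can replace the
local enumeration without touching the classification layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .errors import InputError
from .model import (
    CATEGORY_NAMES,
    LRE_CLOSING_PAIRS,
    UTR_KINDS,
    ScoringModel,
    categorize,
)

_RNA_ALPHABET = frozenset("ACGU")


@dataclass(frozen=True)
class RnaSequence:
    """A single UTR sequence over the RNA alphabet A/C/G/U.

    Use :meth:`from_raw` when loading user input: it upper-cases,
    transliterates T to U and validates the alphabet, reporting the
    record id and the offset of the first offending character.
    """

    id: str
    utr_kind: str
    seq: str

    def __post_init__(self) -> None:
        if self.utr_kind not in UTR_KINDS:
            raise InputError(
                f"{self.id}: utr_kind must be one of {UTR_KINDS}, got {self.utr_kind!r}"
            )
        if not self.seq:
            raise InputError(f"{self.id}: empty sequence")
        bad = next((i for i, b in enumerate(self.seq) if b not in _RNA_ALPHABET), None)
        if bad is not None:
            raise InputError(
                f"{self.id}: invalid character {self.seq[bad]!r} at offset {bad}"
            )

    @classmethod
    def from_raw(cls, id: str, utr_kind: str, raw: str) -> "RnaSequence":
        return cls(id=id, utr_kind=utr_kind, seq=raw.upper().replace("T", "U"))

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Hairpin:
    """A located tri-loop stem-loop candidate.

    ``pairs`` lists the stem base pairs from the outermost pair to the
    loop-closing pair, each as (5' base, 3' base).  The hairpin occupies
    the half-open interval ``span`` = [stem5_start, stem5_start + 2*stem_len + 3).
    """

    seq_id: str
    stem5_start: int
    stem_len: int
    loop_start: int
    loop: str
    pairs: Tuple[Tuple[str, str], ...]

    def __post_init__(self) -> None:
        if self.loop_start != self.stem5_start + self.stem_len:
            raise ValueError("loop_start must equal stem5_start + stem_len")
        if len(self.loop) != 3:
            raise ValueError("tri-loop hairpins have a 3-nt loop")
        if len(self.pairs) != self.stem_len:
            raise ValueError("pairs must have one entry per stem position")

    @property
    def span(self) -> Tuple[int, int]:
        return (self.stem5_start, self.stem5_start + 2 * self.stem_len + 3)

    @property
    def closing_pair(self) -> Tuple[str, str]:
        return self.pairs[-1]


@dataclass(frozen=True)
class LreSite:
    """A hairpin passing the LRE structural constraints, scored and categorised."""

    hairpin: Hairpin
    score: float
    category: str

    @property
    def span(self) -> Tuple[int, int]:
        return self.hairpin.span


def enumerate_triloop_hairpins(
    seq: RnaSequence, model: ScoringModel
) -> List[Hairpin]:
    """Enumerate maximal-stem tri-loop hairpins in ``seq``.

    For every loop position, the stem is extended outwards from the
    loop-closing pair as long as each pair satisfies the pairing policy
    (canonical pairs always; wobble pairs only if allowed and never at
    the closing position), capped at ``model.max_stem``.  A hairpin is
    reported iff the maximal stem reaches ``model.min_stem``, so each
    loop position yields at most one hairpin.  Output is sorted by
    ``stem5_start``.  Sequences too short to host any hairpin yield an
    empty list.
    """
    s = seq.seq
    n = len(s)
    out: List[Hairpin] = []
    if n < 2 * model.min_stem + 3:
        return out
    for loop_start in range(model.min_stem, n - 2 - model.min_stem):
        k = 0
        while k < model.max_stem:
            depth = k + 1
            i = loop_start - depth
            j = loop_start + 2 + depth
            if i < 0 or j >= n:
                break
            if not model.allowed_pair(s[i], s[j], closing=(depth == 1)):
                break
            k = depth
        if k >= model.min_stem:
            pairs = tuple(
                (s[loop_start - d], s[loop_start + 2 + d]) for d in range(k, 0, -1)
            )
            out.append(
                Hairpin(
                    seq_id=seq.id,
                    stem5_start=loop_start - k,
                    stem_len=k,
                    loop_start=loop_start,
                    loop=s[loop_start : loop_start + 3],
                    pairs=pairs,
                )
            )
    out.sort(key=lambda h: h.stem5_start)
    return out


def score_lre(h: Hairpin, model: ScoringModel) -> float:
    """Additive score of a hairpin under the model's position-weight table.

    Scored positions: the three loop bases, the loop-closing pair and
    every non-closing stem pair (the stem is already capped at
    ``model.max_stem`` by the enumerator).  Unlisted positions/bases
    contribute 0, so the empty table scores everything 0.
    """
    total = 0.0
    for pos in (1, 2, 3):
        total += model.loop_weight(pos, h.loop[pos - 1])
    total += model.closing_weight(*h.pairs[-1])
    for p5, p3 in h.pairs[:-1]:
        total += model.stem_weight(p5, p3)
    return total


def classify_lre(h: Hairpin, model: ScoringModel) -> Optional[LreSite]:
    """Return an :class:`LreSite` iff ``h`` satisfies the LRE definition.

    Requirements: (a) the third loop nucleotide is a purine (A or G),
    (b) the loop-closing pair, 5'-strand base first, is U–A or C–G, and
    (c) the score reaches the lowest category threshold.
    """
    if h.loop[2] not in "AG":
        return None
    if h.closing_pair not in LRE_CLOSING_PAIRS:
        return None
    score = score_lre(h, model)
    category = categorize(score, model)
    if category is None:
        return None
    return LreSite(hairpin=h, score=score, category=category)


def resolve_overlaps(sites: Sequence[LreSite]) -> List[LreSite]:
    """Greedy overlap resolution: highest score first, ties by leftmost start.

    A site is kept iff its span does not overlap any already-accepted
    site.  The result is returned sorted by start coordinate.
    """
    accepted: List[LreSite] = []
    for site in sorted(sites, key=lambda x: (-x.score, x.span[0])):
        s0, s1 = site.span
        if all(s1 <= a.span[0] or s0 >= a.span[1] for a in accepted):
            accepted.append(site)
    accepted.sort(key=lambda x: x.span[0])
    return accepted


def scan_sequence(seq: RnaSequence, model: ScoringModel) -> List[LreSite]:
    """Enumerate, classify and overlap-resolve LRE sites on one UTR."""
    hairpins = enumerate_triloop_hairpins(seq, model)
    sites = [s for h in hairpins if (s := classify_lre(h, model)) is not None]
    return resolve_overlaps(sites)


@dataclass
class TranscriptLreProfile:
    """Per-mRNA census of retained LRE sites, partitioned by UTR kind."""

    transcript_id: str
    sites_by_utr: Dict[str, List[LreSite]] = field(
        default_factory=lambda: {kind: [] for kind in UTR_KINDS}
    )

    @property
    def counts(self) -> Dict[str, Dict[str, int]]:
        """category x utr_kind tally of retained sites."""
        table = {
            kind: {cat: 0 for cat in CATEGORY_NAMES} for kind in UTR_KINDS
        }
        for kind, sites in self.sites_by_utr.items():
            for site in sites:
                table[kind][site.category] += 1
        return table

    def n_sites(self, utr_kind: Optional[str] = None,
                categories: Optional[Sequence[str]] = None) -> int:
        kinds = [utr_kind] if utr_kind else list(UTR_KINDS)
        cats = set(categories) if categories is not None else set(CATEGORY_NAMES)
        return sum(
            1
            for kind in kinds
            for site in self.sites_by_utr.get(kind, [])
            if site.category in cats
        )

    def all_sites(self) -> List[Tuple[str, LreSite]]:
        return [
            (kind, site)
            for kind in UTR_KINDS
            for site in self.sites_by_utr.get(kind, [])
        ]


def scan_transcript(
    utr5: Optional[RnaSequence],
    utr3: Optional[RnaSequence],
    model: ScoringModel,
) -> TranscriptLreProfile:
    """Scan a transcript's UTRs for LREs and build its site profile.

    At least one UTR must be present; when both are, they must carry the
    same transcript id.
    """
    if utr5 is None and utr3 is None:
        raise InputError("scan_transcript needs at least one UTR")
    if utr5 is not None and utr3 is not None and utr5.id != utr3.id:
        raise InputError(
            f"UTR id mismatch: 5' is {utr5.id!r} but 3' is {utr3.id!r}"
        )
    tid = utr5.id if utr5 is not None else utr3.id  # type: ignore[union-attr]
    profile = TranscriptLreProfile(transcript_id=tid)
    if utr5 is not None:
        profile.sites_by_utr["five_prime"] = scan_sequence(utr5, model)
    if utr3 is not None:
        profile.sites_by_utr["three_prime"] = scan_sequence(utr3, model)
    return profile


def hairpins_from_dotbracket(
    seq: RnaSequence, structure: str, model: ScoringModel
) -> List[Hairpin]:
    """Extract tri-loop hairpins from an externally computed structure.

    ``structure`` is a dot-bracket string of the same length as ``seq``
    (as produced by standard RNA folding engines).  Every helix stack
    that closes a loop of exactly 3 unpaired bases becomes a hairpin;
    the stem is followed outwards while pairs are nested, contiguous
    (no bulges) and allowed under the model's pairing policy, capped at
    ``model.max_stem``.  Stems shorter than ``model.min_stem`` are
    dropped.  This lets a thermodynamic-folding scan feed the same
    classification layer as the local enumeration.
    """
    s = seq.seq
    if len(structure) != len(s):
        raise InputError(
            f"{seq.id}: structure length {len(structure)} != sequence length {len(s)}"
        )
    partner = [-1] * len(s)
    stack: List[int] = []
    for idx, ch in enumerate(structure):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise InputError(f"{seq.id}: unbalanced ')' at offset {idx}")
            i = stack.pop()
            partner[i] = idx
            partner[idx] = i
        elif ch != ".":
            raise InputError(f"{seq.id}: invalid structure character {ch!r} at {idx}")
    if stack:
        raise InputError(f"{seq.id}: unbalanced '(' at offset {stack[-1]}")

    out: List[Hairpin] = []
    for i, j in enumerate(partner):
        # loop-closing pair with exactly 3 unpaired bases inside
        if j != i + 4:
            continue
        if any(partner[q] != -1 for q in range(i + 1, j)):
            continue
        if not model.allowed_pair(s[i], s[j], closing=True):
            continue
        k = 1
        while k < model.max_stem:
            a, b = i - k, j + k
            if a < 0 or b >= len(s) or partner[a] != b:
                break
            if not model.allowed_pair(s[a], s[b], closing=False):
                break
            k += 1
        if k >= model.min_stem:
            loop_start = i + 1
            pairs = tuple(
                (s[loop_start - d], s[loop_start + 2 + d]) for d in range(k, 0, -1)
            )
            out.append(
                Hairpin(
                    seq_id=seq.id,
                    stem5_start=loop_start - k,
                    stem_len=k,
                    loop_start=loop_start,
                    loop=s[loop_start : loop_start + 3],
                    pairs=pairs,
                )
            )
    out.sort(key=lambda h: h.stem5_start)
    return out
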