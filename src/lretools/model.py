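"""Scoring model for LIN-41 Response Elements (LREs).

An LRE is a tri-loop RNA hairpin — a stem closed by a 3-nucleotide loop —
in which the third loop nucleotide is a purine (A or G) and the
loop-closing stem pair, read with the 5'-strand base first, is U–A or C–G.
The binding strength of LIN-41 for such a hairpin depends on the identity
of the bases at specific positions of the stem–loop.  The
:class:`ScoringModel` bundles everything that definition needs:

* the pairing policy (canonical Watson–Crick pairs always; G–U wobble
  optionally, but never at the loop-closing position),
* stem-length limits for the hairpin enumeration,
* a per-position additive weight table mapping structural positions to
  score contributions,
* the four category thresholds (minimal, weak, medium, strong) with
  twofold spacing: 0.225, 0.45, 0.9, 1.8 — lower bounds inclusive,
* per-UTR weights used when per-site scores are aggregated into a
  per-mRNA predicted binding score.

The exact position weights used by the original LIN-41 binding model are
not publicly available, so the table shipped here (``DEFAULT_POSITION_WEIGHTS``)
is a documented stand-in: it rewards the structural determinants the LRE
definition names (purine identity at loop position 3, closing-pair
identity, stem stability) and is calibrated so that a bare, minimally
valid LRE reaches the "minimal" category and a fully optimal LRE reaches
"strong".  Any user-supplied table can be loaded through the YAML config
(see :mod:`lretools.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Tuple

from .errors import ConfigurationError

#: The two UTR compartments a site can live in.
UTR_KINDS: Tuple[str, str] = ("five_prime", "three_prime")

#: Ascending category names matching the four thresholds.
CATEGORY_NAMES: Tuple[str, str, str, str] = ("minimal", "weak", "medium", "strong")

#: Printed category thresholds; each is exactly twice the previous.
DEFAULT_THRESHOLDS: Tuple[float, float, float, float] = (0.225, 0.45, 0.9, 1.8)

CANONICAL_PAIRS = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")})
WOBBLE_PAIRS = frozenset({("G", "U"), ("U", "G")})

#: Loop-closing pairs compatible with the LRE definition (5' base first).
LRE_CLOSING_PAIRS = frozenset({("U", "A"), ("C", "G")})

#: Stand-in per-position weight table.  Keys are "<position>:<base(s)>":
#: ``loopN:<base>`` for the three loop positions (1-based), ``closing:<p5><p3>``
#: for the loop-closing stem pair and ``stem:<p5><p3>`` for every non-closing
#: stem pair.  Positions/bases absent from the table contribute 0.
DEFAULT_POSITION_WEIGHTS: Mapping[str, float] = {
    "loop1:U": 0.10,
    "loop2:A": 0.05,
    "loop3:A": 0.10,
    "loop3:G": 0.15,
    "closing:UA": 0.125,
    "closing:CG": 0.15,
    "stem:GC": 0.30,
    "stem:CG": 0.30,
    "stem:AU": 0.12,
    "stem:UA": 0.12,
}


@dataclass(frozen=True)
class ScoringModel:
    """Structural constraints, weight table and thresholds for LRE scoring.

    Parameters
    ----------
    min_stem, max_stem
        Inclusive bounds on the stem length (in base pairs) of enumerated
        hairpins.  Defaults 3 and 8.
    allow_wobble
        Whether G–U / U–G pairs are accepted in non-closing stem positions.
        The loop-closing pair must always be canonical.
    position_weights
        Additive score contributions, keyed as documented for
        ``DEFAULT_POSITION_WEIGHTS``.
    thresholds
        Strictly ascending 4-vector of category lower bounds
        (minimal, weak, medium, strong); lower bounds are inclusive.
    utr_weights
        Multipliers applied to per-site scores when aggregating a
        per-mRNA binding score, keyed by UTR kind.
    """

    min_stem: int = 3
    max_stem: int = 8
    allow_wobble: bool = True
    position_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_POSITION_WEIGHTS)
    )
    thresholds: Tuple[float, float, float, float] = DEFAULT_THRESHOLDS
    category_names: Tuple[str, str, str, str] = CATEGORY_NAMES
    utr_weights: Mapping[str, float] = field(
        default_factory=lambda: {"five_prime": 1.0, "three_prime": 1.0}
    )

    def __post_init__(self) -> None:
        if self.min_stem < 2:
            raise ConfigurationError("min_stem must be >= 2")
        if self.max_stem < self.min_stem:
            raise ConfigurationError("max_stem must be >= min_stem")
        if len(self.thresholds) != 4:
            raise ConfigurationError("thresholds must have exactly 4 entries")
        if not all(a < b for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ConfigurationError("thresholds must be strictly ascending")
        if len(self.category_names) != 4:
            raise ConfigurationError("category_names must have exactly 4 entries")
        for kind in UTR_KINDS:
            if self.utr_weights.get(kind, 0.0) <= 0:
                raise ConfigurationError(f"utr_weights[{kind!r}] must be > 0")

    # -- pairing policy ---------------------------------------------------
    def allowed_pair(self, p5: str, p3: str, *, closing: bool = False) -> bool:
        """True if (p5, p3) may pair at this stem position."""
        pair = (p5, p3)
        if pair in CANONICAL_PAIRS:
            return True
        if pair in WOBBLE_PAIRS:
            return self.allow_wobble and not closing
        return False

    def allowed_pairs(self, *, closing: bool = False) -> Tuple[Tuple[str, str], ...]:
        pairs = sorted(CANONICAL_PAIRS)
        if self.allow_wobble and not closing:
            pairs += sorted(WOBBLE_PAIRS)
        return tuple(pairs)

    # -- weight lookup ----------------------------------------------------
    def weight(self, key: str) -> float:
        return float(self.position_weights.get(key, 0.0))

    def loop_weight(self, position: int, base: str) -> float:
        """Weight of ``base`` at 1-based loop position 1..3."""
        return self.weight(f"loop{position}:{base}")

    def closing_weight(self, p5: str, p3: str) -> float:
        return self.weight(f"closing:{p5}{p3}")

    def stem_weight(self, p5: str, p3: str) -> float:
        return self.weight(f"stem:{p5}{p3}")

    # -- calibration bounds ----------------------------------------------
    def max_site_score(self) -> float:
        """Score of the ideal LRE: the table-maximal base at every scored position."""
        total = 0.0
        for pos in (1, 2, 3):
            total += max(
                (self.loop_weight(pos, b) for b in "ACGU"), default=0.0
            )
        total += max(self.closing_weight(*p) for p in sorted(LRE_CLOSING_PAIRS))
        best_stem = max(
            (self.stem_weight(*p) for p in self.allowed_pairs()), default=0.0
        )
        total += best_stem * (self.max_stem - 1)
        return total

    def min_valid_site_score(self) -> float:
        """Lowest score a structurally valid LRE can attain under this model."""
        total = min(self.loop_weight(3, b) for b in "AG")
        total += min(self.closing_weight(*p) for p in sorted(LRE_CLOSING_PAIRS))
        worst_stem = min(self.stem_weight(*p) for p in self.allowed_pairs())
        # loop1/loop2 can always pick an unscored-or-minimal base
        total += min(self.loop_weight(1, b) for b in "ACGU")
        total += min(self.loop_weight(2, b) for b in "ACGU")
        total += min(0.0, worst_stem) * (self.max_stem - 1)
        return total

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "min_stem": self.min_stem,
            "max_stem": self.max_stem,
            "allow_wobble": self.allow_wobble,
            "position_weights": dict(self.position_weights),
            "thresholds": list(self.thresholds),
            "category_names": list(self.category_names),
            "utr_weights": dict(self.utr_weights),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "ScoringModel":
        kwargs = dict(data)
        if "thresholds" in kwargs:
            kwargs["thresholds"] = tuple(kwargs["thresholds"])
        if "category_names" in kwargs:
            kwargs["category_names"] = tuple(kwargs["category_names"])
        unknown = set(kwargs) - {
            "min_stem", "max_stem", "allow_wobble", "position_weights",
            "thresholds", "category_names", "utr_weights",
        }
        if unknown:
            raise ConfigurationError(f"unknown ScoringModel fields: {sorted(unknown)}")
        return cls(**kwargs)


def categorize(score: float, model: ScoringModel) -> Optional[str]:
    """Map a non-negative score to its LRE category, or None below 'minimal'.

    Lower bounds are inclusive: with the default thresholds a score of
    exactly 0.225 is ``minimal``, 0.9 is ``medium`` and 1.8 is ``strong``.
    """
    if score < 0:
        raise ValueError(f"score must be non-negative, got {score}")
    category = None
    for name, lower in zip(model.category_names, model.thresholds):
        if score >= lower:
            category = name
        else:
            break
    return category


# The shipped defaults must span all four categories: a minimally valid
# LRE lands in "minimal" and the ideal LRE in "strong".
_default = ScoringModel()
assert _default.min_valid_site_score() >= _default.thresholds[0]
assert _default.max_site_score() >= _default.thresholds[3]
del _default
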