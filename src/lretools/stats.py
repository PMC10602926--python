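"""Validation statistics: qPCR quantification, ratio tests, set overlap.

Implements the numeric layer used to validate predicted LRE targets:

* ``ddcq_fold_change`` — relative qPCR quantification by the 2^(-ddCq)
  method with an unpaired t-test on per-replicate dCq values (Welch's
  variant by default);
* ``standard_curve_quantify`` — absolute-relative quantification through
  a log10 dilution standard curve, with amplification efficiency;
* ``condition_ratio`` — mutant/wild-type expression ratios compared to 1;
* ``hypergeometric_overlap`` — upper-tail hypergeometric test for
  gene-set overlap, computed in log-gamma space so p-values on the
  1e-33 scale survive transcriptome-sized universes;
* ``rank_sum_test`` — unpaired two-sample Wilcoxon rank-sum with an
  exact enumeration path for small samples and a tie-corrected normal
  approximation otherwise;
* ``fluorescence_ratio`` — per-animal oocyte/distal-gonad intensity
  normalisation with a rank-sum group comparison, optionally excluding
  the ovulating (-1) oocyte.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln, logsumexp

from .errors import InputError
from .pipeline import GeneSet

# ---------------------------------------------------------------------------
# qPCR: 2^-ddCq relative quantification
# ---------------------------------------------------------------------------


@dataclass
class FoldChangeResult:
    """2^(-ddCq) fold change of target vs reference between two conditions."""

    fold_change: float
    ddcq: float
    dcq_control: np.ndarray
    dcq_test: np.ndarray
    replicate_fold_changes: np.ndarray
    t_statistic: float
    p_value: float
    equal_var: bool


_CQ_COLUMNS = ("gene", "condition", "replicate", "cq")


def _dcq_by_replicate(
    cq: pd.DataFrame, target_gene: str, ref_gene: str, condition: str
) -> np.ndarray:
    sub = cq[cq["condition"] == condition]
    tgt = sub[sub["gene"] == target_gene].set_index("replicate")["cq"]
    ref = sub[sub["gene"] == ref_gene].set_index("replicate")["cq"]
    if ref.empty:
        raise InputError(
            f"no reference-gene ({ref_gene!r}) wells for condition {condition!r}"
        )
    if tgt.empty:
        raise InputError(
            f"no target-gene ({target_gene!r}) wells for condition {condition!r}"
        )
    common = tgt.index.intersection(ref.index)
    if len(common) < 2:
        raise InputError(
            f"need >= 2 matched replicates for condition {condition!r}, "
            f"got {len(common)}"
        )
    return (tgt.loc[common] - ref.loc[common]).to_numpy(dtype=float)


def ddcq_fold_change(
    cq: pd.DataFrame,
    target_gene: str,
    ref_gene: str,
    control_cond: str,
    test_cond: str,
    priming: Optional[str] = None,
    equal_var: bool = False,
) -> FoldChangeResult:
    """Relative fold change of ``target_gene`` in ``test_cond`` vs ``control_cond``.

    Per replicate, dCq = Cq(target) - Cq(reference); ddCq is the
    difference of condition means of dCq (test minus control) and the
    fold change is 2^(-ddCq).  Significance comes from an unpaired
    t-test on the per-replicate dCq values, Welch's by default
    (``equal_var=True`` selects the pooled-variance variant).

    ``cq`` must carry columns gene, condition, replicate, cq and may
    carry a ``priming`` column ("total" for random-hexamer priming,
    "polyA" for oligo-dT); pass ``priming`` to restrict to one.
    """
    missing = [c for c in _CQ_COLUMNS if c not in cq.columns]
    if missing:
        raise InputError(f"Cq table lacks columns: {missing}")
    if priming is not None:
        if "priming" not in cq.columns:
            raise InputError("Cq table has no 'priming' column")
        cq = cq[cq["priming"] == priming]
    dup = cq.duplicated(
        subset=[c for c in ("gene", "condition", "replicate", "priming") if c in cq.columns]
    )
    if dup.any():
        raise InputError("duplicate (gene, condition, replicate) wells in Cq table")

    dcq_control = _dcq_by_replicate(cq, target_gene, ref_gene, control_cond)
    dcq_test = _dcq_by_replicate(cq, target_gene, ref_gene, test_cond)
    ddcq = float(dcq_test.mean() - dcq_control.mean())
    fold = 2.0 ** (-ddcq)
    rep_folds = 2.0 ** (-(dcq_test - dcq_control.mean()))
    if np.allclose(dcq_control, dcq_control[0]) and np.allclose(
        dcq_test, dcq_test[0]
    ):
        # zero within-condition variance: t is 0 or +/- infinite
        if np.isclose(dcq_control[0], dcq_test[0]):
            t_stat, p = 0.0, 1.0
        else:
            t_stat = math.copysign(math.inf, dcq_test[0] - dcq_control[0])
            p = 0.0
    else:
        t_res = sps.ttest_ind(dcq_test, dcq_control, equal_var=equal_var)
        t_stat, p = float(t_res.statistic), float(t_res.pvalue)
    return FoldChangeResult(
        fold_change=fold,
        ddcq=ddcq,
        dcq_control=dcq_control,
        dcq_test=dcq_test,
        replicate_fold_changes=rep_folds,
        t_statistic=t_stat,
        p_value=p,
        equal_var=equal_var,
    )


# ---------------------------------------------------------------------------
# Standard-curve quantification
# ---------------------------------------------------------------------------


@dataclass
class StandardCurve:
    """Least-squares fit of Cq against log10 relative concentration."""

    points: List[Tuple[float, float]]  # (log10 concentration, cq)
    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Amplification efficiency, 1.0 meaning perfect doubling per cycle."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


_SLOPE_FLOOR = 1e-9


def fit_standard_curve(points: Sequence[Tuple[float, float]]) -> StandardCurve:
    """Fit a dilution series of (log10 relative concentration, Cq) points."""
    if len(points) < 3:
        raise InputError(f"standard curve needs >= 3 points, got {len(points)}")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    res = sps.linregress(x, y)
    if abs(res.slope) < _SLOPE_FLOOR:
        raise InputError("degenerate standard curve: slope is numerically zero")
    return StandardCurve(
        points=[(float(a), float(b)) for a, b in points],
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
    )


def standard_curve_quantify(
    curve: StandardCurve | Sequence[Tuple[float, float]], sample_cq: float
) -> float:
    """Relative abundance of a sample from its Cq via the standard curve.

    Inverts cq = intercept + slope * log10(conc):
    returns 10^((sample_cq - intercept) / slope).
    """
    if not isinstance(curve, StandardCurve):
        curve = fit_standard_curve(curve)
    return 10.0 ** ((sample_cq - curve.intercept) / curve.slope)


# ---------------------------------------------------------------------------
# Condition ratios (e.g. mutant / wild-type expression, compared to 1)
# ---------------------------------------------------------------------------


@dataclass
class RatioResult:
    ratio: float
    sd: float
    replicate_ratios: np.ndarray
    t_statistic: float
    p_value: float


def condition_ratio(
    values_a: Sequence[float], values_b: Sequence[float]
) -> RatioResult:
    """Ratio of group means (a over b) tested against 1.

    ``values_a`` are the test-condition replicates (e.g. mutant),
    ``values_b`` the baseline (e.g. wild type).  The standard deviation
    of the ratio follows first-order error propagation; per-replicate
    ratios a_i / mean(b) are compared against 1 with a t-test, matching
    the convention of plotting mutant/wild-type ratios against a line
    at 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InputError("need >= 2 replicates per condition")
    if np.any(b <= 0) or b.mean() <= 0:
        raise InputError("baseline values must be strictly positive")
    ratio = float(a.mean() / b.mean())
    rel_var = (a.std(ddof=1) / a.mean()) ** 2 + (b.std(ddof=1) / b.mean()) ** 2 \
        if a.mean() != 0 else float("nan")
    sd = float(abs(ratio) * math.sqrt(rel_var)) if np.isfinite(rel_var) else float("nan")
    rep = a / b.mean()
    if np.allclose(rep, 1.0):
        t_stat, p = 0.0, 1.0
    elif np.allclose(rep, rep[0]):
        t_stat, p = math.inf if rep[0] > 1 else -math.inf, 0.0
    else:
        res = sps.ttest_1samp(rep, 1.0)
        t_stat, p = float(res.statistic), float(res.pvalue)
    return RatioResult(
        ratio=ratio, sd=sd, replicate_ratios=rep, t_statistic=t_stat, p_value=p
    )


# ---------------------------------------------------------------------------
# Hypergeometric gene-set overlap
# ---------------------------------------------------------------------------


@dataclass
class OverlapResult:
    universe_size: int
    set_a_size: int
    set_b_size: int
    overlap: int
    p_upper: float
    fold_enrichment: float


def _log_hypergeom_pmf(k: int, N: int, K: int, n: int) -> float:
    return (
        gammaln(K + 1) - gammaln(k + 1) - gammaln(K - k + 1)
        + gammaln(N - K + 1) - gammaln(n - k + 1) - gammaln(N - K - (n - k) + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )


def hypergeometric_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), summed in log space."""
    if k <= max(0, K + n - N):
        return 1.0
    hi = min(K, n)
    if k > hi:
        return 0.0
    logs = [_log_hypergeom_pmf(j, N, K, n) for j in range(k, hi + 1)]
    return float(min(1.0, math.exp(logsumexp(logs))))


def hypergeometric_overlap(
    set_a: GeneSet, set_b: GeneSet, universe: GeneSet
) -> OverlapResult:
    """Upper-tail hypergeometric test for the overlap of two gene sets.

    Both sets must be subsets of the universe; the p-value is
    P(X >= observed overlap) where X counts the overlap of a random
    draw of |set_b| genes against the |set_a| marked genes, and the
    fold enrichment is observed over expected overlap.
    """
    for s in (set_a, set_b):
        stray = s.members - universe.members
        if stray:
            raise InputError(
                f"{s.name}: {len(stray)} ids outside the universe, "
                f"e.g. {sorted(stray)[:5]}"
            )
    N, K, n = len(universe), len(set_a), len(set_b)
    k = len(set_a.members & set_b.members)
    p = hypergeometric_upper_tail(k, N, K, n)
    expected = K * n / N if N else float("nan")
    fold = k / expected if expected else float("inf") if k else float("nan")
    return OverlapResult(
        universe_size=N,
        set_a_size=K,
        set_b_size=n,
        overlap=k,
        p_upper=p,
        fold_enrichment=fold,
    )


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum (Mann-Whitney) test
# ---------------------------------------------------------------------------


@dataclass
class RankSumResult:
    statistic: float  # rank sum W of the first sample
    p_value: float
    method: str  # "exact" or "normal"


#: Exact enumeration is used while the number of rank splits stays small.
EXACT_ENUMERATION_LIMIT = 20_000


def rank_sum_test(
    x: Sequence[float], y: Sequence[float]
) -> RankSumResult:
    """Unpaired two-sample Wilcoxon rank-sum test, two-sided.

    The statistic is the rank sum W of ``x`` over the pooled midranks.
    When C(n+m, n) <= 20 000 the two-sided p-value is exact: every
    assignment of ranks to the first sample is enumerated and splits at
    least as extreme as observed (|W - E[W]| >= |observed - E[W]|) are
    counted.  Larger samples use the tie-corrected normal approximation
    with continuity correction; the ``method`` field reports which path
    was taken.  If every pooled value is tied the test is uninformative
    and p = 1 is returned with a warning.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise InputError("both samples must be non-empty")
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w = float(ranks[:n].sum())
    mu = n * (n + m + 1) / 2.0

    if np.all(pooled == pooled[0]):
        warnings.warn("all values tied across both samples; rank-sum p = 1")
        return RankSumResult(statistic=w, p_value=1.0, method="degenerate")

    if math.comb(n + m, n) <= EXACT_ENUMERATION_LIMIT:
        obs_dev = abs(w - mu) - 1e-12
        total = 0
        extreme = 0
        for idx in itertools.combinations(range(n + m), n):
            total += 1
            w_perm = ranks[list(idx)].sum()
            if abs(w_perm - mu) >= obs_dev:
                extreme += 1
        return RankSumResult(statistic=w, p_value=extreme / total, method="exact")

    # tie-corrected normal approximation with continuity correction
    N = n + m
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (N * (N - 1))
    sigma2 = n * m / 12.0 * ((N + 1) - tie_term)
    dev = abs(w - mu)
    z = max(0.0, dev - 0.5) / math.sqrt(sigma2)
    p = 2.0 * sps.norm.sf(z)
    return RankSumResult(statistic=w, p_value=min(1.0, p), method="normal")


# ---------------------------------------------------------------------------
# Reporter-fluorescence ratios (oocyte / distal gonad)
# ---------------------------------------------------------------------------

#: One animal's measurements: oocyte intensities ordered distal-to-proximal
#: (the last entry being the ovulating -1 oocyte) and distal-gonad intensities.
Animal = Tuple[Sequence[float], Sequence[float]]


@dataclass
class FluorescenceResult:
    ratios_a: np.ndarray
    ratios_b: np.ndarray
    rank_sum: RankSumResult


def animal_ratio(
    oocyte_values: Sequence[float],
    distal_values: Sequence[float],
    exclude_last: bool = True,
) -> float:
    """Mean oocyte intensity over mean distal-gonad intensity for one animal.

    With ``exclude_last`` the final oocyte entry — the ovulating (-1)
    oocyte, where the repressor is being degraded — is dropped before
    averaging.
    """
    ooc = np.asarray(list(oocyte_values), dtype=float)
    dist = np.asarray(list(distal_values), dtype=float)
    if len(ooc) == 0 or len(dist) == 0:
        raise InputError("each animal needs >= 1 oocyte and >= 1 distal value")
    if exclude_last:
        if len(ooc) < 2:
            raise InputError(
                "cannot exclude the -1 oocyte: only one oocyte value present"
            )
        ooc = ooc[:-1]
    denom = dist.mean()
    if denom <= 0:
        raise InputError("distal-gonad mean intensity must be > 0")
    return float(ooc.mean() / denom)


def fluorescence_ratio(
    group_a: Sequence[Animal],
    group_b: Sequence[Animal],
    exclude_last: bool = True,
) -> FluorescenceResult:
    """Normalised per-animal reporter ratios for two strains, compared.

    Each group is a sequence of (oocyte intensities, distal intensities)
    per animal; per-animal ratios are oocyte mean over distal mean
    (see :func:`animal_ratio`), and the two groups of ratios are compared
    with the unpaired two-sample Wilcoxon rank-sum test.
    """
    ra = np.asarray([animal_ratio(o, d, exclude_last) for o, d in group_a])
    rb = np.asarray([animal_ratio(o, d, exclude_last) for o, d in group_b])
    return FluorescenceResult(
        ratios_a=ra, ratios_b=rb, rank_sum=rank_sum_test(ra, rb)
    )
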