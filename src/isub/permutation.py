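"""Permutation inference with per-labelling re-derivation and minP correction.

Empirical significance of any case-vs-control comparison is obtained by
permuting phenotype labels (preserving group sizes, optionally within
strata) and, for EACH permuted labelling, re-deriving the set-unique
partition and every individual score before computing the test
statistic.  Freezing the observed partition would leak the observed
labelling into the null and break calibration, so every statistic
factory here closes over a :class:`~isub._design.CohortDesign` and
recomputes from the labels alone.

Family-wise correction uses the permutation minP method: each test's
empirical p-value is compared against the permutation distribution of
the minimum per-permutation p-value across the family, which controls
the family-wise error rate without independence assumptions.
"""

from __future__ import annotations

import itertools
import uuid
from dataclasses import dataclass, field
from math import comb
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from ._design import CohortDesign
from .cohort_io import CohortGenotypes

SIDEDNESS = ("greater_in_cases", "two_sided")


@dataclass
class PermutationConfig:
    """Settings for a permutation run.

    B is the number of sampled permutations (the analysis default is
    10,000); a seed is mandatory for any sampled run.  With
    ``exhaustive=True`` all distinct labellings are enumerated instead
    (only feasible for tiny cohorts) and B is ignored.
    """

    B: int = 10_000
    seed: int | None = None
    sided: str = "greater_in_cases"
    exhaustive: bool = False
    max_exhaustive: int = 200_000

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.sided not in SIDEDNESS:
            raise ValueError(f"sided must be one of {SIDEDNESS}")
        if not self.exhaustive and self.seed is None:
            raise ValueError("seed is mandatory for sampled permutation runs")


@dataclass
class PermutationResult:
    statistic_name: str
    observed: float
    null_draws: np.ndarray
    p_empirical: float
    n_permutations: int
    sided: str
    exhaustive: bool = False
    p_minp_adjusted: float | None = None
    stream_id: str | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def wilcoxon_statistic(
    case_values: np.ndarray, control_values: np.ndarray
) -> float:
    """Rank-sum of the case values, with mid-ranks for ties."""
    case_values = np.asarray(case_values, dtype=float)
    control_values = np.asarray(control_values, dtype=float)
    if case_values.size == 0 or control_values.size == 0:
        raise ValueError("both groups must be non-empty")
    ranks = stats.rankdata(np.concatenate([case_values, control_values]))
    return float(ranks[: case_values.size].sum())


def ranksum(values: np.ndarray, is_case: np.ndarray, standardized: bool = False
            ) -> float:
    """Case rank-sum of a combined vector; optionally normal-standardized.

    Standardization ((W - E[W]) / sd[W], without tie correction) makes the
    statistic comparable across labellings whose effective group sizes
    differ, e.g. when zero-variant individuals are excluded per labelling.
    """
    n = values.size
    n1 = int(is_case.sum())
    n2 = n - n1
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    w = float(stats.rankdata(values)[is_case].sum())
    if not standardized:
        return w
    mu = n1 * (n + 1) / 2.0
    sd = np.sqrt(n1 * n2 * (n + 1) / 12.0)
    return (w - mu) / sd if sd > 0 else 0.0


# ---------------------------------------------------------------------------
# label permutation
# ---------------------------------------------------------------------------


def _as_is_case(phenotype) -> np.ndarray:
    arr = np.asarray(phenotype)
    return arr if arr.dtype == bool else arr == "case"


def _permuted_labels(rng, is_case: np.ndarray, strata: np.ndarray | None
                     ) -> np.ndarray:
    if strata is None:
        return rng.permutation(is_case)
    out = is_case.copy()
    for s in np.unique(strata):
        idx = np.where(strata == s)[0]
        out[idx] = rng.permutation(is_case[idx])
    return out


def _tail_p(null: np.ndarray, observed: float, sided: str, plus_one: bool
            ) -> float:
    n = null.size
    add = 1 if plus_one else 0
    denom = n + add
    ge = (int(np.sum(null >= observed)) + add) / denom
    if sided == "greater_in_cases":
        return ge
    le = (int(np.sum(null <= observed)) + add) / denom
    return min(1.0, 2.0 * min(ge, le))


# ---------------------------------------------------------------------------
# core driver
# ---------------------------------------------------------------------------


def permute_family(
    phenotype,
    statistic_fn: Callable[[np.ndarray], np.ndarray],
    names: Sequence[str],
    config: PermutationConfig,
    strata: np.ndarray | None = None,
) -> list[PermutationResult]:
    """Run one shared permutation stream for a family of statistics.

    ``statistic_fn(is_case)`` must return one value per name.  All
    returned results share a stream id and are eligible for
    :func:`minp_adjust`.  With ``config.exhaustive`` the null enumerates
    every distinct assignment of the case labels (the observed labelling
    included), giving exact p-values ``#{stat >= observed} / N``.
    """
    is_case = _as_is_case(phenotype)
    n = is_case.size
    n_case = int(is_case.sum())
    if n_case == 0 or n_case == n:
        raise ValueError("labelling must contain at least one case and one control")
    observed = np.atleast_1d(np.asarray(statistic_fn(is_case), dtype=float))
    if observed.size != len(names):
        raise ValueError("statistic_fn returned wrong number of values")

    if config.exhaustive:
        if strata is not None:
            raise ValueError("exhaustive enumeration does not support strata")
        n_lab = comb(n, n_case)
        if n_lab > config.max_exhaustive:
            raise ValueError(
                f"{n_lab} labellings exceed max_exhaustive={config.max_exhaustive}"
            )
        null = np.empty((n_lab, observed.size))
        for b, case_idx in enumerate(itertools.combinations(range(n), n_case)):
            lab = np.zeros(n, dtype=bool)
            lab[list(case_idx)] = True
            null[b] = np.atleast_1d(statistic_fn(lab))
    else:
        rng = np.random.default_rng(config.seed)
        null = np.empty((config.B, observed.size))
        for b in range(config.B):
            lab = _permuted_labels(rng, is_case, strata)
            null[b] = np.atleast_1d(statistic_fn(lab))

    stream = uuid.uuid4().hex
    plus_one = not config.exhaustive
    results = []
    for t, name in enumerate(names):
        p = _tail_p(null[:, t], observed[t], config.sided, plus_one)
        results.append(
            PermutationResult(
                statistic_name=name,
                observed=float(observed[t]),
                null_draws=null[:, t].copy(),
                p_empirical=p,
                n_permutations=null.shape[0],
                sided=config.sided,
                exhaustive=config.exhaustive,
                stream_id=stream,
            )
        )
    return results


def permute_pvalue(
    phenotype,
    statistic_fn: Callable[[np.ndarray], float],
    config: PermutationConfig,
    strata: np.ndarray | None = None,
    name: str = "statistic",
) -> PermutationResult:
    """Empirical p-value for a single labelling statistic.

    ``statistic_fn(is_case) -> float`` must internally re-derive anything
    that depends on the labelling (set-unique sets, individual scores).
    For ``greater_in_cases`` the sampled p-value is
    ``(1 + #{null >= observed}) / (B + 1)`` (never zero); two-sided
    doubles the smaller tail, capped at 1.
    """
    return permute_family(phenotype, statistic_fn, [name], config, strata)[0]


# ---------------------------------------------------------------------------
# minP family-wise correction
# ---------------------------------------------------------------------------


def minp_adjust(results: Sequence[PermutationResult]) -> list[PermutationResult]:
    """Westfall-Young minP adjustment over a family of permutation results.

    For every permutation draw b, each test's draw is converted to its
    own empirical p-value within that test's null distribution; the
    family minimum over tests gives the per-draw minP.  A test's adjusted
    p-value is the proportion of draws whose minP is at or below the
    test's empirical p (with the same smoothing convention), floored at
    the raw p so that adjusted >= raw always holds.

    All results must come from one shared permutation stream.
    """
    if not results:
        raise ValueError("empty family")
    streams = {r.stream_id for r in results}
    if None in streams or len(streams) != 1:
        raise ValueError("mismatched permutation streams: minP requires all "
                         "tests to share one stream (use permute_family)")
    nperm = {r.n_permutations for r in results}
    if len(nperm) != 1:
        raise ValueError("results disagree on the number of permutations")
    B = nperm.pop()
    plus_one = not results[0].exhaustive
    add = 1 if plus_one else 0
    denom = B + add

    per_draw_p = np.empty((len(results), B))
    for t, r in enumerate(results):
        null = r.null_draws
        order = np.sort(null)
        # #{b': null_b' >= x} = B - searchsorted_left(x)
        ge = B - np.searchsorted(order, null, side="left")
        if r.sided == "greater_in_cases":
            per_draw_p[t] = (ge + add) / denom
        else:
            le = np.searchsorted(order, null, side="right")
            per_draw_p[t] = np.minimum(
                1.0, 2.0 * np.minimum((ge + add) / denom, (le + add) / denom)
            )
    min_p = per_draw_p.min(axis=0)

    adjusted = []
    for r in results:
        adj = (int(np.sum(min_p <= r.p_empirical)) + add) / denom
        adj = max(adj, r.p_empirical)
        adjusted.append(
            PermutationResult(
                statistic_name=r.statistic_name,
                observed=r.observed,
                null_draws=r.null_draws,
                p_empirical=r.p_empirical,
                n_permutations=r.n_permutations,
                sided=r.sided,
                exhaustive=r.exhaustive,
                p_minp_adjusted=min(1.0, adj),
                stream_id=r.stream_id,
            )
        )
    return adjusted


# ---------------------------------------------------------------------------
# statistic factories (each re-derives the partition per labelling)
# ---------------------------------------------------------------------------


def isub_statistic(
    genotypes: CohortGenotypes,
    scored,
    category: str = "DEL",
    dosage_weighted: bool = False,
) -> Callable[[np.ndarray], float]:
    """Wilcoxon rank-sum statistic of the per-individual burden.

    The returned callable re-derives the set-unique partition and all
    individual scores from the labelling it is given.
    """
    design = CohortDesign(genotypes, scored, dosage_weighted=dosage_weighted)

    def stat(is_case: np.ndarray) -> float:
        scores, _ = design.isub_scores(is_case, category)
        return ranksum(scores, is_case)

    return stat


def isub_family_statistic(
    genotypes: CohortGenotypes,
    scored,
    categories: Sequence[str] = ("NS", "DEL", "NS_minus_DEL"),
    dosage_weighted: bool = False,
) -> Callable[[np.ndarray], np.ndarray]:
    """Joint statistic over burden categories sharing one mask derivation."""
    design = CohortDesign(genotypes, scored, dosage_weighted=dosage_weighted)

    def stat(is_case: np.ndarray) -> np.ndarray:
        cu, ku = design.unique_masks(is_case)
        out = np.empty(len(categories))
        for t, cat in enumerate(categories):
            scores, _ = design.scores_for_masks(is_case, cu, ku, cat)
            out[t] = ranksum(scores, is_case)
        return out

    return stat


def decomposition_statistic(
    genotypes: CohortGenotypes,
    scored,
    category: str = "DEL",
) -> Callable[[np.ndarray], np.ndarray]:
    """Joint (count, mean-score) comparison statistic.

    Per labelling: the count comparison is the case rank-sum of the
    per-individual number of own-side set-unique variants; the score
    comparison is the standardized case rank-sum of the mean score per
    carried variant among individuals with at least one variant
    (standardized because the carrier subset changes with the labelling).
    """
    design = CohortDesign(genotypes, scored)

    def stat(is_case: np.ndarray) -> np.ndarray:
        scores, counts = design.isub_scores(is_case, category)
        count_stat = ranksum(counts.astype(float), is_case)
        carrier = counts > 0
        if carrier.sum() == 0 or is_case[carrier].all() or not is_case[carrier].any():
            score_stat = 0.0
        else:
            mean = scores[carrier] / counts[carrier]
            score_stat = ranksum(mean, is_case[carrier], standardized=True)
        return np.array([count_stat, score_stat])

    return stat
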