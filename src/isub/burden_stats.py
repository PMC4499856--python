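"""Per-individual burden scores, their decomposition, and normalisation.

The individual set-unique burden (ISUB) of a subject is the sum of
effective deleteriousness scores over the set-unique variants of the
subject's own phenotype group that the subject carries.  Three nested
categories are scored: all in-scope variants (NS), the deleterious
subset (DEL), and the non-deleterious complement (NS_minus_DEL); per
individual the scores satisfy NS = DEL + NS_minus_DEL exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._design import CohortDesign
from .cohort_io import CohortGenotypes


def compute_isub(
    genotypes: CohortGenotypes,
    scored: pd.DataFrame,
    category: str = "DEL",
    labels: np.ndarray | None = None,
    dosage_weighted: bool = False,
) -> pd.DataFrame:
    """Per-individual burden in one category.

    Returns a DataFrame with columns ``sample_id``, ``phenotype``,
    ``isub``, ``n_variants`` and ``mean_score_per_variant`` (NaN when the
    individual carries no set-unique variants; ``isub`` is then 0).
    Each individual is scored only against their own side's set-unique
    variants; by default every carried variant contributes its score once
    regardless of zygosity.
    """
    design = CohortDesign(genotypes, scored, dosage_weighted=dosage_weighted)
    is_case = genotypes.is_case if labels is None else _as_bool(labels)
    scores, counts = design.isub_scores(is_case, category)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, scores / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "sample_id": genotypes.sample_ids,
            "phenotype": np.where(is_case, "case", "control"),
            "isub": scores,
            "n_variants": counts,
            "mean_score_per_variant": mean,
        }
    )


def compute_burden_profiles(
    genotypes: CohortGenotypes,
    scored: pd.DataFrame,
    labels: np.ndarray | None = None,
    dosage_weighted: bool = False,
) -> pd.DataFrame:
    """Full burden profile: NS, DEL and NS_minus_DEL scores per individual."""
    design = CohortDesign(genotypes, scored, dosage_weighted=dosage_weighted)
    is_case = genotypes.is_case if labels is None else _as_bool(labels)
    out = pd.DataFrame(
        {
            "sample_id": genotypes.sample_ids,
            "phenotype": np.where(is_case, "case", "control"),
        }
    )
    for cat, col in (
        ("NS", "isub_NS"),
        ("DEL", "isub_DEL"),
        ("NS_minus_DEL", "isub_NSminusDEL"),
    ):
        scores, counts = design.isub_scores(is_case, cat)
        out[col] = scores
        out[f"n_{cat}"] = counts
    return out


def _as_bool(labels) -> np.ndarray:
    labels = np.asarray(labels)
    return labels if labels.dtype == bool else labels == "case"


# ---------------------------------------------------------------------------
# quantitative / qualitative decomposition
# ---------------------------------------------------------------------------


@dataclass
class BurdenDecomposition:
    """Per-individual vectors separating 'how many' from 'how damaging'.

    ``counts`` holds the number of own-side set-unique variants carried
    per individual (all individuals); ``mean_scores`` the mean effective
    score per carried variant (individuals with zero variants excluded).
    ``degenerate_scores`` flags a constant mean-score vector, for which
    the qualitative comparison is undefined.
    """

    counts: pd.DataFrame  # sample_id, phenotype, value
    mean_scores: pd.DataFrame  # sample_id, phenotype, value (n_variants > 0 only)
    degenerate_scores: bool


def decompose_burden(profile: pd.DataFrame) -> BurdenDecomposition:
    """Split a one-category burden profile into count and score comparisons.

    The increased burden of one group may come from carrying MORE
    set-unique variants (quantitative) or from carrying variants that are
    individually MORE deleterious (qualitative).  The returned vectors
    feed the same permutation machinery as the burden itself: comparison
    (a) tests ``n_variants`` per individual, comparison (b) tests
    ``mean_score_per_variant`` among individuals carrying at least one
    variant.
    """
    counts = profile[["sample_id", "phenotype"]].copy()
    counts["value"] = profile["n_variants"].to_numpy(dtype=float)

    carriers = profile[profile["n_variants"] > 0]
    mean_scores = carriers[["sample_id", "phenotype"]].copy()
    mean_scores["value"] = carriers["mean_score_per_variant"].to_numpy(dtype=float)

    vals = mean_scores["value"].to_numpy()
    degenerate = len(vals) == 0 or bool(np.all(vals == vals[0]))
    return BurdenDecomposition(counts, mean_scores, degenerate)


# ---------------------------------------------------------------------------
# sample-size correction and inverse-normal transform
# ---------------------------------------------------------------------------


def sample_size_factors(n_cases: int, n_controls: int) -> tuple[float, float]:
    """Correction factors (case_factor, control_factor).

    An individual's set-unique burden depends on the size of the OPPOSITE
    group: a variant is own-side set-unique only if absent from every
    opposite-group member, so the group filtered against the smaller
    opposite group accumulates systematically higher scores.  Each
    group's scores are therefore multiplied by
    ``n_opposite / mean(n_cases, n_controls)``, shrinking the advantaged
    group (to first order in MAF x group size this equalises the null
    expectations).  Equal group sizes give factor 1 for both.
    """
    if n_cases < 1 or n_controls < 1:
        raise ValueError("both groups must be non-empty")
    nbar = (n_cases + n_controls) / 2.0
    return n_controls / nbar, n_cases / nbar


def normalize_isub(
    profile: pd.DataFrame,
    score_col: str = "isub",
) -> pd.DataFrame:
    """Sample-size-corrected, inverse-normal-transformed burden scores.

    Corrected scores are mapped to Blom normal quantiles
    ``z = Phi^-1((rank - 3/8) / (n + 1/4))`` with mid-ranks for ties,
    computed on the combined sample, giving a rank-preserving column
    ``isub_norm`` with mean approximately 0 for use as a regression
    covariate.  The correction factors are recorded in ``.attrs``.

    Raises
    ------
    ValueError
        If the corrected scores are constant (the transform is undefined).
    """
    out = profile.copy()
    is_case = out["phenotype"].to_numpy() == "case"
    n_cases = int(is_case.sum())
    n_controls = int((~is_case).sum())
    f_case, f_control = sample_size_factors(n_cases, n_controls)
    corrected = out[score_col].to_numpy(dtype=float) * np.where(
        is_case, f_case, f_control
    )
    if np.all(corrected == corrected[0]):
        raise ValueError("corrected burden scores are constant; "
                         "inverse normal transform undefined")
    n = len(corrected)
    ranks = stats.rankdata(corrected, method="average")
    out["isub_norm"] = stats.norm.ppf((ranks - 3.0 / 8.0) / (n + 0.25))
    out.attrs["case_factor"] = f_case
    out.attrs["control_factor"] = f_control
    return out
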