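"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's vectorised code paths:
set-unique membership by explicit double loops over (variant, group),
burden scores by per-sample loops, rank sums by sorting, and exact tail
probabilities by enumeration with binomial coefficients.
"""

from __future__ import annotations

from math import comb

import numpy as np
import pandas as pd
import pytest

from isub import SyntheticConfig, apply_condel_augmentation, generate_cohort
from isub.cohort_io import CohortGenotypes


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------


def make_cohort(dosage, phenotype, variant_ids=None, sample_ids=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    return CohortGenotypes(
        sample_ids=sample_ids or [f"s{i}" for i in range(n)],
        variant_ids=variant_ids or [f"v{j}" for j in range(m)],
        phenotype=np.asarray(phenotype, dtype=object),
        dosage=dosage,
    )


def make_annotations(rows):
    """rows: list of dicts with at least variant_id and functional_class."""
    defaults = {
        "chrom": "1", "pos": 1, "ref": "A", "alt": "G", "gene": np.nan,
        "condel_score": np.nan, "deleterious_flag": np.nan,
        "population_maf": np.nan,
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])


def scored_table(rows):
    from isub.cohort_io import validate_annotations

    return apply_condel_augmentation(validate_annotations(make_annotations(rows)))


def random_instance(rng, n_samples=8, n_variants=12, p_carrier=0.25,
                    p_missing=0.05):
    """Random small genotype matrix + scored annotations for oracle checks."""
    dosage = rng.choice(
        [0, 1, 2, -1],
        size=(n_samples, n_variants),
        p=[1 - p_carrier - p_missing, p_carrier * 0.8, p_carrier * 0.2,
           p_missing],
    ).astype(np.int8)
    n_cases = int(rng.integers(1, n_samples))
    phenotype = np.array(
        ["case"] * n_cases + ["control"] * (n_samples - n_cases), dtype=object
    )
    phenotype = rng.permutation(phenotype)
    classes = rng.choice(
        ["nonsynonymous", "splice_site", "stop_altering", "synonymous"],
        size=n_variants, p=[0.6, 0.15, 0.1, 0.15],
    )
    rows = []
    for j in range(n_variants):
        score = np.nan
        flag = np.nan
        if classes[j] == "nonsynonymous" or rng.random() < 0.3:
            score = float(np.round(rng.random(), 3))
            flag = bool(score > 0.5)
        rows.append(
            {
                "variant_id": f"v{j}",
                "gene": f"G{int(rng.integers(0, max(2, n_variants // 3)))}",
                "functional_class": classes[j],
                "condel_score": score,
                "deleterious_flag": flag,
            }
        )
    return make_cohort(dosage, phenotype), scored_table(rows)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def oracle_set_unique(genotypes, scored, is_case=None, in_scope_only=True):
    """Double-loop set-unique oracle: (case_unique, control_unique) id sets."""
    if is_case is None:
        is_case = genotypes.is_case
    sv = scored.drop_duplicates("variant_id").set_index("variant_id")
    case_u, ctrl_u = set(), set()
    for j, vid in enumerate(genotypes.variant_ids):
        if vid not in sv.index:
            continue
        if in_scope_only and not sv.at[vid, "in_scope"]:
            continue
        n_case = n_ctrl = 0
        for i in range(genotypes.n_samples):
            d = genotypes.dosage[i, j]
            if d >= 1:
                if is_case[i]:
                    n_case += 1
                else:
                    n_ctrl += 1
        if n_case > 0 and n_ctrl == 0:
            case_u.add(vid)
        elif n_ctrl > 0 and n_case == 0:
            ctrl_u.add(vid)
    return case_u, ctrl_u


def oracle_isub(genotypes, scored, is_case=None, category="DEL"):
    """Per-sample burden by explicit loops; returns (scores, counts)."""
    if is_case is None:
        is_case = genotypes.is_case
    sv = scored.drop_duplicates("variant_id").set_index("variant_id")
    case_u, ctrl_u = oracle_set_unique(genotypes, scored, is_case)
    scores = np.zeros(genotypes.n_samples)
    counts = np.zeros(genotypes.n_samples, dtype=int)
    for i in range(genotypes.n_samples):
        own = case_u if is_case[i] else ctrl_u
        for j, vid in enumerate(genotypes.variant_ids):
            if vid not in own or genotypes.dosage[i, j] < 1:
                continue
            row = sv.loc[vid]
            deleterious = bool(row["effective_deleterious"])
            if category == "DEL" and not deleterious:
                continue
            if category == "NS_minus_DEL" and deleterious:
                continue
            scores[i] += float(row["effective_score"])
            counts[i] += 1
    return scores, counts


def oracle_ranksum(case_values, control_values):
    """Case rank-sum via an explicit sort, mid-ranks for ties."""
    pooled = sorted(
        [(v, "case") for v in case_values] + [(v, "ctrl") for v in control_values]
    )
    ranks = {}
    i = 0
    while i < len(pooled):
        j = i
        while j < len(pooled) and pooled[j][0] == pooled[i][0]:
            j += 1
        mid = (i + 1 + j) / 2.0
        for k in range(i, j):
            ranks[k] = mid
        i = j
    return sum(ranks[k] for k in range(len(pooled)) if pooled[k][1] == "case")


def oracle_hypergeom_tail(k, M, K, n):
    """P(X >= k) for X ~ Hypergeom(M, K, n), by direct enumeration."""
    total = comb(M, n)
    return sum(
        comb(K, x) * comb(M - K, n - x)
        for x in range(max(k, 0), min(K, n) + 1)
        if n - x <= M - K
    ) / total


def oracle_fisher_greater(a, b, c, d):
    """One-sided Fisher p for enrichment of cell a, by enumeration."""
    # margins: row1 = a+b, col1 = a+c, N = a+b+c+d
    return oracle_hypergeom_tail(a, a + b + c + d, a + b, a + c)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def null_cohort():
    """Small null synthetic cohort shared across read-only tests."""
    cfg = SyntheticConfig(n_cases=150, n_controls=120, n_variants=2000, seed=42)
    genotypes, annotations, covariates = generate_cohort(cfg)
    return genotypes, apply_condel_augmentation(annotations), covariates


@pytest.fixture(scope="session")
def enriched_cohort():
    """Count-mode enriched cohort (deleterious carriage x1.5 in cases)."""
    cfg = SyntheticConfig(
        n_cases=250, n_controls=200, n_variants=3000, seed=7,
        enrichment=1.5, count_vs_score_mode="count",
    )
    genotypes, annotations, covariates = generate_cohort(cfg)
    return genotypes, apply_condel_augmentation(annotations), covariates
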