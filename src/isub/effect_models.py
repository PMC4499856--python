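"""Relative effect sizes of common (PRS) and rare (burden) susceptibility alleles.

Odds ratios are poorly suited to low-frequency burden scores, so effect
sizes are compared on the Nagelkerke pseudo-R^2 scale: fit the full
logistic model

    logit P(case) = b0 + sum_i b_i MDS_i + b_prs PRS + b_isub ISUB_norm

and measure each term's contribution as the drop in Nagelkerke R^2 when
that term alone is removed.  Nagelkerke R^2 rescales the Cox-Snell
likelihood-ratio R^2 to a [0, 1] range:

    R^2 = (1 - (L0 / L1)^(2/n)) / (1 - L0^(2/n))

with L0 the intercept-only likelihood.  Also here: the rank correlation
between PRS and burden scores, and the replication-style comparison of
individual minor-allele counts over a discovery variant list in an
independent cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort_io import CohortGenotypes, CovariateTable


@dataclass
class EffectSizeResult:
    model_terms: list[str]
    n_samples: int
    loglik_full: float
    loglik_null: float
    r2_nagelkerke_full: float
    delta_r2: dict[str, float]
    loglik_reduced: dict[str, float] = field(default_factory=dict)
    coefficients: dict[str, float] = field(default_factory=dict)


def nagelkerke_r2(loglik_model: float, loglik_null: float, n: int) -> float:
    """Nagelkerke pseudo-R^2 from model and intercept-only log-likelihoods."""
    cox_snell = 1.0 - np.exp(2.0 * (loglik_null - loglik_model) / n)
    max_r2 = 1.0 - np.exp(2.0 * loglik_null / n)
    return float(cox_snell / max_r2) if max_r2 > 0 else 0.0


def _fit_logit(y: np.ndarray, X: pd.DataFrame) -> sm.Logit:
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    import warnings as _warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    try:
        with _warnings.catch_warnings():
            if X.shape[1] > 1:  # intercept-only fits cannot separate
                _warnings.filterwarnings("error",
                                         category=PerfectSeparationWarning)
            res = sm.Logit(y, X).fit(disp=False, maxiter=200)
    except PerfectSeparationWarning as exc:
        raise ValueError(
            f"perfect separation in logistic fit (terms: {list(X.columns)})"
        ) from exc
    except Exception as exc:
        raise ValueError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        # near-perfect separation shows up as non-convergence with huge betas
        big = X.columns[np.abs(res.params.to_numpy()) > 50]
        raise ValueError(
            "logistic fit did not converge"
            + (f"; possible separation by {list(big)}" if len(big) else "")
        )
    return res


def fit_liability_model(
    phenotype: Sequence[str] | np.ndarray,
    covariates: CovariateTable,
    isub_norm: pd.Series,
    sample_ids: Sequence[str] | None = None,
    mds_k: int = 10,
    drop_terms: Sequence[str] = ("prs", "isub_norm"),
) -> EffectSizeResult:
    """Fit the liability logistic model and attribute Nagelkerke ΔR^2.

    Parameters
    ----------
    phenotype, sample_ids
        Case/control labels; ``sample_ids`` aligns them with the
        covariate table (defaults to ``isub_norm.index``).
    covariates
        MDS ancestry components (first ``mds_k`` used) and a ``prs``
        column.
    isub_norm
        Sample-size-corrected, inverse-normal-transformed burden scores
        indexed by sample id (from :func:`isub.burden_stats.normalize_isub`).
    drop_terms
        Terms whose ΔR^2 = R^2(full) - R^2(full minus that term) is
        reported.  The reduced model keeps every other term; the null
        model is intercept-only.

    Complete-case analysis: samples missing any term are dropped.
    """
    if sample_ids is None:
        sample_ids = list(isub_norm.index)
    pheno = pd.Series(np.asarray(phenotype, dtype=object), index=sample_ids)

    mds_cols = covariates.mds_columns[:mds_k]
    design = covariates.df.reindex(pheno.index)[mds_cols].copy()
    if covariates.prs is not None:
        design["prs"] = covariates.prs.reindex(pheno.index)
    design["isub_norm"] = pd.Series(isub_norm).reindex(pheno.index)

    keep = design.notna().all(axis=1) & pheno.notna()
    design = design.loc[keep]
    y = (pheno.loc[keep] == "case").to_numpy(dtype=float)
    n = len(design)
    if n == 0 or y.sum() == 0 or y.sum() == n:
        raise ValueError("complete cases must include both cases and controls")

    X_full = sm.add_constant(design, has_constant="add")
    full = _fit_logit(y, X_full)
    null = _fit_logit(y, X_full[["const"]])
    r2_full = nagelkerke_r2(full.llf, null.llf, n)

    delta: dict[str, float] = {}
    ll_red: dict[str, float] = {}
    for term in drop_terms:
        if term not in X_full.columns:
            raise ValueError(f"term {term!r} not in the model")
        reduced = _fit_logit(y, X_full.drop(columns=[term]))
        ll_red[term] = float(reduced.llf)
        delta[term] = r2_full - nagelkerke_r2(reduced.llf, null.llf, n)

    return EffectSizeResult(
        model_terms=list(X_full.columns),
        n_samples=n,
        loglik_full=float(full.llf),
        loglik_null=float(null.llf),
        r2_nagelkerke_full=r2_full,
        delta_r2=delta,
        loglik_reduced=ll_red,
        coefficients={c: float(v) for c, v in full.params.items()},
    )


# ---------------------------------------------------------------------------
# PRS vs burden correlation
# ---------------------------------------------------------------------------


@dataclass
class CorrelationResult:
    method: str
    group: str
    n: int
    correlation: float
    p_permutation: float


def prs_isub_correlation(
    covariates: CovariateTable,
    profile: pd.DataFrame,
    group: str = "case",
    method: str = "spearman",
    n_perm: int = 9999,
    seed: int | None = None,
    score_col: str = "isub",
) -> CorrelationResult:
    """Rank correlation between PRS and burden scores within a group.

    Spearman by default (the burden distribution is strongly skewed);
    the two-sided p-value comes from permuting one vector ``n_perm``
    times with the usual +1 smoothing.
    """
    if group not in ("case", "control", "all"):
        raise ValueError("group must be 'case', 'control' or 'all'")
    if covariates.prs is None:
        raise ValueError("covariate table has no prs column")
    sub = profile if group == "all" else profile[profile["phenotype"] == group]
    merged = sub.set_index("sample_id")[[score_col]].join(
        covariates.prs.rename("prs"), how="inner"
    ).dropna()
    x = merged[score_col].to_numpy(dtype=float)
    y = merged["prs"].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("fewer than 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector; correlation undefined")

    if method == "spearman":
        obs = float(stats.spearmanr(x, y).statistic)
    elif method == "pearson":
        obs = float(stats.pearsonr(x, y).statistic)
    else:
        raise ValueError("method must be 'spearman' or 'pearson'")

    if seed is None:
        raise ValueError("seed is mandatory for the permutation p-value")
    rng = np.random.default_rng(seed)
    count = 0
    fn = stats.spearmanr if method == "spearman" else stats.pearsonr
    for _ in range(n_perm):
        r = float(fn(x, rng.permutation(y)).statistic)
        if abs(r) >= abs(obs) - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return CorrelationResult(method=method, group=group, n=len(x),
                             correlation=obs, p_permutation=p)


# ---------------------------------------------------------------------------
# replication comparison
# ---------------------------------------------------------------------------


@dataclass
class ReplicationResult:
    n_variants: int
    n_cases: int
    n_controls: int
    mean_count_cases: float
    mean_count_controls: float
    p_empirical: float


def replication_compare(
    replication: CohortGenotypes,
    variant_list: Sequence[str],
    B: int = 10_000,
    seed: int | None = None,
) -> ReplicationResult:
    """Compare individual minor-allele counts over a discovery variant list.

    Each replication individual is summarised by the sum of minor-allele
    dosages over the listed variants (missing calls contribute 0);
    significance of the case-minus-control difference in means is
    empirical, by label permutation (greater in cases, +1 smoothing).
    """
    variant_list = list(dict.fromkeys(variant_list))
    if not variant_list:
        raise ValueError("empty variant list")
    present = [v for v in variant_list if v in set(replication.variant_ids)]
    if not present:
        raise ValueError("no listed variant present in the replication data")
    if seed is None:
        raise ValueError("seed is mandatory")

    col = {v: j for j, v in enumerate(replication.variant_ids)}
    idx = [col[v] for v in present]
    dos = replication.dosage[:, idx].astype(np.int64)
    counts = np.where(dos > 0, dos, 0).sum(axis=1).astype(float)

    is_case = replication.is_case
    obs = counts[is_case].mean() - counts[~is_case].mean()
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(B):
        lab = rng.permutation(is_case)
        if counts[lab].mean() - counts[~lab].mean() >= obs:
            ge += 1
    p = (ge + 1) / (B + 1)
    return ReplicationResult(
        n_variants=len(present),
        n_cases=int(is_case.sum()),
        n_controls=int((~is_case).sum()),
        mean_count_cases=float(counts[is_case].mean()),
        mean_count_controls=float(counts[~is_case].mean()),
        p_empirical=p,
    )
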