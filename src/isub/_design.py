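"""Precomputed carrier structure for fast re-derivation under relabelling.

Permutation inference re-derives the set-unique partition and every
individual burden score for each permuted phenotype vector.  Doing that
from the dense dosage matrix each time is wasteful: carriage is fixed,
only the labels move.  :class:`CohortDesign` stores the carrier matrix
once (sparse, variants are rare) together with per-variant scores and
category masks; every labelling then needs only a couple of sparse
matrix-vector products.

All public set-unique / burden operations are built on the same code
path, so the observed analysis and the permutation null cannot drift
apart.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

CATEGORIES = ("NS", "DEL", "NS_minus_DEL", "splice", "stop")


class CohortDesign:
    """Sparse carrier representation of in-scope variants.

    Parameters
    ----------
    genotypes : CohortGenotypes
    scored : pandas.DataFrame
        Output of :func:`isub.variant_scoring.apply_condel_augmentation`.
        Deduplicated on ``variant_id`` internally; only in-scope variants
        (nonsynonymous / splice_site / stop_altering) that occur in the
        genotype matrix participate.
    dosage_weighted : bool
        If True each carried variant contributes ``score * dosage`` instead
        of its score once (config switch; default False, matching the
        carrier-based definition of the burden).
    """

    def __init__(self, genotypes, scored, dosage_weighted: bool = False):
        sv = scored.drop_duplicates(subset="variant_id").set_index("variant_id")
        gvid = genotypes.variant_ids
        in_matrix = [v for v in gvid if v in sv.index]
        sub = sv.loc[in_matrix]
        keep_ids = [v for v in in_matrix if bool(sv.at[v, "in_scope"])]
        self.variant_ids: list[str] = keep_ids
        col = {v: j for j, v in enumerate(gvid)}
        cols = [col[v] for v in keep_ids]

        dosage = genotypes.dosage[:, cols]
        carr = dosage >= 1  # missing (-1) is never carriage
        if dosage_weighted:
            weights_mat = np.where(dosage > 0, dosage, 0).astype(np.float64)
            self.carriers = sparse.csr_matrix(weights_mat)
        else:
            self.carriers = sparse.csr_matrix(carr.astype(np.float64))
        self.carrier_bool = sparse.csr_matrix(carr.astype(np.float64))

        ss = sv.loc[keep_ids]
        score = ss["effective_score"].to_numpy(dtype=float)
        self.score = np.where(np.isnan(score), 0.0, score)
        self.deleterious = ss["effective_deleterious"].fillna(False).to_numpy(bool)
        fc = ss["functional_class"].to_numpy()
        self.splice = fc == "splice_site"
        self.stop = fc == "stop_altering"
        self.n_samples = genotypes.n_samples
        self.n_variants = len(keep_ids)
        # carrier count per variant over all samples (labels-independent)
        self.total_carriers = np.asarray(
            self.carrier_bool.sum(axis=0)
        ).ravel()

    # ------------------------------------------------------------------
    def carrier_counts(self, is_case: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-variant carrier counts among cases and controls."""
        case_ct = is_case.astype(np.float64) @ self.carrier_bool
        case_ct = np.asarray(case_ct).ravel()
        return case_ct, self.total_carriers - case_ct

    def unique_masks(self, is_case: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Boolean masks of case-unique and control-unique variants."""
        case_ct, ctrl_ct = self.carrier_counts(is_case)
        case_unique = (case_ct > 0) & (ctrl_ct == 0)
        control_unique = (ctrl_ct > 0) & (case_ct == 0)
        return case_unique, control_unique

    def category_mask(self, category: str) -> np.ndarray:
        if category == "NS":
            return np.ones(self.n_variants, dtype=bool)
        if category == "DEL":
            return self.deleterious
        if category == "NS_minus_DEL":
            return ~self.deleterious
        if category == "splice":
            return self.splice
        if category == "stop":
            return self.stop
        raise ValueError(f"unknown category {category!r}; use one of {CATEGORIES}")

    # ------------------------------------------------------------------
    def scores_for_masks(
        self,
        is_case: np.ndarray,
        case_unique: np.ndarray,
        control_unique: np.ndarray,
        category: str,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-sample scores/counts given precomputed set-unique masks.

        Lets a family of category statistics share one mask derivation
        per permuted labelling.
        """
        mask = self.category_mask(category)
        w_case = self.score * (case_unique & mask)
        w_ctrl = self.score * (control_unique & mask)
        s_case = np.asarray(self.carriers @ w_case).ravel()
        s_ctrl = np.asarray(self.carriers @ w_ctrl).ravel()
        n_case = np.asarray(
            self.carrier_bool @ (case_unique & mask).astype(float)
        ).ravel()
        n_ctrl = np.asarray(
            self.carrier_bool @ (control_unique & mask).astype(float)
        ).ravel()
        scores = np.where(is_case, s_case, s_ctrl)
        counts = np.where(is_case, n_case, n_ctrl).astype(np.int64)
        return scores, counts

    def isub_scores(
        self, is_case: np.ndarray, category: str = "DEL"
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-sample burden scores and variant counts for a labelling.

        Each individual is scored only against their OWN side's set-unique
        variants in the category; the opposite side's variants contribute
        nothing.
        """
        cu, ku = self.unique_masks(is_case)
        return self.scores_for_masks(is_case, cu, ku, category)
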