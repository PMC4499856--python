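"""Gene-level burden categories, hit-gene selection and overlap tests.

Beyond the per-individual burden, polygenicity is assessed by counting
GENES touched by set-unique variation of different kinds on each side:
genes with at least one deleterious set-unique variant, with a splice
site variant, with a stop-altering variant, and "double hits" — genes in
which some single individual carries two or more own-side set-unique
in-scope variants of which at least one is deleterious.  Differences in
gene counts between cases and controls are tested by the same
label-permutation machinery as the burden itself.

Gene-set work: selecting "differentially hit" genes (deleterious
variants in more than two carriers of one group with enriched carriage
at a lenient one-sided Fisher threshold), hypergeometric overlap against
user-supplied gene lists, and a burden re-run excluding a gene set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats

from ._design import CohortDesign
from .cohort_io import CohortGenotypes, GeneSet
from .permutation import (
    PermutationConfig,
    PermutationResult,
    isub_statistic,
    permute_family,
    permute_pvalue,
)

logger = logging.getLogger(__name__)

GENE_CATEGORIES = ("deleterious", "splice", "stop", "double_hit")


class GeneDesign:
    """Gene incidence on top of a :class:`CohortDesign`.

    Built from the (variant, gene) pairs of the scored annotation table;
    variants without a gene symbol are excluded from gene analyses and
    their count logged.
    """

    def __init__(self, genotypes: CohortGenotypes, scored: pd.DataFrame):
        self.design = CohortDesign(genotypes, scored)
        vindex = {v: i for i, v in enumerate(self.design.variant_ids)}
        pairs = scored.loc[
            scored["in_scope"] & scored["gene"].notna(), ["variant_id", "gene"]
        ].drop_duplicates()
        pairs = pairs[pairs["variant_id"].isin(vindex)]
        n_unannotated = self.design.n_variants - pairs["variant_id"].nunique()
        if n_unannotated:
            logger.info(
                "%d in-scope variants without gene annotation excluded from "
                "gene analyses", n_unannotated
            )
        self.genes: list[str] = sorted(pairs["gene"].unique())
        gindex = {g: i for i, g in enumerate(self.genes)}
        rows = pairs["variant_id"].map(vindex).to_numpy()
        cols = pairs["gene"].map(gindex).to_numpy()
        self.incidence = sparse.csr_matrix(
            (np.ones(len(rows)), (rows, cols)),
            shape=(self.design.n_variants, len(self.genes)),
        )

    # ------------------------------------------------------------------
    def _touched(self, variant_mask: np.ndarray) -> np.ndarray:
        """Gene mask: genes with >= 1 variant in the mask."""
        return np.asarray(variant_mask.astype(float) @ self.incidence).ravel() > 0

    def _double_hit(self, sample_rows: np.ndarray, ns_mask: np.ndarray,
                    del_mask: np.ndarray) -> np.ndarray:
        carr = self.design.carrier_bool[sample_rows]
        per_gene_ns = (carr.multiply(ns_mask.astype(float))).tocsr() @ self.incidence
        per_gene_del = (carr.multiply(del_mask.astype(float))).tocsr() @ self.incidence
        hit = (per_gene_ns >= 2).multiply(per_gene_del >= 1)
        return np.asarray(hit.sum(axis=0)).ravel() > 0

    def gene_masks(self, is_case: np.ndarray) -> dict[str, dict[str, np.ndarray]]:
        """Per category, per side, boolean masks over ``self.genes``."""
        cu, ku = self.design.unique_masks(is_case)
        d = self.design
        out: dict[str, dict[str, np.ndarray]] = {}
        for cat in GENE_CATEGORIES:
            out[cat] = {}
        for side, mask, rows in (
            ("case", cu, np.where(is_case)[0]),
            ("control", ku, np.where(~is_case)[0]),
        ):
            out["deleterious"][side] = self._touched(mask & d.deleterious)
            out["splice"][side] = self._touched(mask & d.splice)
            out["stop"][side] = self._touched(mask & d.stop)
            out["double_hit"][side] = self._double_hit(
                rows, mask, mask & d.deleterious
            )
        return out


def gene_category_counts(
    genotypes: CohortGenotypes,
    scored: pd.DataFrame,
    labels: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-side gene counts for the four burden categories.

    Returns a tidy frame with columns ``category``, ``side``, ``n_genes``.
    """
    gd = GeneDesign(genotypes, scored)
    is_case = genotypes.is_case if labels is None else _as_bool(labels)
    masks = gd.gene_masks(is_case)
    rows = [
        {"category": cat, "side": side, "n_genes": int(masks[cat][side].sum())}
        for cat in GENE_CATEGORIES
        for side in ("case", "control")
    ]
    return pd.DataFrame(rows)


def _as_bool(labels) -> np.ndarray:
    labels = np.asarray(labels)
    return labels if labels.dtype == bool else labels == "case"


# ---------------------------------------------------------------------------
# permutation tests on gene counts
# ---------------------------------------------------------------------------


def gene_count_statistic(
    genotypes: CohortGenotypes, scored: pd.DataFrame, category: str
) -> Callable[[np.ndarray], float]:
    """Statistic factory: (case gene count - control gene count)."""
    if category not in GENE_CATEGORIES:
        raise ValueError(f"category must be one of {GENE_CATEGORIES}")
    gd = GeneDesign(genotypes, scored)

    def stat(is_case: np.ndarray) -> float:
        masks = gd.gene_masks(is_case)
        return float(masks[category]["case"].sum() - masks[category]["control"].sum())

    return stat


def gene_family_statistic(
    genotypes: CohortGenotypes, scored: pd.DataFrame,
    categories: Sequence[str] = GENE_CATEGORIES,
) -> Callable[[np.ndarray], np.ndarray]:
    """Joint gene-count-difference statistic over the 4-test family."""
    gd = GeneDesign(genotypes, scored)

    def stat(is_case: np.ndarray) -> np.ndarray:
        masks = gd.gene_masks(is_case)
        return np.array(
            [
                masks[c]["case"].sum() - masks[c]["control"].sum()
                for c in categories
            ],
            dtype=float,
        )

    return stat


def gene_count_difference_test(
    genotypes: CohortGenotypes,
    scored: pd.DataFrame,
    category: str,
    config: PermutationConfig,
    strata: np.ndarray | None = None,
) -> PermutationResult:
    """Permutation test of the case-minus-control gene count.

    The gene sets are recomputed from scratch for every permuted
    labelling.
    """
    stat = gene_count_statistic(genotypes, scored, category)
    return permute_pvalue(
        genotypes.phenotype, stat, config, strata=strata,
        name=f"gene_count_{category}",
    )


# ---------------------------------------------------------------------------
# per-gene carrier table and Fisher tests
# ---------------------------------------------------------------------------


def fisher_exact_one_sided(a: int, b: int, c: int, d: int) -> float:
    """One-sided Fisher exact p for enrichment of cell ``a``.

    The 2x2 table is ``[[a, b], [c, d]]`` = carriers/non-carriers (rows)
    by case/control (columns); the p-value is the upper hypergeometric
    tail P(case carriers >= a) at fixed margins.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell in 2x2 table")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1])


def build_gene_burden_table(
    genotypes: CohortGenotypes, scored: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene burden table at the observed labelling.

    One row per gene with at least one in-scope set-unique variant on
    either side: number of deleterious set-unique variants and of
    individuals carrying at least one (per side), splice/stop presence,
    number of double-hit individuals, and one-sided Fisher exact
    p-values of carrier enrichment in each direction (carriers vs
    non-carriers by case/control).
    """
    gd = GeneDesign(genotypes, scored)
    d = gd.design
    is_case = genotypes.is_case
    n_cases = int(is_case.sum())
    n_controls = int((~is_case).sum())
    cu, ku = d.unique_masks(is_case)

    rows = []
    M = gd.incidence
    for side, mask in (("case", cu), ("control", ku)):
        rows.append(
            {
                "n_del_variants": np.asarray(
                    (mask & d.deleterious).astype(float) @ M
                ).ravel(),
                "splice": np.asarray(
                    (mask & d.splice).astype(float) @ M
                ).ravel() > 0,
                "stop": np.asarray((mask & d.stop).astype(float) @ M).ravel() > 0,
            }
        )

    def carriers_per_gene(sample_rows: np.ndarray, vmask: np.ndarray) -> np.ndarray:
        carr = d.carrier_bool[sample_rows].multiply(vmask.astype(float)).tocsr()
        per_gene = carr @ M
        return np.asarray((per_gene > 0).sum(axis=0)).ravel()

    case_rows = np.where(is_case)[0]
    ctrl_rows = np.where(~is_case)[0]
    case_carr = carriers_per_gene(case_rows, cu & d.deleterious)
    ctrl_carr = carriers_per_gene(ctrl_rows, ku & d.deleterious)

    def dh_counts(sample_rows, mask):
        carr = d.carrier_bool[sample_rows]
        ns = (carr.multiply(mask.astype(float))).tocsr() @ M
        dl = (carr.multiply((mask & d.deleterious).astype(float))).tocsr() @ M
        hit = (ns >= 2).multiply(dl >= 1)
        return np.asarray(hit.sum(axis=0)).ravel().astype(int)

    table = pd.DataFrame(
        {
            "gene": gd.genes,
            "case_n_del_variants": rows[0]["n_del_variants"].astype(int),
            "case_n_carriers_del": case_carr.astype(int),
            "case_has_splice_unique": rows[0]["splice"],
            "case_has_stop_unique": rows[0]["stop"],
            "case_n_double_hit": dh_counts(case_rows, cu),
            "control_n_del_variants": rows[1]["n_del_variants"].astype(int),
            "control_n_carriers_del": ctrl_carr.astype(int),
            "control_has_splice_unique": rows[1]["splice"],
            "control_has_stop_unique": rows[1]["stop"],
            "control_n_double_hit": dh_counts(ctrl_rows, ku),
        }
    )
    keep = (
        (table["case_n_del_variants"] > 0)
        | (table["control_n_del_variants"] > 0)
        | table["case_has_splice_unique"]
        | table["control_has_splice_unique"]
        | table["case_has_stop_unique"]
        | table["control_has_stop_unique"]
        | (table["case_n_double_hit"] > 0)
        | (table["control_n_double_hit"] > 0)
    )
    table = table[keep].reset_index(drop=True)
    table["fisher_p_case"] = [
        fisher_exact_one_sided(
            int(r.case_n_carriers_del),
            int(r.control_n_carriers_del),
            n_cases - int(r.case_n_carriers_del),
            n_controls - int(r.control_n_carriers_del),
        )
        for r in table.itertuples()
    ]
    table["fisher_p_control"] = [
        fisher_exact_one_sided(
            int(r.control_n_carriers_del),
            int(r.case_n_carriers_del),
            n_controls - int(r.control_n_carriers_del),
            n_cases - int(r.case_n_carriers_del),
        )
        for r in table.itertuples()
    ]
    table.attrs["n_cases"] = n_cases
    table.attrs["n_controls"] = n_controls
    return table


@dataclass
class DifferentiallyHitGenes:
    """Primary hit-gene list plus the separately analysed secondary list.

    ``primary``: genes with deleterious set-unique variants carried by
    more than two individuals of the side, a strictly greater carrier
    proportion than the other side, and one-sided Fisher p < threshold.
    ``secondary``: genes with exactly one or two side carriers and zero
    opposite-side carriers, excluded from the primary list.
    """

    side: str
    primary: frozenset[str]
    secondary: frozenset[str]

    def as_gene_set(self) -> GeneSet:
        return GeneSet(name=f"differentially_hit_{self.side}",
                       members=self.primary)


def differentially_hit_genes(
    gene_table: pd.DataFrame,
    side: str = "case",
    p_threshold: float = 0.5,
    min_carriers: int = 3,
) -> DifferentiallyHitGenes:
    """Select the differentially hit genes of one side.

    See :class:`DifferentiallyHitGenes`; the Fisher threshold is a
    deliberately lenient pre-filter (default strict ``< 0.5``), direction
    is enforced by a carrier-proportion comparison before the test.
    """
    if side not in ("case", "control"):
        raise ValueError("side must be 'case' or 'control'")
    other = "control" if side == "case" else "case"
    n_side = gene_table.attrs[f"n_{side}s"]
    n_other = gene_table.attrs[f"n_{other}s"]
    own = gene_table[f"{side}_n_carriers_del"]
    opp = gene_table[f"{other}_n_carriers_del"]
    fisher = gene_table[f"fisher_p_{side}"]

    increased = own / n_side > opp / n_other
    primary = (own >= min_carriers) & increased & (fisher < p_threshold)
    secondary = own.isin([1, 2]) & (opp == 0)
    return DifferentiallyHitGenes(
        side=side,
        primary=frozenset(gene_table.loc[primary, "gene"]),
        secondary=frozenset(gene_table.loc[secondary, "gene"]),
    )


# ---------------------------------------------------------------------------
# gene-set overlap
# ---------------------------------------------------------------------------


@dataclass
class OverlapResult:
    list_a_size: int
    list_b_size: int
    universe_size: int
    overlap: int
    p_hypergeometric: float
    p_case_control_diff: float | None = None


def overlap_test(genes_a: GeneSet, genes_b: GeneSet, universe: GeneSet
                 ) -> OverlapResult:
    """Upper-tail hypergeometric overlap test between two gene sets.

    p = P(overlap >= observed) drawing |A| genes from a universe
    containing |B| marked genes.  Both lists must be subsets of the
    universe.
    """
    for gs in (genes_a, genes_b):
        outside = gs.members - universe.members
        if outside:
            raise ValueError(
                f"gene set {gs.name!r} has members outside the universe: "
                f"{sorted(outside)[:5]}"
            )
    k = len(genes_a.members & genes_b.members)
    M, K, n = len(universe), len(genes_b), len(genes_a)
    p = float(stats.hypergeom.sf(k - 1, M, K, n))
    return OverlapResult(
        list_a_size=n, list_b_size=K, universe_size=M, overlap=k,
        p_hypergeometric=min(1.0, p),
    )


def overlap_difference_statistic(
    genotypes: CohortGenotypes,
    scored: pd.DataFrame,
    gene_list: GeneSet,
    category: str = "deleterious",
) -> Callable[[np.ndarray], float]:
    """Statistic: case overlap with the list minus control overlap.

    Each side's hit-gene set (genes with >= 1 own-side set-unique variant
    of the category) is recomputed per labelling.
    """
    gd = GeneDesign(genotypes, scored)
    list_mask = np.array([g in gene_list.members for g in gd.genes])

    def stat(is_case: np.ndarray) -> float:
        masks = gd.gene_masks(is_case)
        m = masks[category]
        return float(
            (m["case"] & list_mask).sum() - (m["control"] & list_mask).sum()
        )

    return stat


def overlap_difference_test(
    genotypes: CohortGenotypes,
    scored: pd.DataFrame,
    gene_list: GeneSet,
    config: PermutationConfig,
    category: str = "deleterious",
) -> PermutationResult:
    stat = overlap_difference_statistic(genotypes, scored, gene_list, category)
    return permute_pvalue(
        genotypes.phenotype, stat, config, name=f"overlap_diff_{gene_list.name}"
    )


# ---------------------------------------------------------------------------
# exclusion re-run
# ---------------------------------------------------------------------------


def exclude_gene_set(scored: pd.DataFrame, exclusion: GeneSet) -> pd.DataFrame:
    """Drop all in-scope variants annotated to any excluded gene."""
    excluded_vids = set(
        scored.loc[
            scored["in_scope"] & scored["gene"].isin(exclusion.members),
            "variant_id",
        ]
    )
    filtered = scored[~scored["variant_id"].isin(excluded_vids)].reset_index(
        drop=True
    )
    if not filtered["in_scope"].any():
        raise ValueError("gene exclusion removed every in-scope variant")
    return filtered


def exclude_gene_set_rerun(
    genotypes: CohortGenotypes,
    scored: pd.DataFrame,
    exclusion: GeneSet | None,
    config: PermutationConfig,
    category: str = "DEL",
) -> PermutationResult:
    """Re-run the burden permutation test after excluding a gene set.

    With ``exclusion=None`` this reproduces the baseline run (identical
    under the same seed).  Robustness check: a burden signal that
    survives removal of a candidate gene set is genome-wide polygenic
    rather than driven by those genes.
    """
    filtered = scored if exclusion is None else exclude_gene_set(scored, exclusion)
    stat = isub_statistic(genotypes, filtered, category=category)
    return permute_pvalue(
        genotypes.phenotype, stat, config, name=f"isub_{category}_excluded"
    )
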