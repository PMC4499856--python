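"""Variant scoring (augmented CONDEL) and the set-unique partition.

Two steps define which variants enter the individual set-unique burden
(ISUB) and with what weight:

1. *Augmentation*: CONDEL scores non-synonymous variants in [0, 1] and
   flags them deleterious or neutral, but most splice-site and
   stop-altering variants cause no amino-acid change and carry no score.
   These are assigned the maximal score (1.0) and a deleterious label;
   splice/stop variants that DO carry a CONDEL score keep it unchanged.

2. *Set-unique selection*: for a given case/control labelling, a variant
   is case-unique if at least one case carries the minor allele and no
   control does (control-unique symmetrically).  Carriage means dosage
   >= 1; missing genotypes never count as carriage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._design import CATEGORIES, CohortDesign
from .cohort_io import CohortGenotypes

logger = logging.getLogger(__name__)

IN_SCOPE_CLASSES = ("nonsynonymous", "splice_site", "stop_altering")


# ---------------------------------------------------------------------------


def apply_condel_augmentation(annotations: pd.DataFrame) -> pd.DataFrame:
    """Return a scored variant table with augmented splice/stop scores.

    Adds three columns to a validated annotation table:

    - ``effective_score``: the CONDEL score, or 1.0 for non-scored
      splice-site / stop-altering variants (maximal deleteriousness).
    - ``effective_deleterious``: the CONDEL flag, or True for augmented
      variants; False where no flag is available.
    - ``in_scope``: True iff the variant participates in ISUB
      (functional class nonsynonymous, splice_site or stop_altering).

    Augmentation never lowers a score and never un-flags a deleterious
    variant.  Non-synonymous variants are passed through unchanged.
    """
    df = annotations.copy()
    fc = df["functional_class"]
    score = pd.to_numeric(df.get("condel_score"), errors="coerce")
    flag = df.get("deleterious_flag")
    flag = flag.map(lambda x: bool(x) if pd.notna(x) else False)

    augment = fc.isin(["splice_site", "stop_altering"]) & score.isna()
    n_aug = int(df.loc[augment].drop_duplicates("variant_id").shape[0])
    if n_aug:
        logger.info("augmented %d non-scored splice/stop variants to score 1.0", n_aug)

    df["effective_score"] = np.where(augment, 1.0, score.fillna(0.0))
    df["effective_deleterious"] = np.where(augment, True, flag).astype(bool)
    df["in_scope"] = fc.isin(IN_SCOPE_CLASSES)
    return df


# ---------------------------------------------------------------------------


@dataclass
class SetUniquePartition:
    """Case-unique and control-unique in-scope variants, with category views.

    ``categories[side][cat]`` for side in {"case", "control"} and cat in
    {"NS", "DEL", "NS_minus_DEL", "splice", "stop"} holds frozensets of
    variant ids.  NS is the full in-scope set-unique set on that side;
    DEL and NS_minus_DEL partition it.
    """

    case_unique: frozenset[str]
    control_unique: frozenset[str]
    categories: dict[str, dict[str, frozenset[str]]]

    def side(self, side: str) -> frozenset[str]:
        if side == "case":
            return self.case_unique
        if side == "control":
            return self.control_unique
        raise ValueError(f"side must be 'case' or 'control', got {side!r}")

    def validate(self) -> None:
        if self.case_unique & self.control_unique:
            raise ValueError("case-unique and control-unique sets overlap")
        for side, cats in self.categories.items():
            if cats["DEL"] | cats["NS_minus_DEL"] != cats["NS"]:
                raise ValueError(f"{side}: DEL u NS_minus_DEL != NS")
            if cats["DEL"] & cats["NS_minus_DEL"]:
                raise ValueError(f"{side}: DEL and NS_minus_DEL overlap")


def select_set_unique(
    genotypes: CohortGenotypes,
    scored: pd.DataFrame,
    labels: np.ndarray | None = None,
    restrict_in_scope: bool = True,
) -> SetUniquePartition:
    """Partition variants into case-unique and control-unique sets.

    Parameters
    ----------
    labels
        Phenotype vector to use instead of ``genotypes.phenotype``
        (permutation inference passes relabellings here).  Either the
        string labels or a boolean is-case mask.
    restrict_in_scope
        If False, all variants in the matrix participate regardless of
        functional class (used for whole-platform set-unique counts);
        category views still cover in-scope variants only.
    """
    is_case = _as_is_case(genotypes, labels)
    if is_case.sum() == 0 or (~is_case).sum() == 0:
        raise ValueError("labelling must contain at least one case and one control")

    design = CohortDesign(genotypes, scored)
    cu_mask, ku_mask = design.unique_masks(is_case)
    vids = np.array(design.variant_ids, dtype=object)
    case_unique = frozenset(vids[cu_mask])
    control_unique = frozenset(vids[ku_mask])

    if not restrict_in_scope:
        carr = genotypes.dosage >= 1
        case_ct = carr[is_case].sum(axis=0)
        ctrl_ct = carr[~is_case].sum(axis=0)
        all_ids = np.array(genotypes.variant_ids, dtype=object)
        case_unique = frozenset(all_ids[(case_ct > 0) & (ctrl_ct == 0)])
        control_unique = frozenset(all_ids[(ctrl_ct > 0) & (case_ct == 0)])

    categories: dict[str, dict[str, frozenset[str]]] = {}
    for side, mask in (("case", cu_mask), ("control", ku_mask)):
        cats = {}
        for cat in CATEGORIES:
            cmask = design.category_mask(cat) & mask
            cats[cat] = frozenset(vids[cmask])
        categories[side] = cats

    part = SetUniquePartition(case_unique, control_unique, categories)
    part.validate()
    return part


def _as_is_case(genotypes: CohortGenotypes, labels) -> np.ndarray:
    if labels is None:
        return genotypes.is_case
    labels = np.asarray(labels)
    if labels.dtype == bool:
        return labels
    return labels == "case"


# ---------------------------------------------------------------------------


@dataclass
class PartitionSummary:
    """Counts per side per category, carrier-count and MAF summaries."""

    counts: pd.DataFrame  # index (side, category) -> n_variants
    carrier_stats: pd.DataFrame | None = None
    maf_stats: pd.DataFrame | None = None


def summarize_partition(
    partition: SetUniquePartition,
    scored: pd.DataFrame,
    genotypes: CohortGenotypes | None = None,
) -> PartitionSummary:
    """Summarise a set-unique partition.

    Counts satisfy NS = DEL + NS_minus_DEL on each side.  When genotypes
    are given, the carrier-count distribution of set-unique variants is
    summarised per side (mean/median/max observations per variant); when
    the annotation table has ``population_maf``, its per-side summary
    (mean/median/sd/min/max) is included.
    """
    rows = []
    for side in ("case", "control"):
        for cat in CATEGORIES:
            rows.append(
                {
                    "side": side,
                    "category": cat,
                    "n_variants": len(partition.categories[side][cat]),
                }
            )
    counts = pd.DataFrame(rows)

    carrier_stats = None
    if genotypes is not None:
        carr = genotypes.dosage >= 1
        col = {v: j for j, v in enumerate(genotypes.variant_ids)}
        crows = []
        for side in ("case", "control"):
            members = partition.categories[side]["NS"]
            idx = [col[v] for v in members if v in col]
            if idx:
                per_variant = carr[:, idx].sum(axis=0)
                crows.append(
                    {
                        "side": side,
                        "mean": float(per_variant.mean()),
                        "median": float(np.median(per_variant)),
                        "min": int(per_variant.min()),
                        "max": int(per_variant.max()),
                    }
                )
            else:
                crows.append(
                    {"side": side, "mean": np.nan, "median": np.nan,
                     "min": 0, "max": 0}
                )
        carrier_stats = pd.DataFrame(crows)

    maf_stats = None
    sv = scored.drop_duplicates("variant_id").set_index("variant_id")
    if "population_maf" in sv.columns and sv["population_maf"].notna().any():
        mrows = []
        for side in ("case", "control"):
            members = [v for v in partition.categories[side]["NS"] if v in sv.index]
            maf = sv.loc[members, "population_maf"].dropna()
            if len(maf):
                mrows.append(
                    {
                        "side": side,
                        "n_with_maf": int(len(maf)),
                        "mean": float(maf.mean()),
                        "median": float(maf.median()),
                        "sd": float(maf.std()),
                        "min": float(maf.min()),
                        "max": float(maf.max()),
                    }
                )
        if mrows:
            maf_stats = pd.DataFrame(mrows)

    return PartitionSummary(counts=counts, carrier_stats=carrier_stats,
                            maf_stats=maf_stats)
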