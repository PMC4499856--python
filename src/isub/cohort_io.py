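"""Cohort data model and readers/writers for all external representations.

The central container is :class:`CohortGenotypes`: a samples x variants
minor-allele-count matrix together with case/control phenotype labels.
Dosages are always oriented to the *minor* allele, determined on the
combined case+control sample, so that "carrier" means the same thing on
both sides of every set-unique comparison.  Missing genotypes are encoded
as ``-1`` and are never treated as carriage.

Supported genotype formats: VCF (plain or bgzipped, via cyvcf2), PLINK
``.ped``/``.map`` text, and a simple TSV dialect (first column sample id,
optional ``phenotype`` column, remaining columns one variant each holding
minor-allele counts 0/1/2 or NA).  Variant annotations arrive as a TSV
with a closed functional-class vocabulary; gene lists as one-symbol-per-
line files or GMT lines.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

PHENOTYPES = ("case", "control")
FUNCTIONAL_CLASSES = (
    "synonymous",
    "nonsynonymous",
    "splice_site",
    "stop_altering",
    "other",
)
#: sentinel for a missing genotype call
MISSING = -1

ANNOTATION_COLUMNS = (
    "variant_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "functional_class",
    "condel_score",
    "deleterious_flag",
    "population_maf",
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class CohortGenotypes:
    """Samples x variants minor-allele dosage matrix with phenotypes.

    Parameters
    ----------
    sample_ids
        Unique opaque sample identifiers, one per row of ``dosage``.
    variant_ids
        Unique variant identifiers, one per column of ``dosage``.
    phenotype
        Per-sample label, each ``"case"`` or ``"control"``.
    dosage
        ``int8`` array of minor-allele counts in ``{0, 1, 2}`` with ``-1``
        for missing calls.
    stratum
        Optional per-sample label used for stratified permutation.
    """

    sample_ids: list[str]
    variant_ids: list[str]
    phenotype: np.ndarray
    dosage: np.ndarray
    stratum: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.variant_ids = [str(v) for v in self.variant_ids]
        self.phenotype = np.asarray(self.phenotype, dtype=object)
        self.dosage = np.asarray(self.dosage)
        if self.dosage.dtype != np.int8:
            self.dosage = self.dosage.astype(np.int8)
        if self.stratum is not None:
            self.stratum = np.asarray(self.stratum, dtype=object)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError("duplicate variant ids")
        if self.phenotype.shape != (len(self.sample_ids),):
            raise ValueError("phenotype length does not match samples")
        bad = set(self.phenotype) - set(PHENOTYPES)
        if bad:
            raise ValueError(f"phenotype labels outside {PHENOTYPES}: {sorted(bad)}")
        if self.dosage.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variant_ids)} variants"
            )
        vals = np.unique(self.dosage)
        if not np.all(np.isin(vals, [MISSING, 0, 1, 2])):
            raise ValueError("dosage values must be in {-1, 0, 1, 2}")
        if self.n_cases == 0 or self.n_controls == 0:
            raise ValueError("cohort needs at least one case and one control")
        if self.stratum is not None and self.stratum.shape != self.phenotype.shape:
            raise ValueError("stratum length does not match samples")

    # -- convenience --------------------------------------------------------
    @property
    def is_case(self) -> np.ndarray:
        return np.asarray(self.phenotype == "case")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    @property
    def n_cases(self) -> int:
        return int(self.is_case.sum())

    @property
    def n_controls(self) -> int:
        return int((~self.is_case).sum())

    def subset_variants(self, keep: Sequence[str]) -> "CohortGenotypes":
        """Return a copy restricted to the given variant ids (order kept)."""
        index = {v: i for i, v in enumerate(self.variant_ids)}
        cols = [index[v] for v in keep]
        return CohortGenotypes(
            sample_ids=list(self.sample_ids),
            variant_ids=[self.variant_ids[i] for i in cols],
            phenotype=self.phenotype.copy(),
            dosage=self.dosage[:, cols].copy(),
            stratum=None if self.stratum is None else self.stratum.copy(),
        )


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class CovariateTable:
    """Per-sample covariates: MDS ancestry components and a PRS column."""

    df: pd.DataFrame  # index: sample_id; columns MDS1..MDSk, prs

    def __post_init__(self) -> None:
        mds = self.mds_columns
        if len(mds) != len(set(mds)):
            raise ValueError("duplicate MDS columns")
        if self.df.index.has_duplicates:
            raise ValueError("duplicate sample ids in covariate table")

    @property
    def mds_columns(self) -> list[str]:
        return [c for c in self.df.columns if c.upper().startswith("MDS")]

    @property
    def prs(self) -> pd.Series | None:
        return self.df["prs"] if "prs" in self.df.columns else None


# ---------------------------------------------------------------------------
# minor-allele orientation
# ---------------------------------------------------------------------------


def orient_to_minor(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orient an alt-allele dosage matrix to the minor allele.

    Allele frequency is computed on the combined sample (missing calls
    excluded).  Columns where the counted allele has frequency > 0.5 are
    flipped (``d -> 2 - d``); exact ties stay oriented to the alt allele.
    Idempotent: re-orienting an oriented matrix changes nothing.

    Returns
    -------
    (oriented, flipped)
        The oriented ``int8`` matrix and a boolean per-variant flip mask.
    """
    d = np.asarray(dosage, dtype=np.int8)
    present = d != MISSING
    with np.errstate(invalid="ignore"):
        af = np.where(present, d, 0).sum(axis=0) / np.maximum(
            2 * present.sum(axis=0), 1
        )
    flipped = af > 0.5
    out = d.copy()
    cols = np.where(flipped)[0]
    for c in cols:
        col = out[:, c]
        keep = col != MISSING
        col[keep] = 2 - col[keep]
    return out, flipped


# ---------------------------------------------------------------------------
# genotype readers
# ---------------------------------------------------------------------------


def read_phenotypes(path: str | Path) -> dict[str, str]:
    """Read a two-column sample -> phenotype file (TSV, optional header)."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected two columns")
        sid, label = parts[0].strip(), parts[1].strip().lower()
        if lineno == 1 and label not in PHENOTYPES:
            continue  # header row
        if label not in PHENOTYPES:
            raise ValueError(
                f"{path}:{lineno}: phenotype {label!r} not in {PHENOTYPES}"
            )
        out[sid] = label
    if not out:
        raise ValueError(f"{path}: no phenotype rows")
    return out


def _attach_phenotypes(
    sample_ids: list[str], phenotypes: Mapping[str, str]
) -> np.ndarray:
    missing = [s for s in phenotypes if s not in set(sample_ids)]
    if missing:
        raise ValueError(
            f"samples in phenotype file absent from genotypes: {missing[:5]}"
        )
    unlabelled = [s for s in sample_ids if s not in phenotypes]
    if unlabelled:
        raise ValueError(f"samples without phenotype: {unlabelled[:5]}")
    return np.array([phenotypes[s] for s in sample_ids], dtype=object)


def read_genotypes(
    path: str | Path,
    format_hint: str | None = None,
    phenotype_path: str | Path | None = None,
    phenotypes: Mapping[str, str] | None = None,
) -> CohortGenotypes:
    """Read genotypes from VCF, PLINK ped/map, or the TSV dialect.

    The format is inferred from the file suffix unless ``format_hint`` in
    ``{"vcf", "ped", "tsv"}`` is given.  Phenotypes come from the file
    itself (PLINK column 6, TSV ``phenotype`` column) or from a sidecar
    two-column file / mapping.  Dosages are oriented to the minor allele.
    """
    path = Path(path)
    fmt = format_hint
    if fmt is None:
        name = path.name.lower()
        if name.endswith((".vcf", ".vcf.gz")):
            fmt = "vcf"
        elif name.endswith(".ped"):
            fmt = "ped"
        else:
            fmt = "tsv"
    if phenotype_path is not None:
        phenotypes = read_phenotypes(phenotype_path)

    if fmt == "vcf":
        return _read_vcf(path, phenotypes)
    if fmt == "ped":
        return _read_ped(path, phenotypes)
    if fmt == "tsv":
        return _read_tsv(path, phenotypes)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_vcf(path: Path, phenotypes: Mapping[str, str] | None) -> CohortGenotypes:
    from cyvcf2 import VCF  # lazy: only needed for VCF input

    if phenotypes is None:
        raise ValueError("VCF input requires a phenotype sidecar file")
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows: list[np.ndarray] = []
    ids: list[str] = []
    for rec in vcf:
        gt = np.asarray(rec.gt_types, dtype=np.int8)  # 0/1/2 alt count, 3 unknown
        gt[gt == 3] = MISSING
        rows.append(gt)
        vid = rec.ID
        if vid is None or vid == ".":
            vid = f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0] if rec.ALT else '.'}"
        ids.append(vid)
    dosage = (
        np.stack(rows, axis=1) if rows else np.zeros((len(samples), 0), dtype=np.int8)
    )
    dosage, _ = orient_to_minor(dosage)
    _warn_all_missing(dosage, ids)
    return CohortGenotypes(
        sample_ids=samples,
        variant_ids=ids,
        phenotype=_attach_phenotypes(samples, phenotypes),
        dosage=dosage,
    )


def _read_ped(path: Path, phenotypes: Mapping[str, str] | None) -> CohortGenotypes:
    """PLINK text pedigree: 6 leading columns then two alleles per variant."""
    map_path = path.with_suffix(".map")
    if not map_path.exists():
        raise FileNotFoundError(f"missing .map companion for {path}")
    variant_ids: list[str] = []
    for lineno, line in enumerate(map_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"{map_path}:{lineno}: expected 4 columns")
        variant_ids.append(parts[1])

    sample_ids: list[str] = []
    pheno: list[str] = []
    allele_rows: list[list[tuple[str, str]]] = []
    m = len(variant_ids)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * m:
            raise ValueError(
                f"{path}:{lineno}: expected {6 + 2 * m} fields, got {len(parts)}"
            )
        sample_ids.append(parts[1])
        pheno.append(parts[5])
        allele_rows.append(
            [(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(m)]
        )

    if phenotypes is None:
        codes = {"2": "case", "1": "control"}
        try:
            labels = np.array([codes[p] for p in pheno], dtype=object)
        except KeyError as exc:
            raise ValueError(
                f"{path}: unsupported phenotype code {exc}; supply a sidecar file"
            ) from exc
    else:
        labels = _attach_phenotypes(sample_ids, phenotypes)

    n = len(sample_ids)
    dosage = np.full((n, m), MISSING, dtype=np.int8)
    for j in range(m):
        counts: dict[str, int] = {}
        for i in range(n):
            for a in allele_rows[i][j]:
                if a != "0":
                    counts[a] = counts.get(a, 0) + 1
        if len(counts) > 2:
            raise ValueError(f"{path}: variant {variant_ids[j]} has >2 alleles")
        if not counts:
            continue  # all-missing; left as MISSING
        # count the minor allele; ties broken toward the lexicographically
        # later allele (a fixed, documented convention for .ped input)
        min_count = min(counts.values())
        minor = max(a for a in counts if counts[a] == min_count)
        for i in range(n):
            a1, a2 = allele_rows[i][j]
            if a1 == "0" or a2 == "0":
                continue
            dosage[i, j] = (a1 == minor) + (a2 == minor)
    _warn_all_missing(dosage, variant_ids)
    return CohortGenotypes(
        sample_ids=sample_ids,
        variant_ids=variant_ids,
        phenotype=labels,
        dosage=dosage,
    )


def _read_tsv(path: Path, phenotypes: Mapping[str, str] | None) -> CohortGenotypes:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    if df.columns[0].lower() not in ("sample_id", "sample"):
        raise ValueError(f"{path}: first column must be sample_id")
    df = df.set_index(df.columns[0])
    sample_ids = [str(s) for s in df.index]
    pheno_col = next((c for c in df.columns if c.lower() == "phenotype"), None)
    if pheno_col is not None:
        labels = np.array([str(x).lower() for x in df[pheno_col]], dtype=object)
        df = df.drop(columns=[pheno_col])
    elif phenotypes is not None:
        labels = _attach_phenotypes(sample_ids, phenotypes)
    else:
        raise ValueError(f"{path}: no phenotype column and no sidecar supplied")
    variant_ids = [str(c) for c in df.columns]
    mat = df.to_numpy(dtype=float)
    bad = ~(np.isnan(mat) | np.isin(mat, [0.0, 1.0, 2.0]))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: invalid dosage {mat[i, j]!r} for sample {sample_ids[i]} "
            f"variant {variant_ids[j]} (data line {i + 2})"
        )
    dosage = np.where(np.isnan(mat), MISSING, mat).astype(np.int8)
    dosage, _ = orient_to_minor(dosage)
    _warn_all_missing(dosage, variant_ids)
    return CohortGenotypes(
        sample_ids=sample_ids,
        variant_ids=variant_ids,
        phenotype=labels,
        dosage=dosage,
    )


def _warn_all_missing(dosage: np.ndarray, variant_ids: list[str]) -> None:
    if dosage.shape[1] == 0:
        return
    allmiss = (dosage == MISSING).all(axis=0)
    if allmiss.any():
        ids = [variant_ids[i] for i in np.where(allmiss)[0][:5]]
        warnings.warn(
            f"{int(allmiss.sum())} variant(s) with all-missing genotypes "
            f"(e.g. {ids}); retained",
            stacklevel=3,
        )


def write_genotypes(genotypes: CohortGenotypes, path: str | Path) -> None:
    """Write the TSV genotype dialect (lossless round-trip with read)."""
    df = pd.DataFrame(
        genotypes.dosage,
        index=pd.Index(genotypes.sample_ids, name="sample_id"),
        columns=genotypes.variant_ids,
    ).astype(object)
    df[df == MISSING] = "NA"
    df.insert(0, "phenotype", genotypes.phenotype)
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------


def validate_annotations(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a variant annotation table in place.

    Unknown functional classes are mapped to ``"other"`` (with a warning
    recording the count); duplicate ``(variant_id, gene)`` rows and
    out-of-range scores are hard errors.  One row per (variant, gene) pair
    is allowed; downstream set-unique logic deduplicates on variant_id.
    """
    for col in ("variant_id", "functional_class"):
        if col not in df.columns:
            raise ValueError(f"annotation table missing required column {col!r}")
    df = df.copy()
    for col in ANNOTATION_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    dup = df.duplicated(subset=["variant_id", "gene"], keep=False)
    if dup.any():
        ids = sorted(df.loc[dup, "variant_id"].unique()[:5])
        raise ValueError(f"duplicate variant_id rows: {ids}")
    unknown = ~df["functional_class"].isin(FUNCTIONAL_CLASSES)
    if unknown.any():
        warnings.warn(
            f"{int(unknown.sum())} annotation rows with unknown functional_class "
            "mapped to 'other'",
            stacklevel=2,
        )
        df.loc[unknown, "functional_class"] = "other"
    score = pd.to_numeric(df["condel_score"], errors="coerce")
    raw_present = df["condel_score"].notna()
    if (raw_present & score.isna()).any():
        raise ValueError("non-numeric condel_score values")
    out_of_range = score.notna() & ((score < 0) | (score > 1))
    if out_of_range.any():
        bad = df.loc[out_of_range, "variant_id"].tolist()[:5]
        raise ValueError(f"condel_score outside [0, 1] for variants {bad}")
    df["condel_score"] = score
    maf = pd.to_numeric(df["population_maf"], errors="coerce")
    if (maf.notna() & ((maf < 0) | (maf > 0.5))).any():
        raise ValueError("population_maf outside [0, 0.5]")
    df["population_maf"] = maf
    return df.reset_index(drop=True)


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read and validate a TSV variant annotation table."""
    df = pd.read_csv(path, sep="\t", comment="#")
    # tolerate textual booleans for the deleterious flag
    if "deleterious_flag" in df.columns and df["deleterious_flag"].dtype == object:
        df["deleterious_flag"] = df["deleterious_flag"].map(
            lambda x: {"true": True, "false": False}.get(str(x).strip().lower(), x)
        )
    return validate_annotations(df)


def write_annotations(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------


def _gene_set_from_gmt_fields(fields: Sequence[str]) -> GeneSet:
    members = [f.strip() for f in fields[2:] if f.strip()]
    return GeneSet(name=fields[0].strip(), members=frozenset(members))


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a gene set: one symbol per line, or a single GMT line."""
    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    if not lines:
        raise ValueError(f"{path}: empty gene list")
    if len(lines) == 1 and lines[0].count("\t") >= 2:
        return _gene_set_from_gmt_fields(lines[0].split("\t"))
    members = frozenset(l.strip() for l in lines)
    return GeneSet(name=name or Path(path).stem, members=members)


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read a multi-line GMT file into a list of gene sets."""
    sets = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
        sets.append(_gene_set_from_gmt_fields(fields))
    if not sets:
        raise ValueError(f"{path}: empty GMT file")
    return sets


# ---------------------------------------------------------------------------
# covariates and reports
# ---------------------------------------------------------------------------


def read_covariates(path: str | Path) -> CovariateTable:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    df = df.set_index(df.columns[0])
    df.index.name = "sample_id"
    return CovariateTable(df)


def write_covariates(cov: CovariateTable, path: str | Path) -> None:
    cov.df.to_csv(path, sep="\t")


def config_hash(config: Mapping | None) -> str:
    payload = repr(sorted((config or {}).items())).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_report(
    df: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    config: Mapping | None = None,
) -> None:
    """Write a result table as TSV with a provenance header comment.

    Numeric fields are written at full (round-trip) precision; the header
    records the RNG seed and a hash of the run configuration.
    """
    with open(path, "w") as fh:
        fh.write(f"# isub report; config_hash={config_hash(config)}; seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
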