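"""File formats and core data containers for the genomic-prediction pipeline.

Genotypes are biallelic SNP dosages coded as the count of alternate alleles
(0 = homozygous reference, 1 = heterozygous, 2 = homozygous alternate).
Phenotypes are long-format plot means, one row per genotype x environment x
trait.  Estimated breeding values (EBVs) are the per-genotype response
consumed by the whole-genome regression stage.

Two genotype dialects are supported: VCF (biallelic SNP records with a GT
field, read through cyvcf2) and ``dosage_tsv`` -- a tab-separated table with
a header row of marker identifiers and one row per sample, first column the
sample identifier, missing calls written as ``NA``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PHENOTYPE_COLUMNS = ("genotype_id", "environment_id", "trait_name", "value")


class ValidationError(ValueError):
    """Input violates a structural requirement (duplicates, bad dosage...)."""


class ParseError(ValueError):
    """A file could not be parsed as the requested format."""


class FormatError(ValueError):
    """A record is structurally valid but unsupported (e.g. multiallelic)."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """An N x M matrix of biallelic SNP dosages with missing-call mask.

    Parameters
    ----------
    sample_ids, marker_ids
        Unique identifiers for the N samples and M markers.
    dosages
        Integer array of shape (N, M); entries under ``missing_mask`` are
        placeholders and carry no information.
    missing_mask
        Boolean array of shape (N, M); True marks a missing call.
    """

    sample_ids: list
    marker_ids: list
    dosages: np.ndarray
    missing_mask: np.ndarray = None

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        self.dosages = np.asarray(self.dosages)
        n, m = self.dosages.shape
        if n < 1 or m < 1:
            raise ValidationError("genotype matrix must have >= 1 sample and >= 1 marker")
        if len(self.sample_ids) != n or len(self.marker_ids) != m:
            raise ValidationError("id lists do not match dosage matrix shape")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample id in genotype matrix")
        if len(set(self.marker_ids)) != m:
            raise ValidationError("duplicate marker id in genotype matrix")
        if self.missing_mask is None:
            self.missing_mask = np.zeros((n, m), dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != (n, m):
            raise ValidationError("missing_mask shape does not match dosages")
        observed = self.dosages[~self.missing_mask]
        if observed.size and not np.isin(observed, (0, 1, 2)).all():
            bad = observed[~np.isin(observed, (0, 1, 2))][0]
            raise ValidationError(f"dosage {bad!r} outside {{0,1,2}}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(self.missing_mask.any())

    def subset_samples(self, index) -> "GenotypeMatrix":
        """Row-subset by positional index, keeping all markers."""
        index = np.asarray(index)
        return GenotypeMatrix(
            [self.sample_ids[i] for i in index],
            list(self.marker_ids),
            self.dosages[index],
            self.missing_mask[index],
        )


@dataclass
class PhenotypeRecords:
    """Long-format multi-environment plot-mean phenotype observations.

    ``data`` has the four columns genotype_id, environment_id, trait_name,
    value; (genotype, environment, trait) triples are unique.  ``n_dropped``
    counts rows discarded on read because their value was not numeric.
    """

    data: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self):
        df = self.data
        missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"phenotype table lacks columns {missing}")
        if len(df) == 0:
            raise ValidationError("phenotype table has no usable rows")
        df = df.loc[:, list(PHENOTYPE_COLUMNS)].copy()
        df["genotype_id"] = df["genotype_id"].astype(str)
        df["environment_id"] = df["environment_id"].astype(str)
        df["trait_name"] = df["trait_name"].astype(str)
        df["value"] = pd.to_numeric(df["value"])
        if not np.isfinite(df["value"]).all():
            raise ValidationError("phenotype values must be finite")
        key = ["genotype_id", "environment_id", "trait_name"]
        if df.duplicated(key).any():
            dup = df[df.duplicated(key)].iloc[0]
            raise ValidationError(
                "duplicate phenotype record for "
                f"({dup.genotype_id}, {dup.environment_id}, {dup.trait_name})"
            )
        self.data = df.reset_index(drop=True)

    def traits(self) -> list:
        return sorted(self.data["trait_name"].unique())

    def genotypes(self) -> list:
        return sorted(self.data["genotype_id"].unique())

    def for_trait(self, trait_name: str) -> pd.DataFrame:
        sub = self.data[self.data["trait_name"] == trait_name]
        if len(sub) == 0:
            raise ValidationError(f"trait {trait_name!r} absent from phenotype table")
        return sub.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class EBVTable:
    """Per-genotype estimated breeding values for one trait (trait units)."""

    trait_name: str
    values: pd.Series  # index: genotype_id

    def __post_init__(self):
        s = pd.Series(self.values, dtype=float)
        s.index = s.index.astype(str)
        if s.index.duplicated().any():
            raise ValidationError("duplicate genotype in EBV table")
        if not np.isfinite(s.to_numpy()).all():
            raise ValidationError("EBVs must be finite")
        if len(s) == 0:
            raise ValidationError("EBV table is empty")
        self.values = s

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# genotype readers / writers
# ---------------------------------------------------------------------------

_MISSING_TOKENS = {"NA", "na", ".", "", "nan", "NaN"}


def read_genotype_matrix(path, format_name: str) -> GenotypeMatrix:
    """Read a genotype matrix from ``vcf`` or ``dosage_tsv`` format.

    VCF records must be biallelic SNPs; genotype calls are diploidized to
    alternate-allele counts in {0, 1, 2} and missing calls (``./.``) are
    flagged in the missing mask.
    """
    if format_name == "vcf":
        return _read_vcf(path)
    if format_name == "dosage_tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {format_name!r}")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise ParseError(f"cannot open VCF {path}: {exc}") from exc
    sample_ids = list(vcf.samples)
    marker_ids, columns, missing_cols = [], [], []
    for i, var in enumerate(vcf):
        marker = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        if len(var.ALT) != 1:
            raise FormatError(f"multiallelic record at marker {marker}")
        if len(var.REF) != 1 or len(var.ALT[0]) != 1:
            raise FormatError(f"non-SNP record at marker {marker}")
        gts = var.genotypes
        if gts is None or len(gts) != len(sample_ids):
            raise ParseError(f"record {i + 1} ({marker}): missing GT calls")
        dos = np.zeros(len(sample_ids), dtype=np.int16)
        miss = np.zeros(len(sample_ids), dtype=bool)
        for s, call in enumerate(gts):
            alleles = call[:-1]  # last element is the phasing flag
            if len(alleles) != 2 or any(a < 0 for a in alleles):
                miss[s] = True
            else:
                dos[s] = sum(1 for a in alleles if a > 0)
        marker_ids.append(marker)
        columns.append(dos)
        missing_cols.append(miss)
    if not marker_ids:
        raise ParseError(f"VCF {path} contains no variant records")
    dosages = np.column_stack(columns)
    missing = np.column_stack(missing_cols)
    return GenotypeMatrix(sample_ids, marker_ids, dosages, missing)


def _read_dosage_tsv(path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError(f"{path}: empty file")
        marker_ids = header.split("\t")[1:]
        if not marker_ids:
            raise ParseError(f"{path}, line 1: header row has no marker ids")
        sample_ids, rows, missing_rows = [], [], []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(marker_ids) + 1:
                raise ParseError(
                    f"{path}, line {lineno}: expected {len(marker_ids) + 1} "
                    f"fields, found {len(fields)}"
                )
            sample_ids.append(fields[0])
            dos = np.zeros(len(marker_ids), dtype=np.int16)
            miss = np.zeros(len(marker_ids), dtype=bool)
            for j, tok in enumerate(fields[1:]):
                if tok in _MISSING_TOKENS:
                    miss[j] = True
                    continue
                try:
                    val = float(tok)
                except ValueError as exc:
                    raise ParseError(
                        f"{path}, line {lineno}: non-numeric dosage {tok!r}"
                    ) from exc
                if val not in (0.0, 1.0, 2.0):
                    raise ValidationError(
                        f"{path}, line {lineno}, marker {marker_ids[j]}: "
                        f"dosage {tok!r} outside {{0,1,2}}"
                    )
                dos[j] = int(val)
            rows.append(dos)
            missing_rows.append(miss)
    if not rows:
        raise ParseError(f"{path}: no sample rows")
    return GenotypeMatrix(sample_ids, marker_ids, np.vstack(rows), np.vstack(missing_rows))


def write_genotype_matrix(g: GenotypeMatrix, path) -> None:
    """Write ``g`` in the dosage_tsv dialect (missing calls as ``NA``)."""
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(g.marker_ids) + "\n")
        for i, sid in enumerate(g.sample_ids):
            toks = [
                "NA" if g.missing_mask[i, j] else str(int(g.dosages[i, j]))
                for j in range(g.n_markers)
            ]
            fh.write(sid + "\t" + "\t".join(toks) + "\n")


def impute_missing_mode(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing calls by the per-marker modal dosage.

    Ties break toward the smaller dosage; a marker with no observed call at
    all cannot be imputed and raises.  Matrices with no missing calls are
    returned unchanged.
    """
    if not g.has_missing:
        return g
    dosages = g.dosages.copy()
    for j in np.flatnonzero(g.missing_mask.any(axis=0)):
        obs = g.dosages[~g.missing_mask[:, j], j]
        if obs.size == 0:
            raise ValidationError(f"marker {g.marker_ids[j]} has no observed calls")
        counts = np.bincount(obs, minlength=3)
        mode = int(np.argmax(counts))  # argmax takes the first max -> smaller dosage
        dosages[g.missing_mask[:, j], j] = mode
    return GenotypeMatrix(
        list(g.sample_ids), list(g.marker_ids), dosages,
        np.zeros_like(g.missing_mask),
    )


# ---------------------------------------------------------------------------
# phenotype / EBV tables
# ---------------------------------------------------------------------------


def read_phenotype_table(path) -> PhenotypeRecords:
    """Read a delimited phenotype table (CSV or TSV, four named columns).

    Rows whose value is not numeric are dropped and counted in the returned
    ``n_dropped`` -- field data routinely has gaps -- rather than raising.
    """
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    except Exception as exc:
        raise ParseError(f"cannot parse phenotype table {path}: {exc}") from exc
    if df.empty:
        raise ValidationError(f"phenotype table {path} is empty")
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: phenotype table lacks columns {missing}")
    values = pd.to_numeric(df["value"], errors="coerce")
    dropped = int(values.isna().sum())
    if dropped:
        logger.warning("dropped %d phenotype rows with non-numeric values", dropped)
    df = df[values.notna()].copy()
    df["value"] = values[values.notna()]
    if df.empty:
        raise ValidationError(f"phenotype table {path} has no numeric rows")
    return PhenotypeRecords(df, n_dropped=dropped)


def write_phenotype_table(ph: PhenotypeRecords, path) -> None:
    ph.data.to_csv(path, sep="\t", index=False)


def write_ebv_table(ebv: EBVTable, path) -> None:
    df = pd.DataFrame({"genotype_id": ebv.values.index, "ebv": ebv.values.to_numpy()})
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_ebv_table(path, trait_name: str = "trait") -> EBVTable:
    df = pd.read_csv(path, sep="\t", dtype={"genotype_id": str})
    if "genotype_id" not in df.columns or "ebv" not in df.columns:
        raise ValidationError(f"{path}: EBV table needs columns genotype_id, ebv")
    return EBVTable(trait_name, pd.Series(df["ebv"].to_numpy(), index=df["genotype_id"]))


# ---------------------------------------------------------------------------
# cross-validation reports
# ---------------------------------------------------------------------------

_REPORT_COLUMNS = [
    "trait", "method", "k", "repeats", "n_folds_dropped",
    "accuracy", "repeat_means", "fold_correlations",
]


def write_cv_report(results, path, precision: int = 6) -> None:
    """Write one TSV row per (trait, method) cross-validation result.

    Accepts a single result or a list; per-fold and per-repeat correlations
    are comma-joined at the stated precision so the file round-trips
    losslessly through :func:`read_cv_report`.
    """
    if not isinstance(results, (list, tuple)):
        results = [results]
    if len(results) == 0:
        raise ValidationError("no cross-validation results to write")
    fmt = f"%.{precision}f"
    with open(path, "w") as fh:
        fh.write("\t".join(_REPORT_COLUMNS) + "\n")
        for res in results:
            if len(res.fold_correlations) == 0:
                raise ValidationError(
                    f"result for {res.trait_name}/{res.method} has no folds"
                )
            row = [
                res.trait_name,
                res.method,
                str(res.k),
                str(res.repeats),
                str(res.n_folds_dropped),
                fmt % res.accuracy,
                ",".join(fmt % v for v in res.repeat_means),
                ",".join(fmt % v for v in res.fold_correlations),
            ]
            fh.write("\t".join(row) + "\n")


def read_cv_report(path) -> pd.DataFrame:
    """Read a CV report back into a DataFrame (correlation columns as lists)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != _REPORT_COLUMNS:
        raise ParseError(f"{path}: not a CV report (columns {list(df.columns)})")
    for col in ("k", "repeats", "n_folds_dropped"):
        df[col] = df[col].astype(int)
    df["accuracy"] = df["accuracy"].astype(float)
    for col in ("repeat_means", "fold_correlations"):
        df[col] = df[col].map(lambda s: [float(t) for t in s.split(",")])
    return df
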