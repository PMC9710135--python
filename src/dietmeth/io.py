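"""Readers, writers and validation for beta matrices, sample sheets and probe manifests.

All on-disk formats are tab-separated UTF-8 text with ``.`` as the decimal
point and the literal string ``NA`` for missing values, matching common
methylation-matrix exports.  In memory everything is a :class:`pandas.DataFrame`:

* **beta matrix** — CpG probes as the index (``probe_id``), samples as columns,
  methylation fractions in ``[0, 1]`` (``NaN`` = missing);
* **sample sheet** — one row per sample with columns
  ``sample_id, patient_id, timepoint, group, tissue, fibrosis_grade``;
* **probe manifest** — indexed by ``probe_id`` with columns
  ``chromosome, gene_id, gene_region, cgi_relation, regulatory_feature``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "TIMEPOINTS",
    "GROUPS",
    "TISSUES",
    "GENE_REGIONS",
    "CGI_RELATIONS",
    "REGULATORY_FEATURES",
    "read_beta_matrix",
    "write_beta_matrix",
    "validate_beta_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "validate_sample_sheet",
    "read_manifest",
    "write_manifest",
    "validate_manifest",
    "map_probes_to_genes",
]


class FormatError(ValueError):
    """A file does not have the expected shape/header structure."""


class ValidationError(ValueError):
    """Structurally well-formed data violates a domain invariant."""


#: Study timepoints: baseline, after 30 days, after 60 days.
TIMEPOINTS = ("T1", "T2", "T3")
GROUPS = ("study", "healthy_blood", "healthy_liver", "nafld_liver")
TISSUES = ("blood", "liver")

#: Probe location relative to gene structure (EPIC-manifest style).
GENE_REGIONS = (
    "TSS1500",
    "TSS200",
    "5'UTR",
    "1stExon",
    "ExonBoundary",
    "GeneBody",
    "3'UTR",
    "intergenic",
)
#: Probe position relative to a CpG island.
CGI_RELATIONS = (
    "Island",
    "NorthShore",
    "SouthShore",
    "NorthShelf",
    "SouthShelf",
    "OpenSea",
)
#: Ensembl-style regulatory-build annotation.
REGULATORY_FEATURES = (
    "Promoter",
    "PromoterFlanking",
    "Enhancer",
    "CTCF",
    "OpenChromatin",
    "TFBS",
    "none",
)

SAMPLE_SHEET_COLUMNS = (
    "sample_id",
    "patient_id",
    "timepoint",
    "group",
    "tissue",
    "fibrosis_grade",
)
MANIFEST_COLUMNS = (
    "chromosome",
    "gene_id",
    "gene_region",
    "cgi_relation",
    "regulatory_feature",
)

_NA = "NA"


# ---------------------------------------------------------------------------
# beta matrix
# ---------------------------------------------------------------------------

def validate_beta_matrix(betas: pd.DataFrame) -> pd.DataFrame:
    """Check beta-matrix invariants and return the (unchanged) frame.

    Raises
    ------
    ValidationError
        on duplicate probe/sample IDs or any value outside ``[0, 1]``;
        the error message names the offending probe and sample.
    """
    if betas.index.has_duplicates:
        dups = betas.index[betas.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate probe IDs: {dups[:5]}")
    if betas.columns.has_duplicates:
        dups = betas.columns[betas.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample IDs: {dups[:5]}")
    values = betas.to_numpy(dtype=float)
    bad = (values < 0.0) | (values > 1.0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"beta value out of [0, 1]: probe {betas.index[i]!r}, "
            f"sample {betas.columns[j]!r}, value {values[i, j]}"
        )
    return betas


def read_beta_matrix(path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a probe × sample beta matrix from delimited text.

    The first row must be the sample header (first cell names the probe-ID
    column), the first column the probe IDs.  ``NA`` marks missing values.
    """
    try:
        betas = pd.read_csv(
            path,
            sep=delimiter,
            index_col=0,
            na_values=[_NA],
            keep_default_na=False,
        )
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if betas.shape[0] == 0 or betas.shape[1] == 0:
        raise FormatError(f"{path}: no data rows/columns found")
    try:
        betas = betas.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric beta values: {exc}") from exc
    betas.index = betas.index.astype(str)
    betas.index.name = "probe_id"
    betas.columns = betas.columns.astype(str)
    return validate_beta_matrix(betas)


def write_beta_matrix(betas: pd.DataFrame, path) -> None:
    """Write a beta matrix as TSV (6 decimal places, ``NA`` for missing).

    Round-trips through :func:`read_beta_matrix` to 1e-6.
    """
    if betas.shape[0] == 0 or betas.shape[1] == 0:
        raise ValidationError("refusing to write a beta matrix with no probes or no samples")
    validate_beta_matrix(betas)
    out = betas.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", float_format="%.6f", na_rep=_NA)


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

def validate_sample_sheet(sheet: pd.DataFrame, betas: pd.DataFrame | None = None) -> pd.DataFrame:
    """Check sample-sheet invariants; optionally cross-check against a beta matrix."""
    missing = set(SAMPLE_SHEET_COLUMNS) - set(sheet.columns)
    if missing:
        raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
    if sheet["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in sample sheet")
    for col, vocab in (
        ("timepoint", TIMEPOINTS),
        ("group", GROUPS),
        ("tissue", TISSUES),
    ):
        vals = sheet[col].dropna()
        bad = set(vals) - set(vocab)
        if bad:
            raise ValidationError(f"unknown {col} value(s): {sorted(bad)}")
    grades = sheet["fibrosis_grade"].dropna()
    if not grades.isin([0, 1, 2, 3]).all():
        raise ValidationError("fibrosis_grade must be in {0,1,2,3} or NA")
    graded = sheet[sheet["fibrosis_grade"].notna()]
    wrong = graded[(graded["tissue"] != "liver") | (graded["group"] != "nafld_liver")]
    if len(wrong):
        raise ValidationError(
            "fibrosis_grade set outside liver/nafld_liver samples: "
            f"{wrong['sample_id'].tolist()[:5]}"
        )
    study = sheet[sheet["group"] == "study"]
    if study.duplicated(subset=["patient_id", "timepoint"]).any():
        raise ValidationError("duplicate (patient_id, timepoint) within study group")
    if betas is not None:
        sheet_ids = set(sheet["sample_id"])
        matrix_ids = list(betas.columns)
        absent = [s for s in matrix_ids if s not in sheet_ids]
        if absent:
            raise ValidationError(f"matrix samples absent from sheet: {absent[:5]}")
    return sheet


def read_sample_sheet(path, delimiter: str = "\t") -> pd.DataFrame:
    try:
        sheet = pd.read_csv(
            path,
            sep=delimiter,
            na_values=[_NA],
            keep_default_na=False,
            dtype={"sample_id": str, "patient_id": str},
        )
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if "fibrosis_grade" in sheet.columns:
        sheet["fibrosis_grade"] = pd.to_numeric(sheet["fibrosis_grade"], errors="raise")
    return validate_sample_sheet(sheet)


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    validate_sample_sheet(sheet)
    out = sheet.copy()
    # grades as integers on disk, not 3.0
    out["fibrosis_grade"] = out["fibrosis_grade"].map(
        lambda g: _NA if pd.isna(g) else str(int(g))
    )
    out.to_csv(path, sep="\t", index=False, na_rep=_NA)


# ---------------------------------------------------------------------------
# probe manifest
# ---------------------------------------------------------------------------

def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise FormatError(f"manifest missing columns: {sorted(missing)}")
    if manifest.index.has_duplicates:
        raise ValidationError("duplicate probe_id in manifest")
    for col, vocab in (
        ("gene_region", GENE_REGIONS),
        ("cgi_relation", CGI_RELATIONS),
        ("regulatory_feature", REGULATORY_FEATURES),
    ):
        bad = set(manifest[col].dropna()) - set(vocab)
        if bad:
            raise ValidationError(f"unknown {col} value(s): {sorted(bad)}")
    return manifest


def read_manifest(path, delimiter: str = "\t") -> pd.DataFrame:
    try:
        manifest = pd.read_csv(
            path,
            sep=delimiter,
            index_col=0,
            na_values=[_NA],
            keep_default_na=False,
            dtype=str,
        )
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    manifest.index = manifest.index.astype(str)
    manifest.index.name = "probe_id"
    return validate_manifest(manifest)


def write_manifest(manifest: pd.DataFrame, path) -> None:
    validate_manifest(manifest)
    out = manifest.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", na_rep=_NA)


def map_probes_to_genes(probes, manifest: pd.DataFrame) -> set[str]:
    """Collapse a probe set to its deduplicated set of annotated gene IDs.

    Probes without a gene annotation (intergenic, ``gene_id`` = NA) contribute
    nothing.  Each probe carries at most one gene ID by manifest design.

    Raises
    ------
    KeyError
        if any probe is absent from the manifest.
    """
    probes = list(probes)
    absent = [p for p in probes if p not in manifest.index]
    if absent:
        raise KeyError(f"probe(s) absent from manifest: {absent[:5]}")
    genes = manifest.loc[probes, "gene_id"].dropna()
    return set(genes)
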