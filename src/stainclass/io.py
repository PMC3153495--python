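"""Cohort table input/output and genotype parsing.

A cohort is a tab-separated table, one row per tumor, carrying the
sequencing genotype, the tumor-cell content of the section, the staining
readings (intensity and percent positive) for the four antibodies, and
optional treatment/outcome columns.  The first line of a file written by
this package is a version comment (``# stainclass-cohort-v1``); comment
lines are skipped on read.

Genotypes are strings over a controlled vocabulary of EGFR tyrosine-kinase
domain mutation tokens joined by ``+`` for complex (multi-mutation) tumors,
or the literal ``wild``.  :func:`parse_genotype` derives the boolean labels
the classifiers train and evaluate against.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "GenotypeLabels",
    "GenotypeParseError",
    "CohortFormatError",
    "CohortValidationError",
    "EmptyInputError",
    "ExclusionReport",
    "parse_genotype",
    "read_cohort",
    "write_cohort",
    "MARKERS",
    "STAIN_COLUMNS",
    "REQUIRED_COLUMNS",
    "OUTCOME_COLUMNS",
]

COHORT_FORMAT_TAG = "# stainclass-cohort-v1"

MARKERS = ("l858r", "del19", "total_egfr", "panck")
STAIN_COLUMNS = tuple(
    f"{m}_{kind}" for m in MARKERS for kind in ("intensity", "percent")
)
REQUIRED_COLUMNS = ("patient_id", "genotype", "tumor_content") + STAIN_COLUMNS
OUTCOME_COLUMNS = (
    "sex",
    "smoking",
    "recurrence",
    "tki_treated",
    "treatment_line",
    "ecog_ps",
    "response",
    "pfs_months",
    "pfs_event",
    "ihc_positive",
)

# Exon-19 in-frame deletions (E746-A750 is the most common form).  The
# exon-18 deletion delE709-T710insD is deliberately NOT in this set.
DEL19_TOKENS = frozenset(
    {"delE746-A750", "delL747-T751", "delL747-P753", "delE746-T751insQ"}
)
POINT_TOKENS = frozenset(
    {
        "L858R",
        "V834L",
        "E709V",
        "E709K",
        "T790M",
        "K757N",
        "G719A",
        "G719S",
        "L861Q",
        "L861R",
        "K860I",
        "R831C",
    }
)
OTHER_TOKENS = frozenset({"N771-H773dupNPH", "delE709-T710insD"})
MUTATION_TOKENS = DEL19_TOKENS | POINT_TOKENS | OTHER_TOKENS
WILD_TOKEN = "wild"


class GenotypeParseError(ValueError):
    """A genotype string contains a token outside the controlled vocabulary."""


class CohortFormatError(ValueError):
    """The cohort file is structurally malformed (header, duplicate ids)."""


class CohortValidationError(ValueError):
    """One or more rows violate the staining/genotype invariants."""


class EmptyInputError(ValueError):
    """The cohort file contains no data rows."""


@dataclass(frozen=True)
class GenotypeLabels:
    """Boolean labels derived from a sequencing genotype string."""

    is_l858r: bool
    is_e746_a750: bool
    is_del19: bool
    is_any_mutation: bool
    is_complex: bool
    is_classical_pattern: bool


def parse_genotype(genotype: str) -> GenotypeLabels:
    """Parse a genotype string into classification labels.

    Components are joined by ``+``; a tumor is *complex* when it carries
    two or more concomitant mutations, and shows the *classical pattern*
    when a complex genotype contains L858R or any exon-19 deletion.
    ``is_e746_a750`` implies ``is_del19`` implies ``is_any_mutation``.
    """
    s = str(genotype).strip()
    if not s:
        raise GenotypeParseError("empty genotype string")
    if s == WILD_TOKEN:
        return GenotypeLabels(False, False, False, False, False, False)
    components = [c.strip() for c in s.split("+")]
    unknown = [c for c in components if c not in MUTATION_TOKENS]
    if unknown:
        raise GenotypeParseError(
            f"unknown genotype token(s) {unknown!r}; valid tokens are "
            f"{sorted(MUTATION_TOKENS) + [WILD_TOKEN]}"
        )
    is_l858r = "L858R" in components
    is_e746 = "delE746-A750" in components
    is_del19 = any(c in DEL19_TOKENS for c in components)
    is_complex = len(components) >= 2
    return GenotypeLabels(
        is_l858r=is_l858r,
        is_e746_a750=is_e746,
        is_del19=is_del19,
        is_any_mutation=True,
        is_complex=is_complex,
        is_classical_pattern=is_complex and (is_l858r or is_del19),
    )


@dataclass(frozen=True)
class ExclusionReport:
    """Accounting of rows dropped while loading a cohort.

    ``n_input == n_low_tumor_content + n_failed_quality + n_retained``.
    """

    n_input: int
    n_low_tumor_content: int
    n_failed_quality: int
    n_retained: int


def _validate_rows(df: pd.DataFrame) -> None:
    problems: list[str] = []
    for col in STAIN_COLUMNS + ("tumor_content",):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna()
        if col.endswith("_intensity"):
            bad |= (values % 1 != 0) | (values < 0) | (values > 3)
        elif col.endswith("_percent"):
            bad |= (values < 0) | (values > 100)
        else:  # tumor_content
            bad |= (values < 0) | (values > 100)
        for idx in df.index[bad]:
            problems.append(f"row {idx + 1}: invalid {col} = {df.at[idx, col]!r}")
    for idx, g in df["genotype"].items():
        try:
            parse_genotype(g)
        except GenotypeParseError as exc:
            problems.append(f"row {idx + 1}: {exc}")
    if problems:
        raise CohortValidationError("; ".join(problems))


def read_cohort(
    path,
    tumor_content_min: float = 60.0,
    require_panck: bool = True,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Load and validate a cohort TSV.

    Rows whose section contains fewer than ``tumor_content_min`` percent
    tumor cells are excluded (sequencing of low-purity sections is
    unreliable), as are rows whose pan-cytokeratin control did not stain
    (``require_panck``; a non-reactive section cannot be interpreted).
    Both exclusions are counted in the returned :class:`ExclusionReport`.
    Malformed files or rows raise instead of being silently dropped.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"genotype": str})
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: no data rows") from exc
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"{path}: missing required column(s) {missing}")
    dupes = df["patient_id"][df["patient_id"].duplicated()].tolist()
    if dupes:
        raise CohortFormatError(f"{path}: duplicate patient id(s) {dupes}")
    df = df.reset_index(drop=True)
    _validate_rows(df)

    low = df["tumor_content"].astype(float) < float(tumor_content_min)
    n_low = int(low.sum())
    kept = df[~low]
    n_quality = 0
    if require_panck:
        no_panck = kept["panck_intensity"].astype(int) == 0
        n_quality = int(no_panck.sum())
        kept = kept[~no_panck]
    report = ExclusionReport(
        n_input=len(df),
        n_low_tumor_content=n_low,
        n_failed_quality=n_quality,
        n_retained=len(kept),
    )
    return kept.reset_index(drop=True), report


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort table as versioned TSV (column order normalized)."""
    ordered = [c for c in REQUIRED_COLUMNS if c in df.columns]
    ordered += [c for c in OUTCOME_COLUMNS if c in df.columns]
    ordered += [c for c in df.columns if c not in ordered]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(COHORT_FORMAT_TAG + "\n")
        df[ordered].to_csv(fh, sep="\t", index=False)
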