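"""Quickscore quantification of immunohistochemical (IHC) staining.

Each tumor section is stained with up to four antibodies: two EGFR
mutation-specific antibodies (one against the L858R point mutation, one
against the E746-A750 exon-19 deletion), a total-EGFR antibody, and a
pan-cytokeratin control used as a tissue-quality gate.  For each antibody a
pathologist records an ordinal staining intensity ``I`` (0 none, 1+ weak,
2+ moderate, 3+ strong) and the percentage ``P`` of tumor cells showing
characteristic staining.  The quickscore ``Q = P * I`` (range 0-300) is the
semi-quantitative readout used throughout the package.

The legacy single-marker positivity rule used by most published IHC studies
of these antibodies — more than 10% of tumor cells stained at intensity 1+
or higher — is provided by :func:`intensity_positive`.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

__all__ = [
    "Marker",
    "StainRecord",
    "StainValidationError",
    "quickscore",
    "intensity_positive",
]

MAX_INTENSITY = 3
MAX_QUICKSCORE = 300.0


class Marker(str, Enum):
    """Antibody identity for a staining reading.

    ``DEL19`` denotes the E746-A750-deletion-specific antibody (commonly
    called the "del-19 antibody" even though it targets one specific
    exon-19 deletion).
    """

    L858R = "l858r"
    DEL19 = "del19"
    TOTAL_EGFR = "total_egfr"
    PAN_CK = "panck"


class StainValidationError(ValueError):
    """A staining reading violates the scoring-scale invariants.

    The message names the offending field.
    """


def _validate(intensity: float, percent_positive: float) -> None:
    if not float(intensity).is_integer() or not 0 <= intensity <= MAX_INTENSITY:
        raise StainValidationError(
            f"intensity must be an integer in 0..{MAX_INTENSITY}, got {intensity!r}"
        )
    if not 0.0 <= percent_positive <= 100.0:
        raise StainValidationError(
            f"percent_positive must lie in [0, 100], got {percent_positive!r}"
        )


@dataclass(frozen=True)
class StainRecord:
    """One antibody's consensus reading on one tumor section.

    Parameters
    ----------
    antibody:
        Which antibody produced the reading.
    intensity:
        Ordinal staining intensity, integer 0-3.
    percent_positive:
        Percent of tumor cells stained, in [0, 100].  With intensity 0 any
        percent is accepted (the quickscore collapses to 0 regardless).
    """

    antibody: Marker
    intensity: int
    percent_positive: float

    def __post_init__(self) -> None:
        _validate(self.intensity, self.percent_positive)


def quickscore(record: StainRecord) -> float:
    """Quickscore ``Q = P * I`` of a staining reading, in [0, 300].

    ``Q`` is 0 exactly when the intensity is 0 or no cells stain; the
    maximum, 300, corresponds to every tumor cell staining strongly
    (``I = 3``, ``P = 100``).
    """
    _validate(record.intensity, record.percent_positive)
    return float(record.percent_positive) * float(record.intensity)


def intensity_positive(
    record: StainRecord,
    min_intensity: int = 1,
    min_percent: float = 10.0,
) -> bool:
    """Legacy single-marker positivity call.

    True iff the intensity is at least ``min_intensity`` and *more than*
    ``min_percent`` percent of tumor cells stain (strict inequality on the
    percent, matching the usual "more than 10% of tumor cells at 1+ or
    more" phrasing; a section with exactly 10% is negative).
    """
    _validate(record.intensity, record.percent_positive)
    return (
        record.intensity >= min_intensity
        and record.percent_positive > min_percent
    )
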