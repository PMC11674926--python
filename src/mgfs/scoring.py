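"""Projection, octant classification and the MGFS.

An individual is projected into the fitted component space by z-scoring
their nine measures against the reference means/SDs, rotating with the
stored eigenvectors, and dividing each component score by sqrt(lambda_k) so
every coordinate has unit variance in the reference population.  The sign
pattern of the (three) coordinates places the individual in one of eight
octants; octant I (+,+,+) is the best clinical status and octant VII
(-,-,-) the worst.

The Multidimensional General Functionality Score (MGFS) collapses the
z-scored coordinates onto the unit diagonal (1,..,1)/sqrt(k) — the gradient
from the all-negative corner to the all-positive corner.  Because the
reference density in this space is a spherical multivariate normal, the
diagonal projection is standard normal, so its one-sided quantile Phi(t)
times 10 gives a 0-10 score: the fraction of the reference population with
lower general functionality, scaled by ten.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
from scipy.special import ndtr

from .core_model import MGFSError, MissingValueError, NormativeModel, PhenotypeRecord

logger = logging.getLogger("mgfs")

#: Fixed roman-numeral table for the eight sign octants.  Only I (+,+,+) and
#: VII (-,-,-) are clinically pinned (best/worst corners); the remaining
#: numerals follow this documented convention.
ROMAN_OCTANTS: dict[tuple[str, str, str], str] = {
    ("+", "+", "+"): "I",
    ("-", "+", "+"): "II",
    ("-", "-", "+"): "III",
    ("+", "-", "+"): "IV",
    ("+", "+", "-"): "V",
    ("-", "+", "-"): "VI",
    ("-", "-", "-"): "VII",
    ("+", "-", "-"): "VIII",
}


@dataclass(frozen=True)
class PCScore:
    """z-scored component coordinates of one subject (unit reference variance)."""

    coords: tuple[float, ...]
    subject_id: str = "?"
    timepoint: str | None = None

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.coords):
            raise MGFSError(f"subject {self.subject_id!r}: non-finite PC coordinates")

    @property
    def k(self) -> int:
        return len(self.coords)


@dataclass(frozen=True)
class OctantLabel:
    """Sign pattern of the coordinates, with a roman numeral when k = 3."""

    signs: tuple[str, ...]
    roman: str | None

    def __str__(self) -> str:
        return ",".join(self.signs)


@dataclass(frozen=True)
class MGFSResult:
    """Diagonal projection, quantile and 0-10 score for one subject."""

    projection: float
    quantile: float
    mgfs: float
    mgfs_display: float
    octant: OctantLabel
    coords: tuple[float, ...]
    subject_id: str = "?"
    timepoint: str | None = None


def round_half_away(value: float, decimals: int = 1) -> float:
    """Round with ties going away from zero (matches printed score precision)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def project(model: NormativeModel, record: PhenotypeRecord) -> PCScore:
    """Project a subject into the model's z-scored component space.

    coords_k = (sum_j u_jk (x_j - mu_j) / sigma_j) / sqrt(lambda_k).
    A subject equal to the reference means lands at the origin.
    """
    x = record.as_array(model.variable_order)
    if not np.isfinite(x).all():
        raise MissingValueError(f"subject {record.subject_id!r}: incomplete record")
    z = (x - model.means) / model.sds
    coords = (z @ model.rotation) / np.sqrt(model.eigenvalues)
    return PCScore(tuple(float(c) for c in coords),
                   subject_id=record.subject_id, timepoint=record.timepoint)


def project_matrix(model: NormativeModel, x: np.ndarray) -> np.ndarray:
    """Vectorized projection of an n x p raw-measure matrix to n x k coords."""
    z = (np.asarray(x, dtype=float) - model.means) / model.sds
    return (z @ model.rotation) / np.sqrt(model.eigenvalues)


def octant_of(score: PCScore) -> OctantLabel:
    """Sign octant of the coordinates; a zero coordinate counts as '+'.

    The roman numeral is defined for k = 3 only (eight octants); for other
    dimensions the sign tuple alone labels the sector.
    """
    signs = tuple("-" if c < 0 else "+" for c in score.coords)
    roman = ROMAN_OCTANTS.get(signs) if len(signs) == 3 else None  # type: ignore[arg-type]
    return OctantLabel(signs=signs, roman=roman)


def mgfs(score: PCScore) -> MGFSResult:
    """MGFS of a PC score: 10 * Phi(sum(coords) / sqrt(k)).

    The projection onto the unit diagonal of a spherical standard normal is
    itself standard normal, so Phi gives the one-sided reference quantile.
    The result lies strictly inside (0, 10) and increases in every
    coordinate; the display value is rounded to one decimal.
    """
    proj = float(sum(score.coords)) / math.sqrt(score.k)
    quantile = float(ndtr(proj))
    value = 10.0 * quantile
    return MGFSResult(
        projection=proj,
        quantile=quantile,
        mgfs=value,
        mgfs_display=round_half_away(value, 1),
        octant=octant_of(score),
        coords=score.coords,
        subject_id=score.subject_id,
        timepoint=score.timepoint,
    )


def score_individual(model: NormativeModel, record: PhenotypeRecord) -> MGFSResult:
    """Project a subject and compute their octant and MGFS in one step."""
    return mgfs(project(model, record))


@dataclass(frozen=True)
class LongitudinalDelta:
    """Change between two consecutive timepoints of one subject."""

    subject_id: str
    timepoint_from: str | None
    timepoint_to: str | None
    delta_mgfs: float
    delta_coords: tuple[float, ...]
    octant_from: OctantLabel
    octant_to: OctantLabel


def longitudinal_compare(results: Iterable[MGFSResult]) -> list[LongitudinalDelta]:
    """Per-subject deltas between consecutive timepoints (later minus earlier).

    Results are grouped by ``subject_id`` preserving input order within a
    subject (the caller orders by timepoint).  Subjects with a single
    timepoint are skipped with a warning.
    """
    by_subject: dict[str, list[MGFSResult]] = {}
    for res in results:
        by_subject.setdefault(res.subject_id, []).append(res)
    deltas: list[LongitudinalDelta] = []
    for sid, series in by_subject.items():
        if len(series) < 2:
            logger.warning("subject %r has a single timepoint; skipped", sid)
            continue
        for earlier, later in zip(series, series[1:]):
            deltas.append(LongitudinalDelta(
                subject_id=sid,
                timepoint_from=earlier.timepoint,
                timepoint_to=later.timepoint,
                delta_mgfs=later.mgfs - earlier.mgfs,
                delta_coords=tuple(b - a for a, b in zip(earlier.coords, later.coords)),
                octant_from=earlier.octant,
                octant_to=later.octant,
            ))
    return deltas


def score_cohort(model: NormativeModel, records: Sequence[PhenotypeRecord]) -> list[MGFSResult]:
    """Score every record; errors name the offending subject."""
    return [score_individual(model, rec) for rec in records]
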