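"""Normative reference model for autistic phenotype heterogeneity.

The reference model is a standardized principal component analysis of nine
per-subject phenotype measures: the three Vineland Adaptive Behavior Scales
(VABS) standard scores, the three ADI-R algorithm scores, Total IQ, and the
two CBCL problem T-scores.  Each variable is z-scored against the reference
cohort, the correlation matrix is eigendecomposed, components are retained by
a Kaiser-style eigenvalue rule with a cumulative-variance fallback, and each
retained component is given a deterministic sign by anchoring it to a named
variable.  The fitted model (means, SDs, rotation, eigenvalues) is everything
needed to project new individuals into the reference coordinate system.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("mgfs")

#: Canonical order of the nine phenotype measures.  Everything downstream —
#: rotation rows, CSV columns, synthetic targets — follows this order.
VARIABLE_ORDER: tuple[str, ...] = (
    "vabs_communication",
    "vabs_socialization",
    "vabs_dls",
    "adi_social",
    "adi_communication",
    "adi_rrb",
    "total_iq",
    "cbcl_internalizing",
    "cbcl_externalizing",
)

#: ADI-R algorithm scores are symptom counts and cannot be negative.
NONNEGATIVE_VARIABLES: tuple[str, ...] = ("adi_social", "adi_communication", "adi_rrb")

#: Default anchor per component index: (variable, required sign of the
#: variable-component correlation).  PC1 points toward better adaptive
#: functioning (VABS Communication positive), PC2 toward fewer behavior
#: problems (CBCL Internalizing negative), PC3 toward higher ADI-R
#: Communication scores.  PCA itself leaves each axis's sign arbitrary; the
#: anchors pin the orientation so that fitted loadings are reproducible.
DEFAULT_ANCHORS: tuple[tuple[str, int], ...] = (
    ("vabs_communication", +1),
    ("cbcl_internalizing", -1),
    ("adi_communication", +1),
)


class MGFSError(Exception):
    """Base class for domain errors raised by this package."""


class ZeroVarianceError(MGFSError):
    """A variable has zero sample variance; z-scoring is undefined."""


class MissingValueError(MGFSError):
    """A record is incomplete; the model is complete-case only."""


class SchemaError(MGFSError):
    """A persisted document does not match the expected schema."""


@dataclass(frozen=True)
class PhenotypeRecord:
    """One subject's nine raw phenotype measures.

    VABS standard scores are higher-is-better; ADI-R algorithm scores and
    CBCL T-scores are higher-is-worse; Total IQ is higher-is-better.  All
    nine measures must be present and finite (complete-case requirement).
    """

    subject_id: str
    vabs_communication: float
    vabs_socialization: float
    vabs_dls: float
    adi_social: float
    adi_communication: float
    adi_rrb: float
    total_iq: float
    cbcl_internalizing: float
    cbcl_externalizing: float
    timepoint: str | None = None

    def __post_init__(self) -> None:
        for name in VARIABLE_ORDER:
            value = getattr(self, name)
            if value is None or not math.isfinite(float(value)):
                raise MissingValueError(
                    f"subject {self.subject_id!r}: measure {name!r} is missing or non-finite"
                )
        for name in NONNEGATIVE_VARIABLES:
            if float(getattr(self, name)) < 0:
                raise MGFSError(
                    f"subject {self.subject_id!r}: {name!r} must be >= 0, got {getattr(self, name)}"
                )

    def as_array(self, variable_order: Sequence[str] = VARIABLE_ORDER) -> np.ndarray:
        return np.array([float(getattr(self, v)) for v in variable_order], dtype=float)

    @classmethod
    def from_mapping(cls, data: Mapping[str, object]) -> "PhenotypeRecord":
        known = {f.name for f in dc_fields(cls)}
        kwargs = {k: v for k, v in data.items() if k in known}
        kwargs.setdefault("subject_id", "?")
        return cls(**kwargs)  # type: ignore[arg-type]


@dataclass
class ReferenceCohort:
    """An ordered collection of complete phenotype records.

    Wraps a DataFrame whose columns are ``variable_order`` plus optional
    ``subject_id`` / ``timepoint``; row order is preserved.
    """

    data: pd.DataFrame
    variable_order: tuple[str, ...] = VARIABLE_ORDER

    def __post_init__(self) -> None:
        missing = [v for v in self.variable_order if v not in self.data.columns]
        if missing:
            raise SchemaError(f"cohort is missing variable columns: {missing}")
        self.variable_order = tuple(self.variable_order)

    @classmethod
    def from_records(cls, records: Iterable[PhenotypeRecord],
                     variable_order: Sequence[str] = VARIABLE_ORDER) -> "ReferenceCohort":
        rows = []
        for rec in records:
            row = {"subject_id": rec.subject_id, "timepoint": rec.timepoint}
            row.update({v: float(getattr(rec, v)) for v in variable_order})
            rows.append(row)
        if not rows:
            raise MGFSError("cohort is empty")
        return cls(pd.DataFrame(rows), tuple(variable_order))

    @property
    def n(self) -> int:
        return len(self.data)

    def values(self) -> np.ndarray:
        """n x p matrix of raw measures in canonical column order."""
        return self.data.loc[:, list(self.variable_order)].to_numpy(dtype=float)

    def records(self) -> list[PhenotypeRecord]:
        out = []
        for i, row in self.data.iterrows():
            payload = {v: row[v] for v in self.variable_order}
            payload["subject_id"] = str(row.get("subject_id", i))
            tp = row.get("timepoint")
            payload["timepoint"] = None if tp is None or (isinstance(tp, float) and math.isnan(tp)) else str(tp)
            out.append(PhenotypeRecord(**payload))
        return out


@dataclass(frozen=True)
class SelectionRule:
    """Component-retention rule.

    Components with eigenvalue at or above ``eigenvalue_cutoff`` are kept
    (the boundary is kept when ``inclusive``); if their cumulative explained
    variance falls short of ``cumulative_cutoff``, further components are
    added until it is reached.  The cumulative rule only ever extends the
    eigenvalue rule, never shrinks it.
    """

    eigenvalue_cutoff: float = 1.0
    inclusive: bool = True
    cumulative_cutoff: float = 0.70

    def __post_init__(self) -> None:
        if self.eigenvalue_cutoff <= 0:
            raise MGFSError("eigenvalue_cutoff must be positive")
        if not (0 < self.cumulative_cutoff <= 1):
            raise MGFSError("cumulative_cutoff must be in (0, 1]")

    def to_dict(self) -> dict:
        return {
            "eigenvalue_cutoff": self.eigenvalue_cutoff,
            "inclusive": self.inclusive,
            "cumulative_cutoff": self.cumulative_cutoff,
        }


@dataclass
class NormativeModel:
    """Fitted reference model.

    ``rotation`` holds the k retained eigenvectors (columns, orthonormal);
    ``eigenvalues`` the matching k eigenvalues; ``all_eigenvalues`` every
    eigenvalue of the correlation matrix (their sum equals p, the number of
    variables — trace conservation).  ``means``/``sds`` are the per-variable
    reference statistics (sample SD, n-1 denominator) used for z-scoring.
    """

    variable_order: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    rotation: np.ndarray
    eigenvalues: np.ndarray
    all_eigenvalues: np.ndarray
    selection_rule: dict
    anchor_signs: tuple[tuple[str, int], ...]
    provenance: dict = field(default_factory=dict)

    @property
    def p(self) -> int:
        return len(self.variable_order)

    @property
    def k(self) -> int:
        return self.rotation.shape[1]

    @property
    def total_variance(self) -> float:
        return float(self.p)

    def explained_variance_percent(self) -> np.ndarray:
        """Percent of total variance carried by each retained component."""
        return 100.0 * self.eigenvalues / self.total_variance

    def validate(self, atol: float = 1e-8) -> None:
        gram = self.rotation.T @ self.rotation
        if not np.allclose(gram, np.eye(self.k), atol=atol):
            raise MGFSError("rotation columns are not orthonormal")
        if np.any(np.diff(self.eigenvalues) > atol) or self.eigenvalues[-1] <= 0:
            raise MGFSError("eigenvalues must be descending and positive")
        if abs(self.all_eigenvalues.sum() - self.total_variance) > atol:
            raise MGFSError("eigenvalue sum does not equal the number of variables")


@dataclass(frozen=True)
class LoadingReport:
    """Variable-component correlations ('loadings') with relevance flags.

    For standardized PCA the correlation between variable j and component k
    equals the eigenvector entry times the square root of the eigenvalue.
    Cells with |correlation| > 0.5 are flagged as relevant for
    interpretation.
    """

    variable_order: tuple[str, ...]
    correlations: np.ndarray
    relevant_flags: np.ndarray
    threshold: float = 0.5

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.correlations.shape[1])]
        return pd.DataFrame(self.correlations, index=list(self.variable_order), columns=cols)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def standardize_cohort(cohort: ReferenceCohort) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Z-score each variable against the cohort (sample SD, n-1 denominator).

    Returns ``(z, means, sds)`` where ``z`` is n x p with column means 0 and
    column SDs 1.  Raises :class:`ZeroVarianceError` naming the variable if
    any column is constant, and :class:`MissingValueError` naming subject and
    variable if any cell is missing or non-finite.
    """
    x = cohort.values()
    if not np.isfinite(x).all():
        bad = np.argwhere(~np.isfinite(x))[0]
        sid = cohort.data.iloc[bad[0]].get("subject_id", bad[0])
        raise MissingValueError(
            f"subject {sid!r}: measure {cohort.variable_order[bad[1]]!r} is missing or non-finite"
        )
    if cohort.n < 2:
        raise MGFSError(f"need at least 2 subjects to standardize, got {cohort.n}")
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        raise ZeroVarianceError(
            f"variable {cohort.variable_order[zero[0]]!r} has zero sample variance"
        )
    return (x - means) / sds, means, sds


def select_components(eigenvalues: np.ndarray, total_variance: float,
                      rule: SelectionRule | None = None) -> int:
    """Number of components retained under the eigenvalue + cumulative rule.

    Counts eigenvalues at/above the cutoff, then extends (never shrinks) the
    count until the retained components explain at least the cumulative
    cutoff fraction of total variance.
    """
    rule = rule or SelectionRule()
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    if np.any(np.diff(eigenvalues) > 1e-12):
        raise MGFSError("eigenvalues must be in descending order")
    if rule.inclusive:
        k = int(np.sum(eigenvalues >= rule.eigenvalue_cutoff))
    else:
        k = int(np.sum(eigenvalues > rule.eigenvalue_cutoff))
    k = max(k, 1)
    cumshare = np.cumsum(eigenvalues) / total_variance
    while k < len(eigenvalues) and cumshare[k - 1] < rule.cumulative_cutoff - 1e-12:
        k += 1
    return k


def align_component_signs(rotation: np.ndarray,
                          variable_order: Sequence[str],
                          anchors: Sequence[tuple[str, int]] | None = None,
                          ) -> tuple[np.ndarray, tuple[tuple[str, int], ...]]:
    """Resolve PCA sign indeterminacy by anchoring each component.

    For each retained component the correlation between the anchor variable
    and the component score (which has the sign of the anchor's eigenvector
    entry) is forced to the required sign by flipping the whole column when
    needed.  Idempotent.  Components beyond the anchor table are anchored to
    their largest-|loading| variable with a positive required sign.
    """
    rotation = np.array(rotation, dtype=float, copy=True)
    k = rotation.shape[1]
    defaulted = anchors is None
    anchors = list(DEFAULT_ANCHORS if defaulted else anchors)
    if defaulted and any(v not in variable_order for v, _ in anchors):
        anchors = []  # non-canonical variables: anchor by largest loading
    resolved: list[tuple[str, int]] = []
    index = {v: j for j, v in enumerate(variable_order)}
    for comp in range(k):
        if comp < len(anchors):
            var, sign = anchors[comp]
            if var not in index:
                raise MGFSError(f"anchor variable {var!r} not in variable order")
        else:
            var = variable_order[int(np.argmax(np.abs(rotation[:, comp])))]
            sign = +1
        entry = rotation[index[var], comp]
        if entry == 0:
            raise MGFSError(
                f"component {comp + 1}: anchor {var!r} has zero correlation; orientation undefined"
            )
        if np.sign(entry) != np.sign(sign):
            rotation[:, comp] *= -1.0
        resolved.append((var, int(np.sign(sign))))
    return rotation, tuple(resolved)


def fit_normative_model(cohort: ReferenceCohort,
                        selection: SelectionRule | None = None,
                        anchors: Sequence[tuple[str, int]] | None = None,
                        provenance: dict | None = None) -> NormativeModel:
    """Fit the standardized-PCA normative model to a reference cohort.

    Z-scores the cohort, eigendecomposes the p x p sample correlation
    matrix, retains k components by :func:`select_components`, and orients
    signs with :func:`align_component_signs`.
    """
    selection = selection or SelectionRule()
    p = len(cohort.variable_order)
    if cohort.n < p + 1:
        raise MGFSError(f"cohort too small: n={cohort.n} < p+1={p + 1}")
    z, means, sds = standardize_cohort(cohort)
    corr = (z.T @ z) / (cohort.n - 1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[-1] < 1e-10:
        logger.warning("correlation matrix is rank deficient; "
                       "%d near-zero eigenvalue(s) will not be retained",
                       int(np.sum(evals < 1e-10)))
    k = select_components(evals, float(p), selection)
    k = min(k, int(np.sum(evals > 1e-10)))
    rotation, resolved = align_component_signs(evecs[:, :k], cohort.variable_order, anchors)
    model = NormativeModel(
        variable_order=cohort.variable_order,
        means=means,
        sds=sds,
        rotation=rotation,
        eigenvalues=evals[:k].copy(),
        all_eigenvalues=evals.copy(),
        selection_rule=selection.to_dict(),
        anchor_signs=resolved,
        provenance={"n": cohort.n, **(provenance or {})},
    )
    model.validate()
    return model


def loading_report(model: NormativeModel, threshold: float = 0.5) -> LoadingReport:
    """Variable-component correlations c_jk = u_jk * sqrt(lambda_k)."""
    corr = model.rotation * np.sqrt(model.eigenvalues)
    return LoadingReport(
        variable_order=model.variable_order,
        correlations=corr,
        relevant_flags=np.abs(corr) > threshold,
        threshold=threshold,
    )
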