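"""Synthetic reference cohorts with the published component structure.

The real reference sample (Simons Simplex Collection, access-restricted)
cannot ship with the package, so this module generates Gaussian cohorts
whose population correlation matrix reproduces the published three-component
structure: a rank-3 reconstruction R = sum_k lambda_k u_k u_k' from the
printed variable-component correlations and eigenvalues, with a diagonal
residual filling the variance of each variable back to 1.  Fitting the
normative model to a large cohort drawn from this matrix recovers the
published eigenvalues, explained variance and loading pattern, which is what
makes the whole pipeline testable without the restricted data.

Marginal means/SDs are conventional instrument-style defaults (e.g. IQ-like
100/15 scaling); they are NOT the reference sample's values, which are not
public.  All downstream component math is scale-free, so the marginals only
affect the raw-score columns, never loadings or scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import MGFSError, ReferenceCohort, VARIABLE_ORDER
from .scoring import PCScore

#: Published variable-component correlations (nine variables x three
#: components) of the reference-sample standardized PCA, in canonical
#: variable order.
TABLE_CORRELATIONS: np.ndarray = np.array([
    #  PC1    PC2    PC3
    [0.89, -0.16, 0.17],   # vabs_communication
    [0.87, 0.04, 0.12],    # vabs_socialization
    [0.85, -0.13, 0.19],   # vabs_dls
    [-0.69, -0.18, 0.43],  # adi_social
    [-0.31, -0.34, 0.73],  # adi_communication
    [-0.17, -0.52, 0.45],  # adi_rrb
    [0.78, -0.29, 0.12],   # total_iq
    [-0.04, -0.78, -0.39], # cbcl_internalizing
    [-0.14, -0.71, -0.48], # cbcl_externalizing
])

#: Published eigenvalues of the three retained components.
TABLE_EIGENVALUES: np.ndarray = np.array([3.49, 1.65, 1.39])

#: Conventional marginal means/SDs per instrument, labeled synthetic: these
#: are plausible scales for an autistic cohort (VABS standard scores, ADI-R
#: algorithm counts, deviation IQ, CBCL T-scores), not the reference
#: sample's (non-public) statistics.
DEFAULT_MARGINAL_MEANS: np.ndarray = np.array(
    [75.0, 75.0, 75.0, 20.0, 16.0, 6.0, 85.0, 60.0, 58.0])
DEFAULT_MARGINAL_SDS: np.ndarray = np.array(
    [12.0, 12.0, 12.0, 5.0, 5.0, 2.5, 20.0, 10.0, 10.0])

#: ADI-R algorithm scores are counts and cannot go below zero; the default
#: bounds clamp only those three variables so that every simulated subject
#: is a valid record.  The clamp touches well under 1% of draws, so its
#: perturbation of the correlation structure is negligible.
DEFAULT_VALUE_BOUNDS: dict[str, tuple[float | None, float | None]] = {
    "adi_social": (0.0, None),
    "adi_communication": (0.0, None),
    "adi_rrb": (0.0, None),
}


@dataclass
class SyntheticSpec:
    """Target structure for a simulated reference cohort."""

    variable_order: tuple[str, ...] = VARIABLE_ORDER
    target_correlations: np.ndarray = field(
        default_factory=lambda: TABLE_CORRELATIONS.copy())
    target_eigenvalues: np.ndarray = field(
        default_factory=lambda: TABLE_EIGENVALUES.copy())
    marginal_means: np.ndarray = field(
        default_factory=lambda: DEFAULT_MARGINAL_MEANS.copy())
    marginal_sds: np.ndarray = field(
        default_factory=lambda: DEFAULT_MARGINAL_SDS.copy())
    n: int = 2744
    seed: int = 0
    value_bounds: dict[str, tuple[float | None, float | None]] | None = field(
        default_factory=lambda: dict(DEFAULT_VALUE_BOUNDS))

    def __post_init__(self) -> None:
        self.target_correlations = np.asarray(self.target_correlations, dtype=float)
        self.target_eigenvalues = np.asarray(self.target_eigenvalues, dtype=float)
        p, k = self.target_correlations.shape
        if len(self.variable_order) != p or len(self.target_eigenvalues) != k:
            raise MGFSError("spec dimensions are inconsistent")
        residual = 1.0 - (self.target_correlations ** 2).sum(axis=1)
        if np.any(residual < -1e-6):
            j = int(np.argmin(residual))
            raise MGFSError(
                f"target correlations for {self.variable_order[j]!r} imply "
                f"negative residual variance ({residual[j]:.4f})")
        if self.n < p + 1:
            raise MGFSError(f"n={self.n} too small for p={p}")

    def to_dict(self) -> dict:
        return {
            "variable_order": list(self.variable_order),
            "target_correlations": self.target_correlations.tolist(),
            "target_eigenvalues": self.target_eigenvalues.tolist(),
            "marginal_means": self.marginal_means.tolist(),
            "marginal_sds": self.marginal_sds.tolist(),
            "n": self.n,
            "seed": self.seed,
            "value_bounds": self.value_bounds,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SyntheticSpec":
        kwargs = dict(data)
        if "variable_order" in kwargs:
            kwargs["variable_order"] = tuple(kwargs["variable_order"])
        for key in ("target_correlations", "target_eigenvalues",
                    "marginal_means", "marginal_sds"):
            if key in kwargs:
                kwargs[key] = np.asarray(kwargs[key], dtype=float)
        if kwargs.get("value_bounds"):
            kwargs["value_bounds"] = {k: tuple(v) for k, v in kwargs["value_bounds"].items()}
        return cls(**kwargs)


def build_correlation_from_table(spec: SyntheticSpec | None = None) -> np.ndarray:
    """Population correlation matrix with the spec's component structure.

    Columns c_k / sqrt(lambda_k) are orthonormalized (Gram-Schmidt, then
    renormalized) into eigenvector candidates u_k; the low-rank part
    sum_k lambda_k u_k u_k' gets a diagonal residual filling every variance
    to exactly 1.  Because the printed correlations are rounded, the result
    can be slightly indefinite, so any negative eigenvalues are clipped to
    1e-10 and the matrix rescaled back to unit diagonal.
    """
    spec = spec or SyntheticSpec()
    lam = spec.target_eigenvalues
    raw = spec.target_correlations / np.sqrt(lam)
    q, _ = np.linalg.qr(raw)
    # qr can flip signs; align each orthonormal column with its source
    for k in range(q.shape[1]):
        if q[:, k] @ raw[:, k] < 0:
            q[:, k] *= -1.0
    low_rank = (q * lam) @ q.T
    residual = 1.0 - np.diag(low_rank)
    if np.any(residual < -1e-6):
        j = int(np.argmin(residual))
        raise MGFSError(
            f"inconsistent spec: reconstructed variance for "
            f"{spec.variable_order[j]!r} exceeds 1 by {-residual[j]:.2e}")
    residual = np.clip(residual, 0.0, None)
    # The residual variance must live on the orthogonal complement of the
    # component subspace: naively adding diag(residual) would inflate the
    # leading eigenvalues above their targets.  Alternate three corrections
    # until they agree: project onto the complement, clip to PSD, restore
    # the residual diagonal.
    proj = np.eye(len(low_rank)) - q @ q.T
    b = np.diag(residual)
    for _ in range(200):
        b = proj @ b @ proj
        evals, evecs = np.linalg.eigh(b)
        b = (evecs * np.clip(evals, 0.0, None)) @ evecs.T
        delta = residual - np.diag(b)
        if np.max(np.abs(delta)) < 1e-10:
            break
        b = b + np.diag(delta)
    b = proj @ b @ proj
    r = low_rank + b
    # final PSD repair + exact unit diagonal
    evals, evecs = np.linalg.eigh(r)
    if evals.min() < 0:
        r = (evecs * np.clip(evals, 1e-10, None)) @ evecs.T
    d = np.sqrt(np.diag(r))
    r = r / np.outer(d, d)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return r


def simulate_cohort(spec: SyntheticSpec | None = None) -> ReferenceCohort:
    """Draw a Gaussian cohort with the spec's correlation structure.

    n multivariate-normal draws with the built correlation matrix, scaled
    and shifted to the marginal means/SDs, optionally clamped to
    ``value_bounds``.  Deterministic given ``spec.seed``.
    """
    spec = spec or SyntheticSpec()
    r = build_correlation_from_table(spec)
    try:
        chol = np.linalg.cholesky(r + 1e-12 * np.eye(len(r)))
    except np.linalg.LinAlgError as exc:
        raise MGFSError("correlation matrix not positive definite after repair") from exc
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal((spec.n, len(r))) @ chol.T
    x = z * spec.marginal_sds + spec.marginal_means
    data = pd.DataFrame(x, columns=list(spec.variable_order))
    if spec.value_bounds:
        for var, (lo, hi) in spec.value_bounds.items():
            if var in data.columns:
                data[var] = data[var].clip(lo, hi)
    data.insert(0, "subject_id", [f"SYN-{i + 1:05d}" for i in range(spec.n)])
    return ReferenceCohort(data, spec.variable_order)


#: Frozen published case-study rows: PC coordinates, octant sign pattern and
#: one-decimal MGFS of the eight highlighted subjects.
CASE_STUDY_ROWS: tuple[tuple[str, tuple[float, float, float], tuple[str, str, str], float], ...] = (
    ("ID-29", (-1.55, 0.36, 1.87), ("-", "+", "+"), 6.5),
    ("ID-56", (-1.41, 0.87, 1.14), ("-", "+", "+"), 6.4),
    ("ID-77", (-1.71, 0.29, 0.88), ("-", "+", "+"), 3.8),
    ("ID-39", (-2.48, 0.29, 0.80), ("-", "+", "+"), 2.1),
    ("ID-33", (-2.18, -0.99, 1.82), ("-", "-", "+"), 2.2),
    ("ID-78", (-1.60, -0.38, 0.56), ("-", "-", "+"), 2.1),
    ("ID-31", (-2.49, -0.59, 1.42), ("-", "-", "+"), 1.7),
    ("ID-47", (-1.56, -0.31, -0.02), ("-", "-", "-"), 1.4),
)


def case_study_fixture() -> list[tuple[PCScore, tuple[str, str, str], float]]:
    """The eight published case-study subjects as (PCScore, octant, MGFS)."""
    return [
        (PCScore(coords, subject_id=sid), signs, display)
        for sid, coords, signs, display in CASE_STUDY_ROWS
    ]
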