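"""Subsample stability of the component structure.

The reference model is refit on random subsamples (without replacement) at
a range of fractions of the cohort, and each refit's loading columns are
compared to the full-cohort model with Tucker's congruence coefficient
(the cosine between two loading vectors).  Congruence near 1 after sign
alignment means the component structure survives subsampling; >= 0.95 is
conventionally read as stable in factor-analysis practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_model import (
    MGFSError,
    NormativeModel,
    ReferenceCohort,
    SelectionRule,
    fit_normative_model,
    loading_report,
)


def congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker congruence: sum(a*b) / sqrt(sum(a^2) * sum(b^2)).

    Invariant to positive rescaling of either vector; negating one vector
    negates the coefficient.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise MGFSError("loading columns have different lengths")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise MGFSError("congruence undefined for a zero loading vector")
    return float(a @ b / (na * nb))


@dataclass
class StabilityReport:
    """Per-fraction, per-component congruence and eigenvalue deviations.

    ``congruence[fraction]`` is a (replicates x k) array of sign-aligned
    Tucker coefficients against the full-cohort model;
    ``eigenvalue_deviations[fraction]`` the matching relative eigenvalue
    differences (subsample minus full, over full).
    """

    fractions: tuple[float, ...]
    replicates: int
    seed: int
    congruence: dict[float, np.ndarray] = field(default_factory=dict)
    eigenvalue_deviations: dict[float, np.ndarray] = field(default_factory=dict)

    def median_congruence(self) -> dict[float, np.ndarray]:
        """Median |congruence| per component at each fraction."""
        return {f: np.median(np.abs(c), axis=0) for f, c in self.congruence.items()}

    def to_dict(self) -> dict:
        return {
            "fractions": list(self.fractions),
            "replicates": self.replicates,
            "seed": self.seed,
            "congruence": {str(f): c.tolist() for f, c in self.congruence.items()},
            "eigenvalue_deviations": {
                str(f): d.tolist() for f, d in self.eigenvalue_deviations.items()
            },
            "median_abs_congruence": {
                str(f): m.tolist() for f, m in self.median_congruence().items()
            },
        }


def stability_analysis(cohort: ReferenceCohort,
                       fractions: tuple[float, ...] = (0.3, 0.4, 0.5, 0.6, 0.7, 0.8),
                       replicates: int = 20,
                       seed: int = 0,
                       selection: SelectionRule | None = None,
                       reference_model: NormativeModel | None = None) -> StabilityReport:
    """Refit on random subsamples and score agreement with the full fit.

    For every fraction and replicate: draw ``round(fraction * n)`` subjects
    without replacement, refit the model forcing the full model's k, align
    each refit loading column's sign to the full-cohort column, and record
    the Tucker congruence and the relative eigenvalue deviation.
    Deterministic given ``seed``.
    """
    p = len(cohort.variable_order)
    for f in fractions:
        if not (0 < f <= 1):
            raise MGFSError(f"fraction {f} outside (0, 1]")
        if round(f * cohort.n) < p + 1:
            raise MGFSError(f"fraction {f}: subsample of {round(f * cohort.n)} "
                            f"subjects is too small (need >= {p + 1})")
    full = reference_model or fit_normative_model(cohort, selection)
    full_loadings = loading_report(full).correlations
    k = full.k
    rng_root = np.random.SeedSequence(seed)
    report = StabilityReport(fractions=tuple(fractions), replicates=replicates, seed=seed)
    # one child stream per fraction keeps each fraction's draws independent
    # of how many other fractions were requested
    for frac, child in zip(fractions, rng_root.spawn(len(fractions))):
        rng = np.random.default_rng(child)
        cong = np.empty((replicates, k))
        edev = np.empty((replicates, k))
        for rep in range(replicates):
            idx = rng.choice(cohort.n, size=round(frac * cohort.n), replace=False)
            sub = ReferenceCohort(cohort.data.iloc[np.sort(idx)].reset_index(drop=True),
                                  cohort.variable_order)
            refit = _refit_fixed_k(sub, k, selection)
            sub_loadings = loading_report(refit).correlations
            for comp in range(k):
                c = congruence(full_loadings[:, comp], sub_loadings[:, comp])
                cong[rep, comp] = abs(c)  # sign-aligned agreement
                edev[rep, comp] = (refit.eigenvalues[comp] - full.eigenvalues[comp]) \
                    / full.eigenvalues[comp]
        report.congruence[frac] = cong
        report.eigenvalue_deviations[frac] = edev
    return report


def _refit_fixed_k(cohort: ReferenceCohort, k: int,
                   selection: SelectionRule | None) -> NormativeModel:
    """Refit but keep exactly k components so columns stay comparable."""
    model = fit_normative_model(cohort, selection)
    if model.k == k:
        return model
    # retention differed on this subsample: rebuild with the first k columns
    from .core_model import align_component_signs

    evals = model.all_eigenvalues
    # recover unsigned eigenvectors by refitting the eigendecomposition
    from .core_model import standardize_cohort

    z, means, sds = standardize_cohort(cohort)
    corr = (z.T @ z) / (cohort.n - 1)
    ev, evec = np.linalg.eigh(corr)
    order = np.argsort(ev)[::-1]
    ev, evec = ev[order], evec[:, order]
    rotation, anchors = align_component_signs(evec[:, :k], cohort.variable_order)
    return NormativeModel(
        variable_order=cohort.variable_order,
        means=means, sds=sds,
        rotation=rotation,
        eigenvalues=ev[:k].copy(),
        all_eigenvalues=ev.copy(),
        selection_rule=model.selection_rule,
        anchor_signs=anchors,
        provenance={"n": cohort.n, "forced_k": k},
    )
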