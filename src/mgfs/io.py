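"""Cohort CSV readers/writers, model persistence and run configuration."""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_model import (
    MGFSError,
    NormativeModel,
    ReferenceCohort,
    SchemaError,
    SelectionRule,
    DEFAULT_ANCHORS,
    VARIABLE_ORDER,
)

logger = logging.getLogger("mgfs")

MODEL_FORMAT_VERSION = 1


@dataclass
class RunConfig:
    """Knobs shared across the pipeline commands.

    ``eigenvalue_cutoff`` / ``cumulative_cutoff`` drive component retention
    (defaults: keep eigenvalues >= 1.0, extend to 70% cumulative variance);
    ``anchors`` fixes component orientation; ``rounding_decimals`` sets the
    display precision of the score.
    """

    eigenvalue_cutoff: float = 1.0
    eigenvalue_inclusive: bool = True
    cumulative_cutoff: float = 0.70
    anchors: tuple[tuple[str, int], ...] = DEFAULT_ANCHORS
    variable_order: tuple[str, ...] = VARIABLE_ORDER
    rounding_decimals: int = 1
    log_level: str = "INFO"
    seed: int = 0

    def selection_rule(self) -> SelectionRule:
        return SelectionRule(self.eigenvalue_cutoff, self.eigenvalue_inclusive,
                             self.cumulative_cutoff)


def configure_logging(level: str = "INFO") -> None:
    """Timestamped, leveled log lines on stderr."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("mgfs")
    root.handlers[:] = [handler]
    root.setLevel(level.upper())


def read_cohort_csv(path: str | Path, config: RunConfig | None = None) -> ReferenceCohort:
    """Read a cohort CSV into a complete-case :class:`ReferenceCohort`.

    The header must contain the nine canonical variable names (any column
    order); ``subject_id`` and ``timepoint`` are optional.  Rows with a
    missing or non-numeric measure are rejected and logged with the reason;
    a wholly missing column is an error listing the absent names.
    """
    config = config or RunConfig()
    order = tuple(config.variable_order)
    frame = pd.read_csv(path, comment="#")
    missing_cols = [v for v in order if v not in frame.columns]
    if missing_cols:
        raise SchemaError(f"{path}: missing required columns: {missing_cols}")
    for col in order:
        frame[col] = pd.to_numeric(frame[col], errors="coerce")
    keep_cols = [c for c in ("subject_id", "timepoint") if c in frame.columns]
    frame = frame[keep_cols + list(order)]
    complete = frame[list(order)].notna().all(axis=1)
    for idx in frame.index[~complete]:
        bad = [v for v in order if pd.isna(frame.at[idx, v])]
        sid = frame.at[idx, "subject_id"] if "subject_id" in frame.columns else idx
        logger.warning("rejected subject %r: missing/non-numeric %s", sid, bad)
    frame = frame[complete].reset_index(drop=True)
    if frame.empty:
        raise MGFSError(f"{path}: no complete-case rows")
    if "subject_id" not in frame.columns:
        frame.insert(0, "subject_id", [str(i) for i in range(len(frame))])
    return ReferenceCohort(frame, order)


def write_cohort_csv(cohort: ReferenceCohort, path: str | Path) -> None:
    cols = [c for c in ("subject_id", "timepoint") if c in cohort.data.columns]
    cohort.data[cols + list(cohort.variable_order)].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Model persistence (JSON, full float precision, bit-identical round trip)
# ---------------------------------------------------------------------------

_MODEL_FIELDS = {
    "format_version": int,
    "variable_order": list,
    "means": list,
    "sds": list,
    "rotation": list,
    "eigenvalues": list,
    "all_eigenvalues": list,
    "selection_rule": dict,
    "anchor_signs": list,
    "provenance": dict,
}


def write_model(model: NormativeModel, path: str | Path) -> None:
    """Persist a fitted model as JSON at full float precision."""
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "variable_order": list(model.variable_order),
        "means": model.means.tolist(),
        "sds": model.sds.tolist(),
        "rotation": model.rotation.tolist(),
        "eigenvalues": model.eigenvalues.tolist(),
        "all_eigenvalues": model.all_eigenvalues.tolist(),
        "selection_rule": model.selection_rule,
        "anchor_signs": [[v, s] for v, s in model.anchor_signs],
        "provenance": model.provenance,
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def read_model(path: str | Path) -> NormativeModel:
    """Load a model JSON; schema errors name the offending field."""
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: expected a JSON object")
    for name, typ in _MODEL_FIELDS.items():
        if name not in doc:
            raise SchemaError(f"{path}: missing field {name!r}")
        if not isinstance(doc[name], typ):
            raise SchemaError(f"{path}: field {name!r} has wrong type")
    if doc["format_version"] != MODEL_FORMAT_VERSION:
        raise SchemaError(f"{path}: unsupported format_version {doc['format_version']}")
    model = NormativeModel(
        variable_order=tuple(doc["variable_order"]),
        means=np.asarray(doc["means"], dtype=float),
        sds=np.asarray(doc["sds"], dtype=float),
        rotation=np.asarray(doc["rotation"], dtype=float),
        eigenvalues=np.asarray(doc["eigenvalues"], dtype=float),
        all_eigenvalues=np.asarray(doc["all_eigenvalues"], dtype=float),
        selection_rule=doc["selection_rule"],
        anchor_signs=tuple((v, int(s)) for v, s in doc["anchor_signs"]),
        provenance=doc["provenance"],
    )
    if model.rotation.ndim != 2 or model.rotation.shape[0] != len(model.variable_order):
        raise SchemaError(f"{path}: field 'rotation' has wrong shape")
    return model


def model_digest(model: NormativeModel) -> str:
    """Short content hash of the model, for output provenance lines."""
    import hashlib

    payload = b"".join(arr.tobytes() for arr in
                       (model.means, model.sds, model.rotation, model.eigenvalues))
    return hashlib.sha256(payload).hexdigest()[:12]


def scores_to_frame(results: Sequence) -> pd.DataFrame:
    """Flatten MGFS results into the canonical scores table."""
    rows = []
    for res in results:
        row = {"subject_id": res.subject_id, "timepoint": res.timepoint}
        for i, c in enumerate(res.coords):
            row[f"pc{i + 1}"] = c
        row.update({
            "octant_signs": str(res.octant),
            "octant_roman": res.octant.roman or "",
            "projection": res.projection,
            "quantile": res.quantile,
            "mgfs": res.mgfs,
            "mgfs_display": res.mgfs_display,
        })
        rows.append(row)
    return pd.DataFrame(rows)
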