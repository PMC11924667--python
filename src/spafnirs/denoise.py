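"""Nuisance subtraction: Y_filtered = Y_raw - sum(beta_i * X_i).

The betas always come from the full simultaneous OLS fit of the richest
model containing the requested groups; only the selected nuisance groups'
weighted contributions are removed.  Stimulus and intercept contributions
are never subtracted, so the evoked response stays in the series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .glm import NUISANCE_GROUPS, DesignMatrix, GlmResult


@dataclass
class DenoisedSeries:
    """A nuisance-subtracted time series with provenance."""

    values: np.ndarray  # same shape as the raw input
    removed_sets: tuple[str, ...]
    model: str


def regress_out(
    Y_raw: np.ndarray,
    fit: GlmResult,
    X: DesignMatrix,
    groups: set[str] | tuple[str, ...],
) -> DenoisedSeries:
    """Subtract the weighted contribution of the selected regressor groups."""
    groups = tuple(groups)
    if not groups:
        raise InvalidInputError("at least one regressor group must be selected")
    bad = set(groups) - set(NUISANCE_GROUPS)
    if bad:
        raise InvalidInputError(
            f"only nuisance groups {NUISANCE_GROUPS} may be subtracted; got {sorted(bad)}"
        )
    if fit.columns != X.columns or fit.model != X.model:
        raise InvalidInputError("fit and design matrix do not match")
    present = set(X.groups.values())
    missing = set(groups) - present
    if missing:
        raise InvalidInputError(
            f"groups {sorted(missing)} absent from the {X.model!r} design"
        )
    Y2 = np.atleast_2d(np.asarray(Y_raw, dtype=float))
    cols = [c for g in groups for c in X.columns_in_group(g)]
    idx = [X.columns.index(c) for c in cols]
    contribution = fit.beta[:, idx] @ X.values[:, idx].T
    values = Y2 - contribution
    if np.asarray(Y_raw).ndim == 1:
        values = values[0]
    return DenoisedSeries(values=values, removed_sets=groups, model=X.model)
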