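"""Conditional-effect interpretation: personalized slopes and their range.

In a model with interactions, the coefficient ``beta_j`` is only the effect
of a unit change in covariate j for an individual at the center of all other
covariates. The *personalized unit-change effect*

    E_ij = beta_j + sum_{k != j} beta_jk x_ik

is the slope of covariate j at individual i's covariate values; computed per
posterior draw it carries credible intervals. The *range of significance*
profiles a single interaction: the interval for ``beta_j + beta_jk x_k``
across a grid of x_k, flagging where it excludes zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["UnitChangeEffect", "unit_change_effect", "range_of_significance"]


@dataclass
class UnitChangeEffect:
    """Draws of E_ij, shape (draws, n_test, p_enc)."""

    draws: np.ndarray
    column_names: list

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
        mean = self.draws.mean(axis=0)
        lo, hi = np.quantile(self.draws, [lo_q, hi_q], axis=0)
        n, p = mean.shape
        return pd.DataFrame(
            {
                "individual": np.repeat(np.arange(n), p),
                "covariate": np.tile(self.column_names, n),
                "mean": mean.ravel(),
                "lower": lo.ravel(),
                "upper": hi.ravel(),
            }
        )


def unit_change_effect(draws, x_test, design) -> UnitChangeEffect:
    """Per-draw personalized slopes for every individual and encoded column.

    ``x_test`` must be encoded with the training TransformStats. E_ij is an
    affine function of x_i per draw, so attributions obey superposition
    exactly.
    """
    x = np.atleast_2d(np.asarray(x_test, dtype=float))
    if x.shape[1] != design.p_enc:
        raise ValueError("x_test column count does not match the training design")
    bm = np.atleast_2d(draws.beta_main)
    bi = np.atleast_2d(draws.beta_int)
    S, n = bm.shape[0], x.shape[0]
    E = np.broadcast_to(bm[:, None, :], (S, n, design.p_enc)).copy()
    for t, (j, k) in enumerate(design.interaction_pairs):
        E[:, :, j] += bi[:, t, None] * x[None, :, k]
        E[:, :, k] += bi[:, t, None] * x[None, :, j]
    return UnitChangeEffect(draws=E, column_names=list(design.column_names))


def range_of_significance(
    draws, design, j, k, grid=None, level: float = 0.95
) -> pd.DataFrame:
    """Credible band for ``beta_j + beta_jk x_k`` over a grid of x_k.

    ``j`` and ``k`` are encoded-column indices (or names) with ``j != k``;
    the default grid is 41 equally spaced points over the observed range of
    column k in the training design. Each row flags whether the equal-tailed
    interval at ``level`` excludes zero.
    """
    names = list(design.column_names)
    if isinstance(j, str):
        j = names.index(j)
    if isinstance(k, str):
        k = names.index(k)
    if j == k:
        raise ValueError("j and k must differ")
    pair = (min(j, k), max(j, k))
    try:
        t = design.interaction_pairs.index(pair)
    except ValueError:
        raise ValueError(
            f"columns {names[j]!r} and {names[k]!r} have no interaction term "
            "(within-categorical pairs are excluded)"
        ) from None
    if grid is None:
        col = design.X_main[:, k]
        grid = np.linspace(col.min(), col.max(), 41)
    grid = np.asarray(grid, dtype=float)

    bj = np.atleast_2d(draws.beta_main)[:, j]
    bjk = np.atleast_2d(draws.beta_int)[:, t]
    comb = bj[:, None] + bjk[:, None] * grid[None, :]  # (S, G)
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    lo, hi = np.quantile(comb, [lo_q, hi_q], axis=0)
    return pd.DataFrame(
        {
            "x_k": grid,
            "mean": comb.mean(axis=0),
            "lower": lo,
            "upper": hi,
            "excludes_zero": (lo > 0) | (hi < 0),
            "covariate": names[j],
            "interacting_with": names[k],
        }
    )
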