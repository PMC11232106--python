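"""Exact interventional Shapley values for two-way-interaction regressions.

A Shapley value :math:`\\phi_{ij}` attributes to covariate *j* its average
contribution to the prediction for individual *i*: coalitions ("players") are
covariates fixed at the individual's values, the remaining covariates are
marginalized *interventionally*, i.e. ignoring their dependence on the
players, so only first and second moments of the training distribution are
needed. For a linear model with all two-way interactions the coalition value
is itself linear in the coefficients, which yields a closed form.

With centered covariates the closed form per draw is

.. math::

    \\phi_{ij} = \\beta_j x^*_{ij}
        + \\tfrac{1}{2} \\sum_{k \\ne j} \\beta_{jk}
          \\left( x^*_{ij} x^*_{ik} - E[x_{ij} x_{ik}] \\right),

with :math:`E[x_{ij} x_{ik}]` the training-sample second moment. The
implementation uses the general (non-centered) form, which reduces to the
above when column means vanish, and handles a categorical covariate as one
grouped player: all its contrast columns enter or leave a coalition
together. Applying the formula per posterior draw yields credible intervals
for the attributions.

``shapley_bruteforce`` enumerates all coalitions with the exact Shapley
weights and is the oracle the closed form is validated against.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd

__all__ = [
    "ShapleyResult",
    "players",
    "coalition_value",
    "shapley_bruteforce",
    "shapley_closed_form",
    "global_importance",
]

MAX_BRUTEFORCE_PLAYERS = 15


def players(design) -> list:
    """Ordered (covariate name, encoded column indices) player list.

    One player per source covariate; a categorical's contrast columns form a
    single player because its dummies are not independently manipulable.
    """
    pm = design.player_map()
    return [(name, tuple(cols)) for name, cols in pm.items()]


def _require_moments(design):
    if design.moments is None or design.col_means is None:
        raise ValueError("design lacks moment statistics; call build_interactions")


def _check_encoding(design, x_star):
    x_star = np.atleast_2d(np.asarray(x_star, dtype=float))
    if x_star.shape[1] != design.p_enc:
        raise ValueError(
            f"x_star has {x_star.shape[1]} columns but the training design has "
            f"{design.p_enc}; encode new data with the training TransformStats"
        )
    return x_star


def coalition_value(beta_point, x_star, S, design) -> float:
    """Value v(S): expected prediction fixing players in S, marginalizing the rest.

    ``beta_point`` is a mapping with ``alpha``, ``beta_main`` (p_enc,),
    ``beta_int`` (q,). ``S`` is a set of player indices into
    ``players(design)``. Non-players are integrated out under the
    interventional convention using the training moments: ``E[x_j]`` for
    lone columns and ``E[x_j x_k]`` for products of two non-players.

    ``v(full set)`` is the point prediction; ``v(empty set)`` is the
    model-implied mean prediction.
    """
    _require_moments(design)
    x_star = np.asarray(x_star, dtype=float)
    plist = players(design)
    S = set(S)
    if not S <= set(range(len(plist))):
        raise ValueError("S contains unknown player indices")
    in_S = np.zeros(design.p_enc, dtype=bool)
    for g in S:
        for col in plist[g][1]:
            in_S[col] = True

    alpha = float(beta_point["alpha"])
    bm = np.asarray(beta_point["beta_main"], dtype=float)
    bi = np.asarray(beta_point["beta_int"], dtype=float)
    m = design.col_means

    val = alpha + float(np.sum(bm * np.where(in_S, x_star, m)))
    for t, (j, k) in enumerate(design.interaction_pairs):
        if in_S[j] and in_S[k]:
            val += bi[t] * x_star[j] * x_star[k]
        elif in_S[j]:
            val += bi[t] * x_star[j] * m[k]
        elif in_S[k]:
            val += bi[t] * m[j] * x_star[k]
        else:
            val += bi[t] * design.moments[t]
    return val


def shapley_bruteforce(beta_point, x_star, design) -> np.ndarray:
    """Shapley values by full coalition enumeration (the validation oracle).

    phi_g = sum over S not containing g of |S|!(P-|S|-1)!/P! *
    [v(S + {g}) - v(S)]. Exponential in the player count; refuses more than
    15 players (use ``shapley_closed_form``).
    """
    plist = players(design)
    P = len(plist)
    if P > MAX_BRUTEFORCE_PLAYERS:
        raise ValueError(
            f"{P} players exceeds the enumeration limit "
            f"({MAX_BRUTEFORCE_PLAYERS}); use shapley_closed_form"
        )
    x_star = np.asarray(x_star, dtype=float)
    fact = [factorial(i) for i in range(P + 1)]
    phi = np.zeros(P)
    others = list(range(P))
    for g in range(P):
        rest = [h for h in others if h != g]
        for size in range(P):
            w = fact[size] * fact[P - size - 1] / fact[P]
            for S in combinations(rest, size):
                phi[g] += w * (
                    coalition_value(beta_point, x_star, set(S) | {g}, design)
                    - coalition_value(beta_point, x_star, S, design)
                )
    return phi


@dataclass
class ShapleyResult:
    """Per-draw, per-individual, per-player Shapley attributions.

    ``phi``, ``phi_main``, ``phi_int`` have shape (draws, n_test, P) and
    satisfy ``phi = phi_main + phi_int`` exactly; per draw and individual the
    attributions sum to prediction minus model-implied mean prediction.
    """

    phi: np.ndarray
    phi_main: np.ndarray
    phi_int: np.ndarray
    player_names: list
    player_cols: list

    def posterior_mean(self) -> np.ndarray:
        return self.phi.mean(axis=0)

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        """Long-format table: individual, covariate, component, mean, interval."""
        lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
        rows = []
        for comp, arr in (
            ("total", self.phi),
            ("main", self.phi_main),
            ("interaction", self.phi_int),
        ):
            mean = arr.mean(axis=0)
            lo, hi = np.quantile(arr, [lo_q, hi_q], axis=0)
            n, P = mean.shape
            rows.append(
                pd.DataFrame(
                    {
                        "individual": np.repeat(np.arange(n), P),
                        "covariate": np.tile(self.player_names, n),
                        "component": comp,
                        "mean": mean.ravel(),
                        "lower": lo.ravel(),
                        "upper": hi.ravel(),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _as_draw_arrays(draws_or_point, p_enc, q):
    """Normalize input to (S,), (S, p), (S, q) arrays."""
    if hasattr(draws_or_point, "beta_main") and not isinstance(draws_or_point, dict):
        d = draws_or_point
        return np.atleast_1d(d.alpha), np.atleast_2d(d.beta_main), np.atleast_2d(d.beta_int)
    alpha = np.atleast_1d(np.asarray(draws_or_point["alpha"], dtype=float))
    bm = np.asarray(draws_or_point["beta_main"], dtype=float)
    bi = np.asarray(draws_or_point["beta_int"], dtype=float)
    if bm.ndim == 1:
        bm = bm[None, :]
        bi = bi[None, :]
    if bm.shape[1] != p_enc or bi.shape[1] != q:
        raise ValueError("coefficient dimensions do not match the design")
    return alpha, bm, bi


def shapley_closed_form(draws_or_point, x_star_batch, design) -> ShapleyResult:
    """Exact interventional Shapley values, per posterior draw, closed form.

    Parameters
    ----------
    draws_or_point : PosteriorDraws or mapping
        Posterior draws, or a single coefficient point (``alpha``,
        ``beta_main``, ``beta_int``).
    x_star_batch : (n_test, p_enc) array
        Test individuals, encoded with the *training* TransformStats.
    design : EncodedDesign
        Training design; supplies the frozen moments and player grouping.

    For a main term the attribution to its player is
    ``beta_j (x*_j - E[x_j])``. An interaction ``beta_jk`` between distinct
    players g (owning j) and h (owning k) is a two-player subgame; its exact
    Shapley split gives player g

    ``1/2 beta_jk [ x*_j (E[x_k] + x*_k) - E[x_j x_k] - E[x_j] x*_k ]``

    and symmetrically for h. With centered columns this is the familiar
    ``beta_j x*_j + 1/2 sum_k beta_jk (x*_j x*_k - E[x_j x_k])``.
    """
    _require_moments(design)
    x = _check_encoding(design, x_star_batch)
    plist = players(design)
    P = len(plist)
    player_of = np.empty(design.p_enc, dtype=int)
    for g, (_, cols) in enumerate(plist):
        for c in cols:
            player_of[c] = g

    alpha, bm, bi = _as_draw_arrays(draws_or_point, design.p_enc, design.q)
    S, n = bm.shape[0], x.shape[0]
    m = design.col_means

    phi_main = np.zeros((S, n, P))
    centered = x - m[None, :]
    for j in range(design.p_enc):
        phi_main[:, :, player_of[j]] += bm[:, j, None] * centered[None, :, j]

    phi_int = np.zeros((S, n, P))
    for t, (j, k) in enumerate(design.interaction_pairs):
        g, h = player_of[j], player_of[k]
        M = design.moments[t]
        b = bi[:, t]
        if g == h:
            # both columns belong to one grouped player: it receives the
            # whole contribution (cannot occur for model pairs, which exclude
            # within-categorical interactions, but kept for generality)
            a_g = x[:, j] * x[:, k] - M
            phi_int[:, :, g] += b[:, None] * a_g[None, :]
            continue
        a_g = x[:, j] * (m[k] + x[:, k]) - M - m[j] * x[:, k]
        a_h = x[:, k] * (m[j] + x[:, j]) - M - m[k] * x[:, j]
        phi_int[:, :, g] += 0.5 * b[:, None] * a_g[None, :]
        phi_int[:, :, h] += 0.5 * b[:, None] * a_h[None, :]

    return ShapleyResult(
        phi=phi_main + phi_int,
        phi_main=phi_main,
        phi_int=phi_int,
        player_names=[name for name, _ in plist],
        player_cols=[cols for _, cols in plist],
    )


def global_importance(result: ShapleyResult) -> pd.DataFrame:
    """Global importance I_j = (1/n) sum_i |phi_ij| of posterior-mean values.

    Computed per component as well (I_j^main, I_j^int). Because of sign
    cancellation between the main and interaction parts, I_j is generally
    not the sum of the two components.
    """
    out = {"covariate": result.player_names}
    for name, arr in (
        ("I", result.phi),
        ("I_main", result.phi_main),
        ("I_int", result.phi_int),
    ):
        out[name] = np.abs(arr.mean(axis=0)).mean(axis=0)
    return pd.DataFrame(out)
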