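"""Covariate encoding and interaction design matrices.

Conventions, chosen to keep coefficients comparable across covariate types:

* continuous covariates are standardized, ``(x - mean) / sd`` with the
  ``ddof=1`` sample standard deviation;
* binary covariates are contrast-coded to ``{-1, +1}`` (sorted raw values map
  to ``(-1, +1)``), which standardizes them in the balanced case;
* a categorical covariate with ``L`` levels becomes ``L - 1`` sum-to-zero
  contrast columns with values in ``{-1, 0, 1}``: column ``l`` is ``+1`` for
  level ``l``, ``-1`` for the reference level (the last level in schema
  order), ``0`` otherwise.

The interaction design takes one column per unordered pair of encoded
columns, in lexicographic ``(j, k)`` order with ``j < k``, excluding pairs
whose two columns encode the same categorical covariate (contrast columns of
one categorical are not independently manipulable, and their products carry
no extra information beyond the main contrasts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CovariateSchema",
    "TransformStats",
    "EncodedDesign",
    "encode_covariates",
    "build_interactions",
    "second_moments",
    "interaction_pair_count",
    "load_schema",
]

VALID_KINDS = ("continuous", "binary", "categorical")


@dataclass(frozen=True)
class CovariateSchema:
    """Typing of one raw covariate column.

    Parameters
    ----------
    name : str
        Column name in the raw table.
    kind : {"continuous", "binary", "categorical"}
    levels : tuple of str, optional
        Ordered level labels; required for categoricals (>= 3 levels). The
        last level is the contrast reference.
    """

    name: str
    kind: str
    levels: tuple = ()

    def __post_init__(self):
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown covariate kind {self.kind!r} for {self.name!r}")
        if self.kind == "categorical":
            if len(self.levels) < 3:
                raise ValueError(
                    f"categorical covariate {self.name!r} needs >= 3 levels, "
                    f"got {len(self.levels)}"
                )
            if len(set(self.levels)) != len(self.levels):
                raise ValueError(f"duplicate levels in {self.name!r}")
        object.__setattr__(self, "levels", tuple(self.levels))

    @property
    def n_encoded(self) -> int:
        return len(self.levels) - 1 if self.kind == "categorical" else 1


def load_schema(path) -> list[CovariateSchema]:
    """Read a covariate schema from YAML (a list of name/kind/levels maps)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [
        CovariateSchema(
            name=entry["name"],
            kind=entry["kind"],
            levels=tuple(entry.get("levels") or ()),
        )
        for entry in raw
    ]


@dataclass
class TransformStats:
    """Per-covariate location/scale learned on training data.

    ``centers``/``scales`` are keyed by covariate name and apply to continuous
    covariates; ``binary_values`` maps a binary covariate to its two sorted
    raw values (mapped to -1, +1).
    """

    centers: dict = field(default_factory=dict)
    scales: dict = field(default_factory=dict)
    binary_values: dict = field(default_factory=dict)


@dataclass
class EncodedDesign:
    """Main + interaction design with its encoding and moment statistics.

    Attributes
    ----------
    X_main : (n, p_enc) ndarray
    column_names : list of str
        Encoded column names; categorical contrasts are ``name=level``.
    column_map : list of str
        Source covariate name per encoded column.
    stats : TransformStats
    schema : list of CovariateSchema
    interaction_pairs : list of (int, int)
        Unordered encoded-column pairs, lexicographic, same-categorical pairs
        excluded. Populated by :func:`build_interactions`.
    X_int : (n, q) ndarray or None
    col_means : (p_enc,) ndarray
        Sample means of the encoded main columns (1/n convention).
    moments : (q,) ndarray or None
        Sample second moments E[x_j x_k] per interaction pair (1/n).
    """

    X_main: np.ndarray
    column_names: list
    column_map: list
    stats: TransformStats
    schema: list
    interaction_pairs: list = field(default_factory=list)
    X_int: np.ndarray | None = None
    col_means: np.ndarray | None = None
    moments: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.X_main.shape[0]

    @property
    def p_enc(self) -> int:
        return self.X_main.shape[1]

    @property
    def q(self) -> int:
        return len(self.interaction_pairs)

    def interaction_names(self) -> list:
        return [
            f"{self.column_names[j]}:{self.column_names[k]}"
            for j, k in self.interaction_pairs
        ]

    def full_matrix(self) -> np.ndarray:
        """Main and interaction columns side by side (no intercept column)."""
        if self.X_int is None:
            raise ValueError("interactions not built; call build_interactions first")
        return np.hstack([self.X_main, self.X_int])

    def player_map(self) -> dict:
        """Covariate name -> list of encoded column indices.

        Groups a categorical's contrast columns into one Shapley player.
        """
        out: dict = {}
        for idx, src in enumerate(self.column_map):
            out.setdefault(src, []).append(idx)
        return out


def interaction_pair_count(schema) -> int:
    """q = C(p_enc, 2) - sum_c C(d_c, 2) over categorical covariates c."""
    p_enc = sum(s.n_encoded for s in schema)
    q = comb(p_enc, 2)
    for s in schema:
        if s.kind == "categorical":
            q -= comb(s.n_encoded, 2)
    return q


def _check_schema(raw_table: pd.DataFrame, schema) -> None:
    names = [s.name for s in schema]
    if len(set(names)) != len(names):
        raise ValueError("covariate names in schema are not unique")
    missing = [n for n in names if n not in raw_table.columns]
    if missing:
        raise ValueError(f"schema columns missing from table: {missing}")
    sub = raw_table[names]
    if sub.isna().any().any():
        raise ValueError("missing values in covariate table are not supported")


def encode_covariates(
    raw_table: pd.DataFrame,
    schema,
    stats: TransformStats | None = None,
) -> EncodedDesign:
    """Encode a raw covariate table into the standardized main design.

    When ``stats`` is given (learned on training data), its centers/scales
    and binary value maps are re-applied; otherwise they are learned from
    ``raw_table``. Unknown categorical levels or binary values in new data
    raise a ``ValueError`` naming the offender.
    """
    _check_schema(raw_table, schema)
    learn = stats is None
    if learn:
        stats = TransformStats()

    cols, names, col_map = [], [], []
    for cov in schema:
        x = raw_table[cov.name]
        if cov.kind == "continuous":
            vals = np.asarray(x, dtype=float)
            if learn:
                center = float(vals.mean())
                scale = float(vals.std(ddof=1))
                if scale == 0.0 or not np.isfinite(scale):
                    raise ValueError(f"constant continuous column {cov.name!r}: scale undefined")
                stats.centers[cov.name] = center
                stats.scales[cov.name] = scale
            cols.append((vals - stats.centers[cov.name]) / stats.scales[cov.name])
            names.append(cov.name)
            col_map.append(cov.name)
        elif cov.kind == "binary":
            if learn:
                observed = sorted(pd.unique(x))
                if len(observed) != 2:
                    raise ValueError(
                        f"binary covariate {cov.name!r} has {len(observed)} "
                        "observed values, expected exactly 2"
                    )
                stats.binary_values[cov.name] = tuple(observed)
            lo, hi = stats.binary_values[cov.name]
            known = x.isin([lo, hi])
            if not known.all():
                bad = pd.unique(x[~known])[0]
                raise ValueError(f"unknown value {bad!r} in binary covariate {cov.name!r}")
            cols.append(np.where(np.asarray(x == hi), 1.0, -1.0))
            names.append(cov.name)
            col_map.append(cov.name)
        else:  # categorical
            known = x.isin(cov.levels)
            if not known.all():
                bad = pd.unique(x[~known])[0]
                raise ValueError(f"unknown level {bad!r} in categorical covariate {cov.name!r}")
            ref = cov.levels[-1]
            for level in cov.levels[:-1]:
                col = np.zeros(len(x))
                col[np.asarray(x == level)] = 1.0
                col[np.asarray(x == ref)] = -1.0
                cols.append(col)
                names.append(f"{cov.name}={level}")
                col_map.append(cov.name)

    X_main = np.column_stack(cols) if cols else np.empty((len(raw_table), 0))
    return EncodedDesign(
        X_main=X_main,
        column_names=names,
        column_map=col_map,
        stats=stats,
        schema=list(schema),
    )


def build_interactions(encoded: EncodedDesign) -> EncodedDesign:
    """Attach interaction columns and pair bookkeeping to an encoded design.

    One column per unordered encoded-column pair ``(j, k)`` with ``j < k`` in
    lexicographic order, excluding pairs within one categorical covariate.
    Each column is the exact elementwise product of its parents. Also fills
    ``col_means`` and ``moments`` (see :func:`second_moments`).
    """
    p = encoded.p_enc
    pairs = [
        (j, k)
        for j in range(p)
        for k in range(j + 1, p)
        if not (
            encoded.column_map[j] == encoded.column_map[k]
            and any(
                s.name == encoded.column_map[j] and s.kind == "categorical"
                for s in encoded.schema
            )
        )
    ]
    encoded.interaction_pairs = pairs
    if pairs:
        jj = np.array([j for j, _ in pairs])
        kk = np.array([k for _, k in pairs])
        encoded.X_int = encoded.X_main[:, jj] * encoded.X_main[:, kk]
    else:
        encoded.X_int = np.empty((encoded.n, 0))
    encoded.col_means, encoded.moments = second_moments(encoded)
    return encoded


def second_moments(encoded: EncodedDesign):
    """Sample moments of the encoded design, denominator ``n``.

    Returns ``(col_means, pair_moments)`` where ``pair_moments[t]`` is
    ``mean(x_j * x_k)`` for interaction pair ``t``; these are the plug-in
    estimates of ``E[x_j]`` and ``E[x_j x_k]`` used by the interventional
    Shapley marginalization. Centered continuous columns have mean 0 by
    construction; binary/categorical columns generally do not.
    """
    if encoded.n < 2:
        raise ValueError("need n >= 2 to estimate moments")
    col_means = encoded.X_main.mean(axis=0)
    if not encoded.interaction_pairs:
        return col_means, np.empty(0)
    jj = np.array([j for j, _ in encoded.interaction_pairs])
    kk = np.array([k for _, k in encoded.interaction_pairs])
    pair_moments = (encoded.X_main[:, jj] * encoded.X_main[:, kk]).mean(axis=0)
    return col_means, pair_moments
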