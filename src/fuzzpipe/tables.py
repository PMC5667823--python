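"""Feature tables with FSMD columns, forward filtering and Ω propagation.

Every processing operator in the pipeline emits a rectangular feature
table (a pandas DataFrame): one row per extracted object, named numeric
feature columns, plus zero or more fuzzy-set membership degree (FSMD)
columns bounded in [0, 1] and named ``fsmd_<term>``.  Two thresholds per
operator control the information flow:

* ``alpha`` — forward filter: only rows with FSMD >= alpha are passed on;
* ``beta`` in [alpha, 1] — backward propagation: rows of the *previous*
  operator whose outputs came out uncertain (alpha <= FSMD < beta) are
  carried along so that a downstream operator can fall back on them.

The union of the filtered output and the carried predecessor rows is the
propagation set Ω a downstream operator receives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fuzzy import FuzzySet, TNormKind, combine_conjunction

__all__ = [
    "OperatorThresholds",
    "PropagationSet",
    "filter_forward",
    "build_propagation_set",
    "append_fsmd",
    "fsmd_column",
]

#: required identity columns of an object table (0-based voxel coordinates,
#: x is the fastest-varying image axis)
ID_COLUMNS = ("id", "t", "view", "x", "y", "z")


def fsmd_column(term: str) -> str:
    """Column-name convention for the FSMD of a linguistic term."""
    return f"fsmd_{term}"


@dataclass(frozen=True)
class OperatorThresholds:
    """Forward (alpha) and backward (beta) FSMD thresholds of one operator."""

    alpha: float = 0.0
    beta: float | None = None

    def __post_init__(self) -> None:
        beta = self.alpha if self.beta is None else self.beta
        if not (0.0 <= self.alpha <= beta <= 1.0):
            raise ValueError(
                f"need 0 <= alpha <= beta <= 1, got alpha={self.alpha}, beta={self.beta}"
            )
        object.__setattr__(self, "beta", beta)


@dataclass(frozen=True)
class PropagationSet:
    """Information handed to the next operator: X̃ ∪ Ω̃ of the predecessor.

    ``filtered`` holds the alpha-filtered output of the current operator,
    ``carried`` the predecessor rows that produced uncertain outcomes.
    Both keep a ``source_operator`` column so the union stays disjoint by
    provenance.
    """

    filtered: pd.DataFrame
    carried: pd.DataFrame

    @property
    def union(self) -> pd.DataFrame:
        """The combined propagation set Ω (filtered rows first)."""
        if self.carried.empty:
            return self.filtered.copy()
        cols = list(
            dict.fromkeys(list(self.filtered.columns) + list(self.carried.columns))
        )
        return pd.concat(
            [self.filtered.reindex(columns=cols), self.carried.reindex(columns=cols)],
            ignore_index=True,
        )


def _check_fsmd(table: pd.DataFrame, column: str) -> np.ndarray:
    if column not in table.columns:
        raise KeyError(f"FSMD column {column!r} not present in table")
    vals = table[column].to_numpy(dtype=float)
    if np.any(vals < 0) or np.any(vals > 1):
        raise ValueError(f"FSMD column {column!r} must be bounded in [0, 1]")
    return vals


def filter_forward(
    table: pd.DataFrame, fsmd_col: str, thresholds: OperatorThresholds
) -> pd.DataFrame:
    """Keep rows whose FSMD is at least alpha, preserving row order.

    alpha = 0 keeps everything; alpha = 1 passes only fully certain rows.
    """
    vals = _check_fsmd(table, fsmd_col)
    return table.loc[vals >= thresholds.alpha].reset_index(drop=True)


def build_propagation_set(
    prev_omega: pd.DataFrame,
    current_out: pd.DataFrame,
    parent_link: Mapping[int, int],
    fsmd_col: str,
    thresholds: OperatorThresholds,
    operator_id: int | None = None,
) -> PropagationSet:
    """Assemble Ω = X̃ (alpha-filtered output) ∪ Ω̃ (uncertain predecessors).

    ``parent_link`` maps a row ``id`` of ``current_out`` to the ``id`` of
    the ``prev_omega`` row it was generated from (at most one parent per
    output row).  Predecessor rows linked to outputs with
    alpha <= FSMD < beta are carried forward; with beta == alpha nothing
    is carried and only the current operator's output propagates.
    """
    vals = _check_fsmd(current_out, fsmd_col)
    prev_ids = set(prev_omega["id"]) if "id" in prev_omega.columns else set()
    for child, parent in parent_link.items():
        if parent not in prev_ids:
            raise KeyError(f"parent link {child} -> {parent} dangles: no such prev row")

    filtered = filter_forward(current_out, fsmd_col, thresholds)
    uncertain = (vals >= thresholds.alpha) & (vals < thresholds.beta)
    uncertain_ids = set(current_out.loc[uncertain, "id"])
    carry_parents = {parent_link[i] for i in uncertain_ids if i in parent_link}
    if carry_parents:
        carried = prev_omega.loc[prev_omega["id"].isin(carry_parents)].reset_index(
            drop=True
        )
    else:
        carried = prev_omega.iloc[0:0].reset_index(drop=True)

    filtered = filtered.copy()
    carried = carried.copy()
    if operator_id is not None:
        filtered["source_operator"] = operator_id
        if "source_operator" not in carried.columns:
            carried["source_operator"] = operator_id - 1 if operator_id else -1
    return PropagationSet(filtered=filtered, carried=carried)


def append_fsmd(
    table: pd.DataFrame,
    sets: Sequence[FuzzySet],
    kind: TNormKind | str = TNormKind.MINIMUM,
    column: str | None = None,
    term: str = "correct",
) -> pd.DataFrame:
    """Evaluate fuzzy sets on their feature columns and append the conjunction.

    Each set is evaluated on the column named by its ``feature``; the
    per-feature degrees are combined with the chosen t-norm into a single
    FSMD value per row, appended as a new column (default
    ``fsmd_<term>``).  The input columns are left untouched.
    """
    if not sets:
        raise ValueError("need at least one fuzzy set")
    for s in sets:
        if s.feature not in table.columns:
            raise KeyError(f"feature {s.feature!r} required by fuzzy set not in table")
    column = column or fsmd_column(term)
    out = table.copy()
    if len(table) == 0:
        out[column] = pd.Series(dtype=float)
        return out
    degrees = [s(table[s.feature].to_numpy(dtype=float)) for s in sets]
    out[column] = combine_conjunction(degrees, kind)
    return out
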