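"""Fixed-effect design matrices with treatment contrasts.

Terms are column names, optionally combined with ``*`` (main effects plus
interaction) or ``:`` (interaction only).  Categorical columns (non-numeric
dtype) are expanded into treatment-coded dummies against an explicit
reference level; the reported level effects and contrasts downstream are
computed from posterior draws, so the coding choice cannot change them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Design", "build_design"]


@dataclass
class Design:
    matrix: np.ndarray                 # n x p, first column the intercept
    names: list                        # p column names
    factor_levels: dict = field(default_factory=dict)   # column -> ordered levels (reference first)
    dropped_levels: dict = field(default_factory=dict)  # column -> levels absent from the data


def _is_categorical(col: pd.Series) -> bool:
    return not pd.api.types.is_numeric_dtype(col)


def _expand(term: str, table: pd.DataFrame, reference_levels: dict, design: Design):
    """Expand a single (possibly interaction-only) term into named columns."""
    parts = term.split(":")
    pieces = []  # list of (suffix, vector) per part
    for col in parts:
        if col not in table.columns:
            raise ValueError(f"fixed term {col!r} is not a column of the table")
        series = table[col]
        if _is_categorical(series):
            levels = sorted(series.astype(str).unique())
            ref = reference_levels.get(col)
            if ref is None:
                ref = levels[0]
            if ref in levels:
                levels = [ref] + [l for l in levels if l != ref]
            else:
                design.dropped_levels.setdefault(col, []).append(ref)
            design.factor_levels[col] = levels
            pieces.append([
                (f"{col}[{lev}]", (series.astype(str) == lev).to_numpy(float))
                for lev in levels[1:]
            ])
        else:
            pieces.append([(col, series.to_numpy(float))])
    # cartesian product across the parts of the interaction
    cols = pieces[0]
    for nxt in pieces[1:]:
        cols = [(f"{na}:{nb}", va * vb) for na, va in cols for nb, vb in nxt]
    return cols


def build_design(table: pd.DataFrame, fixed_terms, reference_levels=None) -> Design:
    """Build the n x p design matrix (intercept first) for the given terms."""
    reference_levels = dict(reference_levels or {})
    design = Design(matrix=None, names=["(Intercept)"])
    columns = [("(Intercept)", np.ones(len(table)))]
    seen = {"(Intercept)"}
    for term in fixed_terms:
        term = term.strip()
        if "*" in term:
            a_parts = [p.strip() for p in term.split("*")]
            subterms = a_parts + [":".join(a_parts)]
        else:
            subterms = [term]
        for sub in subterms:
            for name, vec in _expand(sub, table, reference_levels, design):
                if name not in seen:
                    seen.add(name)
                    columns.append((name, vec))
    design.names = [n for n, _ in columns]
    design.matrix = np.column_stack([v for _, v in columns])
    p = design.matrix.shape[1]
    if np.linalg.matrix_rank(design.matrix) < p:
        # identify a collinear column for the error message
        _, r = np.linalg.qr(design.matrix)
        bad = [design.names[j] for j in range(p) if abs(r[j, j]) < 1e-8]
        raise ValueError(f"singular design matrix; collinear terms: {bad}")
    return design
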