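"""Effect-size construction for the comparative inbreeding-avoidance table.

Relatedness estimates (``rPairs``: mean relatedness between mated pairs;
``rAverage``: mean relatedness between opposite-sex pairs in the population)
are correlation coefficients.  Before modelling they are put on the Fisher-Z
scale, zr = atanh(r), with sampling variance 1/(n - 3), the standard
large-sample variance of a z-transformed correlation.  Inbreeding-depression
evidence arrives either as a fitness-inbreeding correlation or as group
summaries (mean/SD/n of inbred vs outbred offspring), which are converted to
a correlation via a standardized mean difference.

The module also validates the categorical classifications (avoidance
mechanism, random mating, cooperative breeding) and collapses duplicate
population rows to one row per species.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "SpeciesRecord",
    "EffectSize",
    "DepressionEffect",
    "fisher_z",
    "inv_fisher_z",
    "sampling_variance",
    "smd_to_r",
    "build_species_table",
    "validate_species_table",
    "SCHEMA_COLUMNS",
]

#: boundary clip applied to |r| = 1 before the z-transform
R_CLIP = 1.0 - 1e-6

DEPRESSION_LEVELS = {"yes", "no", "not_mentioned"}
MECHANISM_LEVELS = {"active_mate_choice", "sex_biased_dispersal", "post_mating_avoidance", "none"}
YESNO_LEVELS = {"yes", "no"}
COOPERATIVE_LEVELS = {"yes", "no", "not_applicable"}
FITNESS_LEVELS = {"reproductive_success", "mortality", "body_mass"}

#: input CSV schema, one row per study population
SCHEMA_COLUMNS = [
    "species_id", "class_name", "r_pairs", "n_pairs", "r_average", "n_average",
    "depression_reported", "mechanism", "random_mating", "cooperative", "year",
    "dep_r", "dep_n", "dep_mean_in", "dep_sd_in", "dep_n_in",
    "dep_mean_out", "dep_sd_out", "dep_n_out", "fitness_category",
]

CATEGORICAL_COLUMNS = [
    "class_name", "depression_reported", "mechanism", "random_mating",
    "cooperative", "fitness_category",
]


@dataclass
class EffectSize:
    """A Fisher-Z effect size with its sampling variance and originating n."""

    zr: float
    var: float
    n: int

    def __post_init__(self) -> None:
        if not math.isfinite(self.zr):
            raise ValueError(f"non-finite Fisher-Z value {self.zr!r}")
        expected = sampling_variance(self.n)
        if not math.isclose(self.var, expected, rel_tol=1e-12):
            raise ValueError(f"var {self.var} != 1/(n-3) = {expected} for n={self.n}")


@dataclass
class DepressionEffect:
    """Fisher-Z of the fitness-inbreeding correlation.

    ``direction_convention`` records the sign orientation: with
    ``"depression_positive"`` (the default produced by :func:`smd_to_r`),
    positive values mean inbreeding reduces fitness.
    """

    zr_depression: float
    var: float
    direction_convention: str = "depression_positive"

    def __post_init__(self) -> None:
        if not self.var > 0:
            raise ValueError(f"sampling variance must be positive, got {self.var}")


@dataclass
class SpeciesRecord:
    """One species in the comparative analysis (the unit of analysis)."""

    species_id: str
    class_name: str
    r_pairs: float
    n_pairs: int
    r_average: float
    n_average: int
    depression_reported: str
    mechanism: str
    random_mating: str
    cooperative: str
    year: int
    depression_raw: Optional[dict] = None
    fitness_category: Optional[str] = None
    warnings: list = field(default_factory=list)


def fisher_z(r: float) -> float:
    """Fisher's Z transform, zr = 0.5 * ln((1+r)/(1-r)) = atanh(r).

    Correlations exactly at the +/-1 boundary are clipped to
    +/-(1 - 1e-6) with a warning; values beyond the boundary raise.
    """
    r = float(r)
    if not math.isfinite(r) or abs(r) > 1:
        raise ValueError(f"correlation {r!r} outside [-1, 1]")
    if abs(r) == 1.0:
        warnings.warn(f"correlation {r} clipped to {math.copysign(R_CLIP, r)} before Fisher-Z")
        r = math.copysign(R_CLIP, r)
    return math.atanh(r)


def inv_fisher_z(zr: float) -> float:
    """Inverse Fisher-Z: r = tanh(zr)."""
    zr = float(zr)
    if not math.isfinite(zr):
        raise ValueError(f"non-finite Fisher-Z value {zr!r}")
    return math.tanh(zr)


def sampling_variance(n) -> float:
    """Sampling variance of a Fisher-Z correlation, 1/(n - 3).

    Requires an integer n >= 4; records with n <= 3 carry no usable
    precision and must be excluded upstream.
    """
    if n != int(n):
        raise ValueError(f"sample size must be an integer, got {n!r}")
    n = int(n)
    if n <= 3:
        raise ValueError(
            f"n = {n} gives no finite sampling variance 1/(n-3); exclude this record"
        )
    return 1.0 / (n - 3)


def smd_to_r(
    mean_inbred: float,
    mean_outbred: float,
    sd_inbred: float,
    sd_outbred: float,
    n_inbred: int,
    n_outbred: int,
) -> DepressionEffect:
    """Convert inbred-vs-outbred group summaries to a depression effect size.

    Computes the pooled-SD standardized mean difference

        d = (mean_inbred - mean_outbred) / s_pooled,

    converts it to a correlation with r = d / sqrt(d^2 + a),
    a = (n1 + n2)^2 / (n1 * n2), and transforms to the Fisher-Z scale.
    The variance of d,

        v_d = (n1 + n2) / (n1 * n2) + d^2 / (2 (n1 + n2)),

    is propagated to the z scale by the delta method.  The sign is oriented
    so that positive zr_depression means inbreeding reduces fitness
    (inbred offspring doing worse than outbred give positive values).
    """
    n1, n2 = int(n_inbred), int(n_outbred)
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2 to pool standard deviations")
    if sd_inbred <= 0 or sd_outbred <= 0:
        raise ValueError("group standard deviations must be positive")
    s_pooled = math.sqrt(
        ((n1 - 1) * sd_inbred ** 2 + (n2 - 1) * sd_outbred ** 2) / (n1 + n2 - 2)
    )
    if s_pooled == 0:
        raise ValueError("pooled standard deviation is zero; effect size undefined")
    d = (mean_inbred - mean_outbred) / s_pooled
    a = (n1 + n2) ** 2 / (n1 * n2)
    r = d / math.sqrt(d * d + a)
    v_d = (n1 + n2) / (n1 * n2) + d * d / (2 * (n1 + n2))
    # delta method: dr/dd = a / (d^2 + a)^{3/2}; dz/dr = 1 / (1 - r^2)
    dr_dd = a / (d * d + a) ** 1.5
    v_r = dr_dd ** 2 * v_d
    v_z = v_r / (1 - r * r) ** 2
    # orientation: lower inbred fitness (d < 0) is "depression present" -> positive z
    zr = -fisher_z(r)
    return DepressionEffect(zr_depression=zr, var=v_z)


def _depression_effect_from_row(row: pd.Series) -> Optional[DepressionEffect]:
    """Build a DepressionEffect from whichever raw evidence a row carries."""
    if pd.notna(row.get("dep_r")):
        if pd.isna(row.get("dep_n")):
            raise ValueError(f"{row['species_id']}: dep_r given without dep_n")
        # a reported fitness~inbreeding correlation: negative r = depression,
        # so flip onto the depression-positive convention
        return DepressionEffect(
            zr_depression=-fisher_z(float(row["dep_r"])),
            var=sampling_variance(row["dep_n"]),
        )
    group_cols = ["dep_mean_in", "dep_sd_in", "dep_n_in", "dep_mean_out", "dep_sd_out", "dep_n_out"]
    present = [c for c in group_cols if pd.notna(row.get(c))]
    if not present:
        return None
    if len(present) < len(group_cols):
        missing = sorted(set(group_cols) - set(present))
        raise ValueError(f"{row['species_id']}: incomplete group summaries, missing {missing}")
    return smd_to_r(
        row["dep_mean_in"], row["dep_mean_out"],
        row["dep_sd_in"], row["dep_sd_out"],
        row["dep_n_in"], row["dep_n_out"],
    )


def validate_species_table(df: pd.DataFrame) -> list:
    """Check schema and category levels; return a list of soft warnings.

    Hard violations (unknown columns/levels, missing required fields, n <= 3)
    raise; pattern violations the analysis tolerates in real data (for
    example a reported avoidance mechanism in a species without inbreeding
    depression) are flagged and returned.
    """
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"input table is missing required columns: {missing}")
    checks = {
        "depression_reported": DEPRESSION_LEVELS,
        "mechanism": MECHANISM_LEVELS,
        "random_mating": YESNO_LEVELS,
        "cooperative": COOPERATIVE_LEVELS,
        "fitness_category": FITNESS_LEVELS,
    }
    for col, levels in checks.items():
        vals = df[col].dropna()
        if col == "fitness_category":
            vals = vals[vals != ""]
        bad = sorted(set(vals) - levels)
        if bad:
            raise ValueError(f"unknown levels {bad} in column {col!r}")
    for col in ["species_id", "r_pairs", "n_pairs", "r_average", "n_average", "year"]:
        if df[col].isna().any():
            rows = df.index[df[col].isna()].tolist()
            raise ValueError(f"missing values in required column {col!r} (rows {rows})")
    flags = []
    for _, row in df.iterrows():
        for col in ("n_pairs", "n_average"):
            sampling_variance(row[col])  # raises on n <= 3
        if row["depression_reported"] == "no" and row["mechanism"] != "none":
            flags.append(
                f"{row['species_id']}: mechanism {row['mechanism']!r} reported "
                "despite no reported inbreeding depression"
            )
    return flags


def _merge_duplicate_populations(df: pd.DataFrame) -> pd.DataFrame:
    """Average duplicate population rows per species on the r scale."""
    out_rows = []
    for species, grp in df.groupby("species_id", sort=False):
        if len(grp) == 1:
            out_rows.append(grp.iloc[0])
            continue
        conflicts = [
            c for c in CATEGORICAL_COLUMNS
            if grp[c].fillna("").nunique() > 1
        ]
        if conflicts:
            raise ValueError(
                f"species {species!r} has conflicting categorical labels across "
                f"populations in columns {conflicts}"
            )
        row = grp.iloc[0].copy()
        for col in ("r_pairs", "r_average"):
            row[col] = grp[col].mean()
        for col in ("n_pairs", "n_average", "year"):
            row[col] = int(round(grp[col].mean()))
        out_rows.append(row)
    return pd.DataFrame(out_rows).reset_index(drop=True)


def build_species_table(raw: pd.DataFrame) -> pd.DataFrame:
    """Build the tidy analysis table: one row per species with Zr columns.

    Steps: validate the schema; average duplicate-population rows on the r
    scale; transform relatedness to Fisher-Z with variances 1/(n-3); derive
    the depression effect size where quantitative evidence exists; and add
    ``depression_analysis``, the analysis-time recoding in which
    ``not_mentioned`` counts as ``yes`` (species lacking a report are
    assumed to suffer inbreeding depression, the most likely outcome;
    the original ``depression_reported`` value is retained).

    The operation is idempotent: applying it to its own output (restricted
    to the schema columns) returns the same table.
    """
    flags = validate_species_table(raw)
    for msg in flags:
        warnings.warn(msg)
    df = _merge_duplicate_populations(raw.copy())
    df["zr_pairs"] = [fisher_z(r) for r in df["r_pairs"]]
    df["var_pairs"] = [sampling_variance(n) for n in df["n_pairs"]]
    df["zr_average"] = [fisher_z(r) for r in df["r_average"]]
    df["var_average"] = [sampling_variance(n) for n in df["n_average"]]
    zr_dep, var_dep = [], []
    for _, row in df.iterrows():
        eff = _depression_effect_from_row(row)
        zr_dep.append(eff.zr_depression if eff else np.nan)
        var_dep.append(eff.var if eff else np.nan)
    df["zr_depression"] = zr_dep
    df["var_depression"] = var_dep
    df["depression_analysis"] = np.where(
        df["depression_reported"].isin(["yes", "not_mentioned"]), "yes", "no"
    )
    df["n_pairs"] = df["n_pairs"].astype(int)
    df["n_average"] = df["n_average"].astype(int)
    df["year"] = df["year"].astype(int)
    return df
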