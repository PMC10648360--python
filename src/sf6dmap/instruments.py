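"""FACT-L scoring, missing-value imputation and mapping design matrices.

The FACT-L (v4.0) holds 36 items in five dimensions: physical (PWB, 7
items), social/family (SWB, 7), emotional (EWB, 6) and functional (FWB, 7)
well-being — together the 27-item FACT-G — plus a 9-item lung cancer
subscale (LCS) of which two items are excluded from scoring.  Each item is
answered 0–4; negatively worded items are reverse-scored as ``4 - response``
so that higher always means better.  Domain scores are sums of scored
items (maxima 28, 28, 24, 28, 28); the analysis total is the sum of the
five scored domains (maximum 136).  The raw instrument item sum, 36 x 4 =
144, is retained only as a validation constant.

Five mapping design matrices are defined on top of the domain scores:

====  =========================================================
M1    total
M2    total, total^2
M3    pwb, swb, ewb, fwb, lcs
M4    M3 + the five squared domain scores
M5    M4 + age + sex
====  =========================================================

each preceded by an intercept column.  Sex is coded 1 = male, 0 = female
by default (configurable; the direction matters for the published
coefficients shipped with the package).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DOMAINS = ("pwb", "swb", "ewb", "fwb", "lcs")
DOMAIN_ITEM_COUNTS = {"pwb": 7, "swb": 7, "ewb": 6, "fwb": 7, "lcs": 9}
DOMAIN_MAXIMA = {"pwb": 28, "swb": 28, "ewb": 24, "fwb": 28, "lcs": 28}

#: Raw instrument constants (validation only; the analysis total maxes at 136).
FACTL_ITEM_COUNT = 36
FACTG_ITEM_COUNT = 27
FACTL_RAW_MAX_SCORE = FACTL_ITEM_COUNT * 4  # 144
FACTL_TOTAL_MAX = 136

MODEL_IDS = ("M1", "M2", "M3", "M4", "M5")

#: Human-readable term lists for the five model specifications.
MODEL_TERMS = {
    "M1": ("total",),
    "M2": ("total", "total_sq"),
    "M3": DOMAINS,
    "M4": DOMAINS + tuple(f"{d}_sq" for d in DOMAINS),
    "M5": DOMAINS + tuple(f"{d}_sq" for d in DOMAINS) + ("age", "sex"),
}


def _default_item_dimensions() -> tuple[str, ...]:
    out: list[str] = []
    for d in DOMAINS:
        out.extend([d] * DOMAIN_ITEM_COUNTS[d])
    return tuple(out)


def _default_reverse_scored() -> tuple[bool, ...]:
    # Negatively worded items are reverse-scored.  The instrument does not
    # publish this map alongside the mapping coefficients, so a standard
    # v4.0 layout ships as the default: all PWB items negative, SWB/FWB
    # positive, EWB negative except the coping item (index 15), LCS mixed.
    flags = [False] * FACTL_ITEM_COUNT
    for i in range(0, 7):  # PWB
        flags[i] = True
    for i in range(14, 20):  # EWB
        flags[i] = True
    flags[15] = False
    for i in (27, 28, 30, 32):  # LCS: short of breath, weight loss, cough, chest
        flags[i] = True
    return tuple(flags)


def _default_scored() -> tuple[bool, ...]:
    # Two of the nine LCS items (conventionally the smoking items, shipped
    # here as the final two LCS slots) are excluded from scoring.
    flags = [True] * FACTL_ITEM_COUNT
    flags[34] = flags[35] = False
    return tuple(flags)


@dataclass(frozen=True)
class FactLItemConfig:
    """Item-level scoring configuration: dimension map, polarity, scored flags."""

    item_dimensions: tuple[str, ...] = field(default_factory=_default_item_dimensions)
    reverse_scored: tuple[bool, ...] = field(default_factory=_default_reverse_scored)
    scored: tuple[bool, ...] = field(default_factory=_default_scored)

    def __post_init__(self) -> None:
        if len(self.item_dimensions) != FACTL_ITEM_COUNT:
            raise ValueError(f"expected {FACTL_ITEM_COUNT} items")
        if len(self.reverse_scored) != FACTL_ITEM_COUNT:
            raise ValueError("one reverse-scored flag per item required")
        if len(self.scored) != FACTL_ITEM_COUNT:
            raise ValueError("one scored flag per item required")
        counts = {d: self.item_dimensions.count(d) for d in DOMAINS}
        if counts != DOMAIN_ITEM_COUNTS:
            raise ValueError(f"dimension item counts {counts} != {DOMAIN_ITEM_COUNTS}")
        unscored = [
            i for i, s in enumerate(self.scored) if not s
        ]
        if any(self.item_dimensions[i] != "lcs" for i in unscored) or len(unscored) != 2:
            raise ValueError("exactly 2 LCS items must be unscored")


def score_factl(
    items: np.ndarray | pd.DataFrame,
    config: FactLItemConfig | None = None,
    impute: str = "median",
) -> pd.DataFrame:
    """Score FACT-L item responses into domain scores and the total.

    Parameters
    ----------
    items
        (n_subjects, 36) array of ordinal responses in 0..4; NaN marks a
        missing response.
    config
        Item scoring configuration; defaults to the shipped v4.0 map.
    impute
        ``"median"`` fills a missing response with the cohort median of
        that item (over non-missing responses, before reverse-scoring);
        ``"none"`` raises on any missing response.

    Returns
    -------
    DataFrame with columns ``pwb, swb, ewb, fwb, lcs, total``.
    """
    config = config or FactLItemConfig()
    values = np.asarray(items, dtype=float)
    if values.ndim == 1:
        values = values[None, :]
    if values.shape[1] != FACTL_ITEM_COUNT:
        raise ValueError(f"expected {FACTL_ITEM_COUNT} item columns, got {values.shape[1]}")
    with np.errstate(invalid="ignore"):
        if np.nanmin(values, initial=0) < 0 or np.nanmax(values, initial=0) > 4:
            raise ValueError("item responses must lie in 0..4")

    dims = np.asarray(config.item_dimensions)
    scored = np.asarray(config.scored)
    # a subject with every scored item of a dimension missing cannot be scored
    for d in DOMAINS:
        cols = (dims == d) & scored
        all_missing = np.isnan(values[:, cols]).all(axis=1)
        if all_missing.any():
            i = int(np.flatnonzero(all_missing)[0])
            raise ValueError(
                f"subject {i}: all scored {d.upper()} items missing; cannot score"
            )

    if np.isnan(values).any():
        if impute == "none":
            raise ValueError("missing item responses present and impute='none'")
        if impute != "median":
            raise ValueError(f"unknown imputation policy {impute!r}")
        medians = np.nanmedian(values, axis=0)
        if np.isnan(medians).any():
            j = int(np.flatnonzero(np.isnan(medians))[0])
            raise ValueError(f"item {j} is missing for every subject")
        values = np.where(np.isnan(values), medians[None, :], values)

    rev = np.asarray(config.reverse_scored)
    scored_vals = np.where(rev[None, :], 4.0 - values, values)
    out = {}
    for d in DOMAINS:
        cols = (dims == d) & scored
        out[d] = scored_vals[:, cols].sum(axis=1)
    frame = pd.DataFrame(out)
    frame["total"] = frame[list(DOMAINS)].sum(axis=1)
    return frame


def impute_median(data: pd.DataFrame) -> pd.DataFrame:
    """Fill missing entries of each numeric column with that column's median.

    The median is taken over non-missing entries (arithmetic mean of the two
    middle values for even counts).  A column with no observed value at all
    cannot be imputed and raises.
    """
    out = data.copy()
    numeric = out.select_dtypes(include=[np.number]).columns
    for col in numeric:
        if out[col].isna().all():
            raise ValueError(f"column {col!r} is entirely missing; cannot impute")
        if out[col].isna().any():
            out[col] = out[col].fillna(out[col].median())
    return out


def build_design_matrix(
    data: pd.DataFrame, spec: str
) -> tuple[np.ndarray, list[str]]:
    """Build the regressor matrix for one of the model specifications M1–M5.

    ``data`` needs the five domain-score columns (``total`` is derived if
    absent) and, for M5, ``age`` and ``sex``.  Returns the matrix with a
    leading intercept column and the column names.
    """
    if spec not in MODEL_IDS:
        raise ValueError(f"unknown model spec {spec!r}; expected one of {MODEL_IDS}")
    df = data
    missing = [d for d in DOMAINS if d not in df.columns]
    if spec in ("M1", "M2") and "total" in df.columns:
        missing = []
    if missing:
        raise ValueError(f"missing domain score columns: {missing}")

    if "total" in df.columns:
        total = df["total"].to_numpy(dtype=float)
    else:
        total = df[list(DOMAINS)].sum(axis=1).to_numpy(dtype=float)

    cols: list[np.ndarray] = [np.ones(len(df))]
    names = ["intercept"]
    for term in MODEL_TERMS[spec]:
        if term == "total":
            cols.append(total)
        elif term == "total_sq":
            cols.append(total**2)
        elif term.endswith("_sq"):
            cols.append(df[term[:-3]].to_numpy(dtype=float) ** 2)
        elif term in ("age", "sex"):
            if term not in df.columns:
                raise ValueError(f"column {term!r} required for spec {spec}")
            cols.append(df[term].to_numpy(dtype=float))
        else:
            cols.append(df[term].to_numpy(dtype=float))
        names.append(term)
    X = np.column_stack(cols)
    if np.isnan(X).any():
        raise ValueError("design matrix contains missing values; impute first")
    return X, names
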