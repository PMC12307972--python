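"""DHS-style relative wealth index from categorical household assets.

Households report categorical asset indicators (water source, toilet
type, cooking arrangements, commodities such as electricity or a radio,
and housing materials).  Multiple correspondence analysis — simple
correspondence analysis of the complete disjunctive (indicator) matrix —
extracts the dominant axis of variation, whose row coordinates rank
households by relative wealth.  Households are then weighted by their
size (all members, including children) and split into person-weighted
quintiles: class 1 is the poorest fifth of *persons*, class 5 the
richest.  No Benzecri/Greenacre inertia correction is applied; raw
inertia shares are reported, as in the DHS construction guide.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ASSET_ITEMS",
    "WealthIndexModel",
    "fit_mca",
    "assign_wealth_classes",
    "validate_index",
    "binarize_items",
]

# item -> number of ordered categories (0 = worst .. m-1 = best)
ASSET_ITEMS: dict[str, int] = {
    "water_source": 3,
    "toilet_type": 3,
    "stove_use": 2,
    "cooking_fuel": 3,
    "electricity": 2,
    "radio": 2,
    "television": 2,
    "mobile_phone": 2,
    "non_mobile_phone": 2,
    "separate_kitchen": 2,
    "windows": 2,
    "floor_material": 3,
    "wall_material": 3,
    "roof_material": 3,
}


@dataclass
class WealthIndexModel:
    """Fitted MCA wealth model: household scores plus category geometry."""

    scores: pd.Series                  # dimension-1 row coordinates per household
    category_coordinates: pd.DataFrame  # index item=category, column per dimension
    inertia_shares: np.ndarray         # fraction of total inertia per dimension
    orientation_sign: float
    anchor: tuple[str, object]
    dropped_items: list[str] = field(default_factory=list)

    @property
    def pct_inertia_dim1(self) -> float:
        return float(100.0 * self.inertia_shares[0])


def _indicator(assets: pd.DataFrame) -> tuple[np.ndarray, list[tuple[str, object]]]:
    blocks, labels = [], []
    for item in assets.columns:
        col = assets[item]
        cats = sorted(col.unique(), key=str)
        dummies = np.stack([(col == c).to_numpy(float) for c in cats], axis=1)
        blocks.append(dummies)
        labels.extend((item, c) for c in cats)
    return np.concatenate(blocks, axis=1), labels


def fit_mca(
    assets: pd.DataFrame,
    n_dims: int = 5,
    anchor: tuple[str, object] | None = None,
) -> WealthIndexModel:
    """Fit multiple correspondence analysis to a household-asset table.

    Parameters
    ----------
    assets : DataFrame indexed by household id, one categorical column per item.
        Missing values must have been excluded upstream.
    n_dims : number of dimensions to retain for reporting.
    anchor : (item, category) whose dimension-1 category coordinate is
        forced positive, fixing the sign so higher scores mean richer.
        Default: the highest observed category of ``electricity`` (or of
        the first column if electricity is absent).

    Notes
    -----
    Standard CA of the indicator matrix: with correspondence matrix
    ``P = Z / N``, row masses r and column masses c, the standardized
    residual matrix ``S = D_r^{-1/2} (P - r c') D_c^{-1/2}`` is
    decomposed by SVD; dimension-d row principal coordinates are
    ``D_r^{-1/2} U_d sigma_d``.
    """
    if assets.isna().any().any():
        raise ValueError("missing asset values must be excluded before fitting")
    if len(assets) < 2:
        raise ValueError("need at least 2 households")
    dropped = [c for c in assets.columns if assets[c].nunique() < 2]
    if dropped:
        warnings.warn(f"dropping constant asset item(s): {dropped}")
        assets = assets.drop(columns=dropped)
    if assets.shape[1] == 0:
        raise ValueError("all asset items are constant; MCA is undefined")

    Z, labels = _indicator(assets)
    N = Z.sum()
    P = Z / N
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sig, Vt = np.linalg.svd(S, full_matrices=False)
    # trivial dimensions have ~zero singular value; total inertia = sum sig^2
    keep = sig > 1e-12
    U, sig, Vt = U[:, keep], sig[keep], Vt[keep]
    n_dims = min(n_dims, len(sig))
    inertia = sig**2
    shares = inertia / inertia.sum()

    row_coords = (U[:, :n_dims] * sig[:n_dims]) / np.sqrt(r)[:, None]
    col_coords = (Vt[:n_dims].T * sig[:n_dims]) / np.sqrt(c)[:, None]

    if anchor is None:
        item = "electricity" if "electricity" in assets.columns else assets.columns[0]
        cats = [lab for lab in labels if lab[0] == item]
        anchor = max(cats, key=lambda lab: str(lab[1]))
    try:
        a_idx = labels.index(anchor)
    except ValueError:
        raise ValueError(f"anchor category {anchor!r} not present in the data")
    sign = 1.0 if col_coords[a_idx, 0] >= 0 else -1.0

    idx = pd.Index([f"{it}={cat}" for it, cat in labels])
    return WealthIndexModel(
        scores=pd.Series(sign * row_coords[:, 0], index=assets.index, name="mca_score"),
        category_coordinates=pd.DataFrame(
            sign * col_coords, index=idx, columns=[f"dim{d + 1}" for d in range(n_dims)]
        ),
        inertia_shares=shares,
        orientation_sign=sign,
        anchor=anchor,
        dropped_items=dropped,
    )


def assign_wealth_classes(scores: pd.Series, household_sizes: pd.Series, n_classes: int = 5):
    """Person-weighted quintile classes (1 = poorest .. 5 = richest).

    Breakpoints are taken on the person-expanded score distribution:
    each household counts once per member, so a large household shifts
    the quintile boundaries.  Households tied on score form a block
    assigned to the lower class.

    Returns
    -------
    (household_classes, person_share) : Series of classes per household,
    and the achieved share of persons per class.
    """
    if (household_sizes < 1).any():
        raise ValueError("household sizes must be >= 1")
    sizes = household_sizes.reindex(scores.index)
    if sizes.isna().any():
        raise ValueError("household_sizes missing for some scored households")
    order = scores.sort_values(kind="mergesort").index
    total = float(sizes.sum())
    per_class = total / n_classes
    classes = pd.Series(0, index=scores.index, dtype=int)
    cum = 0.0
    i = 0
    order = list(order)
    while i < len(order):
        j = i
        while j < len(order) and scores[order[j]] == scores[order[i]]:
            j += 1
        block = order[i:j]  # tie block -> lower class, from its first person
        cls = min(n_classes, int(math.ceil((cum + 1.0) / per_class)))
        classes[block] = max(1, cls)
        cum += float(sizes[block].sum())
        i = j
    share = sizes.groupby(classes).sum() / total
    share = share.reindex(range(1, n_classes + 1), fill_value=0.0)
    return classes, share


def validate_index(scores: pd.Series, external_measure: pd.Series) -> dict:
    """External-validation hook: correlate the index with another measure."""
    common = scores.index.intersection(external_measure.index)
    if len(common) < 3:
        raise ValueError("need at least 3 overlapping households to validate")
    x = scores[common].to_numpy(float)
    y = external_measure[common].to_numpy(float)
    sp = stats.spearmanr(x, y)
    pe = stats.pearsonr(x, y)
    n = len(common)

    def fisher_ci(rho):
        if abs(rho) >= 1 or n < 4:
            return (float("nan"), float("nan"))
        z = np.arctanh(rho)
        hw = 1.959963984540054 / math.sqrt(n - 3)
        return (float(np.tanh(z - hw)), float(np.tanh(z + hw)))

    return {
        "n": n,
        "spearman": float(sp.statistic),
        "spearman_ci": fisher_ci(float(sp.statistic)),
        "spearman_p": float(sp.pvalue),
        "pearson": float(pe.statistic),
        "pearson_ci": fisher_ci(float(pe.statistic)),
        "pearson_p": float(pe.pvalue),
    }


def binarize_items(assets: pd.DataFrame, mapping: dict[str, set] | None = None) -> pd.DataFrame:
    """Map each categorical asset item to a high (1) / low (0) outcome.

    Default mapping marks codes strictly above the midpoint of the
    item's observed code range as "high" (improved); e.g. for a binary
    0/1 item only 1 is high, for a 0/1/2 item only 2 is high.  A custom
    ``mapping`` of item -> set of high categories overrides this and is
    echoed into reports.
    """
    out = {}
    for item in assets.columns:
        col = assets[item]
        if mapping and item in mapping:
            high = mapping[item]
            out[item] = col.isin(high).astype(int)
        else:
            codes = pd.to_numeric(col)
            mid = (codes.min() + codes.max()) / 2.0
            out[item] = (codes > mid).astype(int)
    return pd.DataFrame(out, index=assets.index)
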