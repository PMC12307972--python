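"""Individual-level association batteries linking cycle metrics to wealth.

The battery mirrors a sociocentric study design: for each wealth
variable (the 1-5 wealth index plus binarized asset items) and each
motif size k in {3,4,5}, a mixed model with a village random intercept
relates the outcome to a key network predictor.

Families
--------
quantity_cross / quantity_long
    wealth ~ k-cycles + k-paths + degree + village wealth (+ wave-1
    outcome for the longitudinal case), cycles as the key predictor.
reverse_cross / reverse_long
    k-cycle count (log1p, standardized) as the outcome, wealth as key
    predictor.
quality_cross / quality_long / quality_reverse_cross / quality_reverse_long
    cycle composition ("quality") as key predictor or outcome, with
    village wealth as the control; persons in no k-cycle are excluded
    (quality undefined), never zero-imputed.
benchmark
    any family rerun with eigenvector (optionally degree/betweenness)
    centrality added to the controls.
stratified
    gain-vs-loss contrasts by initial wealth class (separate entry
    point, :func:`stratified_gain_loss`).

Binary outcomes use a random-intercept logistic (Gauss-Hermite ML);
the 1-5 wealth index and continuous count/quality outcomes use a linear
mixed model (statsmodels MixedLM).  All continuous variables are
z-scored before fitting, so coefficients are on the SD scale.
Benjamini-Hochberg correction is applied within each declared family.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .glmm import fit_logistic_random_intercept

__all__ = [
    "ModelSpec", "ModelResult", "BINARY_OUTCOMES", "ALL_OUTCOMES", "FAMILIES",
    "fit_individual_model", "run_battery", "benchmark_with_centrality",
    "stratified_gain_loss", "odds_multiplier", "bh_adjust",
]

BINARY_OUTCOMES = (
    "electricity", "radio", "television", "toilet_type",
    "cooking_fuel", "floor_material", "roof_material",
)
ALL_OUTCOMES = ("wealth_index",) + BINARY_OUTCOMES

FAMILIES = (
    "quantity_cross", "quantity_long", "reverse_cross", "reverse_long",
    "quality_cross", "quality_long", "quality_reverse_cross", "quality_reverse_long",
)


@dataclass(frozen=True)
class ModelSpec:
    """One battery cell: family x outcome x motif size."""

    family: str
    outcome: str
    k: int
    extra_controls: tuple[str, ...] = ()
    scaling: str = "zscore"  # or "2sd" (divide by 2 SD, per Gelman)

    @property
    def spec_id(self) -> str:
        extra = "+".join(self.extra_controls)
        return f"{self.family}:{self.outcome}:k{self.k}" + (f":{extra}" if extra else "")


@dataclass
class ModelResult:
    """One association estimate from the battery."""

    spec_id: str
    family: str
    outcome: str
    k: int
    term: str
    coef: float
    se: float
    p: float
    q: float
    link: str
    n_obs: int
    n_villages: int
    converged: bool
    flags: list[str] = field(default_factory=list)
    max_vif: float = float("nan")

    def to_row(self) -> dict:
        d = self.__dict__.copy()
        d["flags"] = ";".join(d["flags"])
        return d


def odds_multiplier(beta: float, x: float) -> float:
    """Odds multiplier for an x-unit increase under logistic coefficient beta.

    E.g. beta=0.1 and x=10 cycles gives e^(10*0.1) = 2.72: ten more
    length-5 cycles multiply the odds of the outcome by about 2.72.
    """
    return math.exp(beta * x)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg q-values (step-up FDR) for one correction family."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _scale(x: pd.Series, mode: str) -> pd.Series:
    sd = x.std(ddof=0)
    if sd == 0 or np.isnan(sd):
        return x * 0.0
    denom = 2 * sd if mode == "2sd" else sd
    return (x - x.mean()) / denom


def _design(data: pd.DataFrame, spec: ModelSpec):
    """Assemble (y, X, groups, link) for one battery cell.

    The analysis table is wide per person with ``_w1`` / ``_w2``
    suffixed columns (see pipeline.assemble_analysis_table).
    """
    k, fam = spec.k, spec.family
    cyc, pat, qual = f"cycles_{k}", f"paths_{k}", f"quality_{k}"
    out = spec.outcome
    binary = out in BINARY_OUTCOMES

    def col(name, wave):
        return f"{name}_w{wave}"

    controls = list(spec.extra_controls)
    if fam == "quantity_cross":
        y, key = col(out, 1), col(cyc, 1)
        ctrl = [col(pat, 1), col("degree", 1), col("village_wealth", 1)]
        link = "logistic" if binary else "linear"
    elif fam == "quantity_long":
        y, key = col(out, 2), col(cyc, 1)
        ctrl = [col(pat, 1), col("degree", 1), col(out, 1), col("village_wealth", 1)]
        link = "logistic" if binary else "linear"
    elif fam == "reverse_cross":
        y, key = col(cyc, 1), col(out, 1)
        ctrl = [col(pat, 1), col("degree", 1), col("village_wealth", 1)]
        link = "linear"
    elif fam == "reverse_long":
        y, key = col(cyc, 2), col(out, 1)
        ctrl = [col(pat, 1), col("degree", 1), col(cyc, 1), col("village_wealth", 1)]
        link = "linear"
    elif fam == "quality_cross":
        y, key = col(out, 1), col(qual, 1)
        ctrl = [col("village_wealth", 1)]
        link = "logistic" if binary else "linear"
    elif fam == "quality_long":
        y, key = col(out, 2), col(qual, 1)
        ctrl = [col(out, 1), col("village_wealth", 1)]
        link = "logistic" if binary else "linear"
    elif fam == "quality_reverse_cross":
        y, key = col(qual, 1), col(out, 1)
        ctrl = [col("village_wealth", 1)]
        link = "linear"
    elif fam == "quality_reverse_long":
        y, key = col(qual, 2), col(out, 1)
        ctrl = [col(qual, 1), col("village_wealth", 1)]
        link = "linear"
    else:
        raise ValueError(f"unknown model family {fam!r}")
    ctrl += [c if c.endswith(("_w1", "_w2")) else col(c, 1) for c in controls]

    fixed = [key] + ctrl
    if len(set(fixed)) < len(fixed):
        raise ValueError(
            "design matrix would be rank deficient: a control duplicates the key predictor"
        )
    cols = [y, key] + ctrl + ["village_id"]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"analysis table lacks column(s) {missing} for {spec.spec_id}")
    d = data[cols].dropna()

    def prep(name: str, as_outcome: bool) -> pd.Series:
        s = d[name].astype(float)
        base = name.rsplit("_w", 1)[0]
        if base in BINARY_OUTCOMES:
            return s  # binary stays 0/1 even as a control
        if base.startswith("cycles_") or base.startswith("paths_"):
            s = np.log1p(s)  # heavy right tail
        if as_outcome and link == "logistic":
            return s
        return _scale(s, spec.scaling)

    yv = prep(y, as_outcome=True)
    X = pd.DataFrame({"const": 1.0}, index=d.index)
    X[key] = prep(key, as_outcome=False)
    for c in ctrl:
        X[c] = prep(c, as_outcome=False)
    return yv, X, d["village_id"], link, key


def fit_individual_model(data: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """Fit one battery cell; non-convergence is flagged, not raised."""
    y, X, groups, link, key = _design(data, spec)
    n_villages = groups.nunique()
    if n_villages < 2:
        raise ValueError("random intercept requires at least 2 villages")
    flags: list[str] = []
    vif = float("nan")
    if X.shape[1] > 2:
        try:
            arr = X.to_numpy(float)
            vifs = [variance_inflation_factor(arr, i) for i in range(1, X.shape[1])]
            vif = float(np.nanmax(vifs))
            if vif > 10:
                flags.append("high_vif")
        except Exception:
            flags.append("vif_failed")

    coef = se = p = float("nan")
    converged = False
    if link == "logistic":
        if y.nunique() < 2:
            flags.append("degenerate_outcome")
        else:
            # rank deficiency raises (a control duplicating the key predictor
            # is a caller error, not a data pathology)
            res = fit_logistic_random_intercept(X, y, groups)
            coef, se, p = res.params[key], res.bse[key], res.pvalues[key]
            converged = res.converged
            flags += res.flags
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                md = sm.MixedLM(endog=y.to_numpy(), exog=X, groups=groups.to_numpy())
                res = None
                for method in ("lbfgs", "bfgs", "cg", "powell"):
                    res = md.fit(reml=True, method=method, maxiter=1000)
                    if res.converged:
                        break
                coef = float(res.fe_params[key])
                se = float(res.bse_fe[key])
                p = float(res.pvalues[key])
                converged = bool(res.converged)
                if not converged:
                    flags.append("non_convergence")
            except np.linalg.LinAlgError:
                flags.append("singular_fit")
    return ModelResult(
        spec_id=spec.spec_id, family=spec.family, outcome=spec.outcome, k=spec.k,
        term=key, coef=float(coef), se=float(se), p=float(p), q=float("nan"),
        link=link, n_obs=len(y), n_villages=int(n_villages),
        converged=converged, flags=flags, max_vif=vif,
    )


def run_battery(
    data: pd.DataFrame,
    families=FAMILIES,
    K=(3, 4, 5),
    outcomes=ALL_OUTCOMES,
    extra_controls: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Run every (outcome x k) cell of each family; BH within family.

    Returns a long-format results table with one row per cell, a BH
    q-value computed within the family, and a ``significant`` mask
    (q < 0.05) mirroring heatmap rendering where only significant cells
    are shown.
    """
    rows: list[ModelResult] = []
    for fam in families:
        fam_rows = []
        for out in outcomes:
            for k in K:
                spec = ModelSpec(family=fam, outcome=out, k=k, extra_controls=extra_controls)
                fam_rows.append(fit_individual_model(data, spec))
        if not any(r.converged for r in fam_rows):
            raise RuntimeError(f"no converged fits in family {fam!r}")
        qs = bh_adjust([r.p for r in fam_rows])
        for r, q in zip(fam_rows, qs):
            r.q = float(q)
        rows += fam_rows
    tab = pd.DataFrame([r.to_row() for r in rows])
    tab["significant"] = tab["q"] < 0.05
    return tab


def heatmap_table(results: pd.DataFrame) -> pd.DataFrame:
    """Wide heatmap mask: outcome rows x (family, k) columns, NaN if not significant."""
    t = results.copy()
    t["cell"] = t["family"] + ":k" + t["k"].astype(str)
    masked = t.assign(shown=np.where(t["significant"], t["coef"], np.nan))
    return masked.pivot_table(index="outcome", columns="cell", values="shown", dropna=False)


def benchmark_with_centrality(
    data: pd.DataFrame,
    families=("quantity_cross", "quantity_long"),
    K=(3, 4, 5),
    outcomes=ALL_OUTCOMES,
    controls: tuple[str, ...] = ("eigenvector",),
) -> pd.DataFrame:
    """Re-run a battery with centrality controls and compare significance.

    Returns the base and augmented results side by side with a
    ``significance_changed`` column.
    """
    base = run_battery(data, families=families, K=K, outcomes=outcomes)
    aug = run_battery(data, families=families, K=K, outcomes=outcomes, extra_controls=controls)
    merged = base.merge(
        aug, on=["family", "outcome", "k"], suffixes=("_base", "_ctrl"),
    )
    merged["significance_changed"] = merged["significant_base"] != merged["significant_ctrl"]
    return merged


def stratified_gain_loss(data: pd.DataFrame, metric: str = "quality", K=(3, 4, 5)) -> pd.DataFrame:
    """Gain-vs-loss contrasts of a cycle metric by initial wealth class.

    For each wave-1 wealth-class stratum and each k, gainers
    (class rose) are contrasted with losers (class fell) in a mixed
    logistic of gain on the standardized metric; stable individuals are
    excluded.  The ceiling stratum (class 5) cannot gain, so there
    "gain" means holding class 5 versus dropping.  Output rows carry
    -log10(p) for Manhattan-style display plus the BH threshold mask.
    Strata with fewer than 2 villages or 10 contrasts are reported as
    not estimable.
    """
    if metric not in ("quality", "quantity"):
        raise ValueError("metric must be 'quality' or 'quantity'")
    w1 = data["wealth_class_w1"].astype(float)
    w2 = data["wealth_class_w2"].astype(float)
    rows = []
    for stratum in range(1, 6):
        in_s = w1 == stratum
        if stratum == 5:
            gain = (w2 >= 5) & in_s
            loss = (w2 < 5) & in_s
            boundary = "gain=non-loss (ceiling)"
        else:
            gain = (w2 > w1) & in_s
            loss = (w2 < w1) & in_s
            boundary = ""
        sel = gain | loss
        for k in K:
            colname = f"quality_{k}_w1" if metric == "quality" else f"cycles_{k}_w1"
            d = data.loc[sel, [colname, "village_id"]].copy()
            d["gain"] = gain[sel].astype(int)
            d = d.dropna()
            est = {"stratum": stratum, "k": k, "metric": metric,
                   "n": len(d), "n_villages": d["village_id"].nunique(),
                   "note": boundary}
            if len(d) < 10 or d["village_id"].nunique() < 2 or d["gain"].nunique() < 2:
                est.update(coef=np.nan, p=np.nan, neg_log10_p=np.nan, estimable=False)
            else:
                x = d[colname].astype(float)
                if metric == "quantity":
                    x = np.log1p(x)
                x = _scale(x, "zscore")
                X = pd.DataFrame({"const": 1.0, "metric": x})
                res = fit_logistic_random_intercept(X, d["gain"], d["village_id"])
                p = float(res.pvalues["metric"])
                est.update(coef=float(res.params["metric"]), p=p,
                           neg_log10_p=-math.log10(p) if p > 0 else np.inf,
                           estimable=True)
            rows.append(est)
    tab = pd.DataFrame(rows)
    tab["q"] = bh_adjust(tab["p"])
    tab["significant"] = tab["q"] < 0.05
    return tab
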