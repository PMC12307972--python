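"""Village-level summaries, regressions, and the wealth-label permutation null.

The permutation null asks whether a village's observed mean cycle
quality could arise from its network alone: node wealth labels are
shuffled uniformly within the village (B times, network fixed), which
preserves the village's size, wealth distribution and mean wealth
exactly, and the mean cycle quality is recomputed from the cached cycle
membership.  Per-village Z-scores are pooled across villages by
Stouffer's method, weighting each village by the square root of its
number of quality-defined nodes.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .census import CensusResult

__all__ = [
    "QualityCache", "PermutationNullResult", "build_quality_cache",
    "village_summaries", "village_regressions", "permutation_null_quality",
]


@dataclass
class QualityCache:
    """Cached cycle membership of one village graph, vectorised for permutation.

    ``incidence[k]`` is a (defined-nodes x nodes) matrix whose (d, j)
    entry counts how often node j appears as an alter in d's k-cycles;
    dividing the weighted row sums by (k-1) * cycles gives the
    alters-mean quality without re-enumerating cycles.
    """

    nodes: list
    k_range: list[int]
    incidence: dict[int, np.ndarray]
    cycle_counts: dict[int, np.ndarray]  # per defined node
    defined_index: dict[int, np.ndarray]  # positions of defined nodes in `nodes`

    def mean_quality(self, wealth: np.ndarray, k: int) -> float:
        """Village mean alters-mean k-cycle quality for a wealth vector."""
        if len(self.cycle_counts[k]) == 0:
            return float("nan")
        s = self.incidence[k] @ wealth
        q = s / ((k - 1) * self.cycle_counts[k])
        return float(q.mean())


def build_quality_cache(census: CensusResult, nodes) -> QualityCache:
    """Vectorise a membership-bearing census for fast label permutation."""
    if census.cycle_membership is None:
        raise ValueError("census must be run with with_membership=True")
    nodes = list(nodes)
    pos = {v: i for i, v in enumerate(nodes)}
    incidence, counts, dindex = {}, {}, {}
    for k in census.k_range:
        per_node_alt: dict[int, np.ndarray] = {}
        per_node_cnt: dict[int, int] = {}
        for seq in census.cycle_membership[k]:
            idx = [pos[v] for v in seq]
            for d in idx:
                row = per_node_alt.setdefault(d, np.zeros(len(nodes)))
                for j in idx:
                    if j != d:
                        row[j] += 1.0
                per_node_cnt[d] = per_node_cnt.get(d, 0) + 1
        dd = np.array(sorted(per_node_alt), dtype=int)
        incidence[k] = (np.stack([per_node_alt[d] for d in dd])
                        if len(dd) else np.zeros((0, len(nodes))))
        counts[k] = np.array([per_node_cnt[d] for d in dd], dtype=float)
        dindex[k] = dd
    return QualityCache(nodes=nodes, k_range=census.k_range,
                        incidence=incidence, cycle_counts=counts, defined_index=dindex)


@dataclass
class PermutationNullResult:
    """Per-village and pooled permutation statistics for cycle quality."""

    per_village: pd.DataFrame  # village, k, observed, null_mean, null_sd, z, n_defined, flag
    pooled: pd.DataFrame       # k, pooled_z, pooled_p, n_villages
    B: int
    seed: int


def permutation_null_quality(village_data, B: int = 1000, seed: int = 0, K: int = 5):
    """Wealth-label permutation test of mean cycle quality per village.

    Parameters
    ----------
    village_data : iterable of (village_id, QualityCache, wealth mapping)
        One entry per village; wealth maps node -> class.
    B : permutations per village (>= 100)
    """
    if B < 100:
        raise ValueError("need at least 100 permutations")
    rows = []
    ks = None
    for vid, cache, wealth in village_data:
        ks = cache.k_range if ks is None else ks
        w = np.array([float(wealth[v]) for v in cache.nodes])
        vkey = zlib.crc32(str(vid).encode())  # stable across processes
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(vkey,)))
        perms = np.stack([rng.permutation(w) for _ in range(B)])
        for k in cache.k_range:
            if k > K:
                continue
            n_def = len(cache.cycle_counts[k])
            if n_def == 0:
                rows.append(dict(village=vid, k=k, observed=np.nan, null_mean=np.nan,
                                 null_sd=np.nan, z=np.nan, n_defined=0, flag="no_cycles"))
                continue
            obs = cache.mean_quality(w, k)
            null = np.array([cache.mean_quality(perms[b], k) for b in range(B)])
            mu, sd = float(null.mean()), float(null.std(ddof=1))
            if sd == 0:
                rows.append(dict(village=vid, k=k, observed=obs, null_mean=mu, null_sd=0.0,
                                 z=np.nan, n_defined=n_def, flag="degenerate"))
            else:
                rows.append(dict(village=vid, k=k, observed=obs, null_mean=mu, null_sd=sd,
                                 z=(obs - mu) / sd, n_defined=n_def, flag=""))
    per_village = pd.DataFrame(rows)
    pooled_rows = []
    for k in sorted(per_village["k"].unique()):
        sub = per_village[(per_village["k"] == k) & per_village["z"].notna()]
        if len(sub) == 0:
            pooled_rows.append(dict(k=k, pooled_z=np.nan, pooled_p=np.nan, n_villages=0))
            continue
        wgt = np.sqrt(sub["n_defined"].to_numpy(float))
        z = float((wgt * sub["z"]).sum() / np.sqrt((wgt**2).sum()))
        pooled_rows.append(dict(
            k=k, pooled_z=z, pooled_p=float(2 * stats.norm.sf(abs(z))),
            n_villages=len(sub),
        ))
    return PermutationNullResult(per_village=per_village,
                                 pooled=pd.DataFrame(pooled_rows), B=B, seed=seed)


def village_summaries(per_village_tables: pd.DataFrame) -> pd.DataFrame:
    """One row per village-wave from the merged node-metric table.

    Expects the long node table written by the pipeline (columns:
    village_id, wave, wealth_class, k, cycles, quality plus optional
    cyclic_density / path_density carried per village).  Villages where
    no node has defined quality report quality as missing, not zero.
    """
    t = per_village_tables
    rows = []
    for (vid, wave), g in t.groupby(["village_id", "wave"]):
        base = dict(village_id=vid, wave=wave,
                    size=g["person_id"].nunique(),
                    mean_wealth=g.drop_duplicates("person_id")["wealth_class"].mean())
        for k, gk in g.groupby("k"):
            base[f"total_cycles_{k}"] = int(gk["cycles"].sum() // k) if len(gk) else 0
            q = gk["quality"].dropna()
            base[f"mean_quality_{k}"] = float(q.mean()) if len(q) else np.nan
            for dens in ("cyclic_density", "path_density"):
                if dens in gk:
                    base[f"{dens}_{k}"] = gk[dens].iloc[0]
        rows.append(base)
    return pd.DataFrame(rows)


def _fit_mixed(y, X, groups):
    """MixedLM with optimizer fallbacks; None when every attempt fails (flagged singular)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = sm.MixedLM(endog=y, exog=X, groups=groups)
        for method in ("lbfgs", "bfgs", "cg", "powell"):
            try:
                res = md.fit(reml=True, method=method, maxiter=1000)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if res.converged and np.isfinite(res.bse_fe).all():
                return res
        return None


def _zscore(x: pd.Series) -> pd.Series:
    sd = x.std(ddof=0)
    return (x - x.mean()) / sd if sd > 0 else x * 0.0


def village_regressions(summaries: pd.DataFrame, K=(3, 4, 5)) -> pd.DataFrame:
    """Village-level wealth regressions per motif size.

    Two specifications per k: a mixed model of village wealth on cyclic
    and path density, size, and a wave indicator with a village random
    intercept (both waves required), and a linear model of village
    wealth on mean cycle quality and size.  A size-screening block
    regresses cycle totals and densities on village size.
    """
    if summaries["village_id"].nunique() < 2:
        raise ValueError("village regressions need >= 2 villages for the random effect")
    rows = []
    for k in K:
        dens = summaries.dropna(subset=[f"cyclic_density_{k}", f"path_density_{k}"]) \
            if f"cyclic_density_{k}" in summaries else pd.DataFrame()
        if len(dens) and dens["wave"].nunique() == 2:
            X = pd.DataFrame({
                "const": 1.0,
                "cyclic_density": _zscore(dens[f"cyclic_density_{k}"]),
                "path_density": _zscore(dens[f"path_density_{k}"]),
                "size": _zscore(dens["size"].astype(float)),
                "time": (dens["wave"] == 2).astype(float),
            }, index=dens.index)
            res = _fit_mixed(_zscore(dens["mean_wealth"]).to_numpy(), X,
                             dens["village_id"].to_numpy())
            if res is not None:
                rows.append(dict(k=k, model="wealth~density", term="cyclic_density",
                                 coef=float(res.fe_params["cyclic_density"]),
                                 se=float(res.bse_fe["cyclic_density"]),
                                 p=float(res.pvalues["cyclic_density"]),
                                 n=len(dens), converged=bool(res.converged)))
            else:
                rows.append(dict(k=k, model="wealth~density", term="cyclic_density",
                                 coef=np.nan, se=np.nan, p=np.nan,
                                 n=len(dens), converged=False))
        qual = summaries.dropna(subset=[f"mean_quality_{k}"])
        if len(qual) >= 3:
            X = pd.DataFrame({
                "const": 1.0,
                "quality": _zscore(qual[f"mean_quality_{k}"]),
                "size": _zscore(qual["size"].astype(float)),
            }, index=qual.index)
            res = sm.OLS(_zscore(qual["mean_wealth"]).to_numpy(), X).fit()
            rows.append(dict(k=k, model="wealth~quality", term="quality",
                             coef=float(res.params["quality"]), se=float(res.bse["quality"]),
                             p=float(res.pvalues["quality"]), n=len(qual), converged=True))
        # size screening: do bigger villages have more cycles / denser cycles?
        for yname in (f"total_cycles_{k}", f"cyclic_density_{k}"):
            if yname not in summaries:
                continue
            scr = summaries.dropna(subset=[yname])
            if len(scr) < 3:
                continue
            X = pd.DataFrame({"const": 1.0, "size": _zscore(scr["size"].astype(float))},
                             index=scr.index)
            res = sm.OLS(_zscore(scr[yname].astype(float)).to_numpy(), X).fit()
            rows.append(dict(k=k, model=f"{yname}~size", term="size",
                             coef=float(res.params["size"]), se=float(res.bse["size"]),
                             p=float(res.pvalues["size"]), n=len(scr), converged=True))
    return pd.DataFrame(rows)
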