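"""Synthetic two-wave, two-layer village cohorts.

The generator emulates the statistical structure of a rural sociocentric
cohort: villages of households whose members share a latent wealth class
(1..5); categorical asset items driven by that latent wealth through
ordinal-logit models; a friendship layer with heavy-tailed degree and
wealth-class homophily; a borrow/lend layer that shares a target
fraction of its ties with friendship (about three quarters in rural
cohorts of this kind); and a second survey wave in which ties partially persist and
household wealth can move by one class, with the gain probability
optionally logit-linear in the household's standardized wave-1 cycle
quality (a plantable effect for parameter-recovery tests).

Degree propensity combines a lognormal heterogeneity term with a
log-linear wealth effect (``degree_wealth_effect``), reflecting that
richer individuals hold more borrow/lend ties and hence participate in
more cycles; setting both homophily and the wealth-degree link to zero
yields a fully random-mixing cohort.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .census import cycle_census
from .metrics import cycle_composition
from .networks import BORROW_LEND_GENERATORS, FRIENDSHIP_GENERATORS, build_layers
from .wealth import ASSET_ITEMS

__all__ = ["VillageSpec", "SyntheticCohort", "generate_village", "generate_wave2",
           "generate_cohort", "write_cohort", "read_cohort"]


@dataclass(frozen=True)
class VillageSpec:
    """Parameters of one synthetic village (defaults = study-like conditions)."""

    n_households: int = 30
    household_size_mean: float = 4.3
    wealth_class_probs: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    homophily_strength: float = 1.0
    friendship_mean_degree: float = 8.0
    borrow_lend_mean_degree: float = 3.5
    overlap_target: float = 0.76
    item_loading: float = 1.2
    gain_effect_quality: float = 0.0
    degree_wealth_effect: float = 0.5
    persistence: float = 0.7
    move_prob: float = 0.25
    seed: int = 0

    def __post_init__(self):
        p = np.asarray(self.wealth_class_probs, dtype=float)
        if len(p) != 5 or (p < 0).any() or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("wealth_class_probs must be 5 nonnegative values summing to 1")
        for name in ("overlap_target", "persistence", "move_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.homophily_strength < 0:
            raise ValueError("homophily_strength must be nonnegative")
        if self.n_households < 2:
            raise ValueError("need at least 2 households")


@dataclass
class SyntheticCohort:
    """Generated persons, ties, and the planted ground truth."""

    persons: pd.DataFrame  # person_id, household_id, village_id, wave, wealth_class, items...
    ties: pd.DataFrame     # ego_id, alter_id, generator, wave
    truth: dict = field(default_factory=dict)

    def village_ids(self) -> list[str]:
        return sorted(self.persons["village_id"].unique())

    def roster(self, village_id: str, wave: int) -> pd.DataFrame:
        p = self.persons
        return p[(p["village_id"] == village_id) & (p["wave"] == wave)]

    def village_ties(self, village_id: str) -> pd.DataFrame:
        pref = f"{village_id}_"
        return self.ties[self.ties["ego_id"].str.startswith(pref)]


def _sample_assets(rng, wclass: np.ndarray, item_loading: float) -> dict[str, np.ndarray]:
    """Ordinal-logit asset items from latent wealth class (household level)."""
    w_std = (wclass - 3.0) / np.sqrt(2.0)
    out = {}
    for item, n_cat in ASSET_ITEMS.items():
        latent = item_loading * w_std + rng.logistic(size=len(wclass))
        if n_cat == 2:
            cuts = np.array([0.0])
        else:
            cuts = np.linspace(-0.9, 0.9, n_cat - 1)
        out[item] = (latent[:, None] > cuts[None, :]).sum(axis=1)
    return out


def _edge_weights(rng, wclass, household, spec, propensity):
    """Upper-triangle dyad weights: heterogeneity x homophily kernel; 0 within household."""
    n = len(wclass)
    iu, ju = np.triu_indices(n, k=1)
    w = propensity[iu] * propensity[ju] * np.exp(
        -spec.homophily_strength * np.abs(wclass[iu] - wclass[ju])
    )
    w[household[iu] == household[ju]] = 0.0
    return iu, ju, w


def _scale_to_mean_degree(weights: np.ndarray, n: int, mean_degree: float) -> np.ndarray:
    """Find lam so sum(min(1, lam*w)) = n*mean_degree/2 (bisection; clipping-aware)."""
    target = n * mean_degree / 2.0
    pos = weights[weights > 0]
    if pos.size == 0 or target <= 0:
        return np.zeros_like(weights)
    if pos.size <= target:  # cannot reach target; saturate
        return (weights > 0).astype(float)
    lo, hi = 0.0, 1.0
    while np.minimum(1.0, hi * weights).sum() < target:
        hi *= 2.0
        if hi > 1e18:
            break
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if np.minimum(1.0, mid * weights).sum() < target:
            lo = mid
        else:
            hi = mid
    return np.minimum(1.0, hi * weights)


def _weighted_sample_without_replacement(rng, weights: np.ndarray, k: int) -> np.ndarray:
    """Indices of k items sampled without replacement, probability ~ weights (Gumbel top-k)."""
    w = np.where(weights > 0, weights, np.nan)
    keys = np.log(w) + rng.gumbel(size=len(w))
    keys = np.where(np.isnan(keys), -np.inf, keys)
    if np.isfinite(keys).sum() < k:
        raise ValueError("not enough eligible dyads to sample the requested edge count")
    return np.argpartition(-keys, k - 1)[:k]


def generate_village(spec: VillageSpec, village_id: str = "v001") -> SyntheticCohort:
    """Generate one wave-1 village per the spec.

    Households get sizes ~ 1 + Poisson(mean - 1) and one latent wealth
    class shared by members; friendship edges are Bernoulli with
    probability proportional to the dyad weight (degree propensity x
    homophily kernel), scaled to the target mean degree; the borrow/lend
    layer draws ``overlap_target`` of its edges uniformly from realized
    friendship edges and the rest from non-friend dyads under the same
    kernel.  No self-loops, multi-edges, or within-household ties.
    """
    rng = np.random.default_rng(spec.seed)
    sizes = 1 + rng.poisson(max(spec.household_size_mean - 1.0, 0.0), size=spec.n_households)
    hh_class = rng.choice(np.arange(1, 6), size=spec.n_households,
                          p=np.asarray(spec.wealth_class_probs))
    household = np.repeat(np.arange(spec.n_households), sizes)
    wclass = np.repeat(hh_class, sizes).astype(float)
    n = len(household)
    person_ids = np.array([f"{village_id}_p{i:04d}" for i in range(n)])
    household_ids = np.array([f"{village_id}_h{h:03d}" for h in household])

    hh_assets = _sample_assets(rng, hh_class.astype(float), spec.item_loading)

    w_std = (wclass - 3.0) / np.sqrt(2.0)
    propensity = rng.lognormal(mean=0.0, sigma=0.6, size=n) * np.exp(
        spec.degree_wealth_effect * w_std
    )
    iu, ju, weights = _edge_weights(rng, wclass, household, spec, propensity)

    p_edge = _scale_to_mean_degree(weights, n, spec.friendship_mean_degree)
    friend_mask = rng.random(len(weights)) < p_edge
    f_idx = np.flatnonzero(friend_mask)

    m_bl = int(round(n * spec.borrow_lend_mean_degree / 2.0))
    n_overlap = int(round(spec.overlap_target * m_bl))
    if n_overlap > len(f_idx):
        raise ValueError(
            f"infeasible overlap_target: {n_overlap} overlap edges requested but only "
            f"{len(f_idx)} friendship edges exist"
        )
    shared = rng.choice(f_idx, size=n_overlap, replace=False) if n_overlap else np.array([], int)
    nonfriend_w = weights.copy()
    nonfriend_w[f_idx] = 0.0
    n_rest = m_bl - n_overlap
    rest = (_weighted_sample_without_replacement(rng, nonfriend_w, n_rest)
            if n_rest > 0 else np.array([], int))
    bl_idx = np.concatenate([shared, rest]).astype(int)

    ties = _edges_to_ties(rng, person_ids, iu, ju, f_idx, bl_idx, wave=1)
    persons = pd.DataFrame({
        "person_id": person_ids,
        "household_id": household_ids,
        "village_id": village_id,
        "wave": 1,
        "wealth_class": wclass.astype(int),
        **{item: vals[household] for item, vals in hh_assets.items()},
    })
    truth = {
        "item_loading": spec.item_loading,
        "homophily_strength": spec.homophily_strength,
        "degree_wealth_effect": spec.degree_wealth_effect,
        "gain_effect_quality": spec.gain_effect_quality,
        f"latent_class:{village_id}": {f"{village_id}_h{h:03d}": int(c)
                                       for h, c in enumerate(hh_class)},
    }
    return SyntheticCohort(persons=persons, ties=ties.reset_index(drop=True), truth=truth)


def _edges_to_ties(rng, person_ids, iu, ju, f_idx, bl_idx, wave: int) -> pd.DataFrame:
    rows = []
    for idx, gens in ((f_idx, FRIENDSHIP_GENERATORS), (bl_idx, BORROW_LEND_GENERATORS)):
        if len(idx) == 0:
            continue
        gen = rng.choice(gens, size=len(idx))
        flip = rng.random(len(idx)) < 0.5
        a = np.where(flip, iu[idx], ju[idx])
        b = np.where(flip, ju[idx], iu[idx])
        rows.append(pd.DataFrame({
            "ego_id": person_ids[a], "alter_id": person_ids[b],
            "generator": gen, "wave": wave,
        }))
    if not rows:
        return pd.DataFrame(columns=["ego_id", "alter_id", "generator", "wave"])
    return pd.concat(rows, ignore_index=True)


def _standardized_quality(cohort: SyntheticCohort, village_id: str, k: int = 3) -> pd.Series:
    """Per-person wave-1 borrow/lend k-cycle quality (alters-mean), standardized.

    Persons in no cycle get 0 (the mean) so the transition model is
    defined for everyone.
    """
    roster = cohort.roster(village_id, wave=1)
    ties = cohort.village_ties(village_id)
    layers = build_layers(ties, roster, wave=1)
    g = layers["borrow_lend"]
    cen = cycle_census(g, K=k, with_membership=True)
    wealth = dict(zip(roster["person_id"], roster["wealth_class"].astype(float)))
    comp = cycle_composition(cen.cycle_membership[k], wealth, k, nodes=list(roster["person_id"]))
    q = comp.table["alters_mean"]
    defined = q.dropna()
    if len(defined) >= 2 and defined.std(ddof=0) > 0:
        q = (q - defined.mean()) / defined.std(ddof=0)
    else:
        q = q * 0.0
    return q.fillna(0.0)


def generate_wave2(cohort: SyntheticCohort, spec: VillageSpec) -> SyntheticCohort:
    """Extend a wave-1 cohort with wave-2 ties and wealth transitions.

    Wave-2 ties: each wave-1 edge is retained with probability
    ``persistence``; the removed count is redrawn from currently absent
    eligible dyads under the same kernel, preserving the expected edge
    count per layer.  Wave-2 wealth: each household moves with
    probability ``move_prob``; movers go up one class with probability
    ``sigmoid(gain_effect_quality * q)`` where q is the household's mean
    standardized wave-1 borrow/lend cycle quality, else down one class
    (clamped to 1..5).
    """
    if cohort.persons.empty or not (cohort.persons["wave"] == 1).any():
        raise ValueError("cohort lacks wave-1 data")
    if (cohort.persons["wave"] == 2).any():
        raise ValueError("cohort already has wave-2 data")

    all_persons, all_ties = [cohort.persons], [cohort.ties]
    for vid in cohort.village_ids():
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=spec.seed, spawn_key=(2, _vnum(vid))))
        roster = cohort.roster(vid, wave=1).reset_index(drop=True)
        n = len(roster)
        person_ids = roster["person_id"].to_numpy()
        pid_index = {p: i for i, p in enumerate(person_ids)}
        household = pd.factorize(roster["household_id"])[0]
        wclass = roster["wealth_class"].to_numpy(float)

        q_person = _standardized_quality(cohort, vid)
        hh_ids = roster["household_id"].unique()
        q_hh = q_person.groupby(roster.set_index("person_id")["household_id"]).mean()

        # wealth transition at household level
        new_class = {}
        for hh in hh_ids:
            c = int(roster.loc[roster["household_id"] == hh, "wealth_class"].iloc[0])
            if rng.random() < spec.move_prob:
                p_up = 1.0 / (1.0 + np.exp(-spec.gain_effect_quality * q_hh[hh]))
                c = min(5, c + 1) if rng.random() < p_up else max(1, c - 1)
            new_class[hh] = c
        w2_class = roster["household_id"].map(new_class).astype(int)

        # regenerate household assets from the new class
        hh_order = pd.unique(roster["household_id"])
        hh_new = np.array([new_class[h] for h in hh_order], dtype=float)
        assets2 = _sample_assets(rng, hh_new, spec.item_loading)
        hh_pos = pd.Series(range(len(hh_order)), index=hh_order)
        person_hh_pos = roster["household_id"].map(hh_pos).to_numpy()

        propensity = rng.lognormal(0.0, 0.6, size=n) * np.exp(
            spec.degree_wealth_effect * (wclass - 3.0) / np.sqrt(2.0))
        iu, ju, weights = _edge_weights(rng, wclass, household, spec, propensity)
        pair_pos = {(int(a), int(b)): t for t, (a, b) in enumerate(zip(iu, ju))}

        layers1 = build_layers(cohort.village_ties(vid), roster, wave=1)
        new_layer_edges = {}
        for layer in ("friendship", "borrow_lend"):
            edges1 = [tuple(sorted((pid_index[u], pid_index[v])))
                      for u, v in layers1[layer].edges()]
            keep = [e for e in edges1 if rng.random() < spec.persistence]
            n_redraw = len(edges1) - len(keep)
            w = weights.copy()
            for e in edges1:
                w[pair_pos[e]] = 0.0
            if n_redraw > 0:
                new_idx = _weighted_sample_without_replacement(rng, w, n_redraw)
                keep += [(int(iu[t]), int(ju[t])) for t in new_idx]
            new_layer_edges[layer] = keep

        f_pos = np.array([pair_pos[e] for e in new_layer_edges["friendship"]], dtype=int)
        bl_pos = np.array([pair_pos[e] for e in new_layer_edges["borrow_lend"]], dtype=int)
        all_ties.append(_edges_to_ties(rng, person_ids, iu, ju, f_pos, bl_pos, wave=2))
        p2 = roster.copy()
        p2["wave"] = 2
        p2["wealth_class"] = w2_class.to_numpy()
        for item, vals in assets2.items():
            p2[item] = vals[person_hh_pos]
        all_persons.append(p2)

    truth = dict(cohort.truth)
    truth["gain_effect_quality"] = spec.gain_effect_quality
    truth["persistence"] = spec.persistence
    return SyntheticCohort(
        persons=pd.concat(all_persons, ignore_index=True),
        ties=pd.concat(all_ties, ignore_index=True),
        truth=truth,
    )


def _vnum(village_id: str) -> int:
    return int("".join(ch for ch in village_id if ch.isdigit()) or 0)


def generate_cohort(n_villages: int, spec_template: VillageSpec, seed: int,
                    two_wave: bool = True) -> SyntheticCohort:
    """Generate independent villages with deterministically derived seeds.

    Village v gets seed ``SeedSequence(entropy=seed, spawn_key=(1, v))``
    (documented, fixed), so any village regenerates bit-identically from
    the master seed alone.
    """
    if n_villages < 1:
        raise ValueError("n_villages must be >= 1")
    persons, ties = [], []
    truth: dict = {}
    for v in range(1, n_villages + 1):
        vid = f"v{v:03d}"
        vseed = int(np.random.SeedSequence(entropy=seed, spawn_key=(1, v)).generate_state(1)[0]
                    % (2**31))
        spec = dataclasses.replace(spec_template, seed=vseed)
        village = generate_village(spec, village_id=vid)
        if two_wave:
            village = generate_wave2(village, spec)
        persons.append(village.persons)
        ties.append(village.ties)
        truth.update(village.truth)
    truth["master_seed"] = seed
    truth["n_villages"] = n_villages
    return SyntheticCohort(
        persons=pd.concat(persons, ignore_index=True),
        ties=pd.concat(ties, ignore_index=True),
        truth=truth,
    )


def write_cohort(cohort: SyntheticCohort, out_dir) -> dict[str, Path]:
    """Write roster/tie tables (CSV, UTF-8, headered) and a truth key=value file."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "persons": out / "persons.csv",
        "ties": out / "ties.csv",
        "truth": out / "truth.txt",
    }
    cohort.persons.to_csv(paths["persons"], index=False)
    cohort.ties.to_csv(paths["ties"], index=False)
    with open(paths["truth"], "w") as fh:
        for key, val in cohort.truth.items():
            if isinstance(val, dict):
                continue  # nested per-household maps stay in memory only
            fh.write(f"{key}={val}\n")
    return paths


def read_cohort(in_dir) -> SyntheticCohort:
    """Read a cohort written by :func:`write_cohort`."""
    p = Path(in_dir)
    persons = pd.read_csv(p / "persons.csv")
    ties = pd.read_csv(p / "ties.csv")
    truth = {}
    tf = p / "truth.txt"
    if tf.exists():
        for line in tf.read_text().splitlines():
            if "=" in line:
                k, v = line.split("=", 1)
                try:
                    truth[k] = float(v) if "." in v or "e" in v.lower() else int(v)
                except ValueError:
                    truth[k] = v
    return SyntheticCohort(persons=persons, ties=ties, truth=truth)
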