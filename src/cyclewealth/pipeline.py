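"""End-to-end orchestration: simulate -> build -> census -> nulls -> metrics
-> models -> village, with deterministic seeding and a run manifest.

Every stage writes headered CSV tables into the run directory and adds
a manifest entry (stage, output hashes, seed, elapsed seconds), so any
number in a report is traceable to (inputs, seed, config).  Rerunning
with an identical config reproduces identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .census import full_census
from .metrics import assortativity_matrix, centralities, cycle_composition
from .models import ALL_OUTCOMES, BINARY_OUTCOMES, run_battery, stratified_gain_loss
from .networks import build_layers, tie_overlap_summary
from .nulls import null_ensemble
from .village import (build_quality_cache, permutation_null_quality,
                      village_regressions, village_summaries)
from .wealth import ASSET_ITEMS, assign_wealth_classes, binarize_items, fit_mca

__all__ = ["RunConfig", "run_pipeline", "report", "assemble_analysis_table"]

K_ANALYSIS_MAX = 5


@dataclass
class RunConfig:
    """Configuration of one end-to-end run (YAML round-trippable)."""

    out_dir: str = "run"
    seed: int = 0
    n_villages: int = 10
    village: dict = field(default_factory=dict)   # VillageSpec overrides
    K: int = 5
    layer: str = "borrow_lend"
    null_replicates: int = 50
    permutation_B: int = 200
    families: tuple = ("quantity_cross", "quality_cross", "quality_long")
    scaling: str = "zscore"
    use_mca: bool = True
    input_dir: str | None = None  # load a cohort instead of simulating

    def __post_init__(self):
        if not 3 <= self.K <= K_ANALYSIS_MAX:
            raise ValueError(
                f"K={self.K} outside the supported analysis range 3..{K_ANALYSIS_MAX}; "
                "cycle lengths above 5 are not enumerated"
            )
        self.families = tuple(self.families)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["families"] = list(d["families"])
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def assemble_analysis_table(cohort, K: int = 5, layer: str = "borrow_lend",
                            use_mca: bool = True, with_centralities: bool = False,
                            mca_min_households: int = 25) -> pd.DataFrame:
    """Merge network metrics and wealth into a wide per-person table.

    Columns are suffixed ``_w1`` / ``_w2``: wealth_class, the binarized
    asset outcomes, and per k the cycle count, path count, alters-mean
    quality (NaN when the person is in no k-cycle), degree, and
    leave-self-out village mean wealth.  Wealth classes come from the
    MCA index with person-weighted quintiles (``use_mca=True``) or from
    the roster's wealth_class column.
    """
    items = [c for c in ASSET_ITEMS if c in cohort.persons.columns]
    waves = sorted(cohort.persons["wave"].unique())
    per_wave = {}
    for wave in waves:
        pw = cohort.persons[cohort.persons["wave"] == wave]
        if use_mca and len(pw["household_id"].unique()) >= mca_min_households:
            hh = pw.drop_duplicates("household_id").set_index("household_id")
            model = fit_mca(hh[items])
            sizes = pw.groupby("household_id").size()
            classes, _ = assign_wealth_classes(model.scores, sizes)
            wealth = pw["household_id"].map(classes)
        else:
            wealth = pw["wealth_class"]
        binar = binarize_items(pw[items])
        rows = []
        for vid in sorted(pw["village_id"].unique()):
            roster = pw[pw["village_id"] == vid]
            ties = cohort.village_ties(vid)
            layers = build_layers(ties, roster, wave=wave)
            g = layers[layer]
            cen = full_census(g, K, with_membership=True)
            wmap = dict(zip(pw["person_id"], wealth.astype(float)))
            tab = pd.DataFrame(index=roster["person_id"])
            tab["village_id"] = vid
            tab["wealth_class"] = [wmap[p] for p in tab.index]
            n = len(roster)
            tot = tab["wealth_class"].sum()
            tab["village_wealth"] = (tot - tab["wealth_class"]) / max(n - 1, 1)
            tab["degree"] = [g.degree(p) for p in tab.index]
            for k in cen.k_range:
                tab[f"cycles_{k}"] = cen.node_cycle_counts[k].reindex(tab.index).to_numpy()
                tab[f"paths_{k}"] = cen.node_path_counts[k].reindex(tab.index).to_numpy()
                comp = cycle_composition(cen.cycle_membership[k], wmap, k,
                                         nodes=list(tab.index))
                tab[f"quality_{k}"] = comp.table["alters_mean"].to_numpy()
            if with_centralities:
                cent = centralities(g)
                for c in cent.columns:
                    if c != "degree":
                        tab[c] = cent[c].reindex(tab.index).to_numpy()
            for c in binar.columns:
                tab[c] = binar.loc[roster.index, c].to_numpy()
            tab["wealth_index"] = tab["wealth_class"]
            rows.append(tab)
        per_wave[wave] = pd.concat(rows)
    wide = None
    for wave in waves:
        t = per_wave[wave].add_suffix(f"_w{wave}")
        t = t.rename(columns={f"village_id_w{wave}": "village_id"})
        if wide is None:
            wide = t
        else:
            wide = wide.join(t.drop(columns=["village_id"]), how="left")
    return wide.reset_index(names="person_id")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order; returns the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": dataclasses.asdict(config), "stages": []}
    manifest["config"]["families"] = list(config.families)

    def record(stage: str, t0: float, paths: dict, seed=None, warnings_list=()):
        manifest["stages"].append({
            "stage": stage,
            "seed": seed,
            "elapsed_s": round(time.time() - t0, 3),
            "outputs": {k: _hash_file(Path(p)) for k, p in paths.items()},
            "warnings": list(warnings_list),
        })

    # -- simulate or load ---------------------------------------------------
    t0 = time.time()
    if config.input_dir:
        cohort = synthetic.read_cohort(config.input_dir)
    else:
        spec = synthetic.VillageSpec(**config.village)
        cohort = synthetic.generate_cohort(config.n_villages, spec, seed=config.seed)
    paths = synthetic.write_cohort(cohort, out / "cohort")
    record("simulate", t0, paths, seed=config.seed)

    # -- build layers -------------------------------------------------------
    t0 = time.time()
    graphs = {}
    for vid in cohort.village_ids():
        for wave in sorted(cohort.persons["wave"].unique()):
            roster = cohort.roster(vid, wave)
            graphs[(vid, wave)] = build_layers(cohort.village_ties(vid), roster, wave=wave)
    overlap = tie_overlap_summary(list(graphs.values()))
    edge_rows = []
    for (vid, wave), g in graphs.items():
        for layer_name in ("friendship", "borrow_lend", "overlap"):
            for u, v in g[layer_name].edges():
                edge_rows.append((vid, wave, layer_name, *sorted((u, v))))
    edges = pd.DataFrame(edge_rows, columns=["village_id", "wave", "layer", "u", "v"])
    p1, p2 = out / "edges.csv", out / "overlap_summary.csv"
    edges.to_csv(p1, index=False)
    overlap.to_csv(p2, index=False)
    record("build", t0, {"edges": p1, "overlap": p2})

    # -- census + metrics (analysis table) ----------------------------------
    t0 = time.time()
    table = assemble_analysis_table(cohort, K=config.K, layer=config.layer,
                                    use_mca=config.use_mca, with_centralities=True)
    p = out / "analysis_table.csv"
    table.to_csv(p, index=False)
    record("census_metrics", t0, {"analysis_table": p})

    # -- null ensembles -----------------------------------------------------
    t0 = time.time()
    null_rows = []
    for (vid, wave), g in graphs.items():
        gl = g[config.layer]
        if gl.number_of_edges() < 2:
            continue
        st = null_ensemble(gl, K=config.K, replicates=config.null_replicates,
                           seed=config.seed + 7919)
        for k in st.k_range:
            null_rows.append(dict(
                village_id=vid, wave=wave, layer=config.layer, k=k,
                observed_cycles=st.observed_cycles[k],
                null_mean=st.null_mean_cycles[k], null_sd=st.null_sd_cycles[k],
                z=st.z_cycles[k], cyclic_density=st.cyclic_density[k],
                observed_paths=st.observed_paths[k], path_null_mean=st.null_mean_paths[k],
                path_z=st.z_paths[k], path_density=st.path_density[k],
                flags=";".join(st.flags[k]),
            ))
    nulls_tab = pd.DataFrame(null_rows)
    p = out / "null_ensembles.csv"
    nulls_tab.to_csv(p, index=False)
    record("nulls", t0, {"null_ensembles": p}, seed=config.seed + 7919)

    # -- association battery ------------------------------------------------
    t0 = time.time()
    long_fams = [f for f in config.families if f.endswith("_long")]
    fams = config.families if 2 in cohort.persons["wave"].unique() else tuple(
        f for f in config.families if f not in long_fams)
    battery = run_battery(table, families=fams, K=tuple(range(3, config.K + 1)))
    p = out / "battery_results.csv"
    battery.to_csv(p, index=False)
    record("models", t0, {"battery": p})

    # -- village level ------------------------------------------------------
    t0 = time.time()
    node_long = _node_long_table(cohort, table, nulls_tab, config)
    summaries = village_summaries(node_long)
    vdata = []
    for vid in cohort.village_ids():
        roster = cohort.roster(vid, 1)
        g = graphs[(vid, 1)][config.layer]
        cen = full_census(g, config.K, with_membership=True)
        cache = build_quality_cache(cen, roster["person_id"])
        wealth = dict(zip(table["person_id"], table["wealth_class_w1"]))
        vdata.append((vid, cache, wealth))
    perm = permutation_null_quality(vdata, B=config.permutation_B,
                                    seed=config.seed + 104729, K=config.K)
    paths = {"summaries": out / "village_summaries.csv",
             "regressions": out / "village_regressions.csv",
             "permutation": out / "village_permutation.csv",
             "permutation_pooled": out / "village_permutation_pooled.csv"}
    summaries.to_csv(paths["summaries"], index=False)
    try:
        vreg = village_regressions(summaries, K=tuple(range(3, config.K + 1)))
    except ValueError:
        vreg = pd.DataFrame()
    vreg.to_csv(paths["regressions"], index=False)
    perm.per_village.to_csv(paths["permutation"], index=False)
    perm.pooled.to_csv(paths["permutation_pooled"], index=False)
    record("village", t0, paths, seed=config.seed + 104729)

    manifest_path = out / "run_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def _node_long_table(cohort, table, nulls_tab, config) -> pd.DataFrame:
    """Long per-node table feeding village summaries."""
    rows = []
    for wave in sorted(cohort.persons["wave"].unique()):
        suf = f"_w{wave}"
        if f"wealth_class{suf}" not in table:
            continue
        for k in range(3, config.K + 1):
            sub = pd.DataFrame({
                "person_id": table["person_id"],
                "village_id": table["village_id"],
                "wave": wave,
                "wealth_class": table[f"wealth_class{suf}"],
                "k": k,
                "cycles": table[f"cycles_{k}{suf}"],
                "quality": table[f"quality_{k}{suf}"],
            })
            if len(nulls_tab):
                dens = nulls_tab[(nulls_tab["wave"] == wave) & (nulls_tab["k"] == k)]
                dmap = dict(zip(dens["village_id"], dens["cyclic_density"]))
                pmap = dict(zip(dens["village_id"], dens["path_density"]))
                sub["cyclic_density"] = sub["village_id"].map(dmap)
                sub["path_density"] = sub["village_id"].map(pmap)
            rows.append(sub)
    return pd.concat(rows, ignore_index=True)


def report(manifest: dict) -> dict[str, pd.DataFrame]:
    """Assemble figure-analogue tables from a completed run.

    Returns (and writes under <out>/report/) whichever of these the run
    produced: tie-overlap accounting, the Z-score distribution table,
    the battery heatmap mask, the wealth-class assortativity matrix, the
    gain/loss Manhattan table, and the village quality-vs-wealth scatter
    table.  Missing stage outputs are reported by name.
    """
    out = Path(manifest["config"]["out_dir"])
    rep_dir = out / "report"
    rep_dir.mkdir(exist_ok=True)
    produced: dict[str, pd.DataFrame] = {}
    missing = []

    def load(name, fname):
        p = out / fname
        if p.exists():
            produced[name] = pd.read_csv(p)
            return produced[name]
        missing.append(fname)
        return None

    load("overlap", "overlap_summary.csv")
    nulls_tab = load("null_z", "null_ensembles.csv")
    battery = load("battery", "battery_results.csv")
    load("village_scatter", "village_summaries.csv")
    load("village_permutation_pooled", "village_permutation_pooled.csv")

    table_p = out / "analysis_table.csv"
    if table_p.exists():
        table = pd.read_csv(table_p)
        # assortativity from wave-1 edges
        edges = pd.read_csv(out / "edges.csv") if (out / "edges.csv").exists() else None
        if edges is not None:
            import networkx as nx
            sub = edges[(edges["wave"] == 1) & (edges["layer"] == manifest["config"]["layer"])]
            g = nx.from_pandas_edgelist(sub, "u", "v")
            cls = dict(zip(table["person_id"], table["wealth_class_w1"]))
            in_g = [v for v in g.nodes() if v in cls]
            if len(sub):
                am = assortativity_matrix(g.subgraph(in_g), cls)
                produced["assortativity"] = am.matrix
        if "wealth_class_w2" in table:
            try:
                ks = tuple(range(3, manifest["config"]["K"] + 1))
                man = pd.concat([stratified_gain_loss(table, m, K=ks)
                                 for m in ("quality", "quantity")])
                produced["manhattan"] = man
            except ValueError:
                missing.append("manhattan (needs two waves)")
    else:
        missing.append("analysis_table.csv")

    if battery is not None:
        from .models import heatmap_table
        produced["heatmap"] = heatmap_table(battery)
    for name, df in produced.items():
        df.to_csv(rep_dir / f"{name}.csv", index=(name == "assortativity" or name == "heatmap"))
    produced["missing"] = missing
    return produced
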