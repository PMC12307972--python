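"""Village-level wealth-label permutation test of mean cycle quality.

Shuffling wealth labels within each village (network fixed) preserves
village size and mean wealth exactly; comparing observed mean cycle
quality against this null asks whether cycle participation is wealth-
structured beyond the village's composition.
"""

from cyclewealth import (VillageSpec, build_layers, build_quality_cache, cycle_census,
                         generate_cohort, permutation_null_quality)


def entries_for(spec, n_villages, seed):
    cohort = generate_cohort(n_villages, spec, seed=seed, two_wave=False)
    out = []
    for vid in cohort.village_ids():
        roster = cohort.roster(vid, 1)
        g = build_layers(cohort.village_ties(vid), roster, 1)["borrow_lend"]
        census = cycle_census(g, K=3, with_membership=True)
        cache = build_quality_cache(census, roster.person_id)
        wealth = dict(zip(roster.person_id, roster.wealth_class.astype(float)))
        out.append((vid, cache, wealth))
    return out


for label, spec in [
    ("wealth-structured", VillageSpec(homophily_strength=2.0)),
    ("random-mixing", VillageSpec(homophily_strength=0.0, degree_wealth_effect=0.0)),
]:
    res = permutation_null_quality(entries_for(spec, 15, seed=4), B=300, seed=4, K=3)
    row = res.pooled.set_index("k").loc[3]
    print(f"{label:18s}: pooled z = {row.pooled_z:7.2f}, pooled p = {row.pooled_p:.3g} "
          f"({int(row.n_villages)} villages)")
print("\nOnly the cohort where richer people hold more ties (and similar-wealth "
      "people cluster) rejects the label-shuffling null; pure noise does not.")
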