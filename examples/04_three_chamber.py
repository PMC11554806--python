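"""Three-chamber social approach: zone dwell, exclusion, and the ANOVA.

Simulates a small two-genotype cohort in which wild-type walkers are
attracted to the social cup while mutant walkers are indifferent, then runs
the full analysis: near-cup dwell times, the both-side-chambers exclusion
rule, and the two-way repeated-measures ANOVA with Fisher's LSD contrasts.
"""

from habsoc import (
    Animal,
    AnimalRegistry,
    ArenaSpec,
    WalkConfig,
    analyze_animal,
    preference_table,
    simulate_three_chamber,
    two_way_anova_lsd,
)

arena = ArenaSpec()
animals = [Animal(f"m{i:02d}", f"TAG{i:04d}", "WT" if i < 4 else "MUT", "M")
           for i in range(8)]
registry = AnimalRegistry(animals)

results = []
for i, animal in enumerate(animals):
    social_pull = 1.0 if animal.genotype == "WT" else 0.0
    trajs = {}
    for session in ("habituation_all", "test"):
        weights = {"near_cup_left": social_pull} if session == "test" else {}
        walk = WalkConfig(seed=300 + i, zone_weights=weights, step_sd_mm=25.0)
        traj, _ = simulate_three_chamber(arena, walk, animal=animal.animal_id,
                                         session=session, stimulus_side="left")
        trajs[session] = traj
    results.append(analyze_animal(trajs, arena))

excluded = [r.animal for r in results if not r.included]
print(f"included {sum(r.included for r in results)}/{len(results)} animals; "
      f"excluded: {excluded or 'none'}")

table = preference_table(results, registry)
res = two_way_anova_lsd(table)
print("\ncell means (near-cup seconds):")
print(res.cell_means.to_string(index=False))
print("\nANOVA:")
print(res.anova.head(3).to_string(index=False))
print("\nFisher's LSD contrasts:")
print(res.contrasts[["contrast", "estimate", "p", "stars"]].to_string(index=False))
print("\n-> wild types prefer the social cup (within-genotype contrast");
print("   significant); indifferent mutants show no stimulus preference.")
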