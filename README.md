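# habsoc

Social phenotyping of group-housed mice from RFID event streams.

Automated home-cage systems house a whole cohort in a four-compartment
habitat whose compartments are joined in a ring by tube passages; paired
RFID antennas in each tube record every crossing, so the animals' social
life can be measured for days without an experimenter in the room.
`habsoc` turns those antenna reads into science:

- **Occupancy reconstruction** — a deterministic per-animal state machine
  converts antenna reads into compartment visit intervals (with documented,
  logged repairs for dropped reads), then derives circadian **activity**
  (visits per 12-h bin) and per-animal **time budgets**
  (t<sub>a1</sub>…t<sub>a4</sub>, the fraction of a window spent in each
  compartment).
- **In-cohort sociability** — for each pair (a, b) and analysis window,

  S = t<sub>ab</sub> − (t<sub>a1</sub>t<sub>b1</sub> + t<sub>a2</sub>t<sub>b2</sub> + t<sub>a3</sub>t<sub>b3</sub> + t<sub>a4</sub>t<sub>b4</sub>)

  where t<sub>ab</sub> is the normalized time the pair spends in the same
  compartment simultaneously. S is the excess co-dwelling over what
  independent exploration would produce: 0 under independence, positive for
  affiliation, negative for avoidance. Computed by exact interval
  intersection over the 12-h bins of the 48-h testing phase (the first 24 h
  are adaptation and are excluded).
- **Cohort statistics** — relative-frequency histograms, the two-sample
  Kolmogorov–Smirnov test (exact sup-gap D by a sorted-merge ECDF sweep,
  asymptotic p), and a repeated-measures two-way ANOVA (genotype between ×
  stimulus within) with uncorrected Fisher's LSD contrasts.
- **Three-chamber social approach** — zone dwell analysis for the classic
  820 × 420 mm three-chamber arena: chamber and 140 × 140 mm near-cup
  times, path length, and the exclusion rule for animals that never enter
  both side chambers.
- **Seeded simulators** — an agent-based continuous-time Markov model of
  the habitat (circadian rate modulation, tunable pairwise social affinity,
  imperfect detection) and a biased random walker for the three-chamber
  arena, both emitting ground truth for end-to-end validation.

## Worked example

```python
from habsoc import (Apparatus, SimConfig, pairwise_sociability,
                    reconstruct_visits, simulate_habitat, with_alpha)

base = SimConfig(n_animals=10, seed=7, p_det=1.0)
for label, config in [("independent (alpha=0)", base),
                      ("affiliative (alpha=0.5)", with_alpha(base, 0.5))]:
    events, truth = simulate_habitat(config)
    protocol = config.protocol()
    visits, _ = reconstruct_visits(events, Apparatus(), truth.registry,
                                   session_end=protocol.duration_s)
    per_bin, per_pair = pairwise_sociability(visits, truth.registry, protocol)
    print(f"{label}: {len(per_pair)} pairs, mean S = {per_pair['s'].mean():+.4f}")
```

prints

```
independent (alpha=0): 45 pairs, mean S = +0.0024
affiliative (alpha=0.5): 45 pairs, mean S = +0.1175
```

An uncoupled cohort sits at S ≈ 0 — co-dwelling is fully explained by each
animal's own time budget — while a cohort with social affinity co-dwells
far more than independence predicts. The `examples/` directory has one
short script per capability (reconstruction, sociability, cohort
comparison, three-chamber analysis), each printing its numbers with a line
on what they mean. A thin CLI mirrors the pipeline for shell use:
`habsoc simulate`, `habsoc validate`, `habsoc reconstruct`,
`habsoc activity`, `habsoc budget`, `habsoc sociability`, `habsoc compare`.

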