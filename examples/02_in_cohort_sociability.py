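"""In-cohort sociability under the independence null and under affinity.

S = t_ab − Σ_c t_ac·t_bc for each pair over the 48-h testing phase: time
together minus the time expected were the two animals exploring
independently.  An uncoupled cohort should give S ≈ 0; social affinity
pushes S up.
"""

from habsoc import (
    Apparatus,
    SimConfig,
    pairwise_sociability,
    reconstruct_visits,
    simulate_habitat,
    with_alpha,
)

base = SimConfig(n_animals=10, seed=7, p_det=1.0)
for label, config in [("independent (alpha=0)", base),
                      ("affiliative (alpha=0.5)", with_alpha(base, 0.5))]:
    events, truth = simulate_habitat(config)
    protocol = config.protocol()
    visits, _ = reconstruct_visits(events, Apparatus(), truth.registry,
                                   session_end=protocol.duration_s)
    per_bin, per_pair = pairwise_sociability(visits, truth.registry, protocol)
    print(f"{label}: {len(per_pair)} pairs, "
          f"mean S = {per_pair['s'].mean():+.4f} "
          f"(per-pair SD {per_pair['s'].std():.4f})")
print("-> the null cohort sits at S ~ 0; the coupled cohort co-dwells more")
print("   than independent exploration predicts.")
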