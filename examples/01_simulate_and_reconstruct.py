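"""Simulate a habitat cohort and reconstruct visits from its antenna reads.

Builds a 6-animal, 84-h cohort with perfect detection, reconstructs
compartment visits from the RFID event stream, and compares them with the
simulator's ground truth.
"""

from habsoc import (
    Apparatus,
    SimConfig,
    compute_activity,
    reconstruct_visits,
    simulate_habitat,
)

config = SimConfig(n_animals=6, seed=42, p_det=1.0)
events, truth = simulate_habitat(config)
protocol = config.protocol()
print(f"simulated {len(events)} antenna reads, "
      f"{len(truth.transitions)} true transitions over {config.duration_h} h")

visits, repairs = reconstruct_visits(events, Apparatus(), truth.registry,
                                     session_end=protocol.duration_s)
exact = visits.reset_index(drop=True).equals(
    truth.visits.sort_values(["animal", "start_s"], ignore_index=True))
print(f"reconstructed {len(visits)} visits, {len(repairs)} repairs; "
      f"matches ground truth interval-for-interval: {exact}")

activity = compute_activity(visits, protocol)
per_bin = activity.groupby("bin")["visits"].mean().round(1)
print("mean visits per animal per 12-h bin:", per_bin.to_list())
print("-> alternating high/low counts are the dark/light circadian phases;")
print("   with perfect detection, reconstruction is lossless up to tube transits.")
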