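"""Simulate one participant's reaching session and inspect its structure.

Builds a session with the default exercise protocol (per ball mode:
16 baseline, then alternating 24-trial training and 16-trial retention
blocks for the three terminal-feedback modalities), and prints the
block layout plus a few ground-truth facts the generator records.
"""

from collections import Counter

from reachmetrics import SimulationConfig, simulate_session

config = SimulationConfig(n_participants=1, seed=42)
session = simulate_session(config, participant_index=0)

print(f"trials: {len(session.events)}  "
      f"trajectory samples: {session.trajectory.n_samples}  "
      f"EMG samples x channels: {session.emg.samples.shape}")

blocks = Counter()
for trial in session.events:
    blocks[(trial.ball_mode, trial.phase, trial.feedback)] += 1
print("\nblock structure (ball mode, phase, feedback -> segments):")
for key in blocks:
    print(f"  {key}: {blocks[key]}")

truth = session.truth[0]
print(f"\nfirst segment ground truth: primary reach {truth.primary_duration:.2f} s, "
      f"{truth.n_corrective} corrective submovements, "
      f"total {truth.total_duration:.2f} s")
print("programmed muscle latencies (s from target appearance):")
for muscle, lat in truth.muscle_latency.items():
    print(f"  {muscle:20s} {lat:.3f}")

# The printed counts follow the session template (16/24/16/24/16/24/16 per
# ball mode); the truth record is what the analysis modules must recover.
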