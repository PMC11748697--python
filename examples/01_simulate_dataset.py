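"""Simulate one participant's full recording and inspect the folder layout.

Generates the four session folders of the two-day protocol (plus-shaped
position set on day 1, cross-shaped on day 2) and prints the per-position /
per-grasp trial counts read back from disk.
"""

import tempfile
from pathlib import Path

import emgshift as es
from emgshift.dataset_io import discover_sessions, session_summary

config = es.ProtocolConfig(seed=1)
params = es.SimulationParams(seed=1)

with tempfile.TemporaryDirectory() as tmp:
    paths = es.simulate_participant(config, params, participant=1, out_dir=tmp)
    print("written session folders:")
    for p in paths:
        print(" ", Path(p).name)

    sessions = discover_sessions(tmp)
    first = sessions[0]
    counts = session_summary(first.path)
    print(f"\n{first.path.name}: {counts['trials'].sum()} trials")
    print(counts.pivot(index="position", columns="grasp", values="trials"))

# Each cell holds 5 trials: every (position, grasp) pair is recorded as one
# 5-trial block, 5 positions x 6 grasps = 150 trials per session.
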