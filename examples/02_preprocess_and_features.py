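"""Filter one trial and turn it into Hudgins feature windows.

Shows the preprocessing chain (band-pass, notch, offset removal, sliding
windows) and the 64-dimensional feature vector layout.
"""

import numpy as np

import emgshift as es
from emgshift.features import FeatureThresholds, extract_batch
from emgshift.preprocess import FilterSpec, WindowSpec, bandpass, notch, remove_offset, windows

record = es.simulate_trial(es.SimulationParams(seed=2), position=5, grasp=1, seed=42)
print(f"raw EMG: {record.emg.shape[0]} channels x {record.emg.shape[1]} samples")

spec = FilterSpec()          # 4th-order 20-450 Hz band-pass, 50 Hz notch
x = remove_offset(notch(bandpass(record.emg, spec), spec))

segs, starts = windows(x, WindowSpec(), spec.sampling_rate)
print(f"windows: {segs.shape[0]} of {segs.shape[2]} samples "
      f"(128 ms at 2 kHz, 50 ms stride)")

features = extract_batch(segs, FeatureThresholds())
print(f"feature matrix: {features.shape} (16 channels x [MAV, ZC, SSC, WL])")

names = es.feature_columns(16)[:4]
print("\nchannel 0 features of the first window:")
for name, value in zip(names, features[0, :4]):
    print(f"  {name}: {value:.2f}")

# MAV and WL track the signal amplitude of the held grasp; ZC and SSC count
# sign and slope alternations and are insensitive to amplitude scaling.
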