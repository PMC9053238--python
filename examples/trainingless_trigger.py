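"""Training-less hand control from high-gamma LFP band power.

Simulates LFP whose 100-500 Hz power rests at 1.5 V^2/Hz and rises to
12 V^2/Hz during attempted movement, computes the rolling periodogram
feature stream (1-s windows, 500-ms updates) and applies the absolute
10 V^2/Hz close trigger — no decoder training involved.
"""

import numpy as np

import bciloop as b
from bciloop.core import Command

protocol = [("attempt_close", 10.0), ("rest", 10.0)] * 3
intent = b.make_intent_trace(protocol, seed=5)
cfg = b.NeuralSimConfig(rest_band_power=1.5, move_band_power=12.0, seed=5)

stream = b.rolling_feature_stream(b.generate_lfp(intent, cfg))
move = b.window_labels(stream, intent)
commands = b.trainingless_trigger(stream.values[0], b.TriggerConfig(threshold=10.0))
fired = np.array([c is Command.CLOSE for c in commands])

print(f"{stream.values.shape[1]} feature windows over {intent.duration:.0f} s")
print(f"band power: rest windows {stream.values[0][~move].mean():.2f} V^2/Hz, "
      f"movement windows {stream.values[0][move].mean():.2f} V^2/Hz")
print(f"trigger (>10 V^2/Hz) fired in {100 * fired[move].mean():.1f}% of movement "
      f"windows and {100 * fired[~move].mean():.1f}% of rest windows")
print("high hit rate with near-zero false closures is what makes the mode usable")
print("without any per-session decoder calibration.")
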