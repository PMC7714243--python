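"""From raw force signal to the interleaved vGRF peak time series.

Runs the full processing chain on a simulated noisy recording — 35 Hz
zero-phase Butterworth filter, body-weight normalization, 50 N stance
detection, impact/propulsive peak extraction, 10-stride lead-in skip — and
compares the extracted series against the generator's ground truth.
"""

import numpy as np

import gaitar as g

condition = g.GaitCondition("sym_1.00", 1.0, 1.0, 60.0)
params = g.SimulationParams(sensor_noise_sd=5.0)
recording, truth = g.simulate_walking_trial(condition, params, "left", seed=21)

series, qc = g.process_recording(recording, limb="left", condition="sym_1.00")

print(f"QC: {qc.as_dict()}")
print(f"series length: {series.n} values "
      f"({series.n // 2} steps x 2 peaks, first 10 strides skipped)")
print(f"first four values (BW): {np.round(series.values[:4], 3)}  "
      f"types: {series.peak_types[:4]}")
err = np.abs(series.values - truth["peak_value_bw"].to_numpy()[20:])
print(f"max |extracted - truth|: {err.max():.4f} BW "
      f"(5 N sensor noise on a ~700 N signal)")
# The interleaved impact/propulsive series is what the AR(2) model is fit to.
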