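"""Score a measured pressure series against the random-coil prediction.

A series that tracks the random-coil curve within noise across the whole
pressure range is strong evidence that the residue is disordered.
"""

import numpy as np

from hpcoil import PolynomialFit, PressureSeries, evaluate_shift, load_reference, random_coil_deviation

db = load_reference()
rec = db.lookup("Ala", "QB")
press = np.linspace(1, 200, 11)
prediction = evaluate_shift(
    PolynomialFit(delta0=rec.delta0, b1=rec.b1, b2=rec.b2), press)

rng = np.random.default_rng(0)

# case 1: a disordered residue -- random-coil curve plus noise
obs = prediction + rng.normal(0, 0.002, press.size)
series = PressureSeries.from_arrays(press, obs)
score = random_coil_deviation(series, prediction, noise_sd=0.002, reference=rec)
print(f"disordered-like series: RMS/noise = {score.rms_over_noise:.2f}, "
      f"z(B1) = {score.z_b1:+.1f}  ->  random-coil-like: "
      f"{score.random_coil_like}")

# case 2: structured residue -- pressure response 4x too steep
structured = PolynomialFit(delta0=rec.delta0, b1=rec.b1 + 4 * rec.err_b1 + 0.3,
                           b2=rec.b2)
obs = evaluate_shift(structured, press) + rng.normal(0, 0.002, press.size)
series = PressureSeries.from_arrays(press, obs)
score = random_coil_deviation(series, prediction, noise_sd=0.002, reference=rec)
print(f"structured series:      RMS/noise = {score.rms_over_noise:.2f}, "
      f"z(B1) = {score.z_b1:+.1f}  ->  random-coil-like: "
      f"{score.random_coil_like}")
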