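"""Fit diffusion tensors from simulated DWI and check the round trip.

Builds a noiseless 30-direction b = 1000 s/mm^2 acquisition from a known
anisotropic tensor field, refits it with the log-linear least-squares
estimator, and reports the worst-case error of the recovered diagonal.
"""

import numpy as np

from dtialps.synthetic import (
    GeometryConfig,
    generate_subject_dwi,
    generate_subject_volumes,
    make_ground_truth,
)
from dtialps.tensor import extract_diagonal, fit_tensor_loglinear

geom = GeometryConfig(signal_noise_sd=0.0)  # noiseless acquisition
truth = make_ground_truth("demo", alps_left=1.30, alps_right=1.25, geom=geom)

maps_true = generate_subject_volumes(truth, geom)
dwi = generate_subject_dwi(truth, geom)
maps_fit = extract_diagonal(fit_tensor_loglinear(dwi, weighting="wls"))

for name in ("dxx", "dyy", "dzz"):
    err = np.abs(getattr(maps_fit, name) - getattr(maps_true, name)).max()
    print(f"max |{name}_fit - {name}_true| = {err:.2e} mm^2/s")
print(
    "\nErrors at machine precision show the log-linear fit inverts the"
    "\nmono-exponential tensor forward model exactly on noiseless data;"
    "\nwith Rician noise the same numbers quantify the fit error."
)
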