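"""Phase-lag-index connectivity: a planted F2-F7 delta coupling.

Simulates a resting recording in which F2 and F7 share a delta-band
component at a constant quarter-cycle lag, then recovers the coupling
with the PLI pipeline and contrasts it with an uncoupled pair.
"""

import numpy as np

from tmsreact import Montage, band_pli
from tmsreact.simulate import RestingSimSpec, simulate_resting_eeg

montage = Montage()
spec = RestingSimSpec(
    duration=120.0, seed=7, noise_sd=0.5,
    band_fractions={"delta": 0.6, "alpha": 0.4},
    coupled_pairs=(("F2", "F7", "delta", np.pi / 2),),
)
rec = simulate_resting_eeg(spec, montage)
mat = band_pli(rec, (1.0, 4.0))

print(f"delta PLI F2-F7 (coupled, quarter-cycle lag): {mat.pair('F2', 'F7'):.3f}")
print(f"delta PLI Fp1-O2 (independent):               {mat.pair('Fp1', 'O2'):.3f}")
print(f"matrix symmetric: {np.allclose(mat.matrix, mat.matrix.T)}, "
      f"diagonal zero: {np.all(np.diag(mat.matrix) == 0)}")

# The coupled pair approaches PLI = 1 (a constant nonzero lag makes the
# phase-difference distribution maximally asymmetric); independent pairs
# stay near 0. Zero-lag (volume-conducted) coupling would also read 0,
# which is why PLI is the connectivity metric of choice on scalp EEG.
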