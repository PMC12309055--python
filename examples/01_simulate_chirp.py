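"""Generate a CF-FM chirp surrogate and inspect its time-frequency ridge.

A hipposiderid-style echolocation call holds a constant frequency (CF) and
ends in a downward frequency-modulated (FM) sweep.  The generator realizes
this as a second-order all-pole resonator whose pole angle follows the
frequency schedule, driven by Gaussian white noise.
"""

import numpy as np

from batvoc import poles_at
from batvoc.evaluation import stft_ridge
from batvoc.synthetic import ChirpSpec, gen_cf_fm_chirp

spec = ChirpSpec(seed=0)  # 60 kHz CF for 15 ms, sweep to 45 kHz over 5 ms
sig, truth = gen_cf_fm_chirp(spec)
ridge = stft_ridge(sig)

print(f"signal: {len(sig)} samples at {sig.sample_rate_hz:.0f} Hz "
      f"({1e3 * len(sig) / sig.sample_rate_hz:.1f} ms)")
print(f"pole radius (constant): {poles_at(truth, 0).max_radius:.3f}")
print(f"STFT ridge at call start : {ridge[5] / 1e3:.2f} kHz (CF plateau)")
print(f"STFT ridge at call end   : {ridge[-5] / 1e3:.2f} kHz (after FM sweep)")
print(f"ridge span: {np.ptp(ridge[5:-5]) / 1e3:.2f} kHz "
      "(approx. CF minus FM end frequency)")
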