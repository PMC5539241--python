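"""Destruction-replenishment kinetics of a microbubble contrast agent.

Evaluates the mono-exponential replenishment curve I(t) = I0 + A(1 - e^(-beta t))
that models video-intensity recovery after a destruction pulse, and prints
the intensity at a few times.  The plateau I0 + A is proportional to the
perfused vascular volume inside the insonified tissue; beta reflects flow.
"""

import numpy as np

from ceusvv import KineticsParams, replenishment_intensity

params = KineticsParams(baseline=10.0, amplitude=40.0, rate=0.5, onset_time=0.0)
print(f"baseline {params.baseline}, amplitude {params.amplitude}, "
      f"rate {params.rate}/s -> plateau {params.plateau}")
for t in [0.0, 1.0, 2.0, 5.0, 10.0, 40.0]:
    print(f"  t = {t:5.1f} s   intensity = {replenishment_intensity(params, t):8.4f}")
print("The curve rises monotonically from the baseline toward the plateau;")
print("at t = 2 s (beta*t = 1) it has covered 1 - 1/e of the enhancement.")
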