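"""From cine loop to normalized MVE on a noiseless vessel phantom.

Renders a 16x16 long-axis phantom whose lumen enhances with amplitude 40
and adventitia with amplitude 16 after a destruction pulse at t = 2 s,
extracts the time-intensity curve (TIC) of each region through polygon
ROIs, and computes the maximal video-intensity enhancement (MVE = TIC peak
minus pre-pulse background) and the adventitia-to-lumen normalized MVE.
With no noise, the normalized MVE equals the amplitude ratio 16/40 = 0.4.
"""

import numpy as np

from ceusvv import (
    KineticsParams,
    PhantomGeometry,
    RoiPolygon,
    compute_mve,
    estimate_background,
    extract_tic,
    normalized_mve,
    render_cine_loop,
)

geometry = PhantomGeometry(
    image_height=16, image_width=16,
    lumen_band=(6, 10), adventitia_bands=((3, 5), (11, 13)),
)
loop = render_cine_loop(
    geometry,
    KineticsParams(baseline=10.0, amplitude=40.0, rate=0.5, onset_time=2.0),
    KineticsParams(baseline=10.0, amplitude=16.0, rate=0.5, onset_time=2.0),
    noise_sd=0.0, frame_rate=5.0, duration=22.0, background_level=10.0,
)
print(f"cine loop: {loop.n_frames} frames, destruction pulse at "
      f"{loop.destruction_time} s")

rois = {
    "lumen": RoiPolygon("lumen", np.array([[1, 6], [15, 6], [15, 10], [1, 10]])),
    "adventitia": RoiPolygon("adventitia", np.array([[1, 3], [15, 3], [15, 5], [1, 5]])),
}
mves = {}
for name, roi in rois.items():
    tic = extract_tic(loop, roi)
    background = estimate_background(tic, destruction_time=loop.destruction_time)
    mves[name] = compute_mve(tic, background)
    print(f"{name:11s} n_pixels={tic.n_pixels:3d}  background={background:6.3f}  "
          f"peak={mves[name].peak_intensity:7.3f} at t={mves[name].peak_time:4.1f} s  "
          f"MVE={mves[name].mve:7.4f}")

nmve = normalized_mve(mves["adventitia"], mves["lumen"])
print(f"normalized MVE = {nmve.value:.6f}  (true amplitude ratio 16/40 = 0.4)")
print("The dimensionless ratio cancels acquisition gain, making it a")
print("scanner-independent proxy for adventitial vasa-vasorum density.")
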