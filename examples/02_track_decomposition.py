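"""Separate tissue elongation from cell-intrinsic migration in 3D tracks.

Anchor cells (non-migratory epithelial cells) define the elongation
trajectory (ET) as their centroid path; subtracting the net ET
displacement from each observed trajectory (OT) leaves the migration
trajectory (MT). Deep cells here rotate on a 5 μm circle while the whole
tissue drifts, mimicking tailbud cell behaviour during axis elongation.
"""

import numpy as np

from morphlineage import (
    TrackSimSpec,
    decompose_tracks,
    fit_circle_radius,
    movement_directions,
    simulate_explant_tracks,
)

spec = TrackSimSpec(
    n_anchor=3,
    n_deep=8,
    n_frames=120,          # 120 frames at 3 min/frame = 6 h of imaging
    elongation_velocity=(1.0, 0.0, 0.0),  # μm/frame along x
    rotation_radius=5.0,   # μm
    rotation_period=20,    # frames per revolution
    noise_sd=0.3,          # μm positional noise
    seed=3,
)
tracks, _, _ = simulate_explant_tracks(spec)
dec = decompose_tracks(tracks)

et_disp = np.linalg.norm(dec.elongation.positions[-1] - dec.elongation.positions[0])
print(f"anchors used: {dec.anchor_ids}")
print(f"net tissue elongation over {spec.n_frames} frames: {et_disp:.1f} um")

print("\nper-cell migration after removing elongation:")
for tr in tracks:
    mt = dec.migration[tr.track_id].positions
    net = np.linalg.norm(mt[-1] - mt[0])
    if tr.role == "anchor":
        print(f"  {tr.track_id} (anchor): net migration {net:.2f} um (should be ~0)")
    else:
        radius = fit_circle_radius(mt)
        print(f"  {tr.track_id} (deep):   circle-fit radius {radius:.2f} um")

hist = movement_directions(tracks, window=1, n_bins=16)
top = int(np.argmax(hist.counts))
lo, hi = hist.bin_edges[top], hist.bin_edges[top + 1]
print(
    f"\ndirection histogram ({hist.counts.sum()} steps, {hist.n_zero} zero-"
    f"projection): modal bin {lo:.0f}-{hi:.0f} deg in the elongation plane"
)
# Anchors barely migrate once elongation is removed, while deep-cell MTs
# recover the injected 5 um rotation circle; the modal direction bin
# reflects the dominant drift in the projection plane.
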