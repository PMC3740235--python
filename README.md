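# dyntexseg

Motion-based segmentation and tracking of low-contrast image time series
with dynamic textures, multiphase level sets and thrombus measures.

## What it does, and for whom

Time-lapse DIC microscopy of an injured blood vessel shows three regions —
the growing thrombus, the uncoagulated vessel with fast-circulating blood
cells, and a near-static background — that are almost indistinguishable in
any single frame.  What separates them is how they *move*.  `dyntexseg`
is for researchers quantifying thrombus formation (or any scene whose
regions differ by motion pattern rather than intensity): it segments the
scene from its dynamics, tracks the thrombus and vessel through the
recording, and extracts the two standard readouts, the time to attachment
(TTA) and the per-frame thrombus surface area (TSA).

## The model

Each pixel's spatio-temporal patch over a window of `tau + 1` frames is a
**dynamic texture**: a linear dynamical system

    z(t+1) = A z(t) + v(t),        y(t) − ȳ = C z(t) + w(t)

with hidden state of order `n` and orthonormal spatial modes `C`, estimated
in closed form by SVD.  Models are compared with the squared **Martin
distance** between their extended observability subspaces,

    d_M²(D₁, D₂) = −log ∏ᵢ cos² θᵢ ,

`θᵢ` the principal angles between `span[C; CA; …; CAⁿ⁻¹]`.  Each region
gets an approximate normal law on the model manifold (a Fréchet/medoid
mean or the Doss expectation surrogate, plus a variance), and the
partition minimizes

    E = α E_ms + β E_ed − γ E_sp + ζ E_top

— a motion-segmentation likelihood, an event-detection likelihood (the
thrombus is where the motion pattern *changed* relative to the first
window), a tubular shape prior on the aorta, and a topological prior that
keeps the thrombus inside the vessel — via two level-set embedding
functions evolved by diffusion-regularized gradient descent.  A backward
tracker propagates the result through the sequence and reads off TTA/TSA.
See `docs/methods.md` for the full account.

## Worked example

Segment a synthetic three-region scene (a thrombus-like disk inside a
square vessel on a near-static background, 64×64×75 frames) from polygon
initial contours:

```python
import dyntexseg as d
from dyntexseg.levelset_solver import segment, synthetic_config

seq, truth = d.default_three_region_scene(seed=1)
thr_poly, ves_poly = d.default_scene_polygons()   # initial Rand ~ 0.70
res = segment(seq, window=(0, 61), init_polygons=(thr_poly, ves_poly),
              config=synthetic_config(seed=1))
print(round(d.rand_index(res.labels, truth), 3))
print(round(d.dice(res.thrombus_mask, truth == 2), 3))
```

prints

```
0.933
0.891
```

— the Rand index of the recovered 3-label partition against the ground
truth (up from 0.701 at initialization) and the Dice overlap of the
thrombus region.  Tracking a growing-plug sequence and extracting the
measures:

```python
from dyntexseg.tracker import plug_tracking_config, track, normalized_sad

seq, labels, truth = d.make_growing_plug_sequence(seed=0)
res = track(seq, d.default_plug_polygons(), plug_tracking_config(seed=0))
print(res.tta_s, round(normalized_sad(res.tsa_px, truth["tsa_px"]), 3))
```

prints

```
5.36 0.19
```

— the estimated attachment time in seconds (truth: 4.88 s for this scene)
and the normalized sum of absolute differences between the estimated and
true TSA series.

A command-line interface wraps the library:

```bash
dyntexseg simulate --kind scene --seed 1 --output scene/
dyntexseg segment scene/sequence.tif --polygons polys.json --output seg/
dyntexseg evaluate seg/labels.tif scene/truth_labels.tif
dyntexseg track scene/sequence.tif --polygons polys.json --output out/
```

`track` writes per-frame measures as CSV (`frame, time_s, tsa_px, tsa_um2,
vessel_px, active_flag`) with a JSON sidecar carrying the TTA.

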