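# pfv3d

Syntactic-pattern object recognition for volumetric grayscale images — built
for MRI-like brain volumes containing compact high-intensity lesions, but
applicable to any 3D grayscale data with bright objects on a dark background.

Instead of statistical texture features, the pipeline describes an object by
the *composition of local sub-patterns* on its wireframe:

1. **Denoise** — a classical two-stage adaptive median filter removes
   salt-and-pepper impulse noise while preserving edges.
2. **Contrast stretch** — intensities in the histogram range `[c, d]`
   (percentile-derived) are mapped linearly onto `[a, b]`:
   `O = (r − c)·(b − a)/(d − c) + a`.
3. **CLAP wireframe** — cellular-logic array processing repeatedly scans the
   binarized volume with a 3×3×3 window and deletes every foreground voxel
   whose window has *all 27 axis-aligned 3-voxel lines occupied* (the
   interior criterion), leaving a 1-voxel-thick skeletal shell.
4. **3D pattern frequency vector (3D-PFV)** — a 3×3×3 window slides over the
   wireframe with stride 3. Only the 8 corner cells of the window are read,
   giving 2⁸ = 256 occupancy configurations. Patterns are grouped by the
   number of absent corners: P (0 absent), Q (1), R (2), …, X (8), with
   group sizes C(8,k) = 1, 8, 28, 56, 70, 56, 28, 8, 1. Counting the pattern
   at every placement yields a 256-length feature vector.
5. **Classification** — an MLP head on the 3D-PFV (default), or a small
   AlexNet-style 3D convolutional network (5 convolution + 3 fully connected
   layers, max pooling of window 2 after convolutions 1, 2 and 5), both on a
   seeded pure-NumPy backend.

A synthetic phantom module generates MRI-like volumes of three lesion shape
classes (solid ellipsoid, hollow shell, multi-focal blobs) with exact ground
truth for every stage — including binary volumes with *planted* corner
patterns whose expected PFV is known by construction.

## Worked example

```python
import numpy as np
from pfv3d import (PhantomSpec, make_phantom, wireframe_pipeline,
                   extract_pfv, build_vocabulary)

noisy, clean, mask = make_phantom(
    PhantomSpec(shape_class="solid_ellipsoid", volume_shape=(30, 30, 30),
                noise_density=0.05, seed=3))
wf = wireframe_pipeline(clean, threshold=128)
print(wf.iterations, wf.deleted_count, wf.mask.foreground_count)
# 2 1568 872     <- 2 passes; the solid interior is gone, the shell remains

pfv = extract_pfv(wf.mask)           # stride-3 scan, 10x10x10 = 1000 windows
vocab = build_vocabulary()
top = np.argsort(pfv.counts)[::-1][:3]
print([(vocab[i].name, int(pfv.counts[i])) for i in top])
# [('X{1,3,7,9,19,21,25,27}', 880), ('V{1,3,7,9,19,21}', 6), ('W{1,3,7,9,19,21,25}', 6)]
print(int(pfv.counts.sum()) == pfv.n_windows)   # True — counts conserve
```

Most windows miss the thin shell entirely (the all-absent pattern X
dominates); the informative signal is in how the remaining mass spreads over
the other 255 patterns — hollow shells light up roughly twice as many
windows as solid ellipsoids of the same size, and multi-focal blobs far
fewer.

The same flow from the shell:

```sh
pfv3d synth --shape-class solid_ellipsoid --shape 30,30,30 --noise 0.05 --seed 3 --out phantom.nii
pfv3d wireframe --in phantom.nii --threshold 128 --out wire.nii
pfv3d pfv --in wire.nii --out features.csv
```

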