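# twodsil

A hierarchical, biologically based model of 2-D shape representation
(**2DSIL**): five layers of model neurons turn a white-on-black contour image
into the responses of shape-selective cells of the kind recorded in primate
area V4, with no learning stage.

The package is for computational neuroscientists and vision researchers who
want an executable, testable implementation of endstopped-cell based
curvature coding: synthetic contour stimuli (bars, circular arcs, closed
shapes built from convex/concave boundary elements), the full model
hierarchy, and the response-comparison machinery used to evaluate shape
cells against reference (e.g. electrophysiological) response profiles.

## The model

1. **Simple cells** — oriented difference-of-Gaussians filters. In
   coordinates (u, v) along/across the preferred orientation θ:

       K(u,v) = A [exp(−v²/2σ²) − (1/WR)·exp(−v²/2(WR·σ)²)] · exp(−u²/2(AR·σ)²)

   with σ = size/4; four sizes (40, 60, 88, 120 px) with aspect ratios
   AR = (0.7, 1.4, 2.15, 3), width ratio WR = 2.5, and 12 orientations in
   15° steps — 48 filter types. Responses are half-wave rectified.
2. **Complex cells** — the normalized Gaussian-weighted sum of 5 simple
   cells displaced perpendicular to θ (spacing size/8): same orientation
   preference, larger and more position-tolerant receptive fields.
3. **Endstopped cells** — the rectified difference between a central
   excitatory simple cell and two inhibitory displaced complex cells,
   followed by a logistic saturation g (α = 0.01, half-point = population
   max / 8.5). Same-orientation flanks displaced ±size/2 *along* θ give
   **degree-of-curvature** cells: each scale responds over a band of contour
   curvature radii (sharp → small cell, broad → large cell). Flanks at
   θ±45° displaced to one side of the preferred axis give
   **sign-of-curvature** cells; the mirror-image variant detects the
   opposite (convex vs concave) sign.
4. **Local curvature cells** — the degree response is routed to the signed
   class whose sign cell wins, giving 4 scales × 2 signs = 8 curvature
   classes per location; locations with strong oriented but weak endstopped
   drive are flagged as straight (curvature 0).
5. **Shape cells** — curvature-by-parts templates over polar
   (radial × angular) bins relative to the cell centre (10 px radial,
   π/45 angular, 20 × 90 = 1 800 bins; 14 400 addressable curvature parts).
   A cell is *isolated* from a template stimulus; probe responses are the
   template-weighted curvature activity with Gaussian position and
   curvature-class tolerance, normalized so the template scores 1.

## Worked example

```python
import numpy as np
from twodsil import (ModelConfig, curvature_tuning_curve, band_90pct,
                     ArcSpec, render_arc, isolate_shape_neuron, shape_response)

# curvature-radius tuning of the smallest degree-of-curvature scale
curve = curvature_tuning_curve(0, np.arange(4, 41, 1.0))
print(band_90pct(curve))

# isolate a shape cell from a small circle 100 px above centre and probe it
cfg = ModelConfig()
def circle(deg):
    a = np.radians(deg)
    c = (199.5 + 100*np.cos(a), 199.5 + 100*np.sin(a))
    return render_arc(ArcSpec(radius=12, arc_center=c), antialias=True)
neuron = isolate_shape_neuron(circle(90), cfg.grid, cfg)
for deg in (90, 94, 270):
    print(deg, round(shape_response(neuron, circle(deg), cfg), 3))
```

prints

```
(5.5368808641346146, 11.09746279003984)
90 1.0
94 0.97
270 0.003
```

— the smallest scale responds at ≥90% of its maximum for arc radii of about
5.5–11 px, and the shape cell responds fully to its template, almost fully
one angular bin away, and not at all to the same feature on the opposite
side of its receptive field.

A command-line interface `2dsil` exposes the same functionality
(`render`, `battery`, `respond`, `tuning`, `curvature`, `isolate`,
`profile`, `compare`); see `2dsil --help`.

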