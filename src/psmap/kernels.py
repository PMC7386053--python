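"""Convolution kernels for the 2D topological-charge detector.

The topological charge at a cell is the winding number of the phase around
a closed path, computed as a pair of 2D convolutions of derivative stencils
with the wrapped one-step phase-difference fields.  Four stencil pairs are
shipped: ``sobel3`` and ``nabla2`` with the weights conventionally used for
this operator, plus the standard 5x5 Sobel (``sobel5``) and 3x3
central-difference nabla (``nabla3``) forms.

Each pair is stored as written in the source convention (x increases with
column, y increases upward, ``+`` weights on the right/top).  ``ANCHOR``
gives the output alignment of the flipped (true-convolution) stencil and
``CHARGE_NORM`` the loop multiplicity of the pair: the raw response of the
stencil pair to a single unit vortex, so that after division the charge of
an ideal singularity is +-1 for every kernel.  With this calibration the
``nabla2`` pair is *exactly* the winding number of the 2x2 plaquette whose
top-left corner is the output cell.
"""

from __future__ import annotations

import numpy as np

_s3 = np.array([0.5, 1.0, 0.5])
_d3 = np.array([-1.0, 0.0, 1.0])

SOBEL3_X = np.outer(_s3, _d3)  # [[-1/2, 0, +1/2], [-1, 0, +1], [-1/2, 0, +1/2]]
SOBEL3_Y = np.outer(-_d3, _s3)  # [[+1/2, +1, +1/2], [0, 0, 0], [-1/2, -1, -1/2]]

NABLA2_X = np.array([[1.0, -1.0], [0.0, 0.0]])
NABLA2_Y = np.array([[-1.0, 0.0], [1.0, 0.0]])

NABLA3_X = np.array([[0.0, 0.0, 0.0], [-1.0, 0.0, 1.0], [0.0, 0.0, 0.0]])
NABLA3_Y = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 0.0], [0.0, -1.0, 0.0]])

_s5 = np.array([1.0, 4.0, 6.0, 4.0, 1.0])
_d5 = np.array([-1.0, -2.0, 0.0, 2.0, 1.0])

SOBEL5_X = np.outer(_s5, _d5)
SOBEL5_Y = np.outer(-_d5, _s5)

KERNELS: dict[str, tuple[np.ndarray, np.ndarray]] = {
    "sobel3": (SOBEL3_X, SOBEL3_Y),
    "sobel5": (SOBEL5_X, SOBEL5_Y),
    "nabla2": (NABLA2_X, NABLA2_Y),
    "nabla3": (NABLA3_X, NABLA3_Y),
}

# Output-cell anchor of the effective correlation stencil, per kernel and
# per term (anchor_x for the term applied to k_y, anchor_y for the term
# applied to k_x).  Odd kernels anchor at their center; the 2x2 nabla
# anchors are chosen so both terms align on the same plaquette, making the
# nabla2 charge exactly that plaquette's winding number.
ANCHOR: dict[str, tuple[tuple[int, int], tuple[int, int]]] = {
    "sobel3": ((1, 1), (1, 1)),
    "sobel5": ((2, 2), (2, 2)),
    "nabla2": ((1, 0), (0, 1)),
    "nabla3": ((1, 1), (1, 1)),
}

# The two published stencil families carry opposite sign conventions (the
# Sobel pairs put "+" on the right/top, the 2x2 nabla pair on the left), so
# the nabla2 pair enters through its flipped (true-convolution) form while
# the others enter as correlations; with this orientation every kernel's
# charge carries the sign of the winding number.
FLIP: dict[str, bool] = {"sobel3": False, "sobel5": False, "nabla2": True, "nabla3": False}

# Loop multiplicity: raw stencil-pair response to one unit (+1) vortex
# whose core is centered on a plaquette, i.e. the peak of the unnormalized
# charge field over an ideal singularity.  nabla2 (and, by cancellation of
# its smoothing weights, sobel3) is exact; sobel5 and nabla3 were
# calibrated once against an ideal vortex field and are frozen here.
CHARGE_NORM: dict[str, float] = {
    "nabla2": 1.0,
    "nabla3": 0.7048327646991335,
    "sobel3": 1.0,
    "sobel5": 18.0,
}
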