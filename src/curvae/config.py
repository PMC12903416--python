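"""Shared numerical tolerances and defaults."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class Tolerances:
    # manifold-constraint residual treated as exact
    on_manifold: float = 1e-6
    # residuals below this are silently renormalised; above, an error
    reproject: float = 1e-4
    # |<base, v>| allowed for a vector claimed tangent at base
    tangency: float = 1e-6
    # floor added to posterior scale heads
    sigma_floor: float = 1e-4


TOLERANCES = Tolerances()
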