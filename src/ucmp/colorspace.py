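"""RGB to HSL conversion.

The fibrosis filter classifies pixels in the hue-saturation-luminance space,
so the conversion is implemented once, vectorized, and used everywhere.
Convention: L = (max + min) / 2, S = (max - min) / (1 - |2L - 1|) with S = 0
for achromatic pixels, hue from the max-channel sector formula in degrees
[0, 360) with hue = 0 when saturation = 0.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rgb_to_hsl", "hsl_to_rgb"]


def rgb_to_hsl(r, g, b):
    """Convert 8-bit RGB channels to (hue degrees, saturation, luminance).

    Parameters
    ----------
    r, g, b : scalar or array-like
        Channel values in [0, 255]; broadcast together.

    Returns
    -------
    (h, s, l) : tuple of floats or ndarrays
        Hue in [0, 360), saturation and luminance in [0, 1].
    """
    r, g, b = np.broadcast_arrays(
        np.asarray(r, dtype=np.float64) / 255.0,
        np.asarray(g, dtype=np.float64) / 255.0,
        np.asarray(b, dtype=np.float64) / 255.0,
    )
    if np.any(r < 0) or np.any(r > 1) or np.any(g < 0) or np.any(g > 1) \
            or np.any(b < 0) or np.any(b > 1):
        raise ValueError("channel values must lie in [0, 255]")
    mx = np.maximum(np.maximum(r, g), b)
    mn = np.minimum(np.minimum(r, g), b)
    lum = (mx + mn) / 2.0
    delta = mx - mn

    denom = 1.0 - np.abs(2.0 * lum - 1.0)
    sat = np.zeros_like(lum)
    chromatic = delta > 0
    np.divide(delta, denom, out=sat, where=chromatic & (denom > 0))

    # sector formula; delta==0 pixels are left at hue 0
    safe = np.where(chromatic, delta, 1.0)
    h = np.zeros_like(lum)
    is_r = chromatic & (mx == r)
    is_g = chromatic & ~is_r & (mx == g)
    is_b = chromatic & ~is_r & ~is_g
    h = np.where(is_r, np.mod((g - b) / safe, 6.0), h)
    h = np.where(is_g, (b - r) / safe + 2.0, h)
    h = np.where(is_b, (r - g) / safe + 4.0, h)
    hue = np.mod(h * 60.0, 360.0)

    if hue.ndim == 0:
        return float(hue), float(sat), float(lum)
    return hue, sat, lum


def hsl_to_rgb(h, s, l):
    """Inverse conversion, returning float channels in [0, 255].

    Used by the synthetic slide generator to turn nominal stain colors
    (specified in HSL) into RGB paint values.
    """
    h = np.mod(np.asarray(h, dtype=np.float64), 360.0)
    s = np.asarray(s, dtype=np.float64)
    l = np.asarray(l, dtype=np.float64)
    c = (1.0 - np.abs(2.0 * l - 1.0)) * s
    hp = h / 60.0
    x = c * (1.0 - np.abs(np.mod(hp, 2.0) - 1.0))
    z = np.zeros_like(c)
    conds = [hp < 1, hp < 2, hp < 3, hp < 4, hp < 5, hp >= 5]
    r1 = np.select(conds, [c, x, z, z, x, c])
    g1 = np.select(conds, [x, c, c, x, z, z])
    b1 = np.select(conds, [z, z, x, c, c, x])
    m = l - c / 2.0
    rgb = np.stack([r1 + m, g1 + m, b1 + m], axis=-1) * 255.0
    if rgb.ndim == 1:
        return tuple(float(v) for v in rgb)
    return rgb
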