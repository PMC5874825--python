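"""Helpers to build synthetic RDF-like profiles with exact peak points."""

import numpy as np

from solvagg.solvation import RDFProfile


def profile_through(r_max, g_max, r_min, g_min, *, bin_width=0.01,
                    r_start=1.0, r_end=4.0, g_start=0.0, g_end=None,
                    density=0.0334):
    """Piecewise-cosine profile whose first peak/minimum pass exactly
    through (r_max, g_max) and (r_min, g_min).

    The grid is chosen so that r_max and r_min land on bin centers
    (values are given to the same decimal resolution as bin_width).
    """
    n0 = round(r_start / bin_width)
    n1 = round(r_end / bin_width)
    r = np.arange(n0, n1 + 1) * bin_width
    g = np.empty_like(r)
    if g_end is None:
        g_end = g_min + 0.5 * (g_max - g_min)

    def seg(x, x0, x1, y0, y1):
        """Half-cosine ramp from (x0, y0) to (x1, y1)."""
        t = (x - x0) / (x1 - x0)
        return y0 + (y1 - y0) * 0.5 * (1 - np.cos(np.pi * t))

    for i, ri in enumerate(r):
        if ri <= r_max:
            g[i] = seg(ri, r[0], r_max, g_start, g_max)
        elif ri <= r_min:
            g[i] = seg(ri, r_max, r_min, g_max, g_min)
        else:
            g[i] = seg(ri, r_min, r[-1], g_min, g_end)
    return RDFProfile(r=r, g=g, density=density)
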