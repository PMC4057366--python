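"""Packaged example data.

One small synthetic wholemount counting record is shipped with the package:
200 sites on the 10x10 um frame / 320x320 um grid design, with per-site
counts constructed so the count sum is exactly 8970 — the sum implied by a
published fractionator total of 9,185,280 at 1/asf = 1024.  It exercises
the exact integer arithmetic of the estimator without any real specimen
data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd
from shapely.geometry import MultiPoint

from .stereology import SamplingDesign, WholemountSample

__all__ = ["load_synthetic_longipes_sample"]


def load_synthetic_longipes_sample() -> WholemountSample:
    """Synthetic 200-site counting record on the 10x10/320x320 um design."""
    ref = resources.files("lanterneye.data") / "synthetic_counts_blongipes_A.csv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, comment="#")
    design = SamplingDesign(frame_w=10, frame_h=10, grid_dx=320, grid_dy=320)
    # outline is not recorded in the CSV; a convex hull padded by one grid
    # step encloses every site and suffices for the estimator
    hull = MultiPoint(df[["site_x_mm", "site_y_mm"]].to_numpy()).convex_hull.buffer(0.32)
    return WholemountSample.from_frame(df, design, hull)
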