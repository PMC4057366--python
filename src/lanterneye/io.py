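"""File I/O: Newick trees via dendropy, CSV tables via pandas."""

from __future__ import annotations

from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from shapely.geometry import Polygon

__all__ = [
    "read_tree",
    "write_tree",
    "read_traits",
    "write_traits",
    "read_outline",
    "write_outline",
]


def read_tree(path: str | Path) -> dendropy.Tree:
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    tree.is_rooted = True
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=False)


def read_traits(path: str | Path, species_col: str = "species") -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if species_col not in df.columns:
        raise ValueError(f"trait table must contain a {species_col!r} column")
    return df


def write_traits(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_outline(path: str | Path) -> Polygon:
    """Outline polygon from a CSV vertex list with x_mm, y_mm columns."""
    df = pd.read_csv(path, comment="#")
    if not {"x_mm", "y_mm"} <= set(df.columns):
        raise ValueError("outline CSV must have x_mm and y_mm columns")
    return Polygon(df[["x_mm", "y_mm"]].to_numpy(float))


def write_outline(outline: Polygon, path: str | Path) -> None:
    xy = np.asarray(outline.exterior.coords)
    pd.DataFrame({"x_mm": xy[:, 0], "y_mm": xy[:, 1]}).to_csv(path, index=False)
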