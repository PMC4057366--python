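import dendropy
import numpy as np
import pytest

from lanterneye import (
    SamplingDesign,
    SpecializationSpec,
    build_true_retina,
    grafen_transform,
    slit_disc_outline,
)
from lanterneye.treesim import simulate_tree


def newick(s: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=s, schema="newick")
    tree.is_rooted = True
    return tree


@pytest.fixture(scope="session")
def three_tip_grafen():
    """((A,B),C) after Grafen rho = 2.5: internal height 0.5^2.5."""
    return grafen_transform(newick("((A:1,B:1):1,C:2);"), rho=2.5)


@pytest.fixture(scope="session")
def tree64():
    return grafen_transform(simulate_tree(64, seed=11))


@pytest.fixture(scope="session")
def tree128():
    return grafen_transform(simulate_tree(128, seed=12))


@pytest.fixture(scope="session")
def default_design():
    return SamplingDesign(frame_w=10, frame_h=10, grid_dx=320, grid_dy=320)


@pytest.fixture(scope="session")
def arch_retina():
    """Shallow arch specialisation (2:1 peak:background) on a slit disc sized
    to admit roughly 200 sites at a 320 um grid."""
    spec = SpecializationSpec(
        kind="arch",
        background_density=400e3,
        peak_density=800e3,
        center=(0.0, 0.0),
        radius_mm=1.3,
        width_mm=0.8,
        arc_span=180.0,
    )
    return build_true_retina(spec, slit_disc_outline(radius_mm=2.6))


@pytest.fixture(scope="session")
def uniform_retina():
    spec = SpecializationSpec(
        kind="uniform", background_density=522e3, peak_density=522e3
    )
    return build_true_retina(spec, slit_disc_outline(radius_mm=2.6))


@pytest.fixture(scope="session")
def ring_retina():
    spec = SpecializationSpec(
        kind="ring",
        background_density=300e3,
        peak_density=520e3,
        center=(0.0, 0.0),
        radius_mm=1.4,
        width_mm=0.35,
    )
    return build_true_retina(spec, slit_disc_outline(radius_mm=2.6))
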