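import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ringtier as rt
from ringtier.synthetic import AssemblyParams, HelixParams

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
    max_examples=30,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def spiral_assembly():
    """Open-spiral hexamer at the default (study) helix parameters."""
    return rt.make_assembly(AssemblyParams(helix=HelixParams(seed=11), seed=11))


@pytest.fixture(scope="session")
def breached_assembly():
    """Hexamer with a 20 Å planted opening at one subunit interface."""
    return rt.make_assembly(
        AssemblyParams(helix=HelixParams(seed=12), breach_gap=20.0, seed=12)
    )


@pytest.fixture(scope="session")
def two_tier_assembly():
    """Spiral tier plus a planar tier tilted by 15°."""
    return rt.make_assembly(
        AssemblyParams(
            helix=HelixParams(seed=13),
            second_tier=HelixParams(rise=0.0, twist=60.0, radius=35.0, seed=14),
            tier_tilt=15.0,
            seed=13,
        )
    )


@pytest.fixture()
def single_carbon():
    return [rt.AtomRecord("A", 1, "ALA", "CA", "C", (0.0, 0.0, 0.0))]


def make_ca_atoms(points, chain="A", start=1):
    """Helper: one Cα pseudo-atom per point."""
    return [
        rt.AtomRecord(chain, start + i, "ALA", "CA", "C", tuple(p))
        for i, p in enumerate(np.asarray(points, dtype=float))
    ]
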