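"""Shared fixtures: small hand-built structures with known geometry."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from cadmech.io_formats import Atom, DomainDefinition, Structure

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


def make_rod(
    n: int = 12,
    axis=(0.0, 0.0, 1.0),
    origin=(0.0, 0.0, 0.0),
    start_res: int = 1,
    spacing: float = 4.0,
    helix_radius: float = 0.5,
    chain: str = "A",
) -> list[Atom]:
    """A helical rod of Cα pseudo-atoms along ``axis`` starting at ``origin``.

    The small helical offset keeps the second principal axis defined while
    the long axis is unambiguous; residue numbers increase along the axis
    (N->C), so the oriented principal axis equals ``axis``.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    ref = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    atoms = []
    for i in range(n):
        pos = (
            np.asarray(origin, dtype=float)
            + i * spacing * axis
            + helix_radius * (np.cos(0.8 * i) * e1 + np.sin(0.8 * i) * e2)
        )
        atoms.append(
            Atom(
                serial=start_res + i,
                name="CA",
                element="C",
                residue_name="GLY",
                residue_number=start_res + i,
                chain=chain,
                altloc="",
                occupancy=1.0,
                coordinates=tuple(float(c) for c in pos),
                mass=12.011,
            )
        )
    return atoms


@pytest.fixture
def rod_structure() -> tuple[Structure, DomainDefinition]:
    atoms = make_rod(n=12)
    return Structure(atoms=atoms), DomainDefinition("rod", "A", 1, 12)


@pytest.fixture
def bent_synthetic():
    """Bent two-domain structure with three pseudo-calcium sites at the
    atypical d23 spacing, plus its generator truth."""
    from cadmech.synthetic_data import gen_two_domain_structure

    structure, truth = gen_two_domain_structure(
        bend_angle=90.0, with_ca_sites=True, ca_spacings=(4.7, 8.48), seed=11
    )
    doms = {k: DomainDefinition(**v) for k, v in truth.labels["domains"].items()}
    return structure, truth, doms
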