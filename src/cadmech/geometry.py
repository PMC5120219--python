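"""Structure- and trajectory-level mechanics geometry.

This module measures the quantities the structural analysis turns on:
principal axes of EC repeats, inter-repeat bend angles, probability maps of
projected domain orientations, Kabsch-superposed RMSD, atom/centroid
distance series with running averages, calcium-site geometry at linkers
(including the site-2/site-3 separation d23), mass-weighted radius of
gyration, and buried surface area of a domain-domain interface via
Shrake-Rupley solvent-accessible surface areas.

Conventions
-----------
* Bend angle 0° means collinear tandem repeats (the straight, canonical
  arrangement); a calcium-free bent linker shows up near 90°.
* Principal axes are computed from Cα positions and oriented from the
  N-terminal half of the domain toward the C-terminal half, so angles
  between axes are meaningful for chain topology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

import biotite.structure as bst

from .io_formats import DomainDefinition, Structure, Trajectory

__all__ = [
    "DegenerateAxisError",
    "OrientationMap",
    "CaSiteSet",
    "MetricSeries",
    "running_average",
    "principal_axis",
    "secondary_axis",
    "orientation_map",
    "bend_angle",
    "kabsch_rmsd",
    "distance_series",
    "locate_ca_sites",
    "radius_of_gyration",
    "shrake_rupley_sasa",
    "buried_surface",
]


#: Default PCDH15 EC8-10 domain boundaries in processed-protein numbering
#: (repeat termini are a convention: the linkers are pinned by the
#: published residue ranges, exact repeat ends are user-overridable).
def pcdh15_domains(chain: str = "A") -> dict[str, DomainDefinition]:
    return {
        "EC8": DomainDefinition("EC8", chain, 795, 896),
        "EC9": DomainDefinition("EC9", chain, 902, 1004),
        "EC10": DomainDefinition("EC10", chain, 1014, 1116),
    }


#: Inter-repeat linker residue ranges (inclusive), processed numbering.
PCDH15_LINKERS: dict[str, tuple[int, int]] = {
    "EC8-9": (897, 901),
    "EC9-10": (1005, 1013),
}

#: Mean site-2/site-3 calcium separation over a canonical-linker reference
#: set (Å).  Ships as a constant for comparison; the reference structures
#: themselves are not distributed with the package.
CANONICAL_D23_MEAN_A = 6.84


class DegenerateAxisError(ValueError):
    """The domain's inertia ellipsoid is too close to spherical for a
    well-defined long axis (top-eigenvalue ratio below the threshold)."""


@dataclass
class OrientationMap:
    """Gridded probability of probe-domain axis directions projected onto
    the plane normal to the reference-domain axis (unit disk)."""

    edges: np.ndarray                 # (n_bins+1,) shared x/y bin edges over [-1, 1]
    probabilities: np.ndarray         # (n_bins, n_bins), sums to 1
    reference_domain: str
    probe_domain: str
    stride_ps: float | None = None
    points: np.ndarray | None = None  # (n_frames, 2) raw projections

    def __post_init__(self) -> None:
        total = float(self.probabilities.sum())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError(f"probabilities sum to {total}, not 1")
        if (self.probabilities < 0).any():
            raise ValueError("negative probability bin")


@dataclass
class CaSiteSet:
    """Calcium ions bound at one inter-repeat linker, labeled 1..3 along
    the first repeat's axis (site 1 nearest the repeat's base)."""

    positions: list[np.ndarray]       # ordered site coordinates, Å
    linker: tuple[int, int]

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def d23(self) -> float | None:
        """Site-2 to site-3 distance (Å); defined only when all three
        sites are present (with fewer ions the labeling is ambiguous)."""
        if self.n_sites != 3:
            return None
        return float(np.linalg.norm(self.positions[2] - self.positions[1]))


@dataclass
class MetricSeries:
    """A scalar metric along a trajectory (times in ns)."""

    times: np.ndarray
    values: np.ndarray
    name: str = ""
    window_ns: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values differ in length")
        if self.window_ns is not None and self.window_ns <= 0:
            raise ValueError("running-average window must be positive")


def running_average(values: np.ndarray, n: int) -> np.ndarray:
    """Centered running mean over ``n`` samples; windows are truncated at
    the edges (no padding, no NaNs)."""
    values = np.asarray(values, dtype=float)
    if n <= 1:
        return values.copy()
    csum = np.concatenate(([0.0], np.cumsum(values)))
    half = n // 2
    idx = np.arange(len(values))
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + (n - half), len(values))
    return (csum[hi] - csum[lo]) / (hi - lo)


def _domain_calpha(structure: Structure, domain: DomainDefinition) -> tuple[np.ndarray, np.ndarray]:
    """Cα coordinates and residue numbers of a domain, in residue order."""
    sel = structure.select(
        chain=domain.chain,
        residues=(domain.first_residue, domain.last_residue),
        name="CA",
        hetero=False,
    )
    pairs = sorted(
        ((a.residue_number, np.asarray(a.coordinates)) for a in sel.atoms),
        key=lambda p: p[0],
    )
    if not pairs:
        raise ValueError(f"domain {domain.name}: no Cα atoms found")
    resnums = np.array([p[0] for p in pairs])
    coords = np.array([p[1] for p in pairs])
    return coords, resnums


def _principal_frame(coords: np.ndarray, min_ratio: float = 1.2) -> tuple[np.ndarray, np.ndarray]:
    """Top two covariance eigenvectors; raises if the top two eigenvalues
    are within a factor ``min_ratio`` of each other."""
    if len(coords) < 4:
        raise ValueError("need at least 4 Cα positions for a principal axis")
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(coords)
    evals, evecs = np.linalg.eigh(cov)      # ascending
    lam1, lam2 = evals[-1], evals[-2]
    if lam2 <= 0 or lam1 / lam2 < min_ratio:
        raise DegenerateAxisError(
            f"top covariance eigenvalues too close (ratio {lam1 / max(lam2, 1e-300):.3f} < {min_ratio})"
        )
    return evecs[:, -1], evecs[:, -2]


def principal_axis(structure: Structure, domain: DomainDefinition) -> np.ndarray:
    """Oriented unit vector along the domain's long axis.

    The largest-eigenvalue eigenvector of the Cα covariance, with sign
    chosen so the axis points from the N-terminal-half centroid toward the
    C-terminal-half centroid.
    """
    coords, _ = _domain_calpha(structure, domain)
    axis, _ = _principal_frame(coords)
    half = len(coords) // 2
    direction = coords[half:].mean(axis=0) - coords[:half].mean(axis=0)
    if float(axis @ direction) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def secondary_axis(structure: Structure, domain: DomainDefinition) -> np.ndarray:
    """Second principal axis of the domain, orthogonalized against the
    first; sign fixed so the first Cα lies on its positive side.  Used as
    the azimuth gauge for orientation maps."""
    coords, _ = _domain_calpha(structure, domain)
    a1, a2 = _principal_frame(coords)
    half = len(coords) // 2
    direction = coords[half:].mean(axis=0) - coords[:half].mean(axis=0)
    if float(a1 @ direction) < 0:
        a1 = -a1
    a2 = a2 - (a2 @ a1) * a1
    a2 /= np.linalg.norm(a2)
    gauge = coords[0] - coords.mean(axis=0)
    if float(a2 @ gauge) < 0:
        a2 = -a2
    return a2


def bend_angle(structure: Structure, dom_a: DomainDefinition, dom_b: DomainDefinition) -> float:
    """Angle in degrees between the oriented principal axes of two domains;
    0° is the collinear (straight tandem) arrangement."""
    a = principal_axis(structure, dom_a)
    b = principal_axis(structure, dom_b)
    return float(np.degrees(np.arccos(np.clip(a @ b, -1.0, 1.0))))


def orientation_map(
    traj: Trajectory,
    ref: DomainDefinition,
    probe: DomainDefinition,
    stride_ps: float | None = None,
    n_bins: int = 50,
) -> OrientationMap:
    """Probability map of the probe-domain axis in the reference frame.

    Per sampled frame, the reference domain's principal axis is aligned to
    +z (with its second principal axis fixing the azimuth gauge along +x)
    and the probe domain's unit axis is projected onto the x-y plane.  The
    projected points are histogrammed on an ``n_bins`` × ``n_bins`` grid
    over the unit disk's bounding square and normalized to a probability.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    if stride_ps is None:
        indices = np.arange(len(traj))
    else:
        if not (stride_ps > 0 and math.isfinite(stride_ps)):
            raise ValueError(f"stride must be positive and finite, got {stride_ps}")
        dt_ns = float(np.median(np.diff(traj.times))) if len(traj) > 1 else 1.0
        step = max(1, int(round(stride_ps / 1000.0 / dt_ns)))
        indices = np.arange(0, len(traj), step)
    if len(indices) == 0:
        raise ValueError("stride leaves no frames to sample")
    points = np.empty((len(indices), 2))
    for k, i in enumerate(indices):
        frame = traj.frames[i]
        ez = principal_axis(frame, ref)
        ex = secondary_axis(frame, ref)
        ey = np.cross(ez, ex)
        p = principal_axis(frame, probe)
        points[k] = (p @ ex, p @ ey)
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    hist, _, _ = np.histogram2d(points[:, 0], points[:, 1], bins=[edges, edges])
    return OrientationMap(
        edges=edges,
        probabilities=hist / hist.sum(),
        reference_domain=ref.name,
        probe_domain=probe.name,
        stride_ps=stride_ps,
        points=points,
    )


def _paired_calpha(
    ref: Structure,
    frame: Structure,
    selection: Sequence[DomainDefinition] | None,
) -> tuple[np.ndarray, np.ndarray]:
    def keyed(s: Structure) -> dict[tuple[str, int], np.ndarray]:
        out = {}
        for a in s.atoms:
            if a.name != "CA" or a.hetero:
                continue
            if selection is not None and not any(
                d.contains(a.chain, a.residue_number) for d in selection
            ):
                continue
            out[(a.chain, a.residue_number)] = np.asarray(a.coordinates)
        return out

    ka, kb = keyed(ref), keyed(frame)
    if set(ka) != set(kb):
        missing = set(ka) ^ set(kb)
        raise ValueError(f"selections do not map one-to-one; mismatched residues: {sorted(missing)[:5]}")
    keys = sorted(ka)
    if not keys:
        raise ValueError("empty selection")
    return np.array([ka[k] for k in keys]), np.array([kb[k] for k in keys])


def kabsch_rmsd(
    ref: Structure,
    frame: Structure,
    selection: Sequence[DomainDefinition] | None = None,
) -> float:
    """RMSD (Å) over matched Cα atoms after optimal least-squares
    superposition (Kabsch)."""
    A, B = _paired_calpha(ref, frame, selection)
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    _, rssd = Rotation.align_vectors(Ac, Bc)
    return float(rssd / math.sqrt(len(A)))


def _resolve_selector(structure: Structure, selector) -> np.ndarray:
    """An atom selector ``(chain, resnum, name)`` or a DomainDefinition
    (resolved to the domain's center of mass)."""
    if isinstance(selector, DomainDefinition):
        sel = structure.select(
            chain=selector.chain,
            residues=(selector.first_residue, selector.last_residue),
            hetero=False,
        )
        if len(sel) == 0:
            raise ValueError(f"selector {selector.name}: no atoms")
        m = sel.masses
        return (sel.coordinates * m[:, None]).sum(axis=0) / m.sum()
    chain, resnum, name = selector
    for a in structure.atoms:
        if a.chain == chain and a.residue_number == resnum and a.name == name:
            return np.asarray(a.coordinates)
    raise ValueError(f"selector {selector} resolves to no atom")


def distance_series(
    traj: Trajectory,
    sel_a,
    sel_b,
    window_ns: float | None = None,
    name: str = "distance",
) -> MetricSeries:
    """Per-frame Euclidean distance (Å) between two selectors, each an
    atom ``(chain, resnum, name)`` or a DomainDefinition center of mass;
    optionally smoothed with a centered running average."""
    values = np.empty(len(traj))
    for i, frame in enumerate(traj.frames):
        try:
            pa = _resolve_selector(frame, sel_a)
            pb = _resolve_selector(frame, sel_b)
        except ValueError as exc:
            raise ValueError(f"frame {i}: {exc}") from None
        values[i] = np.linalg.norm(pa - pb)
    if window_ns is not None:
        dt = float(np.median(np.diff(traj.times))) if len(traj) > 1 else 1.0
        n = max(1, int(round(window_ns / dt)))
        values = running_average(values, n)
    return MetricSeries(times=traj.times.copy(), values=values, name=name, window_ns=window_ns)


def locate_ca_sites(
    structure: Structure,
    linker: tuple[int, int],
    chain: str | None = None,
    cutoff: float = 8.0,
) -> CaSiteSet:
    """Collect calcium ions bound at an inter-repeat linker.

    Calcium ions (HETATM, element Ca) within ``cutoff`` Å of any atom of a
    linker residue are kept and labeled 1..3 by their position along the
    first repeat's principal axis, site 1 nearest the repeat's base
    (N-terminal end).  An empty set is a valid result.
    """
    if chain is None:
        chains = structure.chains()
        chain = chains[0] if chains else ""
    linker_atoms = structure.select(chain=chain, residues=linker, hetero=False)
    ions = [a for a in structure.atoms if a.hetero and a.element.upper() == "CA"]
    if not ions or len(linker_atoms) == 0:
        return CaSiteSet(positions=[], linker=linker)
    lcoords = linker_atoms.coordinates
    bound = []
    for ion in ions:
        pos = np.asarray(ion.coordinates)
        if np.min(np.linalg.norm(lcoords - pos, axis=1)) <= cutoff:
            bound.append(pos)
    if not bound:
        return CaSiteSet(positions=[], linker=linker)

    # axial labeling: project onto the first repeat (residues before the
    # linker), oriented base->linker; fall back to the linker's own
    # N->C direction when no upstream repeat exists
    first_repeat = structure.select(chain=chain, residues=(-(10 ** 9), linker[0] - 1), hetero=False)
    ca = [a for a in first_repeat.atoms if a.name == "CA"]
    if len(ca) >= 4:
        dom = DomainDefinition("first_repeat", chain, min(a.residue_number for a in ca), linker[0] - 1)
        try:
            axis = principal_axis(structure, dom)
        except DegenerateAxisError:
            axis = None
    else:
        axis = None
    if axis is None:
        resnums = linker_atoms.residue_numbers()
        first = structure.select(chain=chain, residues=(resnums[0], resnums[0]), hetero=False)
        last = structure.select(chain=chain, residues=(resnums[-1], resnums[-1]), hetero=False)
        axis = last.coordinates.mean(axis=0) - first.coordinates.mean(axis=0)
        norm = np.linalg.norm(axis)
        axis = axis / norm if norm > 0 else np.array([0.0, 0.0, 1.0])
    order = np.argsort([float(p @ axis) for p in bound])
    return CaSiteSet(positions=[bound[i] for i in order], linker=linker)


def radius_of_gyration(structure: Structure) -> float:
    """Mass-weighted radius of gyration in Å:
    R_g = sqrt(Σ m_i |r_i − r_cm|² / Σ m_i)."""
    if len(structure) == 0:
        raise ValueError("structure has no atoms")
    r = structure.coordinates
    m = structure.masses
    cm = (r * m[:, None]).sum(axis=0) / m.sum()
    return float(np.sqrt((m * ((r - cm) ** 2).sum(axis=1)).sum() / m.sum()))


def _to_atom_array(structure: Structure) -> bst.AtomArray:
    n = len(structure)
    arr = bst.AtomArray(n)
    arr.coord = structure.coordinates.astype(np.float32)
    for i, a in enumerate(structure.atoms):
        arr.chain_id[i] = a.chain or "A"
        arr.res_id[i] = a.residue_number
        arr.res_name[i] = a.residue_name
        arr.atom_name[i] = a.name
        arr.element[i] = a.element.capitalize()
        arr.hetero[i] = a.hetero
    return arr


def shrake_rupley_sasa(
    structure: Structure,
    probe_radius: float = 1.4,
    point_number: int = 1000,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²), Shrake-Rupley with a
    1.4 Å probe and element-based van der Waals radii."""
    arr = _to_atom_array(structure)
    sasa = bst.sasa(
        arr,
        probe_radius=probe_radius,
        point_number=point_number,
        vdw_radii="Single",
        ignore_ions=False,
    )
    if np.isnan(sasa).any():
        bad = {structure.atoms[i].element for i in np.flatnonzero(np.isnan(sasa))}
        raise ValueError(f"no van der Waals radius for element(s) {sorted(bad)}")
    return np.asarray(sasa, dtype=float)


def buried_surface(
    structure: Structure,
    dom_a: DomainDefinition,
    dom_b: DomainDefinition,
    probe_radius: float = 1.4,
    point_number: int = 1000,
    halve: bool = True,
    interface_cutoff: float = 1.0,
) -> dict:
    """Buried surface area (Å²) of the interface between two domains.

    BSA = (SASA_A + SASA_B − SASA_AB) / 2 by default (the interface-area
    convention; pass ``halve=False`` for the full summed loss).  Interface
    residues are those losing more than ``interface_cutoff`` Å² of SASA on
    complexation (unhalved, per residue).
    """
    sa = structure.select(chain=dom_a.chain, residues=(dom_a.first_residue, dom_a.last_residue), hetero=False)
    sb = structure.select(chain=dom_b.chain, residues=(dom_b.first_residue, dom_b.last_residue), hetero=False)
    if len(sa) == 0 or len(sb) == 0:
        raise ValueError("empty domain selection")
    complex_ = Structure(atoms=sa.atoms + sb.atoms)
    kw = dict(probe_radius=probe_radius, point_number=point_number)
    sasa_a = shrake_rupley_sasa(sa, **kw)
    sasa_b = shrake_rupley_sasa(sb, **kw)
    sasa_ab = shrake_rupley_sasa(complex_, **kw)
    total_loss = float(sasa_a.sum() + sasa_b.sum() - sasa_ab.sum())
    bsa = total_loss / 2.0 if halve else total_loss
    iso = np.concatenate([sasa_a, sasa_b])
    loss_per_atom = iso - sasa_ab
    per_res: dict[tuple[str, int, str], float] = {}
    for atom, loss in zip(complex_.atoms, loss_per_atom):
        key = (atom.chain, atom.residue_number, atom.residue_name)
        per_res[key] = per_res.get(key, 0.0) + float(loss)
    interface = sorted(k for k, v in per_res.items() if v > interface_cutoff)
    return {"bsa": max(bsa, 0.0), "interface_residues": interface}
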