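"""Ground-truth synthetic crystals for end-to-end testing.

Toy molecules with idealized geometry (1.5 Å bonds, trigonal/tetrahedral
angles) are posed in small cells, and noise-free or noise-added amplitudes
are forward-computed to a chosen resolution.  Every fixture is solvable by
construction and ships with a truth record (true conformer, pose, torsion
angles), so recovery can be asserted exactly.

The generator emulates the *shape* of a merged MicroED amplitude file —
unique reflections with sigmas to a resolution cutoff — not the physics of
electron diffraction: noise is multiplicative Gaussian on |F| (matching the
package's sigma usage), with no dynamical scattering, no radiation damage
and no partial-occupancy solvent.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation

from hamr.chem_model import (
    Atom,
    Bond,
    Conformer,
    Molecule,
    find_torsions,
    measure_torsion,
    set_torsion,
)
from hamr.crystal_model import (
    ReflectionSet,
    SpaceGroup,
    UnitCell,
    calc_structure_factors,
    generate_hkl,
)
from hamr.mr_engine import Pose, clash_check

BOND = 1.5  # idealized heavy-atom bond length, Å


@dataclass
class FixtureSpec:
    """Recipe for one synthetic crystal; same spec -> identical outputs."""

    template: str = "macrolactone12"      # butane|hexagon|macrolactone12|random_chain
    chain_length: int = 8                  # for random_chain
    cell: UnitCell = field(
        default_factory=lambda: UnitCell(8.0, 12.0, 13.0)
    )
    spacegroup: str = "P 21 2 21"
    torsion_angles: Optional[tuple[float, ...]] = None
    pose_rotvec: tuple[float, float, float] = (-0.618, -0.693, 0.19)
    pose_translation: tuple[float, float, float] = (0.981, 0.733, 0.278)
    d_min: float = 1.0
    noise_frac: float = 0.0
    b_true: float = 3.0
    seed: int = 0


@dataclass
class Fixture:
    molecule: Molecule
    conformer: Conformer        # un-posed, local frame
    true_conformer: Conformer   # posed, crystal frame
    true_pose: Pose
    reflections: ReflectionSet
    spec: FixtureSpec
    truth: dict


def _zigzag_chain(n: int) -> np.ndarray:
    """Ideal tetrahedral zig-zag chain in the xz plane."""
    half = np.radians(109.47) / 2.0
    dx = BOND * np.sin(half)
    dz = BOND * np.cos(half)
    pts = np.zeros((n, 3))
    for i in range(1, n):
        pts[i, 0] = pts[i - 1, 0] + dx
        pts[i, 2] = pts[i - 1, 2] + (dz if i % 2 == 1 else -dz)
    return pts


def make_butane() -> tuple[Molecule, Conformer]:
    mol = Molecule(
        atoms=[Atom("C")] * 4,
        bonds=[Bond(0, 1), Bond(1, 2), Bond(2, 3)],
        name="butane",
    )
    return mol, Conformer(mol, _zigzag_chain(4))


def make_hexagon(side: float = BOND) -> tuple[Molecule, Conformer]:
    """Planar six-membered carbon ring (C2-symmetric by construction)."""
    ang = np.arange(6) * np.pi / 3.0
    coords = np.column_stack(
        [side * np.cos(ang), side * np.sin(ang), np.zeros(6)]
    )
    mol = Molecule(
        atoms=[Atom("C")] * 6,
        bonds=[Bond(i, (i + 1) % 6) for i in range(6)],
        name="hexagon",
    )
    return mol, Conformer(mol, coords)


def make_macrolactone12() -> tuple[Molecule, Conformer]:
    """12-membered puckered ring (one ring oxygen) with three exocyclic
    two-bond chains, one rotatable torsion each: the headline flexible
    fixture.  The crown-like pucker keeps the molecule genuinely
    three-dimensional (a flat ring would leave a near-degenerate mirror
    placement for molecular replacement)."""
    ring_n = 12
    # fixed irregular pucker: a regular (self-similar) crown would leave
    # near-degenerate ghost orientations in amplitude space
    zpat = np.array(
        [0.45, -0.25, 0.5, -0.45, 0.1, -0.5, 0.35, -0.15, 0.55, -0.4,
         0.2, -0.3]
    )
    radius = BOND * 0.92 / (2.0 * np.sin(np.pi / ring_n))
    ang = np.arange(ring_n) * 2.0 * np.pi / ring_n
    ring = np.column_stack(
        [radius * np.cos(ang), radius * np.sin(ang), zpat]
    )
    # one ring sulfur: a strong scatterer pinned in the (never-driven)
    # ring breaks the mirror-image/atom-permutation near-degeneracy that
    # C/N/O alone leave in amplitude space
    atoms = [
        Atom({1: "N", 3: "S", 6: "O"}.get(i, "C")) for i in range(ring_n)
    ]
    bonds = [Bond(i, (i + 1) % ring_n) for i in range(ring_n)]
    coords = [ring]
    # chains: (anchor ring atom, first element, second element)
    chains = [(0, "C", "O"), (4, "C", "N"), (8, "C", "C")]
    for anchor, el1, el2 in chains:
        out_dir = ring[anchor].copy()
        out_dir[2] = 0.0
        out_dir /= np.linalg.norm(out_dir)
        # first chain atom: radially out, tilted to the ring atom's side
        tilt = np.array([0.0, 0.0, 0.6 * np.sign(ring[anchor, 2])])
        v1 = out_dir + tilt
        v1 = v1 / np.linalg.norm(v1)
        p1 = ring[anchor] + BOND * v1
        i1 = len(atoms)
        atoms.append(Atom(el1))
        bonds.append(Bond(anchor, i1))
        # second chain atom: tetrahedral continuation
        axis = np.cross(v1, [0.0, 0.0, 1.0])
        axis = axis / np.linalg.norm(axis)
        v2 = Rotation.from_rotvec(axis * np.radians(180 - 109.47)).apply(v1)
        p2 = p1 + BOND * v2
        i2 = len(atoms)
        atoms.append(Atom(el2))
        bonds.append(Bond(i1, i2))
        coords.append(np.array([p1, p2]))
    mol = Molecule(atoms=atoms, bonds=bonds, name="macrolactone12")
    return mol, Conformer(mol, np.vstack(coords))


def make_random_chain(n: int, seed: int = 0) -> tuple[Molecule, Conformer]:
    rng = np.random.default_rng(seed)
    mol = Molecule(
        atoms=[Atom("C")] * n,
        bonds=[Bond(i, i + 1) for i in range(n - 1)],
        name=f"random_chain{n}",
    )
    conf = Conformer(mol, _zigzag_chain(n))
    for t in find_torsions(mol):
        if t.rotatable:
            conf = set_torsion(conf, t, float(rng.uniform(-180, 180)))
    return mol, conf


_TEMPLATES = {
    "butane": make_butane,
    "hexagon": make_hexagon,
    "macrolactone12": make_macrolactone12,
}


def build_fixture(spec: FixtureSpec, outdir: Optional[Path] = None) -> Fixture:
    """Construct molecule, set true torsions, pose in cell, forward-compute
    amplitudes, truncate to d_min, add noise; optionally write HKL + SDF +
    truth JSON."""
    if spec.template == "random_chain":
        mol, conf = make_random_chain(spec.chain_length, spec.seed)
    elif spec.template in _TEMPLATES:
        mol, conf = _TEMPLATES[spec.template]()
    else:
        raise ValueError(f"unknown template {spec.template!r}")
    torsions = [t for t in find_torsions(mol) if t.rotatable]
    angles = spec.torsion_angles
    if angles is not None:
        if len(angles) != len(torsions):
            raise ValueError(
                f"{len(angles)} torsion angles given, "
                f"molecule has {len(torsions)} rotatable torsions"
            )
        for t, a in zip(torsions, angles):
            conf = set_torsion(conf, t, float(a))
    true_angles = tuple(measure_torsion(conf, t) for t in torsions)
    conf.cid = "truth"

    cell = spec.cell
    sg = SpaceGroup(spec.spacegroup)
    pose = Pose(
        Rotation.from_rotvec(spec.pose_rotvec).as_matrix(),
        np.array(spec.pose_translation),
    )
    if not clash_check(conf, pose, cell, sg, min_dist=1.5):
        raise ValueError("fixture packing clash: molecule does not fit cell")
    posed = conf.copy(coords=pose.apply(conf.coords, cell))

    hkl = generate_hkl(cell, sg, spec.d_min)
    f = np.abs(
        calc_structure_factors(
            posed, None, cell, sg, hkl, b_iso=spec.b_true
        )
    )
    rng = np.random.default_rng(spec.seed)
    if spec.noise_frac > 0:
        eps = rng.normal(0.0, spec.noise_frac, size=len(f))
        f_noisy = np.abs(f * (1.0 + eps))
        sigma = spec.noise_frac * np.maximum(f, 1e-6)
    else:
        f_noisy = f
        sigma = np.full(len(f), 1e-4 * max(float(f.mean()), 1.0))
    refls = ReflectionSet(
        hkl=hkl, f=f_noisy, sigma=sigma, cell=cell, spacegroup=sg
    )
    truth = {
        "template": spec.template,
        "cell": cell.as_tuple(),
        "spacegroup": sg.symbol,
        "torsion_bonds": [t.bond for t in torsions],
        "torsion_angles_deg": [float(a) for a in true_angles],
        "pose_rotvec": list(spec.pose_rotvec),
        "pose_translation": list(spec.pose_translation),
        "d_min": spec.d_min,
        "noise_frac": spec.noise_frac,
        "b_true": spec.b_true,
        "seed": spec.seed,
        "n_reflections": int(len(hkl)),
    }
    fx = Fixture(
        molecule=mol, conformer=conf, true_conformer=posed,
        true_pose=pose, reflections=refls, spec=spec, truth=truth,
    )
    if outdir is not None:
        _write_fixture(fx, Path(outdir))
    return fx


def _write_fixture(fx: Fixture, outdir: Path) -> None:
    from hamr.io_formats import write_hkl, write_ensemble

    outdir.mkdir(parents=True, exist_ok=True)
    write_hkl(outdir / "fixture.hkl", fx.reflections)
    write_ensemble(outdir / "truth.sdf", fx.molecule, [fx.conformer])
    write_ensemble(
        outdir / "truth_posed.sdf", fx.molecule, [fx.true_conformer]
    )
    with open(outdir / "truth.json", "w") as fh:
        json.dump(fx.truth, fh, indent=1, sort_keys=True)


def make_decoy_ensemble(
    truth: Conformer,
    n: int,
    torsion_perturb_range,
    seed: int = 0,
) -> list[Conformer]:
    """Perturbed copies of the truth conformer (truth itself excluded).

    ``torsion_perturb_range`` is either a scalar r — offsets drawn
    U(-r, +r) — or a (lo, hi) pair — offset magnitudes U(lo, hi) with
    random sign.  Offsets are recorded in each conformer's lineage.
    """
    rng = np.random.default_rng(seed)
    torsions = [t for t in find_torsions(truth.parent) if t.rotatable]
    out = []
    for i in range(n):
        conf = truth.copy(cid=f"decoy-{i:04d}")
        offsets = []
        for t in torsions:
            if np.isscalar(torsion_perturb_range):
                off = float(rng.uniform(-torsion_perturb_range,
                                        torsion_perturb_range))
            else:
                lo, hi = torsion_perturb_range
                off = float(rng.uniform(lo, hi)) * (1 if rng.random() < 0.5 else -1)
            ang = measure_torsion(conf, t) + off
            conf = set_torsion(conf, t, ang)
            offsets.append(off)
        conf.lineage = Lineage0(offsets)
        out.append(conf)
    return out


def Lineage0(offsets):
    from hamr.chem_model import Lineage

    return Lineage(
        generation=0, parent_id="truth", torsion_id=None,
        angles_deg=tuple(float(o) for o in offsets),
    )


def fixture_checksum(fx: Fixture) -> str:
    """Stable digest of the fixture's numeric content (determinism checks)."""
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(fx.reflections.hkl).tobytes())
    h.update(np.round(fx.reflections.f, 10).tobytes())
    h.update(np.round(fx.true_conformer.coords, 10).tobytes())
    return h.hexdigest()
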