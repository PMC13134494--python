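"""Molecular graph, conformer geometry, torsion driving and RMSD metrics.

A :class:`Molecule` is the chemical identity (elements + bond graph) shared
by all of its :class:`Conformer` geometries.  Torsions are identified on the
graph: every non-ring single bond whose two ends each carry at least two
heavy neighbours defines a drivable dihedral.  Ring bonds — any bond lying
on any simple cycle, which includes the whole macrocycle core — are never
driven; core conformations must come from the input ensemble.

All RMSD metrics default to heavy atoms: in the resolution regime this
method targets, hydrogen positions are not resolved and the published
model-accuracy numbers are heavy-atom quantities.  Hydrogens present in the
input ride along in torsion moving sets but are excluded from metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.transform import Rotation

#: Elements with an electron scattering-factor entry (see crystal_model).
SUPPORTED_ELEMENTS = frozenset(
    {"H", "C", "N", "O", "F", "P", "S", "Cl", "Br", "I"}
)


@dataclass(frozen=True)
class Atom:
    element: str
    charge: int = 0
    is_heavy: bool = True


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: int = 1


class Molecule:
    """Chemical identity: atoms, bonds and a connected molecular graph."""

    def __init__(
        self,
        atoms: Sequence[Atom | tuple],
        bonds: Sequence[Bond | tuple],
        name: str = "",
    ):
        self.atoms = tuple(
            a if isinstance(a, Atom) else Atom(a[0], *a[1:]) for a in atoms
        )
        self.bonds = tuple(
            b if isinstance(b, Bond) else Bond(*b) for b in bonds
        )
        self.name = name
        n = len(self.atoms)
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n) or b.i == b.j:
                raise ValueError(f"bond ({b.i}, {b.j}) out of range for {n} atoms")
        for a in self.atoms:
            if a.element not in SUPPORTED_ELEMENTS:
                raise ValueError(
                    f"element {a.element!r} has no scattering-table entry"
                )
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from((b.i, b.j) for b in self.bonds)
        if n and not nx.is_connected(g):
            comps = [sorted(c) for c in nx.connected_components(g)]
            raise ValueError(f"molecular graph is disconnected: components {comps}")
        self._graph = g

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def heavy_indices(self) -> np.ndarray:
        return np.array(
            [i for i, a in enumerate(self.atoms) if a.is_heavy], dtype=int
        )

    def heavy_neighbors(self, i: int) -> list[int]:
        return sorted(
            j for j in self._graph.neighbors(i) if self.atoms[j].is_heavy
        )

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def __repr__(self) -> str:
        return (
            f"Molecule({self.name!r}, {self.n_atoms} atoms, "
            f"{len(self.bonds)} bonds)"
        )


@dataclass(frozen=True)
class Lineage:
    """Provenance of a conformer inside a GA run."""

    generation: int
    parent_id: Optional[str]
    torsion_id: Optional[tuple[int, int]]
    angles_deg: Optional[tuple[float, ...]]


@dataclass
class Conformer:
    """One 3-D geometry of a molecule (coordinates in Å)."""

    parent: Molecule
    coords: np.ndarray
    lineage: Optional[Lineage] = None
    cid: Optional[str] = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.parent.n_atoms, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{self.parent.n_atoms} atoms"
            )

    def validate(self, dmin: float = 0.6, dmax: float = 2.2) -> None:
        """Sanity-check bonded heavy-atom distances against [dmin, dmax] Å."""
        for b in self.parent.bonds:
            if not (
                self.parent.atoms[b.i].is_heavy
                and self.parent.atoms[b.j].is_heavy
            ):
                continue
            d = float(np.linalg.norm(self.coords[b.i] - self.coords[b.j]))
            if not (dmin <= d <= dmax):
                raise ValueError(
                    f"bond ({b.i}, {b.j}) length {d:.3f} Å outside "
                    f"[{dmin}, {dmax}] Å"
                )

    def copy(self, **changes) -> "Conformer":
        kw = dict(
            parent=self.parent,
            coords=self.coords.copy(),
            lineage=self.lineage,
            cid=self.cid,
        )
        kw.update(changes)
        return Conformer(**kw)

    def heavy_coords(self) -> np.ndarray:
        return self.coords[self.parent.heavy_indices]


@dataclass(frozen=True)
class TorsionDef:
    """A dihedral a–b–c–d about bond b–c, plus the atom set it rotates."""

    a: int
    b: int
    c: int
    d: int
    rotatable: bool
    in_ring: bool
    moving_set: frozenset[int] = frozenset()
    delta_rmsd: Optional[float] = None

    @property
    def bond(self) -> tuple[int, int]:
        return (self.b, self.c)


def _ring_bonds(g: nx.Graph) -> set[frozenset]:
    """Bonds on any simple cycle = non-bridge edges (conservative, not SSSR)."""
    bridges = {frozenset(e) for e in nx.bridges(g)}
    return {frozenset(e) for e in g.edges} - bridges


def find_torsions(mol: Molecule) -> list[TorsionDef]:
    """Identify all torsion definitions of a molecule.

    One entry per bond b–c (b < c) whose two ends each have at least two
    heavy neighbours.  Rotatable iff the bond is a non-ring single bond.
    Reference atoms a, d are the lowest-index heavy neighbour on each side.
    Output ordered by (b, c).
    """
    g = mol.graph
    ring = _ring_bonds(g)
    out: list[TorsionDef] = []
    for bond in sorted(
        (min(b.i, b.j), max(b.i, b.j)) for b in mol.bonds
    ):
        b, c = bond
        nb = [x for x in mol.heavy_neighbors(b) if x != c]
        nc = [x for x in mol.heavy_neighbors(c) if x != b]
        if not nb or not nc:
            continue  # terminal-only rotation: nothing to define a dihedral
        in_ring = frozenset(bond) in ring
        order = next(
            bd.order for bd in mol.bonds if {bd.i, bd.j} == {b, c}
        )
        rotatable = (not in_ring) and order == 1
        if rotatable:
            h = g.copy()
            h.remove_edge(b, c)
            moving = frozenset(nx.node_connected_component(h, c))
        else:
            moving = frozenset()
        out.append(
            TorsionDef(
                a=nb[0], b=b, c=c, d=nc[0],
                rotatable=rotatable, in_ring=in_ring, moving_set=moving,
            )
        )
    return out


def measure_torsion(conf: Conformer, t: TorsionDef) -> float:
    """Signed dihedral a–b–c–d in degrees, in (−180, 180]."""
    p = conf.coords
    b1 = p[t.b] - p[t.a]
    b2 = p[t.c] - p[t.b]
    b3 = p[t.d] - p[t.c]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("collinear atoms: dihedral undefined")
    b2n = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2n))
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def set_torsion(conf: Conformer, t: TorsionDef, angle_deg: float) -> Conformer:
    """Return a new conformer with dihedral a–b–c–d driven to ``angle_deg``.

    Only atoms in the torsion's moving set change; the rotation is rigid
    about the b→c axis, so all bond lengths and all angles not spanning
    b–c are untouched.
    """
    if not t.rotatable:
        raise ValueError(f"torsion about bond {t.bond} is not rotatable")
    current = measure_torsion(conf, t)
    delta = np.radians(angle_deg - current)
    p = conf.coords.copy()
    axis = p[t.c] - p[t.b]
    axis = axis / np.linalg.norm(axis)
    rot = Rotation.from_rotvec(axis * delta)
    idx = np.fromiter(t.moving_set, dtype=int)
    p[idx] = rot.apply(p[idx] - p[t.b]) + p[t.b]
    out = conf.copy(coords=p)
    # convention check: right-hand rotation of the c-side adds to the dihedral
    got = measure_torsion(out, t)
    err = (got - angle_deg + 180.0) % 360.0 - 180.0
    if abs(err) > 1e-6:
        rot = Rotation.from_rotvec(-axis * delta)
        p = conf.coords.copy()
        p[idx] = rot.apply(p[idx] - p[t.b]) + p[t.b]
        out = conf.copy(coords=p)
    return out


def rmsd(
    c1: Conformer,
    c2: Conformer,
    superpose: bool = False,
    heavy_only: bool = True,
) -> float:
    """RMSD between two conformers under the identity atom mapping.

    With ``superpose`` the deviation is minimized over rigid
    rotation+translation (least-squares superposition).
    """
    if c1.parent.n_atoms != c2.parent.n_atoms:
        raise ValueError("atom-count mismatch")
    if heavy_only:
        x, y = c1.heavy_coords(), c2.heavy_coords()
    else:
        x, y = c1.coords, c2.coords
    if x.shape != y.shape:
        raise ValueError("atom-count mismatch")
    return _rmsd_arrays(x, y, superpose)


def _rmsd_arrays(x: np.ndarray, y: np.ndarray, superpose: bool) -> float:
    if superpose:
        xc = x - x.mean(axis=0)
        yc = y - y.mean(axis=0)
        rot, _ = Rotation.align_vectors(xc, yc)
        y = rot.apply(yc)
        x = xc
    return float(np.sqrt(np.mean(np.sum((x - y) ** 2, axis=1))))


def adjusted_rmsd(c1: Conformer, c2: Conformer, tol: float = 1e-8) -> float:
    """Element-agnostic heavy-atom RMSD under the best one-to-one assignment.

    At modest resolution an electron-potential map cannot distinguish
    scatterers of similar power (e.g. C vs N), so a model may come back with
    a pseudo-symmetric group flipped.  This metric scores positional
    agreement only: it alternates optimal superposition (given the current
    atom assignment) with optimal assignment (Hungarian algorithm on the
    squared-distance matrix) until converged.  Started from the identity
    mapping; the alternation is a local optimizer, not a guaranteed global
    one.
    """
    x = c1.heavy_coords()
    y = c2.heavy_coords()
    if x.shape != y.shape:
        raise ValueError("heavy-atom count mismatch")
    n = len(x)
    xc = x - x.mean(axis=0)
    yc0 = y - y.mean(axis=0)

    def alternate(perm):
        prev = np.inf
        best = np.inf
        for _ in range(100):
            val = _rmsd_arrays(x, y[perm], superpose=True)
            best = min(best, val)
            # superpose y[perm] onto x under the current assignment,
            # then reassign on the squared-distance matrix
            yc = y[perm] - y[perm].mean(axis=0)
            rot, _ = Rotation.align_vectors(xc, yc)
            y_fit = rot.apply(y - y[perm].mean(axis=0))
            d2 = ((xc[:, None, :] - y_fit[None, :, :]) ** 2).sum(axis=2)
            _, perm = linear_sum_assignment(d2)
            if abs(prev - val) < tol:
                break
            prev = val
        return min(best, _rmsd_arrays(x, y[perm], superpose=True))

    # multi-start: the alternation is a local optimizer, so seed it from
    # the identity mapping, the centered-coordinate assignment, and a few
    # deterministic random orientations of the second conformer
    starts = [np.arange(n)]
    d2 = ((xc[:, None, :] - yc0[None, :, :]) ** 2).sum(axis=2)
    starts.append(linear_sum_assignment(d2)[1])
    rng = np.random.default_rng(0)
    for _ in range(8):
        rot = Rotation.from_quat(_random_quat(rng))
        d2 = ((xc[:, None, :] - rot.apply(yc0)[None, :, :]) ** 2).sum(axis=2)
        starts.append(linear_sum_assignment(d2)[1])
    return min(alternate(p) for p in starts)


def _random_quat(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    return q / np.linalg.norm(q)


def rank_torsions(
    conf: Conformer,
    torsions: Iterable[TorsionDef],
    step_deg: float = 10.0,
) -> list[TorsionDef]:
    """Order torsions by impact (ΔRMSD), largest first.

    ΔRMSD of a torsion is the mean heavy-atom RMSD (no superposition — the
    scan measures absolute atomic displacement, which is what perturbs the
    structure factors) between the input conformer and the conformer driven
    to each of the 360/step settings.
    """
    if abs(360.0 / step_deg - round(360.0 / step_deg)) > 1e-9:
        raise ValueError("step_deg must divide 360")
    nstep = int(round(360.0 / step_deg))
    out = []
    for t in torsions:
        if not t.rotatable:
            out.append(replace(t, delta_rmsd=0.0))
            continue
        vals = [
            rmsd(set_torsion(conf, t, k * step_deg), conf,
                 superpose=False, heavy_only=True)
            for k in range(nstep)
        ]
        out.append(replace(t, delta_rmsd=float(np.mean(vals))))
    out.sort(key=lambda t: (-t.delta_rmsd, t.bond))
    return out
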