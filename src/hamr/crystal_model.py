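"""Unit cell, space-group symmetry, electron-scattering structure factors,
scaling and amplitude-space statistics.

Structure factors are computed by direct summation over atoms and symmetry
operators — for small molecules (< a few hundred atoms, < 10^4 reflections)
this is fast, exact, and avoids any density-grid sampling decisions.  No
solvent contribution is modelled.

Conventions
-----------
* Electron scattering factors: 5-Gaussian parameterization
  f(s) = sum_i a_i exp(-b_i s^2) with s = sin(theta)/lambda = 1/(2d),
  coefficients from the standard crystallographic tables (via gemmi).
* Isotropic displacement: amplitudes are attenuated by exp(-B s^2) with the
  same s — note conventions differ between codes by factors of 4; this
  package always uses exp(-B (sin(theta)/lambda)^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import gemmi
import numpy as np
from scipy.optimize import least_squares

from hamr.chem_model import Conformer, SUPPORTED_ELEMENTS

TWO_PI = 2.0 * np.pi


# ---------------------------------------------------------------------------
# cell and symmetry


@dataclass(frozen=True)
class UnitCell:
    """Crystal unit cell (lengths in Å, angles in degrees)."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")

    @property
    def gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(
            self.a, self.b, self.c, self.alpha, self.beta, self.gamma
        )

    @property
    def orth(self) -> np.ndarray:
        """Fractional -> Cartesian matrix (columns are cell basis vectors)."""
        return np.array(self.gemmi.orth.mat)

    @property
    def frac(self) -> np.ndarray:
        """Cartesian -> fractional matrix."""
        return np.array(self.gemmi.frac.mat)

    @property
    def volume(self) -> float:
        return float(self.gemmi.volume)

    @property
    def reciprocal_metric(self) -> np.ndarray:
        """G* such that 1/d^2 = h G* h^T for Miller index row-vector h."""
        f = self.frac
        return f @ f.T

    def d_spacing(self, hkl: np.ndarray) -> np.ndarray:
        hkl = np.atleast_2d(np.asarray(hkl, dtype=float))
        inv_d2 = np.einsum("ni,ij,nj->n", hkl, self.reciprocal_metric, hkl)
        with np.errstate(divide="ignore"):
            return 1.0 / np.sqrt(inv_d2)

    def fractionalize(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz) @ self.frac.T

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac) @ self.orth.T

    def as_tuple(self) -> tuple:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)


class SpaceGroup:
    """Crystallographic space group resolved from a Hermann–Mauguin symbol."""

    def __init__(self, symbol: str):
        sg = gemmi.SpaceGroup(symbol)
        self.symbol = sg.xhm()
        self.number = sg.number
        self._gemmi = sg
        self._gops = sg.operations()
        rots, trans = [], []
        for op in self._gops:
            rots.append(np.array(op.rot, dtype=float) / gemmi.Op.DEN)
            trans.append(np.array(op.tran, dtype=float) / gemmi.Op.DEN)
        self.rotations = np.array(rots)  # (n_ops, 3, 3)
        self.translations = np.array(trans)  # (n_ops, 3)

    @property
    def n_ops(self) -> int:
        return len(self.rotations)

    @property
    def gemmi(self) -> gemmi.SpaceGroup:
        return self._gemmi

    def is_absent(self, hkl: Sequence[int]) -> bool:
        return self._gops.is_systematically_absent([int(x) for x in hkl])

    def triplets(self) -> list[str]:
        return [op.triplet() for op in self._gops]

    def polar_axes(self) -> np.ndarray:
        """Boolean mask of cell axes with continuous origin freedom."""
        if not hasattr(self, "_polar"):
            eye = np.eye(3)
            self._polar = np.array([
                all(np.allclose(R @ eye[k], eye[k]) for R in self.rotations)
                for k in range(3)
            ])
        return self._polar

    def allowed_origin_shifts(self) -> np.ndarray:
        """Discrete origin shifts t0 with (R - I) t0 integral for all ops.

        Such shifts leave every |F| unchanged, so model positions are only
        determined modulo this set (plus any continuous polar freedom).
        """
        if hasattr(self, "_origin_shifts"):
            return self._origin_shifts
        fracs = np.array([0, 1 / 4, 1 / 3, 1 / 2, 2 / 3, 3 / 4])
        grid = np.stack(
            np.meshgrid(fracs, fracs, fracs, indexing="ij"), axis=-1
        ).reshape(-1, 3)
        # (R - I) t0 for every op and candidate at once
        rmi = self.rotations - np.eye(3)
        vals = np.einsum("oij,cj->oci", rmi, grid)
        ok = np.all(np.abs(vals - np.round(vals)) < 1e-9, axis=(0, 2))
        self._origin_shifts = grid[ok]
        return self._origin_shifts

    def __repr__(self) -> str:
        return f"SpaceGroup({self.symbol!r})"


# ---------------------------------------------------------------------------
# reflections


@dataclass
class ReflectionSet:
    """Experimental reflection amplitudes with cell/symmetry context.

    ``f`` holds |F_obs| (intensities are converted on read), ``sigma`` the
    amplitude standard deviations, ``d`` resolution in Å (always recomputed
    from the cell, never trusted from a file), ``is_free`` the
    cross-validation flags.
    """

    hkl: np.ndarray
    f: np.ndarray
    sigma: np.ndarray
    cell: UnitCell
    spacegroup: Optional[SpaceGroup] = None
    is_free: np.ndarray = None
    d: np.ndarray = field(init=False)

    def __post_init__(self):
        self.hkl = np.asarray(self.hkl, dtype=int).reshape(-1, 3)
        self.f = np.asarray(self.f, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        n = len(self.hkl)
        if self.is_free is None:
            self.is_free = np.zeros(n, dtype=bool)
        self.is_free = np.asarray(self.is_free, dtype=bool)
        if not (len(self.f) == len(self.sigma) == len(self.is_free) == n):
            raise ValueError("reflection arrays have inconsistent lengths")
        uniq = {tuple(h) for h in self.hkl}
        if len(uniq) != n:
            raise ValueError("duplicate hkl in ReflectionSet")
        if n and not (self.sigma > 0).all():
            raise ValueError("sigma must be positive for every reflection")
        self.d = self.cell.d_spacing(self.hkl)

    @property
    def n(self) -> int:
        return len(self.hkl)

    def subset_mask(self, subset: str) -> np.ndarray:
        if subset == "work":
            return ~self.is_free
        if subset == "free":
            return self.is_free
        if subset == "all":
            return np.ones(self.n, dtype=bool)
        raise ValueError(f"unknown subset {subset!r}")

    def select(self, mask: np.ndarray) -> "ReflectionSet":
        return ReflectionSet(
            hkl=self.hkl[mask], f=self.f[mask], sigma=self.sigma[mask],
            cell=self.cell, spacegroup=self.spacegroup,
            is_free=self.is_free[mask],
        )

    def copy(self) -> "ReflectionSet":
        return self.select(np.ones(self.n, dtype=bool))


def merge_friedel(
    hkl: np.ndarray, f: np.ndarray, sigma: np.ndarray, cell: UnitCell,
    spacegroup: Optional[SpaceGroup] = None,
    free: Optional[np.ndarray] = None,
) -> ReflectionSet:
    """Merge Friedel (and, when a space group is given, symmetry) equivalents.

    Each observation is mapped to the lexicographically largest member of
    its orbit under {±R^T}; duplicates are merged by inverse-variance
    weighting.  Systematic absences are removed with a warning count.
    """
    hkl = np.asarray(hkl, dtype=int).reshape(-1, 3)
    f = np.asarray(f, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if spacegroup is not None:
        rots = [np.round(R).astype(int) for R in spacegroup.rotations]
    else:
        rots = [np.eye(3, dtype=int)]

    def canonical(h):
        orbit = []
        for R in rots:
            he = h @ R
            orbit.append(tuple(int(x) for x in he))
            orbit.append(tuple(int(-x) for x in he))
        return max(orbit)

    groups: dict[tuple, list[int]] = {}
    for i, h in enumerate(hkl):
        groups.setdefault(canonical(h), []).append(i)

    n_absent = 0
    out_h, out_f, out_s, out_free = [], [], [], []
    for h, idx in sorted(groups.items()):
        if spacegroup is not None and spacegroup.is_absent(h):
            n_absent += len(idx)
            continue
        w = 1.0 / np.maximum(sigma[idx], 1e-12) ** 2
        out_h.append(h)
        out_f.append(float(np.sum(w * f[idx]) / np.sum(w)))
        out_s.append(float(np.sqrt(1.0 / np.sum(w))))
        out_free.append(bool(free[idx].any()) if free is not None else False)
    if n_absent:
        warnings.warn(f"removed {n_absent} systematically absent observations")
    return ReflectionSet(
        hkl=np.array(out_h, dtype=int), f=np.array(out_f),
        sigma=np.array(out_s), cell=cell, spacegroup=spacegroup,
        is_free=np.array(out_free, dtype=bool),
    )


def flag_free_set(
    refls: ReflectionSet, fraction: float = 0.05, seed: int = 0
) -> ReflectionSet:
    """Flag round(fraction * N) reflections as the free (held-out) set."""
    if not 0.0 < fraction < 0.5:
        raise ValueError("free fraction must be in (0, 0.5)")
    n_free = int(round(fraction * refls.n))
    rng = np.random.default_rng(seed)
    idx = rng.choice(refls.n, size=n_free, replace=False)
    out = refls.copy()
    out.is_free = np.zeros(refls.n, dtype=bool)
    out.is_free[idx] = True
    return out


def apply_resolution_cutoff(refls: ReflectionSet, d_min: float) -> ReflectionSet:
    """Keep reflections with d >= d_min (d recomputed from the cell)."""
    if d_min < 0:
        raise ValueError("d_min must be non-negative")
    mask = refls.d >= d_min - 1e-9
    if not mask.any():
        raise ValueError(f"no reflections remain at d_min = {d_min} Å")
    return refls.select(mask)


# ---------------------------------------------------------------------------
# scattering


class ScatteringTable:
    """Electron scattering factors f(s), 5-Gaussian parameterization.

    Coefficients follow the standard crystallographic tables
    (International Tables C, 4.3.2.2 parameterization), resolved per
    element through gemmi.
    """

    def __init__(self, elements: Sequence[str] = tuple(sorted(SUPPORTED_ELEMENTS))):
        self.coeffs: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for el in elements:
            c = gemmi.Element(el).c4322
            a = np.array(c.a, dtype=float)
            b = np.array(c.b, dtype=float)
            if not len(a) or not np.isfinite(a).all():
                raise ValueError(f"no electron scattering entry for {el!r}")
            self.coeffs[el] = (a, b)

    def __contains__(self, el: str) -> bool:
        return el in self.coeffs

    def f(self, element: str, s: np.ndarray) -> np.ndarray:
        """f(s) with s = sin(theta)/lambda in Å^-1."""
        if element not in self.coeffs:
            raise KeyError(f"element {element!r} not in scattering table")
        a, b = self.coeffs[element]
        s2 = np.atleast_1d(np.asarray(s, dtype=float)) ** 2
        return np.exp(-np.outer(s2, b)) @ a


@dataclass
class ScalingModel:
    """Overall scale k and isotropic B (Å²) mapping |F_calc| onto |F_obs|."""

    k: float = 1.0
    b_iso: float = 0.0

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("scale k must be positive")

    def apply(self, fcalc: np.ndarray, d: np.ndarray) -> np.ndarray:
        s2 = 1.0 / (4.0 * np.asarray(d) ** 2)
        return self.k * np.exp(-self.b_iso * s2) * np.asarray(fcalc)


# ---------------------------------------------------------------------------
# structure factors


def calc_structure_factors(
    conf: Conformer,
    pose,
    cell: UnitCell,
    sg: SpaceGroup,
    hkl: np.ndarray,
    table: Optional[ScatteringTable] = None,
    b_iso: float = 0.0,
) -> np.ndarray:
    """Complex structure factors by direct summation.

    F(h) = sum_sym sum_atoms f_el(s) exp(-B s^2) exp(2 pi i h.(R x + t))
    with s = 1/(2d).  ``pose`` (may be None) maps the conformer into the
    crystal frame before fractionalization; no solvent term.
    """
    if table is None:
        table = _default_table()
    xyz = conf.coords
    if pose is not None:
        xyz = pose.apply(xyz, cell)
    elements = conf.parent.elements
    for el in set(elements):
        if el not in table:
            raise KeyError(f"element {el!r} missing from scattering table")
    xfrac = cell.fractionalize(xyz)
    return structure_factors_frac(
        xfrac, elements, cell, sg, hkl, table, b_iso
    )


def structure_factors_frac(
    xfrac: np.ndarray,
    elements: Sequence[str],
    cell: UnitCell,
    sg: SpaceGroup,
    hkl: np.ndarray,
    table: ScatteringTable,
    b_iso: float = 0.0,
) -> np.ndarray:
    """Direct summation given fractional coordinates (see calc_structure_factors)."""
    hkl = np.asarray(hkl, dtype=float).reshape(-1, 3)
    d = cell.d_spacing(hkl)
    s = 1.0 / (2.0 * d)
    s2 = s * s
    # per-atom form factors at each reflection, with isotropic-B attenuation
    uniq = sorted(set(elements))
    fel = {el: table.f(el, s) for el in uniq}
    w = np.empty((len(hkl), len(elements)))
    for j, el in enumerate(elements):
        w[:, j] = fel[el]
    w *= np.exp(-b_iso * s2)[:, None]
    ftot = np.zeros(len(hkl), dtype=complex)
    for R, t in zip(sg.rotations, sg.translations):
        hs = hkl @ R  # row-vector transform: (h^T R) . x == h . (R x)
        args = TWO_PI * (hs @ xfrac.T + (hkl @ t)[:, None])
        ftot += (w * np.exp(1j * args)).sum(axis=1)
    return ftot


_TABLE_CACHE: Optional[ScatteringTable] = None


def _default_table() -> ScatteringTable:
    global _TABLE_CACHE
    if _TABLE_CACHE is None:
        _TABLE_CACHE = ScatteringTable()
    return _TABLE_CACHE


# ---------------------------------------------------------------------------
# scaling and statistics


def fit_scale(refls: ReflectionSet, fcalc: np.ndarray) -> ScalingModel:
    """Fit (k, B) minimizing sum (|Fobs| - k exp(-B s^2) |Fcalc|)^2.

    Working-set reflections only.  A log-linear Wilson-style fit provides
    the start, followed by a nonlinear polish; deterministic.
    """
    mask = ~refls.is_free
    fo = refls.f[mask]
    fc = np.abs(np.asarray(fcalc))[mask]
    d = refls.d[mask]
    if len(fo) < 10:
        raise ValueError("need at least 10 working reflections to fit scale")
    s2 = 1.0 / (4.0 * d * d)
    good = (fo > 0) & (fc > 0)
    if np.ptp(s2) < 1e-12:
        warnings.warn("degenerate resolution range: fitting scale only, B=0")
        k = float(np.sum(fo * fc) / np.sum(fc * fc))
        return ScalingModel(k=max(k, 1e-12), b_iso=0.0)
    y = np.log(fo[good] / fc[good])
    A = np.column_stack([np.ones(good.sum()), -s2[good]])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    k0, b0 = float(np.exp(coef[0])), float(coef[1])

    def resid(p):
        return fo - p[0] * np.exp(-p[1] * s2) * fc

    sol = least_squares(resid, x0=[k0, b0], method="lm", max_nfev=200)
    k, b = float(sol.x[0]), float(sol.x[1])
    if k <= 0:
        k, b = k0, b0
    return ScalingModel(k=k, b_iso=float(np.clip(b, -20.0, 200.0)))


def r_factor(
    refls: ReflectionSet,
    fcalc: np.ndarray,
    scaling: ScalingModel,
    subset: str = "work",
) -> float:
    """R = sum | |Fobs| - k exp(-B s^2) |Fcalc| | / sum |Fobs| over a subset."""
    mask = refls.subset_mask(subset)
    if not mask.any():
        raise ValueError(f"empty subset {subset!r}")
    fo = refls.f[mask]
    fc = scaling.apply(np.abs(np.asarray(fcalc))[mask], refls.d[mask])
    return float(np.sum(np.abs(fo - fc)) / np.sum(fo))


def amplitude_correlation(
    refls: ReflectionSet,
    fcalc: np.ndarray,
    scaling: Optional[ScalingModel] = None,
) -> float:
    """Pearson correlation of |Fobs| with (scaled) |Fcalc|, working set."""
    mask = ~refls.is_free
    fo = refls.f[mask]
    fc = np.abs(np.asarray(fcalc))[mask]
    if scaling is not None:
        fc = scaling.apply(fc, refls.d[mask])
    if fo.std() < 1e-12 or fc.std() < 1e-12:
        raise ValueError("zero variance: correlation undefined")
    return float(np.corrcoef(fo, fc)[0, 1])


def generate_hkl(
    cell: UnitCell, sg: SpaceGroup, d_min: float
) -> np.ndarray:
    """Unique (symmetry- and Friedel-merged, absence-free) hkl to d_min.

    Canonical representative of each orbit is its lexicographically largest
    member, matching merge_friedel.
    """
    hmax = int(np.floor(cell.a / d_min)) + 1
    kmax = int(np.floor(cell.b / d_min)) + 1
    lmax = int(np.floor(cell.c / d_min)) + 1
    h, k, l = np.meshgrid(
        np.arange(-hmax, hmax + 1),
        np.arange(-kmax, kmax + 1),
        np.arange(-lmax, lmax + 1),
        indexing="ij",
    )
    hkl = np.column_stack([h.ravel(), k.ravel(), l.ravel()])
    hkl = hkl[np.any(hkl != 0, axis=1)]
    d = cell.d_spacing(hkl)
    hkl = hkl[d >= d_min - 1e-9]
    rots = [np.round(R).astype(int) for R in sg.rotations]
    seen = set()
    out = []
    for hh in hkl:
        orbit = []
        for R in rots:
            he = hh @ R
            orbit.append(tuple(int(x) for x in he))
            orbit.append(tuple(int(-x) for x in he))
        canon = max(orbit)
        if canon in seen:
            continue
        seen.add(canon)
        if not sg.is_absent(canon):
            out.append(canon)
    return np.array(sorted(out), dtype=int)
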