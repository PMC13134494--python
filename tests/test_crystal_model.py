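"""Cell/symmetry machinery, structure factors, scaling and statistics."""

import numpy as np
import pytest

from hamr.chem_model import Atom, Conformer, Molecule
from hamr.crystal_model import (
    ReflectionSet,
    ScalingModel,
    ScatteringTable,
    SpaceGroup,
    UnitCell,
    amplitude_correlation,
    apply_resolution_cutoff,
    calc_structure_factors,
    fit_scale,
    flag_free_set,
    generate_hkl,
    merge_friedel,
    r_factor,
    structure_factors_frac,
    _default_table,
)

CELL = UnitCell(8, 11, 13)
SG = SpaceGroup("P 21 2 21")


def make_refls(f, cell=CELL, sg=None, hkl=None, sigma=None):
    f = np.asarray(f, dtype=float)
    n = len(f)
    if hkl is None:
        hkl = generate_hkl(cell, SG, 1.0)[:n]
    if sigma is None:
        sigma = np.full(n, 0.1)
    return ReflectionSet(hkl=hkl, f=f, sigma=sigma, cell=cell, spacegroup=sg)


class TestUnitCell:
    def test_round_trip_identity(self):
        cell = UnitCell(7.3, 11.9, 13.4, 90, 103.5, 90)
        rng = np.random.default_rng(0)
        x = rng.uniform(-10, 10, (20, 3))
        np.testing.assert_allclose(
            cell.orthogonalize(cell.fractionalize(x)), x, atol=1e-12
        )

    def test_axial_d_spacing(self):
        cell = UnitCell(10, 10, 10)
        assert cell.d_spacing([[5, 0, 0]])[0] == pytest.approx(2.0)

    def test_invalid_cell_rejected(self):
        with pytest.raises(ValueError):
            UnitCell(-1, 5, 5)
        with pytest.raises(ValueError):
            UnitCell(5, 5, 5, 0.0, 90, 90)


class TestSpaceGroup:
    def test_ops_closed_under_composition(self):
        rots = SG.rotations
        trans = SG.translations
        triplets = {
            (tuple(np.round(R).astype(int).ravel()), tuple(np.round(t * 12)))
            for R, t in zip(rots, trans)
        }
        for i in range(len(rots)):
            for j in range(len(rots)):
                R = rots[i] @ rots[j]
                t = (rots[i] @ trans[j] + trans[i]) % 1.0
                key = (tuple(np.round(R).astype(int).ravel()),
                       tuple(np.round(t * 12)))
                assert key in triplets

    def test_screw_axis_absences(self):
        # 2_1 along a: h00 with odd h are systematically absent
        assert SG.is_absent([1, 0, 0])
        assert not SG.is_absent([2, 0, 0])
        assert SG.is_absent([0, 0, 3])
        assert not SG.is_absent([0, 1, 0])  # b axis is a pure 2-fold

    def test_no_polar_axes_in_222(self):
        assert not SG.polar_axes().any()

    def test_p1_fully_polar(self):
        assert SpaceGroup("P 1").polar_axes().all()

    def test_allowed_origin_shifts_are_half_cells(self):
        shifts = {tuple(s) for s in SG.allowed_origin_shifts()}
        expected = {
            (a, b, c) for a in (0, 0.5) for b in (0, 0.5) for c in (0, 0.5)
        }
        assert shifts == expected


class TestScatteringTable:
    def test_forward_peaked_and_positive(self):
        table = _default_table()
        s = np.linspace(0, 1.5, 200)
        for el in ("C", "N", "O"):
            f = table.f(el, s)
            assert f[0] > 0
            assert np.all(np.diff(f) < 0)

    def test_unknown_element(self):
        with pytest.raises(KeyError):
            _default_table().f("Zz", np.array([0.1]))


class TestStructureFactors:
    def test_single_atom_at_origin_gives_form_factor(self):
        mol = Molecule([Atom("C")], [])
        conf = Conformer(mol, [[0.0, 0.0, 0.0]])
        p1 = SpaceGroup("P 1")
        hkl = generate_hkl(CELL, SG, 1.2)
        f = calc_structure_factors(conf, None, CELL, p1, hkl, b_iso=0.0)
        s = 1.0 / (2.0 * CELL.d_spacing(hkl))
        np.testing.assert_allclose(np.abs(f), _default_table().f("C", s),
                                   atol=1e-12)
        np.testing.assert_allclose(np.angle(f), 0.0, atol=1e-12)

    def test_friedel_symmetry(self):
        rng = np.random.default_rng(1)
        xfrac = rng.random((15, 3))
        els = ["C"] * 10 + ["N", "O", "O", "S", "Cl"]
        hkl = generate_hkl(CELL, SG, 1.2)
        fp = structure_factors_frac(xfrac, els, CELL, SG, hkl,
                                    _default_table(), 2.0)
        fm = structure_factors_frac(xfrac, els, CELL, SG, -hkl,
                                    _default_table(), 2.0)
        np.testing.assert_allclose(np.abs(fp), np.abs(fm), atol=1e-10)

    def test_space_group_sum_equals_p1_expansion(self):
        """Direct summation in the space group vs brute-force expansion of
        all symmetry copies to a P1 list (20-atom fixture)."""
        rng = np.random.default_rng(2)
        n = 20
        els = list(rng.choice(["C", "N", "O"], n))
        xfrac = rng.random((n, 3))
        hkl = generate_hkl(CELL, SG, 1.0)
        f_sg = structure_factors_frac(xfrac, els, CELL, SG, hkl,
                                      _default_table(), 3.0)
        xs, es = [], []
        for R, t in zip(SG.rotations, SG.translations):
            xs.append(xfrac @ R.T + t)
            es.extend(els)
        f_p1 = structure_factors_frac(
            np.vstack(xs), es, CELL, SpaceGroup("P 1"), hkl,
            _default_table(), 3.0,
        )
        rel = np.abs(np.abs(f_sg) - np.abs(f_p1)) / np.abs(f_p1)
        assert rel.max() < 1e-8

    def test_missing_element_raises(self):
        mol = Molecule([Atom("C")], [])
        conf = Conformer(mol, [[0.0, 0.0, 0.0]])
        table = ScatteringTable(elements=("N", "O"))
        with pytest.raises(KeyError, match="C"):
            calc_structure_factors(conf, None, CELL, SG,
                                   [[1, 2, 3]], table, 0.0)


class TestScaling:
    def _model_data(self, b_true=0.0, k_true=1.0, n=400, seed=3):
        rng = np.random.default_rng(seed)
        hkl = generate_hkl(CELL, SG, 1.0)[:n]
        d = CELL.d_spacing(hkl)
        fc = rng.uniform(5, 50, n)
        s2 = 1.0 / (4 * d * d)
        fo = k_true * np.exp(-b_true * s2) * fc
        refls = ReflectionSet(hkl=hkl, f=fo, sigma=np.full(n, 0.1),
                              cell=CELL, spacegroup=SG)
        return refls, fc

    def test_pure_scale_recovered(self):
        refls, fc = self._model_data(k_true=2.5)
        sc = fit_scale(refls, fc)
        assert sc.k == pytest.approx(2.5, abs=1e-6)
        assert sc.b_iso == pytest.approx(0.0, abs=1e-6)

    def test_b_factor_recovered(self):
        refls, fc = self._model_data(b_true=5.0)
        sc = fit_scale(refls, fc)
        assert sc.b_iso == pytest.approx(5.0, abs=1e-3)

    def test_r_factor_scale_invariant(self):
        refls, fc = self._model_data(b_true=2.0)
        noisy = fc * (1 + 0.05 * np.sin(np.arange(len(fc))))
        r1 = r_factor(refls, noisy, fit_scale(refls, noisy))
        scaled = refls.copy()
        scaled.f = refls.f * 7.3
        r2 = r_factor(scaled, noisy, fit_scale(scaled, noisy))
        assert r1 == pytest.approx(r2, abs=1e-9)

    def test_degenerate_resolution_warns_and_fits_k(self):
        hkl = np.array([[h, 0, 0] for h in (2, -2)])
        # single |h| value: no resolution spread at all
        refls = ReflectionSet(
            hkl=np.array([[2, 0, 0], [0, 2, 0]]),
            f=np.array([10.0, 20.0]), sigma=np.array([1.0, 1.0]),
            cell=UnitCell(10, 10, 10),
        )
        with pytest.raises(ValueError, match="at least 10"):
            fit_scale(refls, np.array([5.0, 10.0]))


class TestRFactor:
    def test_perfect_model_zero(self):
        refls = make_refls([10, 20, 30, 40] * 5)
        fc = refls.f.copy()
        assert r_factor(refls, fc, ScalingModel(1.0, 0.0)) == 0.0

    def test_three_reflection_hand_value(self):
        refls = make_refls([10.0, 20.0, 30.0])
        fc = np.array([12.0, 18.0, 33.0])
        r = r_factor(refls, fc, ScalingModel(1.0, 0.0), subset="all")
        assert r == pytest.approx((2 + 2 + 3) / 60.0, rel=1e-6)

    def test_random_model_approaches_wilson_limit(self):
        """Uncorrelated acentric amplitudes give <|F1|-|F2|>/<F> -> 0.586
        in the Wilson limit; checked by Monte Carlo over 20 random models."""
        rng = np.random.default_rng(4)
        hkl = generate_hkl(CELL, SG, 1.0)
        n = len(hkl)
        assert n >= 500
        table = _default_table()
        vals = []
        fo = None
        for rep in range(21):
            xfrac = rng.random((12, 3))
            amp = np.abs(structure_factors_frac(
                xfrac, ["C"] * 12, CELL, SpaceGroup("P 1"), hkl, table, 0.0
            ))
            if fo is None:
                fo = amp
                refls = ReflectionSet(hkl=hkl, f=fo, sigma=np.full(n, 0.1),
                                      cell=CELL)
                continue
            vals.append(
                r_factor(refls, amp, fit_scale(refls, amp), subset="all")
            )
        assert np.mean(vals) == pytest.approx(0.586, abs=0.1)


class TestAmplitudeCorrelation:
    def test_identical_unity(self):
        refls = make_refls(np.linspace(5, 50, 40))
        assert amplitude_correlation(refls, refls.f) == pytest.approx(1.0)

    def test_affine_invariance(self):
        refls = make_refls(np.linspace(5, 50, 40))
        assert amplitude_correlation(
            refls, 3.0 * refls.f + 7.0
        ) == pytest.approx(1.0)

    def test_permutation_null(self):
        rng = np.random.default_rng(5)
        f = rng.uniform(5, 80, 600)
        refls = make_refls(f)
        cc = amplitude_correlation(refls, rng.permutation(f))
        assert abs(cc) < 3.0 / np.sqrt(600)

    def test_zero_variance_errors(self):
        refls = make_refls(np.linspace(5, 50, 40))
        with pytest.raises(ValueError, match="variance"):
            amplitude_correlation(refls, np.full(40, 7.0))


class TestFreeSet:
    def test_exact_count_and_determinism(self):
        refls = make_refls(np.linspace(1, 100, 1000),
                           hkl=generate_hkl(UnitCell(12, 16, 18), SG, 0.9)[:1000])
        flagged = flag_free_set(refls, fraction=0.05, seed=42)
        assert flagged.is_free.sum() == 50
        again = flag_free_set(refls, fraction=0.05, seed=42)
        np.testing.assert_array_equal(flagged.is_free, again.is_free)
        other = flag_free_set(refls, fraction=0.05, seed=43)
        assert (flagged.is_free != other.is_free).any()

    def test_ten_percent_variant(self):
        refls = make_refls(np.linspace(1, 100, 1000),
                           hkl=generate_hkl(UnitCell(12, 16, 18), SG, 0.9)[:1000])
        assert flag_free_set(refls, fraction=0.10, seed=0).is_free.sum() == 100

    def test_fraction_bounds(self):
        refls = make_refls(np.linspace(5, 50, 40))
        with pytest.raises(ValueError):
            flag_free_set(refls, fraction=0.6, seed=0)


class TestResolutionCutoff:
    def test_axial_reflection_kept_then_dropped(self):
        cell = UnitCell(10, 10, 10)
        refls = ReflectionSet(
            hkl=np.array([[5, 0, 0], [4, 0, 0]]),
            f=np.array([1.0, 2.0]), sigma=np.array([0.1, 0.1]), cell=cell,
        )
        kept = apply_resolution_cutoff(refls, 2.0)
        assert len(kept.hkl) == 2
        kept = apply_resolution_cutoff(refls, 2.1)
        assert [tuple(h) for h in kept.hkl] == [(4, 0, 0)]

    def test_monotone_in_cutoff(self, crystal_fixture):
        refls = crystal_fixture.reflections
        sizes = [
            apply_resolution_cutoff(refls, d).n for d in (1.0, 1.5, 2.0, 2.5)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_zero_is_identity(self, crystal_fixture):
        refls = crystal_fixture.reflections
        assert apply_resolution_cutoff(refls, 0.0).n == refls.n

    def test_empty_result_errors(self, crystal_fixture):
        with pytest.raises(ValueError):
            apply_resolution_cutoff(crystal_fixture.reflections, 99.0)


class TestMerging:
    def test_friedel_pairs_merged(self):
        cell = UnitCell(10, 12, 14)
        hkl = np.array([[1, 2, 3], [-1, -2, -3], [2, 0, 1]])
        merged = merge_friedel(hkl, np.array([10.0, 12.0, 5.0]),
                               np.array([1.0, 1.0, 0.5]), cell)
        assert merged.n == 2
        i = [tuple(h) for h in merged.hkl].index((1, 2, 3))
        assert merged.f[i] == pytest.approx(11.0)

    def test_absences_removed_with_warning(self):
        cell = UnitCell(10, 12, 14)
        hkl = np.array([[1, 0, 0], [0, 2, 0]])  # (1,0,0) absent in P2_1 2 2_1
        with pytest.warns(UserWarning, match="absent"):
            merged = merge_friedel(hkl, np.array([3.0, 5.0]),
                                   np.array([0.3, 0.5]), cell, SG)
        assert [tuple(h) for h in merged.hkl] == [(0, 2, 0)]

    def test_symmetry_equivalents_merged(self):
        cell = UnitCell(10, 12, 14)
        # (h,k,l) and (h,-k,-l) are equivalent under the 2-fold along a
        hkl = np.array([[2, 3, 4], [2, -3, -4]])
        merged = merge_friedel(hkl, np.array([8.0, 10.0]),
                               np.array([1.0, 1.0]), cell, SG)
        assert merged.n == 1
        assert merged.f[0] == pytest.approx(9.0)
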