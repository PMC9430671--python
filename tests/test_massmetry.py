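"""GF calibration, sequence masses, charge-state inversion and stoichiometry."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualysin import massmetry as mm

# independent monoisotopic residue table (standard values) for the oracle
RESIDUE_MONO = {
    "G": 57.02146372, "A": 71.03711379, "S": 87.03202841, "P": 97.05276385,
    "V": 99.06841392, "T": 101.04767847, "C": 103.00918448, "L": 113.08406398,
    "I": 113.08406398, "N": 114.04292744, "D": 115.02694302, "Q": 128.05857751,
    "K": 128.09496302, "E": 129.04259309, "M": 131.04048509, "H": 137.05891186,
    "F": 147.06841391, "R": 156.10111102, "Y": 163.06332853, "W": 186.07931295,
}
WATER_MONO = 18.01056468


def exact_line_standards():
    """Standards generated on an exact line log10(M) = -2*Kav + 3, v0=8, vt=24."""
    v0, vt = 8.0, 24.0
    standards = []
    for i, k in enumerate((0.1, 0.3, 0.5, 0.7, 0.9)):
        mass = 10 ** (-2 * k + 3)
        rs = 10.0 - 8.0 * k  # any monotone Rs works for the fixture
        standards.append(mm.GFStandard(f"s{i}", mass, rs, v0 + k * (vt - v0)))
    return standards, v0, vt


class TestKav:
    def test_limits_and_midpoint(self):
        assert mm.kav(8.0, 8.0, 24.0) == 0.0
        assert mm.kav(24.0, 8.0, 24.0) == 1.0
        assert mm.kav(16.0, 8.0, 24.0) == 0.5

    def test_out_of_range_elution_raises(self):
        with pytest.raises(ValueError, match="fractionation"):
            mm.kav(30.0, 8.0, 24.0)
        with pytest.raises(ValueError):
            mm.kav(16.0, 24.0, 8.0)


class TestCalibrate:
    def test_exact_line_recovery(self):
        standards, v0, vt = exact_line_standards()
        curve = mm.calibrate(standards, v0, vt)
        assert curve.mass_fit[0] == pytest.approx(-2.0, abs=1e-9)
        assert curve.mass_fit[1] == pytest.approx(3.0, abs=1e-9)
        assert curve.r2_mass == pytest.approx(1.0, abs=1e-12)

    def test_duplicate_standards_do_not_change_the_fit(self):
        standards, v0, vt = exact_line_standards()
        curve_a = mm.calibrate(standards, v0, vt)
        curve_b = mm.calibrate(standards + standards[:2], v0, vt)
        assert curve_a.mass_fit == pytest.approx(curve_b.mass_fit, abs=1e-9)

    def test_standard_outside_range_excluded_with_warning(self, caplog):
        standards, v0, vt = exact_line_standards()
        standards.append(mm.GFStandard("late", 1.0, 0.5, vt + 2.0))
        with caplog.at_level("WARNING"):
            curve = mm.calibrate(standards, v0, vt)
        assert "excluded" in caplog.text
        assert curve.mass_fit[0] == pytest.approx(-2.0, abs=1e-9)

    def test_too_few_standards_raise(self):
        standards, v0, vt = exact_line_standards()
        with pytest.raises(ValueError, match=">= 3"):
            mm.calibrate(standards[:2], v0, vt)


class TestEstimate:
    def test_closed_form_mass_at_kav_half(self):
        standards, v0, vt = exact_line_standards()
        curve = mm.calibrate(standards, v0, vt)
        ve = v0 + 0.5 * (vt - v0)
        assert mm.estimate_mass(ve, curve) == pytest.approx(100.0, rel=1e-9)

    def test_round_trip_identity(self):
        standards, v0, vt = exact_line_standards()
        curve = mm.calibrate(standards, v0, vt)
        for ve in (10.0, 14.2, 19.7, 23.0):
            mass = mm.estimate_mass(ve, curve)
            slope, intercept = curve.mass_fit
            ve_back = v0 + (vt - v0) * (math.log10(mass) - intercept) / slope
            assert ve_back == pytest.approx(ve, abs=1e-9)

    def test_monotone_negative_slope(self):
        standards, v0, vt = exact_line_standards()
        curve = mm.calibrate(standards, v0, vt)
        masses = [mm.estimate_mass(ve, curve) for ve in (10.0, 14.0, 18.0, 22.0)]
        assert masses == sorted(masses, reverse=True)

    def test_rs_route_recovers_an_rs_consistent_fixture(self):
        # standards exactly on sqrt(-ln Kav) = (Rs - 2) / 3 and
        # log10(mass) = 0.4 * Rs + 0.3: both Rs-route fits are then exact
        v0, vt = 8.0, 24.0
        standards = []
        for i, k in enumerate((0.1, 0.3, 0.5, 0.7, 0.9)):
            rs = 2.0 + 3.0 * math.sqrt(-math.log(k))
            standards.append(
                mm.GFStandard(f"s{i}", 10 ** (0.4 * rs + 0.3), rs, v0 + k * (vt - v0))
            )
        curve = mm.calibrate(standards, v0, vt)
        ve = v0 + 0.5 * (vt - v0)
        rs_expected = 2.0 + 3.0 * math.sqrt(-math.log(0.5))
        assert mm.estimate_rs(ve, curve) == pytest.approx(rs_expected, rel=1e-9)
        assert mm.estimate_mass_via_rs(ve, curve) == pytest.approx(
            10 ** (0.4 * rs_expected + 0.3), rel=1e-6
        )
        est = mm.estimate_all(ve, curve)
        assert set(est) == {"mass_kda", "rs_nm", "mass_via_rs_kda"}


class TestSequenceMass:
    def test_glycine_monoisotopic(self):
        assert mm.sequence_mass("G") == pytest.approx(75.03203, abs=1e-4)

    def test_diglycine_monoisotopic(self):
        assert mm.sequence_mass("GG") == pytest.approx(132.05349, abs=1e-4)

    def test_average_exceeds_monoisotopic(self):
        assert mm.sequence_mass("PEPTIDE", "average") > mm.sequence_mass("PEPTIDE")

    def test_empty_raises(self):
        with pytest.raises(ValueError, match="empty"):
            mm.sequence_mass("")

    def test_unknown_residue_names_position(self):
        with pytest.raises(ValueError, match="position 3"):
            mm.sequence_mass("GGZGG")

    def test_matches_residue_table_oracle(self):
        rng = random.Random(99)
        letters = "".join(RESIDUE_MONO)
        for _ in range(100):
            pep = "".join(rng.choice(letters) for _ in range(rng.randint(1, 60)))
            oracle = sum(RESIDUE_MONO[a] for a in pep) + WATER_MONO
            assert mm.sequence_mass(pep) == pytest.approx(oracle, abs=1e-4)


class TestMassDeviation:
    @pytest.mark.parametrize(
        "exp,theo,expected",
        [(34063.70, 34064.28, 0.58), (10790.40, 10790.20, 0.20), (500.0, 500.0, 0.0)],
    )
    def test_absolute_deviation(self, exp, theo, expected):
        assert mm.mass_deviation(exp, theo) == pytest.approx(expected, abs=1e-9)

    def test_nonpositive_mass_raises(self):
        with pytest.raises(ValueError):
            mm.mass_deviation(-1.0, 10.0)


class TestExtinction:
    @pytest.mark.parametrize(
        "seq,eps", [("W", 5500.0), ("WYY", 8480.0), ("AAAA", 0.0)]
    )
    def test_gill_von_hippel(self, seq, eps):
        assert mm.extinction_coefficient(seq) == eps

    def test_cystine_pairs(self):
        assert mm.extinction_coefficient("CCCC", cystines=True) == 250.0
        assert mm.extinction_coefficient("CCC", cystines=True) == 125.0
        assert mm.extinction_coefficient("CCCC", cystines=False) == 0.0


class TestMassFromCSD:
    def test_single_peak_inversion(self):
        mean, sd = mm.mass_from_csd([(4412.457, 20)])
        assert mean == pytest.approx(88229.0, abs=0.01)
        assert sd == 0.0

    def test_consistent_series_has_zero_spread(self):
        M = 88229.0
        peaks = [((M + z * mm.PROTON_MASS_DA) / z, z) for z in range(18, 24)]
        mean, sd = mm.mass_from_csd(peaks)
        assert mean == pytest.approx(M, abs=1e-6)
        assert sd == pytest.approx(0.0, abs=1e-6)

    def test_empty_and_zero_charge_raise(self):
        with pytest.raises(ValueError):
            mm.mass_from_csd([])
        with pytest.raises(ValueError, match="charge"):
            mm.mass_from_csd([(1000.0, 0)])

    @given(
        st.floats(min_value=5_000.0, max_value=900_000.0),
        st.lists(st.integers(min_value=1, max_value=40), min_size=1, max_size=8),
    )
    @settings(derandomize=True, max_examples=60)
    def test_synthesized_series_recovers_the_mass(self, mass, charges):
        peaks = [((mass + z * mm.PROTON_MASS_DA) / z, z) for z in charges]
        mean, sd = mm.mass_from_csd(peaks)
        assert mean == pytest.approx(mass, rel=1e-12)
        assert sd == pytest.approx(0.0, abs=1e-6)


class TestStoichiometry:
    def test_complex_mass_linearity(self):
        rng = random.Random(17)
        for _ in range(50):
            a1, b1, a2, b2 = (rng.randint(0, 5) for _ in range(4))
            if (a1 + b1) == 0 or (a2 + b2) == 0:
                continue
            mf, mc = rng.uniform(10, 60), rng.uniform(5, 20)
            assert mm.complex_mass(a1 + a2, b1 + b2, mf, mc) == pytest.approx(
                mm.complex_mass(a1, b1, mf, mc) + mm.complex_mass(a2, b2, mf, mc)
            )

    def test_empty_composition_raises(self):
        with pytest.raises(ValueError):
            mm.complex_mass(0, 0, 34.1, 10.8)

    @pytest.mark.parametrize(
        "observed,expected",
        [(88.229, (1, 5)), (75.7, (0, 7)), (34.1, (1, 0))],
    )
    def test_best_composition(self, observed, expected):
        fit = mm.best_stoichiometry(observed, 34.1, 10.8, 3, 10)
        assert fit.best == expected

    def test_exact_hit_has_zero_residual(self):
        fit = mm.best_stoichiometry(34.1, 34.1, 10.8, 3, 10)
        assert fit.residual_kda == pytest.approx(0.0, abs=1e-12)

    def test_residual_minimality_invariant(self):
        fit = mm.best_stoichiometry(88.229, 34.1, 10.8, 3, 10)
        best_res = abs(fit.residual_kda)
        for a in range(4):
            for b in range(11):
                if (a, b) == (0, 0):
                    continue
                assert best_res <= abs(a * 34.1 + b * 10.8 - 88.229) + 1e-12

    def test_tie_breaks_to_smaller_flp_count(self):
        # m_flp == 2 * m_ctp makes (0, 2) and (1, 0) exact ties
        fit = mm.best_stoichiometry(20.0, 20.0, 10.0, 3, 10)
        assert fit.best == (0, 2)
        # (0,2) and (1,0) both have zero residual; smaller a wins
        zero_res = [(a, b) for a, b, _, r in fit.table if r < 1e-12]
        assert (0, 2) in zero_res and (1, 0) in zero_res

    def test_agrees_with_independent_enumeration(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            mf = float(rng.uniform(10, 80))
            mc = float(rng.uniform(3, 30))
            obs = float(rng.uniform(10, 300))
            amax = int(rng.integers(1, 5))
            bmax = int(rng.integers(1, 12))
            fit = mm.best_stoichiometry(obs, mf, mc, amax, bmax)
            # independently coded exhaustive search
            best = None
            for a in range(amax + 1):
                for b in range(bmax + 1):
                    if a == 0 and b == 0:
                        continue
                    res = abs(a * mf + b * mc - obs)
                    key = (res, a, b)
                    if best is None or key < best:
                        best = key
            assert fit.best == (best[1], best[2])
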