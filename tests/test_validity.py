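"""Agreement statistics: rank correlation, kappa, binning, interpretation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from snaq.composition import Nutrient, ValidationError
from snaq.engine import AdequacyClass, NutrientProfile
from snaq.validity import (
    ConstantInputError,
    bin_energy,
    cohen_kappa,
    crosstab,
    interpret_kappa,
    spearman,
    spearman_exact_p,
    validity_table,
)


# --- independent oracles (deliberately naive, no shared code paths) ---------

def midranks(values):
    """Midranks by explicit definition: 1-based average position among equals."""
    out = []
    for v in values:
        less = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        out.append(less + (equal + 1) / 2.0)
    return out


def pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def kappa_oracle(a, b, labels):
    n = len(a)
    po = sum(1 for x, y in zip(a, b) if x == y) / n
    pe = sum(
        (sum(1 for x in a if x == lab) / n) * (sum(1 for y in b if y == lab) / n)
        for lab in labels
    )
    return (po - pe) / (1 - pe)


class TestSpearman:
    def test_perfect_monotone(self):
        rho, p = spearman([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rho == 1.0
        assert p < 1e-300

    def test_perfect_inverse(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert rho == -1.0

    def test_tied_example_matches_hand_ranked_pearson(self):
        x, y = [1, 2, 2, 4], [3, 1, 4, 4]
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(pearson(midranks(x), midranks(y)), abs=1e-12)

    def test_matches_bruteforce_oracle_on_random_instances(self):
        rng = np.random.default_rng(20240917)
        for _ in range(250):
            n = int(rng.integers(3, 13))
            x = rng.integers(0, 6, size=n).astype(float)
            y = rng.integers(0, 6, size=n).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            rho, _ = spearman(x, y)
            expected = pearson(midranks(list(x)), midranks(list(y)))
            assert rho == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy_rho_and_p(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            x = rng.normal(size=25)
            y = x + rng.normal(size=25)
            rho, p = spearman(x, y)
            ref = sps.spearmanr(x, y)
            assert rho == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_constant_vector_is_degenerate(self):
        with pytest.raises(ConstantInputError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_symmetry(self):
        x, y = [3.0, 1.0, 4.0, 1.5, 5.0], [2.0, 7.0, 1.0, 8.0, 2.0]
        assert spearman(x, y) == spearman(y, x)

    @given(
        st.lists(st.integers(0, 100), min_size=4, max_size=10, unique=True),
        st.lists(st.integers(0, 100), min_size=10, max_size=10),
    )
    @settings(max_examples=40, deadline=None)
    def test_invariant_under_strictly_increasing_transform(self, x, y):
        x = [float(v) for v in x]
        y = [float(v) for v in y[: len(x)]]
        if len(set(y)) < 2:
            return
        rho1, _ = spearman(x, y)
        rho2, _ = spearman([math.exp(v / 25) for v in x], y)
        assert rho1 == pytest.approx(rho2, abs=1e-12)

    def test_exact_permutation_p_agrees_with_t_approx_roughly(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [2.0, 1.0, 4.0, 3.0, 6.0, 5.0]
        _, p_t = spearman(x, y)
        p_exact = spearman_exact_p(x, y)
        assert 0 < p_exact < 1
        assert p_exact == pytest.approx(p_t, abs=0.08)


class TestCohenKappa:
    def test_identical_nonconstant_sequences(self):
        a = ["x", "y", "x", "z", "y"]
        kappa, p, degenerate = cohen_kappa(a, a)
        assert kappa == pytest.approx(1.0)
        assert not degenerate
        assert p < 0.05

    def test_constant_on_either_side_is_degenerate(self):
        const = [AdequacyClass.BELOW_EAR] * 5
        varied = [AdequacyClass.BELOW_EAR] * 4 + [AdequacyClass.AT_OR_ABOVE_RDI]
        for a, b in ((const, const), (const, varied), (varied, const)):
            kappa, p, degenerate = cohen_kappa(a, b)
            assert degenerate and kappa is None and p is None

    def test_printed_two_by_two_crosstab(self):
        # crosstab ((20,5),(10,15)): po=0.7, pe=0.5 -> kappa 0.4
        a = [0] * 25 + [1] * 25
        b = [0] * 20 + [1] * 5 + [0] * 10 + [1] * 15
        kappa, _, degenerate = cohen_kappa(a, b)
        assert kappa == pytest.approx(0.4, abs=1e-12)
        assert not degenerate

    def test_matches_direct_formula_oracle_on_random_instances(self):
        rng = np.random.default_rng(20240918)
        labels = [0, 1, 2]
        for _ in range(250):
            n = int(rng.integers(2, 13))
            a = list(rng.integers(0, 3, size=n))
            b = list(rng.integers(0, 3, size=n))
            kappa, _, degenerate = cohen_kappa(a, b, labels)
            if len(set(a)) < 2 or len(set(b)) < 2:
                assert degenerate
                continue
            assert kappa == pytest.approx(kappa_oracle(a, b, labels), abs=1e-12)

    def test_matches_statsmodels_value_and_null_p(self):
        from statsmodels.stats.inter_rater import cohens_kappa

        rng = np.random.default_rng(11)
        for _ in range(20):
            a = list(rng.integers(0, 3, size=30))
            b = list((np.array(a) + rng.integers(0, 2, size=30)) % 3)
            if len(set(a)) < 2 or len(set(b)) < 2:
                continue
            table, _ = crosstab(a, b, [0, 1, 2])
            ref = cohens_kappa(table)
            kappa, p, _ = cohen_kappa(a, b, [0, 1, 2])
            assert kappa == pytest.approx(ref.kappa, abs=1e-12)
            assert p == pytest.approx(ref.pvalue_two_sided, rel=1e-9)

    def test_symmetry(self):
        a = [0, 1, 2, 0, 1, 2, 0]
        b = [0, 1, 1, 0, 2, 2, 1]
        assert cohen_kappa(a, b)[0] == pytest.approx(cohen_kappa(b, a)[0], abs=1e-12)

    def test_kappa_never_exceeds_one(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            a = list(rng.integers(0, 3, size=10))
            b = list(rng.integers(0, 3, size=10))
            kappa, _, degenerate = cohen_kappa(a, b, [0, 1, 2])
            if not degenerate:
                assert kappa <= 1.0 + 1e-12

    def test_linear_weights_option(self):
        a = [0, 1, 2, 0, 1, 2, 1, 2]
        b = [0, 2, 2, 1, 1, 2, 0, 1]
        from sklearn.metrics import cohen_kappa_score

        kappa, p, degenerate = cohen_kappa(a, b, [0, 1, 2], weights="linear")
        assert not degenerate and p is None
        assert kappa == pytest.approx(cohen_kappa_score(a, b, weights="linear"), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="mismatch"):
            cohen_kappa([0, 1], [0, 1, 2])


class TestBinEnergy:
    def test_reference_bins(self):
        assert list(bin_energy([0.0, 7738.89, 8418.33, 1000.0, 999.999])) == [0, 7, 8, 1, 0]

    def test_negative_energy_rejected(self):
        with pytest.raises(ValidationError):
            bin_energy([-1.0])

    def test_custom_width(self):
        assert list(bin_energy([1500.0], width=500)) == [3]


class TestInterpretKappa:
    @pytest.mark.parametrize(
        "kappa,label",
        [
            (0.488, "moderate"),
            (0.803, "substantial"),  # banded at the scale's two-decimal resolution
            (0.60, "moderate"),  # inclusive upper endpoint
            (0.61, "substantial"),
            (0.80, "substantial"),
            (0.031, "slight"),
            (-0.068, "poor"),
            (1.0, "almost perfect"),
        ],
    )
    def test_bands(self, kappa, label):
        assert interpret_kappa(kappa) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            interpret_kappa(1.5)


def _profiles(intakes_by_nutrient, included, ids=None):
    n = len(next(iter(intakes_by_nutrient.values())))
    ids = ids or [f"P{i}" for i in range(n)]
    return [
        NutrientProfile(
            intakes={nut: vals[i] for nut, vals in intakes_by_nutrient.items()},
            supplements_included=included,
            participant_id=ids[i],
        )
        for i in range(n)
    ]


class TestValidityTable:
    def test_self_agreement_is_perfect(self, nrv):
        rng = np.random.default_rng(3)
        intakes = {
            Nutrient.ENERGY: rng.uniform(5000, 12000, 10),
            Nutrient.IRON: rng.uniform(5, 30, 10),
            Nutrient.CALCIUM: rng.uniform(400, 1400, 10),
            Nutrient.FOLATE_DFE: rng.uniform(200, 900, 10),
            Nutrient.IODINE: rng.uniform(50, 300, 10),
            Nutrient.ZINC: rng.uniform(5, 15, 10),
        }
        profiles = _profiles(intakes, included=True)
        results = validity_table(profiles, profiles, nrv)
        assert len(results) == 6
        for r in results:
            assert r.rho == pytest.approx(1.0)
            assert r.degenerate or r.kappa == pytest.approx(1.0)

    def test_all_iron_below_ear_is_degenerate_like_the_study(self, nrv):
        rng = np.random.default_rng(4)
        n = 25
        iron_a = rng.uniform(7.70, 10.85, n)  # the printed food-only IQR
        iron_b = iron_a * 1.24 * np.exp(0.1 * rng.standard_normal(n))
        base = {
            Nutrient.ENERGY: rng.uniform(5000, 12000, n),
            Nutrient.IRON: iron_a,
            Nutrient.CALCIUM: rng.uniform(400, 1400, n),
            Nutrient.FOLATE_DFE: rng.uniform(200, 900, n),
            Nutrient.IODINE: rng.uniform(50, 300, n),
            Nutrient.ZINC: rng.uniform(5, 15, n),
        }
        other = {**base, Nutrient.IRON: iron_b}
        results = validity_table(
            _profiles(base, included=False), _profiles(other, included=False), nrv
        )
        iron_row = next(r for r in results if r.nutrient is Nutrient.IRON)
        assert iron_b.max() < 22
        assert iron_row.degenerate and iron_row.kappa is None
        assert iron_row.condition == "food_only"
        # margins: all 25 below the EAR on both sides
        assert iron_row.class_margins["a"][AdequacyClass.BELOW_EAR] == (25, 100.0)
        assert iron_row.class_margins["b"][AdequacyClass.BELOW_EAR] == (25, 100.0)

    def test_crosstab_sums_and_margins_consistent(self, nrv):
        rng = np.random.default_rng(9)
        n = 20
        make = lambda: {
            Nutrient.ENERGY: rng.uniform(5000, 12000, n),
            Nutrient.IRON: rng.uniform(5, 35, n),
            Nutrient.CALCIUM: rng.uniform(400, 1400, n),
            Nutrient.FOLATE_DFE: rng.uniform(200, 900, n),
            Nutrient.IODINE: rng.uniform(50, 300, n),
            Nutrient.ZINC: rng.uniform(5, 15, n),
        }
        results = validity_table(
            _profiles(make(), included=True), _profiles(make(), included=True), nrv
        )
        for r in results:
            assert r.crosstab.sum() == r.n == n
            row_margin = r.crosstab.sum(axis=1)
            col_margin = r.crosstab.sum(axis=0)
            for i, lab in enumerate(r.labels):
                assert r.class_margins["a"][lab][0] == row_margin[i]
                assert r.class_margins["b"][lab][0] == col_margin[i]
            for method in ("a", "b"):
                assert sum(pct for _, pct in r.class_margins[method].values()) == pytest.approx(100.0)

    def test_participant_mismatch_rejected(self, nrv):
        vals = {n: np.linspace(1, 30, 5) for n in Nutrient}
        a = _profiles(vals, included=True, ids=list("abcde"))
        b = _profiles(vals, included=True, ids=list("abcdX"))
        with pytest.raises(ValidationError, match="participant"):
            validity_table(a, b, nrv)

    def test_both_conditions_emitted(self, nrv):
        vals = {n: np.linspace(1, 30, 6) for n in Nutrient}
        a = _profiles(vals, included=True) + _profiles(vals, included=False)
        results = validity_table(a, a, nrv)
        assert {r.condition for r in results} == {"with_supplements", "food_only"}
        assert len(results) == 12
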