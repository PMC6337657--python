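"""Decision rule against published worked examples and an enumeration oracle;
class maps, fractions, rendering."""

import numpy as np
import pandas as pd
import pytest

from frostspec.segmentation import EmbryoMask
from frostspec.synth import random_fraction_cases
from frostspec.visualize import (
    CategoryFractions,
    ClassMap,
    ThresholdRule,
    assign_category,
    category_fractions,
    decide_all,
    render_m2m,
    render_m2p,
    search_thresholds,
)

from reference_cases import (
    DECISION_CASES,
    HAOYU21_UNCERTAIN,
    SUBTRACTION_CASES,
    THRESHOLDS,
    fractions_of,
)


def enumeration_oracle(p, t):
    """Independent truth-table re-implementation of the decision rule."""
    exceed = [c for c in (0, 1, 2) if p[c] >= t[c]]
    if len(exceed) == 1:
        return exceed[0] + 1, "unique"
    if len(exceed) >= 2:
        best = exceed[0]
        for c in exceed[1:]:
            if p[c] > p[best]:
                best = c
        return best + 1, "bigger_fraction"
    best, bestd = 0, abs(p[0] - t[0])
    for c in (1, 2):
        d = abs(p[c] - t[c])
        if d < bestd:
            best, bestd = c, d
    return best + 1, "min_difference"


class TestAssignCategoryReferenceCases:
    @pytest.mark.parametrize(
        "variety,sample,orig,p,path,category",
        DECISION_CASES,
        ids=[f"{v}-{s}" for v, s, *_ in DECISION_CASES],
    )
    def test_published_rows_reproduce(self, variety, sample, orig, p, path, category):
        rule = ThresholdRule(THRESHOLDS[variety])
        d = assign_category(CategoryFractions(sample, np.array(p), atol=1e-4), rule)
        assert d.category == category
        assert d.path == path

    @pytest.mark.parametrize(
        "variety,sample,subtractions",
        SUBTRACTION_CASES,
        ids=[f"{v}-{s}" for v, s, _ in SUBTRACTION_CASES],
    )
    def test_published_subtractions_to_five_decimals(self, variety, sample, subtractions):
        p = fractions_of(variety, sample)
        rule = ThresholdRule(THRESHOLDS[variety])
        d = assign_category(CategoryFractions(sample, np.array(p), atol=1e-4), rule)
        np.testing.assert_allclose(d.differences, subtractions, atol=5e-6)


class TestAssignCategoryProperties:
    def test_saturated_fraction_is_its_category(self):
        d = assign_category(
            CategoryFractions(1, np.array([1.0, 0.0, 0.0])), ThresholdRule((0.5, 0.5, 0.5))
        )
        assert d.category == 1 and d.path == "unique"

    def test_matches_enumeration_oracle_on_random_cases(self):
        for fr, rule in random_fraction_cases(10_000, seed=3):
            d = assign_category(fr, rule)
            cat, path = enumeration_oracle(fr.p, rule.t)
            assert (d.category, d.path) == (cat, path)

    def test_random_cases_cover_all_three_paths(self):
        paths = {
            assign_category(fr, rule).path
            for fr, rule in random_fraction_cases(500, seed=0)
        }
        assert paths == {"unique", "bigger_fraction", "min_difference"}

    def test_min_difference_shift_invariance(self):
        p = np.array([0.30, 0.33, 0.37])
        t = (0.40, 0.45, 0.50)  # nothing exceeds
        base = assign_category(CategoryFractions(1, p), ThresholdRule(t))
        assert base.path == "min_difference"
        delta = 0.04
        shifted = assign_category(
            CategoryFractions(1, p + delta, atol=1.0),
            ThresholdRule(tuple(x + delta for x in t)),
        )
        assert shifted.category == base.category

    def test_exact_ties_resolve_to_lower_category(self):
        # both fractions exceed and are equal -> lower category
        d = assign_category(
            CategoryFractions(1, np.array([0.4, 0.4, 0.2])), ThresholdRule((0.3, 0.3, 0.9))
        )
        assert d.category == 1 and d.path == "bigger_fraction"
        # no exceedance, equal differences (binary-exact) -> lower category
        d2 = assign_category(
            CategoryFractions(1, np.array([0.25, 0.25, 0.5])),
            ThresholdRule((0.5, 0.5, 0.75)),
        )
        assert d2.category == 1 and d2.path == "min_difference"


class TestCategoryFractions:
    @staticmethod
    def _mask(shape, where):
        m = np.zeros(shape, dtype=bool)
        m[where] = True
        return EmbryoMask.from_binary(m, seed_id=1)

    def test_single_class_map(self):
        cm = ClassMap(np.full((10, 10), 2))
        mask = self._mask((10, 10), np.s_[2:8, 2:8])
        fr = category_fractions(cm, mask)
        np.testing.assert_allclose(fr.p, [0, 1, 0])

    def test_mixed_split(self):
        vals = np.zeros((10, 10), dtype=int)
        vals[:5, :] = 1
        vals[5:, :5] = 2
        vals[5:, 5:] = 3
        cm = ClassMap(vals)
        fr = category_fractions(cm, self._mask((10, 10), np.s_[:, :]))
        np.testing.assert_allclose(fr.p, [0.5, 0.25, 0.25])

    def test_matches_independent_counting_loop(self, rng):
        vals = rng.integers(0, 4, (12, 12))
        mask = rng.random((12, 12)) > 0.4
        mask &= vals > 0  # the map is only defined inside embryo pixels
        if not mask.any():
            mask[0, 0] = True
            vals[0, 0] = 1
        em = EmbryoMask.from_binary(mask, 1)
        fr = category_fractions(ClassMap(vals), em)
        counts = [0, 0, 0]
        for y in range(12):
            for x in range(12):
                if mask[y, x]:
                    counts[vals[y, x] - 1] += 1
        np.testing.assert_allclose(fr.p, np.array(counts) / sum(counts))

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            CategoryFractions(1, np.array([0.5, 0.4, 0.2]))
        with pytest.raises(ValueError):
            CategoryFractions(1, np.array([-0.1, 0.6, 0.5]))


class TestDecideAll:
    @staticmethod
    def _scene_from_fractions(cases):
        """Build a map + masks whose fractions reproduce given (p1,p2,p3)."""
        n = len(cases)
        H, W = 12, 12 * n
        vals = np.zeros((H, W), dtype=int)
        masks = []
        for i, p in enumerate(cases):
            x0 = 12 * i
            counts = np.round(np.array(p) * 100).astype(int)
            counts[2] = 100 - counts[0] - counts[1]
            if counts[2] < 0:  # rounding overshoot on near-zero p3
                counts[1] += counts[2]
                counts[2] = 0
            block = np.repeat([1, 2, 3], counts).reshape(10, 10)
            vals[1:11, x0 + 1 : x0 + 11] = block
            m = np.zeros((H, W), dtype=bool)
            m[1:11, x0 + 1 : x0 + 11] = True
            masks.append(EmbryoMask.from_binary(m, seed_id=i + 1))
        return ClassMap(vals), masks

    def test_haoyu21_uncertain_seeds_decide_as_published(self):
        samples = HAOYU21_UNCERTAIN["samples"]
        cases = [fractions_of("haoyu21", s) for s in samples]
        cm, masks = self._scene_from_fractions(cases)
        labels = {
            i + 1: lab for i, lab in enumerate(HAOYU21_UNCERTAIN["original"])
        }
        table, n_wrong = decide_all(
            cm, masks, ThresholdRule(THRESHOLDS["haoyu21"]), labels
        )
        assert tuple(table["final"]) == HAOYU21_UNCERTAIN["decided"]
        assert n_wrong == HAOYU21_UNCERTAIN["n_misclassified"]
        assert (table["path"] == "min_difference").all()

    def test_decisions_equal_to_labels_count_zero(self):
        cm, masks = self._scene_from_fractions([(1.0, 0.0, 0.0), (0.0, 1.0, 0.0)])
        labels = {1: 1, 2: 2}
        _, n_wrong = decide_all(cm, masks, ThresholdRule((0.5, 0.5, 0.5)), labels)
        assert n_wrong == 0

    def test_count_matches_loop_oracle_and_order_invariance(self, rng):
        ps = rng.dirichlet(np.ones(3), size=8)
        cm, masks = self._scene_from_fractions(ps)
        labels = {i + 1: int(l) for i, l in enumerate(rng.integers(1, 4, 8))}
        rule = ThresholdRule((0.37, 0.32, 0.44))
        table, n_wrong = decide_all(cm, masks, rule, labels)
        expected = sum(
            1
            for _, row in table.iterrows()
            if row["final"] != labels[row["seed_id"]]
        )
        assert n_wrong == expected
        _, n_wrong_rev = decide_all(cm, masks[::-1], rule, labels)
        assert n_wrong_rev == n_wrong

    def test_missing_label_is_an_error(self):
        cm, masks = self._scene_from_fractions([(1.0, 0.0, 0.0)])
        with pytest.raises(KeyError):
            decide_all(cm, masks, ThresholdRule((0.5, 0.5, 0.5)), {99: 1})


class TestRendering:
    def test_m2m_single_seed_single_colour(self):
        mask = EmbryoMask.from_binary(np.pad(np.ones((4, 4), bool), 2), 1)
        img = render_m2m({1: 3}, [mask], (8, 8))
        fg = img[mask.mask]
        assert (fg == fg[0]).all() and fg[0].any()
        assert (img[~mask.mask] == 0).all()

    def test_m2p_single_class_single_colour(self):
        cm = ClassMap(np.full((6, 6), 2))
        img = render_m2p(cm)
        assert len(np.unique(img.reshape(-1, 3), axis=0)) == 1

    def test_m2m_colour_histogram_matches_decision_histogram(self, rng):
        masks, decisions = [], {}
        vals = np.zeros((10, 40), dtype=bool)
        for i in range(4):
            m = np.zeros((10, 40), dtype=bool)
            m[2:8, 10 * i + 2 : 10 * i + 8] = True
            masks.append(EmbryoMask.from_binary(m, i + 1))
            decisions[i + 1] = int(rng.integers(1, 4))
        img = render_m2m(decisions, masks, (10, 40))
        area = 36
        from frostspec.visualize import CATEGORY_COLORS

        for c in (1, 2, 3):
            n_seeds = sum(1 for v in decisions.values() if v == c)
            colour = np.array(CATEGORY_COLORS[c])
            n_px = (img.reshape(-1, 3) == colour).all(axis=1).sum()
            if tuple(colour) != (0, 0, 0):
                assert n_px == n_seeds * area

    def test_threshold_search_recovers_separating_thresholds(self):
        fracs = [
            CategoryFractions(1, np.array([0.6, 0.2, 0.2])),
            CategoryFractions(2, np.array([0.2, 0.6, 0.2])),
            CategoryFractions(3, np.array([0.2, 0.2, 0.6])),
        ]
        rule = search_thresholds(fracs, {1: 1, 2: 2, 3: 3})
        for f, expected in zip(fracs, (1, 2, 3)):
            assert assign_category(f, rule).category == expected
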