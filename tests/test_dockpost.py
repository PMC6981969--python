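"""Docking cutpoint calibration, ligand efficiency and pose RMSD."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from qsarstack import dockpost, synthetic
from qsarstack.dockpost import (
    apply_energy_cutoff,
    ligand_efficiency,
    max_specificity_cutpoint,
    optimal_cutpoint,
    rmsd,
)


def _cutpoint_oracle(energies, labels):
    """Exhaustive threshold scan with explicit loops (independent of the
    implementation's candidate generation and tie logic)."""
    energies = np.asarray(energies, float)
    labels = np.asarray(labels, int)
    uniq = sorted(set(energies))
    candidates = [uniq[0] - 1.0] + [
        (a + b) / 2 for a, b in zip(uniq, uniq[1:])
    ] + [uniq[-1] + 1.0]
    n_pos = int(sum(labels == 1))
    n_neg = int(sum(labels == 0))
    best = None
    for c in candidates:
        tp = sum(1 for e, l in zip(energies, labels) if l == 1 and e <= c)
        tn = sum(1 for e, l in zip(energies, labels) if l == 0 and e > c)
        # rational comparison of tp/P + tn/N without floats
        key = (tp * n_neg + tn * n_pos, tn, -c)
        if best is None or key > best[0]:
            best = (key, c, tp / n_pos, tn / n_neg)
    return best[1], 100 * best[2], 100 * best[3]


class TestOptimalCutpoint:
    def test_separable_case_is_perfect(self):
        energies = [-10, -9, -8, -7, -6]
        labels = [1, 1, 1, 0, 0]
        res = optimal_cutpoint(energies, labels)
        assert -8 < res.cutoff < -7
        assert res.sensitivity == 100.0
        assert res.specificity == 100.0
        assert res.accuracy == 100.0

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_brute_force_oracle_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        energies = rng.normal(-8, 1, 20).round(2)
        labels = rng.integers(0, 2, 20)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        res = optimal_cutpoint(energies, labels)
        c, sens, spec = _cutpoint_oracle(energies, labels)
        assert res.cutoff == pytest.approx(c)
        assert res.sensitivity == pytest.approx(sens)
        assert res.specificity == pytest.approx(spec)

    def test_shuffled_labels_give_chance_level_sum(self):
        rng = np.random.default_rng(7)
        energies = rng.normal(-8, 1, 400)
        labels = rng.integers(0, 2, 400)
        res = optimal_cutpoint(energies, labels)
        assert res.sensitivity + res.specificity <= 115.0  # ~100 + noise

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            optimal_cutpoint([-9, -8], [1, 1])

    def test_string_labels_accepted(self):
        res = optimal_cutpoint([-10, -6], ["active", "inactive"])
        assert res.sensitivity == 100.0


class TestMaxSpecificityCutpoint:
    def test_hand_computed_midpoint(self):
        # inactive min -9.2; actives {-10, -9.5, -7} -> cutoff -9.35
        energies = [-10, -9.5, -7, -9.2, -6]
        labels = [1, 1, 1, 0, 0]
        res = max_specificity_cutpoint(energies, labels)
        assert res.cutoff == pytest.approx(-9.35)
        assert res.specificity == 100.0
        assert res.sensitivity == pytest.approx(66.67, abs=0.01)

    def test_fully_separable_matches_optimal_cutpoint_metrics(self):
        energies = [-10, -9, -7, -6]
        labels = [1, 1, 0, 0]
        opt = optimal_cutpoint(energies, labels)
        spec100 = max_specificity_cutpoint(energies, labels)
        assert spec100.sensitivity == opt.sensitivity == 100.0
        assert spec100.specificity == opt.specificity == 100.0

    def test_no_active_below_inactive_min_degenerate_but_valid(self):
        energies = [-7, -6, -9, -8]
        labels = [1, 1, 0, 0]
        res = max_specificity_cutpoint(energies, labels)
        assert res.sensitivity == 0.0
        assert res.specificity == 100.0

    def test_inactive_tying_active_minimum_raises(self):
        with pytest.raises(ValueError, match="unattainable"):
            max_specificity_cutpoint([-9, -9, -7], [1, 0, 0])

    def test_always_at_least_as_stringent_as_optimal(self):
        rng = np.random.default_rng(0)
        for seed in range(20):
            r = np.random.default_rng(seed)
            y = r.integers(0, 2, 30)
            if y.min() == y.max():
                continue
            e = np.where(y == 1, -8.5, -7.5) + r.normal(0, 0.8, 30)
            if e[y == 0].min() == e[y == 1].min():
                continue
            assert (
                max_specificity_cutpoint(e, y).cutoff
                <= optimal_cutpoint(e, y).cutoff
            )


class TestApplyEnergyCutoff:
    def test_published_hits_all_pass_their_calibrated_cutoff(self):
        hits = dockpost.load_screening_hits()
        assert len(hits) == 89
        assert len(apply_energy_cutoff(hits, -9.21)) == 89

    def test_cutoff_below_minimum_empty_and_infinite_full(self):
        hits = dockpost.load_screening_hits()
        assert apply_energy_cutoff(hits, hits.energy.min() - 1).empty
        assert len(apply_energy_cutoff(hits, np.inf)) == len(hits)

    def test_order_preserved(self):
        table = pd.DataFrame({"id": list("abc"), "energy": [-9.0, -10.0, -9.5]})
        out = apply_energy_cutoff(table, -9.4)
        assert list(out.id) == ["b", "c"]


class TestLigandEfficiency:
    def test_simple_ratios(self):
        assert ligand_efficiency(-10.0, {"mw": 500.0}, "mw") == pytest.approx(-0.02)
        assert ligand_efficiency(-10.0, {"logp": 2.0}, "logp_sq") == pytest.approx(-2.5)
        assert ligand_efficiency(-9.0, {"heavy_atoms": 30}, "heavy_atoms") == pytest.approx(-0.3)

    def test_missing_or_zero_property_flagged_missing(self):
        assert ligand_efficiency(-10.0, {}, "mw") is None
        assert ligand_efficiency(-10.0, {"logp": 0.0}, "logp") is None
        assert ligand_efficiency(-10.0, {"mw": float("nan")}, "mw") is None

    def test_unknown_variant_raises(self):
        with pytest.raises(ValueError, match="variant"):
            ligand_efficiency(-10.0, {"mw": 1.0}, "qed")

    def test_cutpoint_interface_reruns_on_le_transformed_energies(self):
        rng = np.random.default_rng(3)
        y = np.array([1] * 40 + [0] * 40)
        e = np.where(y == 1, -8.5, -7.0) + rng.normal(0, 0.5, 80)
        mw = rng.uniform(200, 600, 80)
        le = e / mw
        res = optimal_cutpoint(le, y)
        c, sens, spec = _cutpoint_oracle(le, y)
        assert res.cutoff == pytest.approx(c)


class TestRMSD:
    def test_identical_coordinates_zero(self, rng):
        a = rng.standard_normal((10, 3))
        assert rmsd(a, a) == 0.0

    def test_one_displaced_atom_of_two(self):
        a = np.array([[0.0, 0, 0], [0, 0, 0]])
        b = np.array([[2.0, 0, 0], [0, 0, 0]])
        assert rmsd(a, b) == pytest.approx(math.sqrt(2), abs=1e-12)

    def test_uniform_translation(self, rng):
        a = rng.standard_normal((7, 3))
        assert rmsd(a, a + np.array([1.0, 0, 0])) == pytest.approx(1.0)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="shapes"):
            rmsd(np.zeros((3, 3)), np.zeros((4, 3)))

    def test_metric_properties_on_random_fixtures(self, rng):
        for _ in range(5):
            a, b, c = (rng.standard_normal((6, 3)) for _ in range(3))
            assert rmsd(a, b) == pytest.approx(rmsd(b, a))
            assert rmsd(a, a) == 0.0
            assert rmsd(a, c) <= rmsd(a, b) + rmsd(b, c) + 1e-9


def test_cutoff_recovery_centers_between_class_means():
    """Calibrated cutoffs center at the class-density intersection.

    With equal class SDs the population-optimal cutoff is the midpoint of
    the class means (-7.655); the empirical sens+spec maximizer is an
    unbiased but noisy estimate of it (sampling SD ~0.25 kcal/mol at
    n=175), so the mean lands at the midpoint and most replicates fall
    between the class means.
    """
    y = np.array([1] * 100 + [0] * 75)  # calibration-set class structure
    cutoffs = []
    for seed in range(50):
        t = synthetic.generate_docking_scores(y, -8.02, -7.29, sd=0.8, seed=seed)
        cutoffs.append(optimal_cutpoint(t.energy, y).cutoff)
    cutoffs = np.asarray(cutoffs)
    assert cutoffs.mean() == pytest.approx(-7.655, abs=0.12)
    assert np.mean((-8.02 < cutoffs) & (cutoffs < -7.29)) >= 0.8
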