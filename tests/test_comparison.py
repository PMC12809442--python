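"""R_DC/R_CC protocol: fragment RMSD, classification, patterns, pair table."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from saqc import synthetic
from saqc.comparison import (
    CALL_UNASSIGNED,
    R_CC,
    R_DC,
    ComparisonResult,
    ModelMismatchError,
    PatternSet,
    ResidueComparison,
    classify_call,
    compare_models,
    extract_patterns,
    fragment_rmsd,
    sl_pair_table,
)
from conftest import random_fragment_pair
from oracles import brute_force_fragment_rmsd, runs_by_regex


class TestFragmentRmsd:
    def test_identical_fragments_give_zero(self):
        frag = np.random.default_rng(0).normal(size=(4, 3))
        assert fragment_rmsd(frag, frag) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_is_removed(self):
        rng = np.random.default_rng(1)
        frag = rng.normal(scale=3, size=(4, 3))
        rot = Rotation.from_rotvec([0.5, -0.2, 1.3])
        moved = rot.apply(frag) + np.array([10.0, -4.0, 2.0])
        assert fragment_rmsd(frag, moved) < 1e-6

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a, b = random_fragment_pair(rng)
            assert fragment_rmsd(a, b) == pytest.approx(fragment_rmsd(b, a), abs=1e-9)

    def test_degenerate_fragment_rejected(self):
        with pytest.raises(ValueError):
            fragment_rmsd(np.zeros((4, 3)), np.ones((4, 3)))

    def test_matches_quaternion_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        for i in range(50):
            a, b = random_fragment_pair(rng)
            assert fragment_rmsd(a, b) == pytest.approx(
                brute_force_fragment_rmsd(a, b, seed=i), abs=2e-3
            )


class TestClassificationRule:
    def test_equal_letters_are_consistent(self):
        assert classify_call("A", "A", None, 0.1) == R_CC

    def test_subthreshold_letter_change_reclassified(self):
        assert classify_call("A", "B", 0.05, 0.1) == R_CC

    def test_suprathreshold_letter_change_is_questionable(self):
        assert classify_call("A", "B", 0.15, 0.1) == R_DC

    def test_threshold_is_inclusive(self):
        assert classify_call("A", "B", 0.1, 0.1) == R_DC

    def test_unassigned_propagates(self):
        assert classify_call("-", "B", None, 0.1) == CALL_UNASSIGNED


class TestCompareModels:
    def test_self_comparison_gives_zero_p_dc(self, mixed_model, params):
        result = compare_models(mixed_model, mixed_model, params)
        assert result.n_rdc == 0
        assert result.p_dc == 0.0
        assert all(r.call in (R_CC, CALL_UNASSIGNED) for r in result.residues)

    def test_perturbation_detected_near_target(self, perturbed_pair, params):
        model, pert, target, _ = perturbed_pair(0, target=25, delta=35.0)
        result = compare_models(model, pert, params)
        hits = [r.res_key[0] - 1 for r in result.residues if r.call == R_DC]
        assert hits, "no R_DC residues detected"
        # superposition makes windows on one side of the bond rigid, so every
        # call must sit on a window that truly spans the rotated dihedral
        assert all(target - 2 <= h <= target + 2 for h in hits)

    def test_raising_threshold_never_increases_n_rdc(self, perturbed_pair, params):
        model, pert, _, _ = perturbed_pair(1, target=30, delta=40.0)
        previous = None
        for threshold in np.linspace(0.0, 0.3, 7):
            n = compare_models(model, pert, params, threshold=threshold).n_rdc
            if previous is not None:
                assert n <= previous
            previous = n

    def test_threshold_zero_equals_letter_difference_set(self, perturbed_pair, params):
        model, pert, _, _ = perturbed_pair(2, target=40, delta=30.0)
        result = compare_models(model, pert, params, threshold=0.0)
        for r in result.residues:
            if r.call != CALL_UNASSIGNED:
                assert (r.call == R_DC) == (r.sl_ref != r.sl_alt)

    def test_p_dc_definition_and_pattern_cover(self, perturbed_pair, params):
        model, pert, _, _ = perturbed_pair(3)
        result = compare_models(model, pert, params)
        assert result.p_dc == result.n_rdc / model.n_residues
        cover = result.patterns.n_isolated + result.patterns.n_in_runs
        assert cover == result.n_rdc

    def test_amino_acid_mismatch_rejected(self, mixed_model, params):
        import copy

        other = copy.deepcopy(mixed_model)
        other.chains[0].residues[5].aa = "G"
        with pytest.raises(ModelMismatchError, match="mismatch"):
            compare_models(mixed_model, other, params)

    def test_excessive_residue_loss_rejected(self, mixed_model, params):
        import copy

        other = copy.deepcopy(mixed_model)
        other.chains[0].residues = other.chains[0].residues[:20]
        with pytest.raises(ModelMismatchError, match="matched"):
            compare_models(mixed_model, other, params)

    def test_sl_pair_counts_sum_to_n_rdc(self, perturbed_pair, params):
        model, pert, _, _ = perturbed_pair(4, target=22, delta=45.0)
        result = compare_models(model, pert, params)
        assert result.sl_pair_counts.values.sum() == result.n_rdc


def _fake_result(calls):
    records = [
        ResidueComparison("A", (i + 1, ""), "A", "A", "A", None, c)
        for i, c in enumerate(calls)
    ]
    return ComparisonResult(
        residues=records, n_rdc=sum(c == R_DC for c in calls),
        n_assigned=len(calls), n_residues_ref=len(calls), n_dropped=0,
        p_dc=0.0, threshold=0.1, patterns=PatternSet([], []),
        sl_pair_counts=None, mode="emission_only",
    )


class TestPatterns:
    def test_isolated_flanked_by_consistent_calls(self):
        patterns = extract_patterns(_fake_result([R_CC, R_DC, R_CC]))
        assert patterns.n_isolated == 1
        assert patterns.runs == []

    def test_maximal_run(self):
        patterns = extract_patterns(_fake_result([R_DC, R_DC, R_DC]))
        assert patterns.n_isolated == 0
        assert patterns.runs == [("A", (1, ""), 3)]

    def test_unassigned_breaks_runs(self):
        patterns = extract_patterns(
            _fake_result([R_DC, CALL_UNASSIGNED, R_DC, R_DC])
        )
        assert patterns.n_isolated == 1
        assert patterns.run_lengths() == [2]

    def test_random_call_vector_matches_regex_oracle(self):
        rng = np.random.default_rng(5)
        calls = list(
            rng.choice([R_CC, R_DC, CALL_UNASSIGNED], size=1000, p=[0.6, 0.3, 0.1])
        )
        patterns = extract_patterns(_fake_result(calls))
        n_isolated, run_lengths = runs_by_regex(calls)
        assert patterns.n_isolated == n_isolated
        assert sorted(patterns.run_lengths()) == sorted(run_lengths)


class TestSlPairTable:
    def test_single_pair_row_proportion(self, perturbed_pair, params):
        model, pert, _, _ = perturbed_pair(6, target=10, delta=50.0)
        result = compare_models(model, pert, params)
        counts, props = sl_pair_table(result)
        nonzero_rows = counts.sum(axis=1)
        for letter, total in nonzero_rows.items():
            if total > 0:
                assert props.loc[letter].sum() == pytest.approx(1.0)
        assert counts.values.sum() == result.n_rdc

    def test_empty_table_warns(self, mixed_model, params):
        result = compare_models(mixed_model, mixed_model, params)
        with pytest.warns(UserWarning):
            counts, _ = sl_pair_table(result)
        assert counts.values.sum() == 0


class TestFragmentRmsdProperties:
    """Metric-like behaviour of the superposed fragment RMSD, fuzzed."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    frag_strategy = st.lists(
        st.floats(-8, 8, allow_nan=False, allow_infinity=False),
        min_size=24, max_size=24,
    )

    @given(frag_strategy)
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_symmetry_and_nonnegativity(self, values):
        from hypothesis import assume

        arr = np.array(values).reshape(2, 4, 3)
        a, b = arr
        assume(np.ptp(a, axis=0).max() > 1e-6 and np.ptp(b, axis=0).max() > 1e-6)
        ab = fragment_rmsd(a, b)
        assert ab >= 0
        assert ab == pytest.approx(fragment_rmsd(b, a), abs=1e-8)

    @given(frag_strategy)
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_rigid_motion_yields_zero(self, values):
        from hypothesis import assume

        arr = np.array(values).reshape(2, 4, 3)
        a = arr[0]
        assume(np.ptp(a, axis=0).max() > 1e-6)
        rot = Rotation.from_rotvec(arr[1, 0] / 10.0)
        moved = rot.apply(a) + arr[1, 1]
        assert fragment_rmsd(a, moved) < 1e-6
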