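import math

import pytest

from trnamass import (
    RNASE_T1,
    candidate_genes,
    differential_screen,
    match_peaks,
    quantify_states,
)
from trnamass.simulate import (
    SimulationConfig,
    simulate_peaklist,
    simulate_state_mixture,
    simulate_strain_panel,
    simulate_trnas,
)

PANEL = {
    "geneA": frozenset({"m6t6A"}),
    "geneB": frozenset({"ct6A"}),
    "geneC": frozenset({"t6A", "m6t6A", "ct6A"}),
    "geneD": frozenset({"D"}),
}


class TestConfig:
    def test_bad_probability(self):
        with pytest.raises(ValueError):
            SimulationConfig(modification_profile={37: ("t6A", 1.5)})

    def test_bad_dropout(self):
        with pytest.raises(ValueError):
            SimulationConfig(dropout=-0.1)

    def test_bad_jitter(self):
        with pytest.raises(ValueError):
            SimulationConfig(mz_jitter_ppm=-1.0)


class TestSimulateTrnas:
    def test_deterministic(self):
        config = SimulationConfig(seed=1, n_trnas=4)
        first, truth_first = simulate_trnas(config)
        second, truth_second = simulate_trnas(config)
        assert [r.sequence for r in first] == [r.sequence for r in second]
        assert truth_first == truth_second

    def test_different_seeds_differ(self):
        a, _ = simulate_trnas(SimulationConfig(seed=1, n_trnas=4))
        b, _ = simulate_trnas(SimulationConfig(seed=2, n_trnas=4))
        assert [r.sequence for r in a] != [r.sequence for r in b]

    def test_full_occupancy(self):
        config = SimulationConfig(
            seed=3, n_trnas=10, modification_profile={37: ("t6A", 1.0)}
        )
        records, truth = simulate_trnas(config)
        for record in records:
            assert record.residue_at(37) == "t6A"
            assert truth[record.id] == {37: "t6A"}

    def test_zero_occupancy(self):
        config = SimulationConfig(
            seed=3, n_trnas=10, modification_profile={37: ("t6A", 0.0)}
        )
        records, truth = simulate_trnas(config)
        for record in records:
            assert record.residue_at(37) != "t6A"
            assert truth[record.id] == {}

    def test_anticodon_positions_set(self):
        records, _ = simulate_trnas(SimulationConfig(seed=0, n_trnas=3))
        for record in records:
            assert len(record.anticodon()) == 3
            assert record.has_position(37)

    def test_unknown_profiled_code(self):
        with pytest.raises(ValueError):
            simulate_trnas(
                SimulationConfig(modification_profile={37: ("nope", 1.0)})
            )


class TestSimulatePeaklist:
    def test_noiseless_full_recovery(self):
        config = SimulationConfig(seed=5, n_trnas=4)
        records, _ = simulate_trnas(config)
        peaks, truth, predicted = simulate_peaklist(records, RNASE_T1, config)
        assert len(peaks) == len(predicted)
        result = match_peaks(predicted, peaks, tol_ppm=1.0)
        assert not result.unmatched_peaks

    def test_dropout_one_empty(self):
        config = SimulationConfig(seed=5, n_trnas=2, dropout=1.0)
        records, _ = simulate_trnas(config)
        peaks, truth, predicted = simulate_peaklist(records, RNASE_T1, config)
        assert peaks == []
        assert truth == []
        assert predicted  # predictions still enumerated

    def test_truth_links_peaks_to_ions(self):
        config = SimulationConfig(seed=6, n_trnas=2, mz_jitter_ppm=3.0)
        records, _ = simulate_trnas(config)
        peaks, truth, _ = simulate_peaklist(records, RNASE_T1, config)
        for entry in truth:
            peak = peaks[entry.peak_index]
            expected = entry.ion.mz * (1 + entry.jitter_ppm * 1e-6)
            assert peak.mz == pytest.approx(expected, abs=1e-9)

    def test_jitter_recovery_rate(self):
        """5 ppm jitter at 10 ppm tolerance: recovery ~ P(|N(0,5)| <= 10)."""
        config = SimulationConfig(seed=7, n_trnas=40, mz_jitter_ppm=5.0)
        records, _ = simulate_trnas(config)
        peaks, truth, predicted = simulate_peaklist(records, RNASE_T1, config)
        n = len(truth)
        assert n >= 500
        result = match_peaks(predicted, peaks, tol_ppm=10.0)
        matched_pairs = {
            (a.peak.mz, a.ion.mz, a.ion.charge) for a in result.assignments
        }
        recovered = sum(
            1
            for entry in truth
            if (peaks[entry.peak_index].mz, entry.ion.mz, entry.ion.charge)
            in matched_pairs
        )
        expected = math.erf(2.0 / math.sqrt(2.0))  # = P(|Z| <= 2)
        sigma = math.sqrt(expected * (1 - expected) / n)
        assert abs(recovered / n - expected) <= 3 * sigma


class TestSimulateStrainPanel:
    def test_recovers_planted_map(self):
        config = SimulationConfig(seed=8, strain_panel=PANEL)
        matrix, causal = simulate_strain_panel(config, extra_marks=["m2A"])
        report = differential_screen(matrix, "WT")
        for gene, marks in causal.items():
            assert report[f"Δ{gene}"] == sorted(marks)

    def test_no_op_gene_empty_difference(self):
        config = SimulationConfig(
            seed=8, strain_panel={**PANEL, "geneE": frozenset()}
        )
        matrix, _ = simulate_strain_panel(config, extra_marks=["m2A"])
        assert differential_screen(matrix, "WT")["ΔgeneE"] == []

    def test_two_genes_for_one_mark(self):
        config = SimulationConfig(seed=9, strain_panel=PANEL)
        matrix, causal = simulate_strain_panel(config)
        report = differential_screen(matrix, "WT")
        hits = {
            strain[1:] for strain, absent in report.items() if "m6t6A" in absent
        }
        result = candidate_genes(set(causal), hits)
        assert set(result.genes) == {"geneA", "geneC"}
        assert result.status == "ambiguous"

    def test_empty_spec_rejected(self):
        with pytest.raises(ValueError):
            simulate_strain_panel(SimulationConfig(seed=0))

    def test_deterministic(self):
        config = SimulationConfig(seed=10, strain_panel=PANEL, dropout=0.2)
        a, _ = simulate_strain_panel(config)
        b, _ = simulate_strain_panel(config)
        assert a.data.equals(b.data)


class TestSimulateStateMixture:
    def test_single_state(self):
        out = simulate_state_mixture({"t6A": 1.0}, 100, SimulationConfig(seed=0))
        assert out == {"t6A": 100.0}

    def test_law_of_large_numbers(self):
        fractions = {"m6t6A": 0.56, "t6A": 0.16, "A": 0.16, "other": 0.12}
        out = simulate_state_mixture(fractions, 100_000, SimulationConfig(seed=1))
        total = sum(out.values())
        for state, expected in fractions.items():
            assert out[state] / total == pytest.approx(expected, abs=0.01)

    def test_recovery_within_3_sigma(self):
        fractions = {"m6t6A": 0.56, "t6A": 0.16, "A": 0.16, "ct6A": 0.12}
        n = 1000
        out = simulate_state_mixture(fractions, n, SimulationConfig(seed=2))
        result = quantify_states(out)
        for state, expected in fractions.items():
            sigma = math.sqrt(expected * (1 - expected) / n)
            assert abs(result.fractions[state] - expected) <= 3 * sigma

    def test_partial_fractions_leave_unassigned_pool(self):
        out = simulate_state_mixture(
            {"m6t6A": 0.5, "t6A": 0.2}, 10_000, SimulationConfig(seed=3)
        )
        assert sum(out.values()) < 10_000

    def test_negative_fraction(self):
        with pytest.raises(ValueError):
            simulate_state_mixture({"a": -0.1}, 10, SimulationConfig(seed=0))

    def test_fractions_over_one(self):
        with pytest.raises(ValueError):
            simulate_state_mixture({"a": 0.7, "b": 0.6}, 10, SimulationConfig(seed=0))

    def test_zero_ions(self):
        out = simulate_state_mixture({"a": 1.0}, 0, SimulationConfig(seed=0))
        assert out == {"a": 0.0}


class TestEndToEnd:
    def test_pipeline_recovers_planted_map_zero_dropout(self):
        """simulate -> digest -> mass -> match -> screen, no false positives."""
        config = SimulationConfig(seed=11, n_trnas=6, strain_panel=PANEL)
        records, _ = simulate_trnas(config)
        peaks, truth, predicted = simulate_peaklist(records, RNASE_T1, config)
        result = match_peaks(predicted, peaks, tol_ppm=5.0)
        assert not result.unmatched_peaks
        matrix, causal = simulate_strain_panel(config, extra_marks=["m2A", "D"])
        report = differential_screen(matrix, "WT")
        for gene, marks in causal.items():
            assert report[f"Δ{gene}"] == sorted(marks)
        false_positives = {
            strain: absent
            for strain, absent in report.items()
            if set(absent) - set(causal[strain[1:]])
        }
        assert not false_positives
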