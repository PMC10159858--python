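"""Four-filter decontamination: rules, boundaries and planted recovery."""

import json

import numpy as np
import pandas as pd
import pytest

from bloodsift.decontam import (
    ContaminantCall,
    DecontamConfig,
    batch_filter,
    clr_transform,
    correlation_filter,
    prevalence_by_batch,
    prevalence_filter,
    read_count_filter,
    run_decontamination,
)
from bloodsift.errors import DataError
from bloodsift.profiles import call_presence
from bloodsift.synth import SimulationConfig, simulate_cohort_counts
from conftest import presence_frame


def two_batch_presence(prev_a, prev_b, n_a=200, n_b=300, species="spX"):
    """Presence frame with given prevalence in batches A and B."""
    k_a, k_b = round(prev_a * n_a), round(prev_b * n_b)
    col = [True] * k_a + [False] * (n_a - k_a) + [True] * k_b + [False] * (n_b - k_b)
    present = presence_frame(np.array(col)[:, None], species=[species])
    meta = pd.DataFrame(
        {"kit": ["A"] * n_a + ["B"] * n_b},
        index=present.index,
    )
    return present, meta


class TestPrevalenceFilter:
    def test_prevalence_by_batch_counts(self):
        present, meta = two_batch_presence(0.4, 0.0, n_a=10, n_b=5)
        tab = prevalence_by_batch(present, meta, "kit")
        row_a = tab[(tab.batch_label == "A")].iloc[0]
        assert row_a.prevalence == 0.4 and row_a.n_samples == 10
        row_b = tab[(tab.batch_label == "B")].iloc[0]
        assert row_b.prevalence == 0.0 and row_b.n_samples == 5

    def test_called_when_fold_and_threshold_exceeded(self):
        present, meta = two_batch_presence(0.40, 0.10)
        calls = prevalence_filter(present, meta, ["kit"])
        assert len(calls) == 1
        call = calls[0]
        assert (call.species, call.batch_variable, call.batch_label) == (
            "spX", "kit", "A")
        assert call.evidence["prevalence_in_batch"] == pytest.approx(0.40)
        assert call.evidence["max_other_prevalence"] == pytest.approx(0.10)

    def test_not_called_when_fold_fails(self):
        present, meta = two_batch_presence(0.30, 0.20)
        assert prevalence_filter(present, meta, ["kit"]) == []

    def test_zero_prevalence_comparator_satisfies_fold(self):
        present, meta = two_batch_presence(0.26, 0.0)
        calls = prevalence_filter(present, meta, ["kit"])
        assert [c.batch_label for c in calls] == ["A"]

    def test_small_batches_excluded(self):
        present, meta = two_batch_presence(0.40, 0.0, n_a=200, n_b=50)
        with pytest.warns(UserWarning, match="fewer than 2 batches"):
            calls = prevalence_filter(present, meta, ["kit"])
        assert calls == []

    def test_invariant_to_sample_order_and_label_renaming(self):
        present, meta = two_batch_presence(0.40, 0.10)
        perm = np.random.default_rng(0).permutation(len(present))
        shuffled = prevalence_filter(present.iloc[perm], meta, ["kit"])
        renamed_meta = meta.replace({"A": "zz_batch", "B": "aa_batch"})
        renamed = prevalence_filter(present, renamed_meta, ["kit"])
        base = prevalence_filter(present, meta, ["kit"])
        assert len(base) == len(shuffled) == len(renamed) == 1
        assert renamed[0].batch_label == "zz_batch"
        assert shuffled[0].evidence == base[0].evidence


class TestClrTransform:
    def test_known_composition(self):
        # ln(x / geometric mean) for (0.5, 0.25, 0.25)
        abund = pd.DataFrame([[0.5, 0.25, 0.25]], index=["A"],
                             columns=["x", "y", "z"])
        clr = clr_transform(abund)
        assert clr.loc["A"].to_numpy() == pytest.approx(
            [0.4621, -0.2310, -0.2310], abs=1e-4)

    def test_uniform_composition_maps_to_zero(self):
        abund = pd.DataFrame([[0.25] * 4], index=["A"], columns=list("wxyz"))
        assert np.allclose(clr_transform(abund).to_numpy(), 0.0)

    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(0)
        raw = rng.dirichlet(np.ones(6), size=20)
        raw[raw < 0.05] = 0.0       # introduce zeros for replacement
        abund = pd.DataFrame(raw, index=[f"S{i}" for i in range(20)],
                             columns=[f"sp{j}" for j in range(6)])
        abund = abund[abund.sum(axis=1) > 0]
        clr = clr_transform(abund)
        assert np.allclose(clr.sum(axis=1), 0.0, atol=1e-6)

    def test_all_zero_row_rejected_unless_allowed(self):
        abund = pd.DataFrame([[0.5, 0.5], [0.0, 0.0]], index=["A", "B"],
                             columns=["x", "y"])
        with pytest.raises(DataError, match="all-zero"):
            clr_transform(abund)
        clr = clr_transform(abund, allow_zero_rows=True)
        assert np.allclose(clr.loc["B"], 0.0)


class TestCorrelationFilter:
    @staticmethod
    def _batch_setup(n=60, seed=0):
        rng = np.random.default_rng(seed)
        meta = pd.DataFrame({"kit": ["A"] * n},
                            index=pd.Index([f"S{i}" for i in range(n)],
                                           name="sample_id"))
        seed_call = ContaminantCall("contam", "prevalence", "kit", "A",
                                    {"prevalence_in_batch": 0.5})
        return rng, meta, seed_call

    def test_identical_profile_called_with_partner(self):
        rng, meta, seed_call = self._batch_setup()
        base = rng.lognormal(0, 1, 60)
        abund = pd.DataFrame({
            "contam": base, "copycat": base * 2.0,
            "other": rng.lognormal(0, 1, 60),
        }, index=meta.index)
        abund = abund.div(abund.sum(axis=1), axis=0)
        calls = correlation_filter(abund, meta, [seed_call])
        called = {c.species: c for c in calls}
        assert "copycat" in called
        assert called["copycat"].evidence["partner_species"] == "contam"
        assert called["copycat"].evidence["rho"] > 0.99

    def test_independent_species_not_called(self):
        rng, meta, seed_call = self._batch_setup(n=200, seed=1)
        abund = pd.DataFrame({
            "contam": rng.lognormal(0, 1, 200),
            "indep": rng.lognormal(0, 1, 200),
            "other": rng.lognormal(0, 1, 200),
        }, index=pd.Index([f"S{i}" for i in range(200)], name="sample_id"))
        meta = pd.DataFrame({"kit": ["A"] * 200}, index=abund.index)
        abund = abund.div(abund.sum(axis=1), axis=0)
        calls = correlation_filter(abund, meta, [seed_call])
        assert "indep" not in {c.species for c in calls}

    def test_threshold_is_strict(self):
        rng, meta, seed_call = self._batch_setup()
        base = rng.lognormal(0, 1, 60)
        abund = pd.DataFrame({
            "contam": base, "copycat": base, "other": rng.lognormal(0, 1, 60),
        }, index=meta.index)
        abund = abund.div(abund.sum(axis=1), axis=0)
        # rho = 1.0 exactly: called at threshold 0.7, not at threshold 1.0
        assert {c.species for c in correlation_filter(abund, meta, [seed_call])} \
            == {"copycat"}
        assert correlation_filter(abund, meta, [seed_call],
                                  rho_threshold=1.0) == []

    def test_tiny_batch_skipped_with_warning(self):
        _, _, seed_call = self._batch_setup()
        meta = pd.DataFrame({"kit": ["A", "A"]}, index=["S0", "S1"])
        abund = pd.DataFrame([[0.5, 0.5], [0.4, 0.6]], index=["S0", "S1"],
                             columns=["contam", "x"])
        with pytest.warns(UserWarning, match="correlation filter skipped"):
            assert correlation_filter(abund, meta, [seed_call]) == []


class TestBatchFilter:
    @staticmethod
    def _meta():
        return pd.DataFrame({
            "extraction_kit": ["E1", "E1", "E2", "E2"],
            "flow_cell": ["F1", "F2", "F1", "F2"],
            "library_kit": ["L1", "L1", "L2", "L2"],
        }, index=pd.Index([f"S{i}" for i in range(4)], name="sample_id"))

    def test_single_flow_cell_called(self):
        present = presence_frame([[True], [False], [True], [False]],
                                 species=["spX"])
        calls = batch_filter(present, self._meta(),
                             ["extraction_kit", "flow_cell", "library_kit"])
        assert len(calls) == 1
        assert calls[0].batch_variable == "flow_cell"
        assert calls[0].batch_label == "F1"

    def test_multi_batch_species_not_called(self):
        present = presence_frame([[True], [True], [False], [True]],
                                 species=["spX"])
        assert batch_filter(present, self._meta(),
                            ["extraction_kit", "flow_cell", "library_kit"]) == []

    def test_excluded_variable_ignored(self):
        # species spans two kits and two flow cells but one library kit;
        # library_kit is excluded by default, so no call
        meta = pd.DataFrame({
            "extraction_kit": ["E1", "E1", "E2", "E2"],
            "flow_cell": ["F1", "F2", "F1", "F2"],
            "library_kit": ["L1", "L1", "L1", "L2"],
        }, index=pd.Index([f"S{i}" for i in range(4)], name="sample_id"))
        present = presence_frame([[True], [True], [True], [False]],
                                 species=["spX"])
        variables = ["extraction_kit", "flow_cell", "library_kit"]
        assert batch_filter(present, meta, variables) == []
        # ...and called once library_kit participates
        calls = batch_filter(present, meta, variables, excluded_variables=())
        assert len(calls) == 1
        assert calls[0].batch_variable == "library_kit"

    def test_zero_presence_species_called_degenerate(self):
        present = presence_frame([[False]] * 4, species=["ghost"])
        calls = batch_filter(present, self._meta(), ["extraction_kit"],
                             excluded_variables=())
        assert calls[0].evidence["n_batches_detected"] == 0
        assert calls[0].evidence["n_samples_present"] == 0

    def test_all_excluded_is_error(self):
        present = presence_frame([[True]] * 4, species=["spX"])
        with pytest.raises(DataError, match="excluded"):
            batch_filter(present, self._meta(), ["flow_cell"],
                         excluded_variables=("flow_cell",))


class TestReadCountFilter:
    @pytest.mark.parametrize("max_reads,called", [(22, True), (99, True),
                                                  (100, False), (150, False)])
    def test_boundary(self, max_reads, called):
        counts = pd.DataFrame(
            {"spX": [max_reads, max_reads // 2, 0]},
            index=["S0", "S1", "S2"],
        )
        calls = read_count_filter(counts)
        assert (len(calls) == 1) is called
        if called:
            assert calls[0].evidence["max_reads"] == max_reads


class TestRunDecontamination:
    def test_planted_recovery_on_default_scenario(self):
        counts, meta, truth = simulate_cohort_counts(SimulationConfig(seed=0))
        pm = call_presence(counts)
        report = run_decontamination(pm, meta)
        called = report.called_species()
        recovered = len(set(truth.contaminants) & called)
        false_calls = len(set(truth.genuine) & called)
        assert recovered >= 0.9 * len(truth.contaminants)
        assert false_calls <= 0.05 * len(truth.genuine)

    def test_monotone_counts_and_disjoint_survivors(self):
        counts, meta, _ = simulate_cohort_counts(
            SimulationConfig(seed=3, n_samples=800))
        pm = call_presence(counts)
        report = run_decontamination(pm, meta)
        seq = [report.species_before] + report.species_after_each_filter
        assert all(a >= b for a, b in zip(seq, seq[1:]))
        assert not (set(report.survivors) & report.called_species())

    def test_no_batch_structure_keeps_high_read_species(self):
        rng = np.random.default_rng(4)
        n = 450
        counts = pd.DataFrame({
            "big": rng.integers(200, 2000, n),
            "small": rng.integers(11, 60, n),
            "filler": rng.integers(200, 600, n),
        }, index=pd.Index([f"S{i}" for i in range(n)], name="sample_id"))
        meta = pd.DataFrame({
            "kit": np.repeat(["A", "B", "C"], n // 3),
        }, index=counts.index)
        pm = call_presence(counts)
        report = run_decontamination(pm, meta)
        assert "big" in report.survivors and "filler" in report.survivors
        # 'small' never reaches 100 reads in any sample
        assert "small" in {c.species for c in report.calls
                           if c.filter == "read_count"}

    def test_empty_species_set(self):
        counts = pd.DataFrame(index=pd.Index(["S0"], name="sample_id"),
                              dtype=np.int64)
        counts["only"] = [200]
        pm = call_presence(counts)
        meta = pd.DataFrame({"kit": ["A"]}, index=counts.index)
        report = run_decontamination(pm, meta, species=[])
        assert report.species_before == 0
        assert report.survivors == []

    def test_disabling_all_filters_keeps_everything(self):
        counts, meta, _ = simulate_cohort_counts(
            SimulationConfig(seed=5, n_samples=600))
        pm = call_presence(counts)
        cfg = DecontamConfig(enable_prevalence=False, enable_correlation=False,
                             enable_batch=False, enable_read_count=False)
        report = run_decontamination(pm, meta, cfg)
        assert report.survivors == pm.species_detected()
        assert report.calls == []

    def test_evidence_recomputes_calls(self):
        """Every stored call's evidence satisfies its own filter rule."""
        counts, meta, _ = simulate_cohort_counts(SimulationConfig(seed=0))
        pm = call_presence(counts)
        report = run_decontamination(pm, meta)
        cfg = DecontamConfig()
        for call in report.calls:
            ev = call.evidence
            if call.filter == "prevalence":
                assert ev["prevalence_in_batch"] > cfg.prev_threshold
                assert ev["prevalence_in_batch"] > cfg.fold * ev["max_other_prevalence"]
                assert ev["n_samples"] >= cfg.min_batch_size
            elif call.filter == "correlation":
                assert ev["rho"] > cfg.rho_threshold
            elif call.filter == "batch":
                assert ev["n_batches_detected"] <= 1
            elif call.filter == "read_count":
                assert ev["max_reads"] < cfg.min_max_reads

    def test_report_json_round_trip(self, tmp_path):
        counts, meta, _ = simulate_cohort_counts(
            SimulationConfig(seed=6, n_samples=600))
        pm = call_presence(counts)
        report = run_decontamination(pm, meta)
        path = tmp_path / "report.json"
        report.to_json(str(path))
        payload = json.loads(path.read_text())
        assert payload["species_before"] == report.species_before
        assert payload["survivors"] == report.survivors
        assert len(payload["calls"]) == len(report.calls)
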