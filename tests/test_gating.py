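import dataclasses
import logging

import numpy as np
import pandas as pd
import pytest

from csfcyto import (ThresholdSet, apply_gate_tree, default_thresholds,
                     estimate_thresholds, simulate_donor)
from csfcyto.gating import (EXHAUSTIVE_PARTITIONS, GateTree, MarkerPredicate,
                            counts_frame, default_gate_tree, gate_masks)
from csfcyto.panel import MarkerPanel
from csfcyto.simulate import latent_lineage

from conftest import make_events


class TestDefaultTree:
    def test_asc_is_a_b_cell_subset(self, tree):
        assert "ASC" in tree
        assert tree.node("ASC").parent == "B"

    def test_structure_and_self_validation(self, tree):
        tree.validate()
        assert tree.names[0] == "leukocytes"
        assert tree.node("Treg").parent == "CD4"
        assert set(tree.node("CD4_memory").union_of) == {"CD4_CM", "CD4_EM",
                                                         "CD4_TEMRA"}
        assert tree.node("NKT").parent == "T"
        assert set(tree.node("lymphocytes").union_of) == {"T", "B", "NK"}

    def test_partition_siblings_mutually_exclusive(self, tree, thresholds):
        rng = np.random.default_rng(0)
        events = pd.DataFrame(rng.uniform(-1, 7, size=(500, 17)),
                              columns=list(MarkerPanel().channels))
        masks = gate_masks(events, tree, thresholds)
        for parent, siblings in EXHAUSTIVE_PARTITIONS.items():
            stack = np.array([masks[s] for s in siblings])
            assert (stack.sum(axis=0) <= 1).all()

    def test_invalid_trees_rejected(self, tree):
        pops = [dataclasses.replace(p) for p in tree.populations]
        with pytest.raises(ValueError, match="root"):
            GateTree(pops[1:])  # no leukocytes root
        shuffled = [pops[1], pops[0]] + pops[2:]
        with pytest.raises(ValueError):
            GateTree(shuffled)  # child precedes parent

    def test_yaml_round_trip(self, tree, tmp_path):
        path = tmp_path / "tree.yaml"
        tree.to_yaml(path)
        back = GateTree.from_yaml(path)
        assert back.names == tree.names
        assert back.node("ASC").predicates == tree.node("ASC").predicates


class TestThresholds:
    def test_fixed_method_is_identity(self, toy_events):
        custom = ThresholdSet(primary={"CD45": 1.0}, high={})
        assert estimate_thresholds(toy_events, "fixed", custom) is custom

    def test_defaults_match_documented_values(self, thresholds):
        assert thresholds.primary["CD3"] == 2.0
        assert thresholds.high == {"CD27": 5.0, "CD38": 5.0, "SSC": 3.0}

    def test_high_must_exceed_primary(self):
        with pytest.raises(ValueError):
            ThresholdSet(primary={"CD27": 5.0}, high={"CD27": 2.0})

    def test_midpoint_on_bimodal_channel(self):
        rng = np.random.default_rng(1)
        events = pd.DataFrame(
            np.zeros((1000, 17)), columns=list(MarkerPanel().channels))
        for ch in events.columns:
            events[ch] = np.r_[rng.normal(0, 0.5, 500), rng.normal(4, 0.5, 500)]
        est = estimate_thresholds(events, "midpoint-mixture")
        assert 1.0 < est.primary["CD3"] < 3.0
        assert est.high["CD27"] == pytest.approx(est.primary["CD27"] + 3.0)

    def test_degenerate_channel_falls_back_with_warning(self, caplog):
        events = pd.DataFrame(np.zeros((200, 17)),
                              columns=list(MarkerPanel().channels))
        with caplog.at_level(logging.WARNING, logger="csfcyto.gating"):
            est = estimate_thresholds(events, "midpoint-mixture")
        assert est.primary["CD3"] == 2.0
        assert any("degenerate" in r.message for r in caplog.records)

    def test_empty_events_rejected(self):
        empty = pd.DataFrame(columns=list(MarkerPanel().channels))
        with pytest.raises(ValueError):
            estimate_thresholds(empty, "midpoint-mixture")


class TestApplyGateTree:
    def test_empty_input_all_zero(self, tree, thresholds):
        empty = pd.DataFrame(np.zeros((0, 17)),
                             columns=list(MarkerPanel().channels))
        counts = apply_gate_tree(empty, tree, thresholds)
        assert all(v == 0 for v in counts.counts.values())

    def test_toy_matrix_hand_gated_counts(self, tree, thresholds, toy_events):
        counts = apply_gate_tree(toy_events, tree, thresholds, donor_id="toy")
        expected = {"leukocytes": 7, "T": 2, "B": 1, "ASC": 1, "NK": 1,
                    "DC": 1, "CD14myeloid": 1, "PMN": 1, "CD4": 1, "CD8": 1,
                    "CD4_CM": 1, "CD8_naive": 1, "B_nonASC": 0,
                    "lymphocytes": 4, "unassigned": 0, "nonMyeloid": 5}
        for name, n in expected.items():
            assert counts[name] == n, name

    def test_boundary_value_counts_as_positive(self, tree, thresholds):
        events = make_events([{"CD45": 2.0}])  # exactly at threshold
        counts = apply_gate_tree(events, tree, thresholds)
        assert counts["leukocytes"] == 1

    def test_missing_channel_named(self, tree, thresholds, toy_events):
        with pytest.raises(ValueError, match="CD3"):
            apply_gate_tree(toy_events.drop(columns=["CD3"]), tree, thresholds)

    def test_counts_frame_long_format(self, tree, thresholds, toy_events):
        counts = apply_gate_tree(toy_events, tree, thresholds, donor_id="toy")
        frame = counts_frame([counts])
        assert list(frame.columns) == ["donor_id", "population", "count"]
        assert len(frame) == len(tree.names)


@pytest.fixture(scope="module")
def donor_masks(nind_config, tree, thresholds):
    _, events = simulate_donor(nind_config, "NIND", 13)
    return events, gate_masks(events, tree, thresholds)


class TestGatingInvariants:
    def test_monotone_nesting(self, tree, donor_masks):
        _, masks = donor_masks
        for pop in tree:
            if pop.parent is not None:
                assert not (masks[pop.name] & ~masks[pop.parent]).any()

    def test_partition_conservation_exact(self, tree, donor_masks):
        _, masks = donor_masks
        for parent, siblings in EXHAUSTIVE_PARTITIONS.items():
            total = sum(int(masks[s].sum()) for s in siblings)
            assert total == int(masks[parent].sum())

    def test_row_permutation_invariance(self, nind_config, tree, thresholds):
        _, events = simulate_donor(nind_config, "NIND", 13)
        counts = apply_gate_tree(events, tree, thresholds)
        rng = np.random.default_rng(0)
        shuffled = events.iloc[rng.permutation(len(events))].reset_index(drop=True)
        assert apply_gate_tree(shuffled, tree, thresholds).counts == counts.counts

    def test_latent_label_oracle_agreement(self, nind_config, tree, thresholds):
        # with matched fixed thresholds and >=6 sigma separation, gated
        # lineage counts deviate from ground truth by < 0.1% of events
        _, events = simulate_donor(nind_config, "NIND", 17)
        counts = apply_gate_tree(events, tree, thresholds)
        truth = events["latent_label"].map(latent_lineage).value_counts()
        n = len(events)
        for lineage in ("T", "B", "NK", "DC", "CD14myeloid", "PMN", "unassigned"):
            assert abs(counts[lineage] - truth.get(lineage, 0)) <= max(1, 0.001 * n)
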