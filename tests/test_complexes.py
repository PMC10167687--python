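"""Complex hypothesis handling, decoys, detection, collapsing, differential."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import secdiff as sd


class TestReadHypotheses:
    def _write(self, path, rows):
        pd.DataFrame(rows, columns=["complex_id", "protein_id"]).to_csv(
            path, sep="\t", index=False)

    def test_basic_and_dedup(self, tmp_path):
        path = tmp_path / "h.tsv"
        self._write(path, [("C1", "A"), ("C1", "B"), ("C1", "C"), ("C1", "B")])
        hyps = sd.read_hypotheses(path)
        assert len(hyps) == 1
        assert hyps[0].subunits == frozenset({"A", "B", "C"})

    def test_single_subunit_dropped(self, tmp_path):
        path = tmp_path / "h.tsv"
        self._write(path, [("C1", "A"), ("C2", "X"), ("C2", "Y")])
        hyps = sd.read_hypotheses(path)
        assert [h.complex_id for h in hyps] == ["C2"]


class TestComplexDecoys:
    def test_path_graph_distance_constraint(self):
        g = nx.path_graph(["a", "b", "c", "d", "e"])
        hyp = sd.ComplexHypothesis("C1", {"a", "e"})
        decoys = sd.make_complex_decoys([hyp], g, min_edge_distance=3, seed=0)
        # the only admissible pairs on the path have distance >= 3
        for d in decoys:
            subs = sorted(d.subunits)
            assert nx.shortest_path_length(g, subs[0], subs[1]) >= 3

    def test_close_pair_rejected(self):
        g = nx.path_graph(["a", "b", "c"])
        hyp = sd.ComplexHypothesis("C1", {"a", "c"})  # distance 2 pair
        decoys = sd.make_complex_decoys([hyp], g, min_edge_distance=3, seed=1)
        assert decoys[0].relaxed_decoy  # no valid decoy exists on this graph

    def test_size_and_determinism(self):
        hyps = [sd.ComplexHypothesis(f"C{i}", {f"P{i}a", f"P{i}b", f"P{i}c"})
                for i in range(6)]
        d1 = sd.make_complex_decoys(hyps, seed=5)
        d2 = sd.make_complex_decoys(hyps, seed=5)
        assert len(d1) == len(hyps)
        assert [d.subunits for d in d1] == [d.subunits for d in d2]
        for d, h in zip(d1, sorted(hyps, key=lambda x: x.complex_id)):
            assert len(d.subunits) == len(h.subunits)
            assert d.is_decoy

    def test_no_graph_means_no_shared_membership(self):
        hyps = [sd.ComplexHypothesis("C1", {"A", "B", "C"}),
                sd.ComplexHypothesis("C2", {"D", "E", "F"})]
        decoys = sd.make_complex_decoys(hyps, seed=3)
        for d in decoys:
            if d.relaxed_decoy:
                continue
            for h in hyps:
                assert len(d.subunits & h.subunits) <= 1


class TestDetectComplexFeatures:
    def _setup(self, complex_mw, mmws, seed=0):
        """Three proteins coeluting at complex_mw plus their monomers."""
        mmw = dict(zip(["A", "B", "C"], mmws))
        states = [sd.StateSpec("CPX", ("A", "B", "C"), complex_mw,
                               {"c1": 3000.0, "c2": 3000.0})]
        for p, m in mmw.items():
            states.append(sd.StateSpec(f"{p}_mono", (p,), m,
                                       {"c1": 1000.0, "c2": 1000.0}))
        config = sd.SimulationConfig(
            protein_mmw=mmw, states=states, conditions=("c1", "c2"),
            noise_cv=0.05, seed=seed,
        )
        ds = sd.simulate(config)
        prot = sd.quantify_proteins(ds.traces)
        hyp = sd.ComplexHypothesis("CPX", frozenset(["A", "B", "C"]))
        decoy = sd.ComplexHypothesis("DECOY_CPX", frozenset(["A", "B", "C"]),
                                     source="decoy")
        return ds, prot, hyp

    def test_high_mw_feature_kept(self):
        ds, prot, hyp = self._setup(600.0, [100.0, 80.0, 60.0])
        acc, primaries, _, _ = sd.detect_complex_features(
            [hyp], [], prot, calibration=ds.calibration,
            mw_annotation=ds.mw_annotation)
        assert len(acc) == 1
        assert acc[0].apex_mw > 2 * 100.0
        assert sd.completeness_class(acc[0]) == "full"

    def test_low_mw_feature_discarded(self):
        # coelution at 150 kDa with max subunit MMW 100 -> fails 2x filter
        ds, prot, hyp = self._setup(150.0, [100.0, 80.0, 60.0])
        acc, primaries, _, _ = sd.detect_complex_features(
            [hyp], [], prot, calibration=ds.calibration,
            mw_annotation=ds.mw_annotation)
        assert primaries == [] and acc == []

    def test_mw_filter_invariant_on_benchmark(self):
        config, hyps, real, null = sd.complex_benchmark(
            n_real=4, n_null=10, seed=2)
        ds = sd.simulate(config)
        prot = sd.quantify_proteins(ds.traces)
        decoys = sd.make_complex_decoys(hyps, seed=8)
        acc, *_ = sd.detect_complex_features(
            hyps, decoys, prot, calibration=ds.calibration,
            mw_annotation=ds.mw_annotation)
        for f in acc:
            owner = next(h for h in hyps if h.complex_id == f.owner_id)
            max_mmw = max(ds.mw_annotation.get(s) for s in owner.subunits)
            assert f.apex_mw > 2 * max_mmw


class TestCollapseFeatures:
    def _feat(self, owner, members, apex, score=0.95):
        return sd.ElutionFeature(owner, list(members), apex, apex - 2,
                                 apex + 2, coelution_score=score)

    def test_same_subunits_close_apex_collapsed(self):
        f1 = self._feat("C1", ["A", "B", "C"], 20)
        f2 = self._feat("C2", ["A", "B", "C"], 21)
        reps, mapping = sd.collapse_features([f1, f2], distance_cutoff=1.25)
        assert len(reps) == 1

    def test_disjoint_subunits_not_collapsed(self):
        f1 = self._feat("C1", ["A", "B"], 20)
        f2 = self._feat("C2", ["X", "Y"], 20)
        reps, _ = sd.collapse_features([f1, f2])
        assert len(reps) == 2

    def test_single_linkage_chain(self):
        # A~B and B~C but A and C too far apart: one group regardless
        f1 = self._feat("C1", ["A", "B"], 20.0)
        f2 = self._feat("C2", ["B", "C"], 21.0)
        f3 = self._feat("C3", ["C", "D"], 22.0)
        reps, mapping = sd.collapse_features([f1, f2, f3])
        # brute-force connected components over the linkage predicate
        feats = [f1, f2, f3]
        g = nx.Graph()
        g.add_nodes_from(range(3))
        for i in range(3):
            for j in range(i + 1, 3):
                if abs(feats[i].apex_fraction - feats[j].apex_fraction) <= 1.25 \
                        and set(feats[i].member_ids) & set(feats[j].member_ids):
                    g.add_edge(i, j)
        assert len(reps) == nx.number_connected_components(g) == 1

    def test_representative_is_largest_then_best(self):
        f1 = self._feat("C1", ["A", "B"], 20, score=0.99)
        f2 = self._feat("C2", ["A", "B", "C"], 20.5, score=0.92)
        reps, _ = sd.collapse_features([f1, f2])
        assert reps[0].owner_id == "C2"

    def test_idempotence(self):
        rng = np.random.default_rng(6)
        feats = [self._feat(f"C{i}", rng.choice(list("ABCDEFGH"), 3,
                                                replace=False),
                            float(rng.uniform(5, 45)))
                 for i in range(12)]
        once, _ = sd.collapse_features(feats)
        twice, _ = sd.collapse_features(once)
        assert [(f.owner_id, f.apex_fraction) for f in once] == \
            [(f.owner_id, f.apex_fraction) for f in twice]


class TestComplexDifferential:
    def test_uniform_fourfold_complex(self):
        mmw = {"A": 50.0, "B": 60.0, "C": 40.0}
        states = [sd.StateSpec("CPX", ("A", "B", "C"), 600.0,
                               {"c1": 4000.0, "c2": 1000.0})]
        config = sd.SimulationConfig(
            protein_mmw=mmw, states=states, conditions=("c1", "c2"),
            noise_cv=0.0, seed=3,
        )
        ds = sd.simulate(config)
        feat = sd.ElutionFeature("CPX", ["A", "B", "C"],
                                 apex_fraction=8, left_boundary=2,
                                 right_boundary=14)
        res = sd.complex_differential([feat], ds.traces, ds.design,
                                      "c1", "c2",
                                      rng=np.random.default_rng(0))
        assert len(res) == 1
        assert res[0].log2fc == pytest.approx(2.0, abs=0.05)
        assert res[0].significant

    def test_complex_without_peptides_omitted(self):
        mmw = {"A": 50.0}
        states = [sd.StateSpec("A_mono", ("A",), 50.0, {"c1": 100.0,
                                                        "c2": 100.0})]
        config = sd.SimulationConfig(protein_mmw=mmw, states=states,
                                     conditions=("c1", "c2"), seed=0)
        ds = sd.simulate(config)
        feat = sd.ElutionFeature("GHOST", ["X", "Y"], 10, 5, 15)
        res = sd.complex_differential([feat], ds.traces, ds.design,
                                      "c1", "c2")
        assert res == []
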