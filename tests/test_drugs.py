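"""Signature reversal scoring and the two-gate repurposing shortlist."""

import numpy as np
import pytest

from mpem_interactome import interactome as inter
from mpem_interactome.drugs import (
    DESignature,
    DrugRecord,
    drug_target_summary,
    read_drug_targets,
    read_signature,
    shortlist,
    signature_correlation,
    write_signature,
)
from mpem_interactome.io import EdgeRecord, ValidationError


def sig(name, values):
    return DESignature(name=name, lfc={f"G{i}": v for i, v in enumerate(values)})


@pytest.fixture
def net():
    return inter.assemble(
        ["S1"], [EdgeRecord.make("S1", f"G{i}") for i in range(3)]
    )


class TestSignatureCorrelation:
    def test_exact_negation_gives_rho_minus_one(self):
        base = sig("disease", np.linspace(-2, 2, 20))
        drug = sig("drug", -np.linspace(-2, 2, 20))
        rho, p, n = signature_correlation(drug, base)
        assert rho == pytest.approx(-1.0)
        assert n == 20

    def test_identity_gives_rho_plus_one(self):
        base = sig("disease", np.linspace(-2, 2, 20))
        assert signature_correlation(base, base)[0] == pytest.approx(1.0)

    def test_too_few_shared_genes_absent(self):
        a = DESignature("a", {f"A{i}": 1.0 * i for i in range(12)})
        b = DESignature("b", {f"B{i}": 1.0 * i for i in range(12)})
        assert signature_correlation(a, b) is None

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        vals = rng.standard_normal(50)
        base = sig("disease", vals)
        drug = sig("drug", rng.standard_normal(50))
        rho1, *_ = signature_correlation(drug, base)
        transformed = sig("disease2", np.exp(vals) + 5)
        rho2, *_ = signature_correlation(drug, transformed)
        assert rho1 == pytest.approx(rho2)

    def test_null_shuffles_concentrate_near_zero(self):
        rng = np.random.default_rng(5)
        vals = rng.standard_normal(1000)
        base = sig("disease", vals)
        ok = 0
        for _ in range(100):
            drug = sig("drug", rng.permutation(vals))
            rho, *_ = signature_correlation(drug, base)
            ok += abs(rho) < 0.1
        assert ok >= 95


class TestShortlist:
    def _drug(self, did, values, targets):
        return DrugRecord(did, did, frozenset(targets), sig(did, values))

    def test_target_gate_excludes_strong_reverser(self, net):
        base = sig("disease", np.linspace(-2, 2, 30))
        off_target = self._drug("D1", -np.linspace(-2, 2, 30), {"ZZZ"})
        assert shortlist([off_target], [base], net) == []

    def test_single_dataset_reverser_shortlisted(self, net):
        base = sig("disease", np.linspace(-2, 2, 30))
        drug = self._drug("D1", -np.linspace(-2, 2, 30), {"G1"})
        (cand,) = shortlist([drug], [base], net)
        assert cand.n_negative == 1
        assert cand.group == "single_dataset"
        assert cand.targeted_nodes == {"G1": "known_interactor"}

    def test_gate_order_irrelevance(self, net):
        rng = np.random.default_rng(7)
        base = sig("disease", rng.standard_normal(40))
        drugs = [
            self._drug(f"D{i}", rng.standard_normal(40), {"G1"} if i % 2 else {"ZZ"})
            for i in range(10)
        ]
        drugs += [self._drug("DREV", -np.array(list(base.lfc.values())), {"G2"})]
        full = {c.drug_id for c in shortlist(drugs, [base], net)}
        # manual two-gate application in the reverse order
        targeting = [d for d in drugs if d.targets & set(net.node_class)]
        manual = {c.drug_id for c in shortlist(targeting, [base], net)}
        assert full == manual

    def test_min_datasets_monotonicity(self, net):
        rng = np.random.default_rng(9)
        sigs = [sig(f"dis{j}", rng.standard_normal(40)) for j in range(3)]
        drugs = []
        for i in range(12):
            vals = -np.array(list(sigs[i % 3].lfc.values())) + 0.5 * rng.standard_normal(40)
            drugs.append(self._drug(f"D{i}", vals, {"G1"}))
        n1 = len(shortlist(drugs, sigs, net, min_datasets=1))
        n2 = len(shortlist(drugs, sigs, net, min_datasets=2))
        n3 = len(shortlist(drugs, sigs, net, min_datasets=3))
        assert n1 >= n2 >= n3

    def test_drug_without_signature_excluded(self, net):
        base = sig("disease", np.linspace(-2, 2, 30))
        bare = DrugRecord("D0", "D0", frozenset({"G1"}), None)
        assert shortlist([bare], [base], net) == []


class TestDrugTargetSummary:
    def test_empty_library_zeros(self, net):
        summary = drug_target_summary([], net)
        assert summary == {
            "n_drugs_targeting": 0,
            "n_targeted_nodes": 0,
            "n_targeted_by_class": {},
        }

    def test_single_seed_targeting_drug(self, net):
        d = DrugRecord("D1", "D1", frozenset({"S1"}))
        summary = drug_target_summary([d], net)
        assert summary["n_drugs_targeting"] == 1
        assert summary["n_targeted_by_class"] == {"seed": 1}

    def test_union_counting_matches_brute_force(self, net):
        rng = np.random.default_rng(3)
        pool = list(net.node_class) + ["X1", "X2"]
        drugs = [
            DrugRecord(f"D{i}", f"D{i}", frozenset(rng.choice(pool, 3, replace=False)))
            for i in range(8)
        ]
        summary = drug_target_summary(drugs, net)
        brute = set().union(*(d.targets for d in drugs)) & set(net.node_class)
        assert summary["n_targeted_nodes"] == len(brute)


def test_signature_and_target_file_round_trip(tmp_path):
    s = sig("drugA", np.linspace(-1, 1, 15))
    p = tmp_path / "drugA.tsv"
    write_signature(p, s)
    back = read_signature(p)
    assert back.lfc == pytest.approx(s.lfc)

    t = tmp_path / "targets.tsv"
    t.write_text("drug_id\tname\ttarget_symbol\nD1\tdrug-1\tBAP1\nD1\tdrug-1\tNF2\n")
    (rec,) = read_drug_targets(t)
    assert rec.targets == {"BAP1", "NF2"}
    with pytest.raises(ValidationError):
        read_drug_targets(p)
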