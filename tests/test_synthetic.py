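"""Generator contracts: determinism, planted structure, validator compliance."""

import numpy as np
import pytest

from mpem_interactome.io import ValidationError
from mpem_interactome.survival import logrank
from mpem_interactome.synthetic import (
    DEFAULT_TISSUES,
    generate_disease_signatures,
    generate_disease_study,
    generate_drug_library,
    generate_labeled_pairs,
    generate_survival_cohort,
    generate_tissue_matrix,
    generate_world,
)
from mpem_interactome.tissue import TissueSpecificityCall, classify


class TestWorld:
    def test_reproducible_and_seed_sensitive(self):
        w1 = generate_world(500, seed=1)
        w2 = generate_world(500, seed=1)
        assert w1.truth_edges == w2.truth_edges
        assert w1.resource.expression.equals(w2.resource.expression)
        others = [generate_world(500, seed=s).truth_edges for s in range(2, 6)]
        assert all(e != w1.truth_edges for e in others)

    def test_degree_distribution_heavy_tailed(self):
        w = generate_world(500, seed=1)
        degrees = np.array([d for _, d in w.truth.degree])
        assert degrees.max() >= 5 * np.median(degrees)

    def test_no_self_loops(self):
        w = generate_world(200, seed=3)
        assert all(a != b for a, b in w.truth.edges)


class TestLabeledPairs:
    def test_positives_are_edges_negatives_are_not(self):
        w = generate_world(600, seed=2)
        pairs, _ = generate_labeled_pairs(w, 50, 50, signal=0.5, seed=2)
        for (a, b), lab in pairs:
            assert w.truth.has_edge(a, b) == bool(lab)

    def test_zero_positives_rejected(self):
        w = generate_world(300, seed=2)
        with pytest.raises(ValidationError):
            generate_labeled_pairs(w, 0, 10, signal=0.5, seed=1)

    def test_pairs_are_disjoint(self):
        w = generate_world(600, seed=4)
        pairs, _ = generate_labeled_pairs(w, 60, 60, signal=1.0, seed=4)
        flat = [g for p, _ in pairs for g in p]
        assert len(flat) == len(set(flat))


class TestDiseaseStudy:
    def test_null_odds_ratio_near_one_over_seeds(self):
        from mpem_interactome.enrichment import hypergeom_overlap

        nodes = [f"G{i:04d}" for i in range(1, 1001)]
        ors = []
        for s in range(1, 51):
            study = generate_disease_study(nodes, 1.0, 500, 10000, seed=s)
            r = hypergeom_overlap(nodes, study.sets["DEG"], study.universe)
            ors.append(r.odds_ratio)
        assert 0.9 <= np.mean(ors) <= 1.1

    def test_oversized_set_rejected(self):
        with pytest.raises(ValidationError):
            generate_disease_study(["A"], 1.0, set_size=50, universe_size=20, seed=1)


class TestTissueMatrix:
    def test_zero_noise_recovers_all_planted_categories(self):
        planted = {
            "T0001": TissueSpecificityCall("T0001", "tissue_enriched", ("spleen",)),
            "T0002": TissueSpecificityCall("T0002", "group_enriched", ("spleen", "thymus", "brain")),
            "T0003": TissueSpecificityCall("T0003", "tissue_enhanced", ("lung",)),
        }
        m = generate_tissue_matrix(20, planted=planted, noise_cv=0.0, seed=1)
        calls = {c.gene: c for c in classify(m)}
        for g, want in planted.items():
            assert calls[g].category == want.category
            assert set(want.tissues) <= set(calls[g].tissues) or calls[g].tissues == want.tissues
        assert calls["T0010"].category == "not_specific"

    def test_oversized_group_rejected(self):
        from types import SimpleNamespace

        bad = SimpleNamespace(
            gene="T0001", category="group_enriched", tissues=tuple(DEFAULT_TISSUES[:8])
        )
        with pytest.raises(ValidationError):
            generate_tissue_matrix(10, planted={"T0001": bad}, noise_cv=0.0, seed=1)


class TestSurvivalCohort:
    def test_null_logrank_p_uniform(self):
        """Under hazard ratio 1 the screen's p-values are uniform (KS)."""
        from scipy import stats

        pvals = []
        for s in range(400):
            c = generate_survival_cohort(60, ["G"], planted_hr={}, seed=s)
            x = c.expression["G"].to_numpy()
            _, p = logrank(c.time, c.event, x > np.median(x))
            pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_full_censoring_branch(self):
        c = generate_survival_cohort(30, ["G"], censor_rate=1.0, seed=2)
        assert c.event.sum() == 0
        x = c.expression["G"].to_numpy()
        assert logrank(c.time, c.event, x > np.median(x))[1] == 1.0

    def test_censor_rate_controls_fraction(self):
        c = generate_survival_cohort(2000, ["G"], censor_rate=0.3, seed=3)
        assert 0.2 < 1 - c.event.mean() < 0.4


class TestDrugLibrary:
    def test_zero_noise_planted_rho_is_minus_one(self):
        from mpem_interactome.drugs import signature_correlation

        sigs = generate_disease_signatures(1, 100, seed=1)
        lib = generate_drug_library(5, sigs, ["D001"], noise_sd=0.0, seed=1)
        planted = next(d for d in lib if d.drug_id == "D001")
        rho, *_ = signature_correlation(planted.signature, sigs[0])
        assert rho == pytest.approx(-1.0)

    def test_empty_library(self):
        sigs = generate_disease_signatures(1, 100, seed=1)
        assert generate_drug_library(0, sigs, [], noise_sd=0.1, seed=1) == []

    def test_noisy_planted_drug_ranks_top_decile(self):
        from mpem_interactome.drugs import signature_correlation

        sigs = generate_disease_signatures(3, 200, seed=5)
        lib = generate_drug_library(50, sigs, ["D001"], noise_sd=0.5, seed=5)
        mean_rho = {
            d.drug_id: np.mean([signature_correlation(d.signature, s)[0] for s in sigs])
            for d in lib
        }
        ranked = sorted(mean_rho, key=mean_rho.get)
        assert ranked.index("D001") < 5  # top 10% of 50
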