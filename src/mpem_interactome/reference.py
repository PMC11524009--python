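"""Published reference values for the MPeM interactome study.

These numbers depend on external resources — GEO expression series, the
GTEx and mouse ENCODE atlases, the pleural-mesothelioma (MPM)
interactome, the HumanBase functional networks, DrugBank and a
proprietary correlation engine — and on background universes that were
never stated, so they cannot be recomputed from packaged data.  They are
retained here purely as documented reference cases for users who load
those external resources themselves; nothing in the package asserts
against them.
"""

from __future__ import annotations

REFERENCE_CASES: dict[str, dict] = {
    "mpm_interactome_overlap": {
        "description": "MPeM vs MPM interactome node overlap",
        "n_shared": 989,
        "p": 3.18e-289,
        "odds_ratio": 2.92,
        "requires": "the prior MPM interactome file",
        "reproducible_from_packaged_data": False,
    },
    "spleen_specific_enrichment": {
        "description": "human orthologues of mouse spleen-specific genes in the interactome",
        "n_genes": 81,
        "p": 0.019,
        "odds_ratio": 1.39,
        "requires": "mouse ENCODE tissue-specific gene lists",
        "reproducible_from_packaged_data": False,
    },
    "thymus_specific_enrichment": {
        "description": "human orthologues of mouse thymus-specific genes in the interactome",
        "n_genes": 57,
        "p": 0.028,
        "odds_ratio": 1.42,
        "requires": "mouse ENCODE tissue-specific gene lists",
        "reproducible_from_packaged_data": False,
    },
    "biphasic_subtype_enrichment": {
        "description": "biphasic-vs-epithelial MPeM DEGs in the interactome",
        "n_genes": 118,
        "p": 2.17e-19,
        "odds_ratio": 2.25,
        "requires": "the biphasic/epithelial tumour DEG lists",
        "reproducible_from_packaged_data": False,
    },
    "functional_modules": {
        "description": "functional modules detected on tissue-specific functional networks",
        "n_modules": 14,
        "n_modules_over_4_proteins": 11,
        "requires": "HumanBase pretrained networks",
        "reproducible_from_packaged_data": False,
    },
    "drug_shortlist": {
        "description": "repurposable drug shortlist",
        "n_drugs_total": 39,
        "n_multi_dataset": 23,
        "n_single_dataset": 16,
        "n_drugs_targeting_interactome": 152,
        "n_targeted_proteins": 427,
        "requires": "DrugBank targets and the proprietary correlation engine's scores",
        "reproducible_from_packaged_data": False,
    },
    "interactome_global_counts": {
        "description": "global interactome accounting as published",
        "n_known_ppis": 4747,
        "n_novel_ppis": 417,
        "n_known_interactors": 2747,
        "n_novel_interactors": 306,
        "requires": "the unprinted known-PPI edge lists for all but the novel-PPI counts",
        "reproducible_from_packaged_data": False,
    },
}


def reference_cases() -> dict[str, dict]:
    """Documented published values that require external resources."""
    return {k: dict(v) for k, v in REFERENCE_CASES.items()}
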