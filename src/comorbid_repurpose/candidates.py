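"""Candidate-drug generation and the drug x disease pair table.

A drug is a candidate for a complex disease when it targets a causal gene
of some Mendelian disease comorbid with that complex disease.  The pair
table is the full cross product of the drug universe (all drugs targeting
at least one Mendelian causal gene) with the complex-disease universe,
carrying the candidate flag, the chosen outcome, and the regression
covariates (disease category, number of drug targets).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .core import (
    Bundle,
    ClinicalEvidence,
    ComorbidityMap,
    ComplexDisease,
    DrugTargetMap,
    MendelianDisease,
    PhaseGroup,
)

logger = logging.getLogger(__name__)

__all__ = [
    "OUTCOME_DEFS",
    "CandidateSet",
    "candidate_drugs",
    "build_candidate_set",
    "drug_universe",
    "build_pair_table",
]

#: Valid outcome definitions for :func:`build_pair_table`.
OUTCOME_DEFS = (
    "investigated_or_indicated",
    "investigated_only",
    "indicated_only",
    "phase_1",
    "phase_2",
    "phase_3",
    "phases_1_3",
)

_PHASE_K = {
    "phase_1": PhaseGroup.PHASE_I,
    "phase_2": PhaseGroup.PHASE_II,
    "phase_3": PhaseGroup.PHASE_III,
}


@dataclass(frozen=True)
class CandidateSet:
    """Candidate drugs per complex disease, with supporting provenance.

    ``provenance`` is a long-format frame with one row per supporting
    (drug, complex, mendelian, gene) quadruple.
    """

    drugs: Mapping[str, frozenset[str]]
    provenance: pd.DataFrame

    def is_candidate(self, drug_id: str, complex_id: str) -> bool:
        return drug_id in self.drugs.get(complex_id, frozenset())


def candidate_drugs(
    complex_id: str,
    comorbidity: ComorbidityMap,
    mendelian: Mapping[str, MendelianDisease],
    drug_targets: DrugTargetMap,
) -> tuple[frozenset[str], list[tuple[str, str, str, str]]]:
    """Candidate drugs for one complex disease.

    Returns the drug set and provenance rows (drug, complex, mendelian,
    gene).  A drug is included iff some comorbid Mendelian disease has a
    causal gene in the drug's target set.  An empty result is valid.
    """
    gene_to_drugs = drug_targets.gene_to_drugs
    drugs: set[str] = set()
    provenance: list[tuple[str, str, str, str]] = []
    for mid in sorted(comorbidity.mendelian_for(complex_id)):
        for gene in sorted(mendelian[mid].causal_genes):
            for drug in sorted(gene_to_drugs.get(gene, frozenset())):
                drugs.add(drug)
                provenance.append((drug, complex_id, mid, gene))
    return frozenset(drugs), provenance


def build_candidate_set(bundle: Bundle) -> CandidateSet:
    """Candidates for every registered complex disease."""
    per_disease: dict[str, frozenset[str]] = {}
    rows: list[tuple[str, str, str, str]] = []
    for cid in sorted(bundle.complex):
        drugs, prov = candidate_drugs(
            cid, bundle.comorbidity, bundle.mendelian, bundle.drug_targets
        )
        per_disease[cid] = drugs
        rows.extend(prov)
    provenance = pd.DataFrame(
        rows, columns=["drug_id", "complex_id", "mendelian_id", "gene"]
    )
    return CandidateSet(drugs=per_disease, provenance=provenance)


def drug_universe(bundle: Bundle) -> list[str]:
    """All drugs targeting at least one Mendelian causal gene, sorted."""
    genes = bundle.mendelian_genes
    return sorted(
        d for d, tg in bundle.drug_targets.targets.items() if tg & genes
    )


def _outcome(
    drug_id: str,
    complex_id: str,
    evidence: ClinicalEvidence,
    outcome_def: str,
    include_unknown: bool,
) -> int:
    has_trial = evidence.has_trial(drug_id, complex_id)
    if has_trial and not include_unknown:
        ph = evidence.phases[(drug_id, complex_id)]
        has_trial = ph is not PhaseGroup.UNKNOWN
    indicated = (drug_id, complex_id) in evidence.indicated
    if outcome_def == "investigated_or_indicated":
        return int(has_trial or indicated)
    if outcome_def == "investigated_only":
        return int(has_trial)
    if outcome_def == "indicated_only":
        return int(indicated)
    mp = evidence.max_phase(drug_id, complex_id)
    if outcome_def == "phases_1_3":
        return int(
            mp in (PhaseGroup.PHASE_I, PhaseGroup.PHASE_II, PhaseGroup.PHASE_III)
        )
    return int(mp is _PHASE_K[outcome_def])


def build_pair_table(
    drugs: Iterable[str],
    diseases: Mapping[str, ComplexDisease],
    candidates: CandidateSet,
    evidence: ClinicalEvidence,
    drug_targets: DrugTargetMap,
    outcome_def: str = "investigated_or_indicated",
    include_unknown: bool = True,
) -> pd.DataFrame:
    """Full drug x disease cross product with flags and covariates.

    Columns: drug_id, complex_id, is_candidate, outcome, category,
    n_targets, phase (most advanced evidence label or empty).  Outcome
    definitions: ``investigated_or_indicated`` (any trial — including
    unknown phase unless ``include_unknown`` is False — or indicated),
    ``investigated_only``, ``indicated_only``, ``phase_k`` (most advanced
    evidence is exactly phase k), ``phases_1_3`` (most advanced evidence
    in phases I-III).  Pure function of its inputs.
    """
    if outcome_def not in OUTCOME_DEFS:
        raise ValueError(f"unknown outcome_def {outcome_def!r}; use one of {OUTCOME_DEFS}")
    drug_list = sorted(drugs)
    if not drug_list:
        raise ValueError("no druggable Mendelian genes: empty drug universe")
    rows = []
    for drug in drug_list:
        nt = drug_targets.n_targets(drug)
        for cid in sorted(diseases):
            mp = evidence.max_phase(drug, cid)
            rows.append(
                (
                    drug,
                    cid,
                    int(candidates.is_candidate(drug, cid)),
                    _outcome(drug, cid, evidence, outcome_def, include_unknown),
                    diseases[cid].category,
                    nt,
                    mp.label if mp is not None else "",
                )
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "drug_id",
            "complex_id",
            "is_candidate",
            "outcome",
            "category",
            "n_targets",
            "phase",
        ],
    )
    logger.info(
        "pair table: %d rows (%d drugs x %d diseases), %d candidate, %d positive",
        len(table),
        len(drug_list),
        len(diseases),
        int(table["is_candidate"].sum()),
        int(table["outcome"].sum()),
    )
    return table
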