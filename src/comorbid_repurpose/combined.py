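"""Stratification of drug-cancer pairs by comorbidity and similarity support.

A drug's provenance for a cancer is the set of Mendelian diseases whose
causal genes it targets.  A (drug, cancer) pair is comorbidity-supported
when some provenance disease is comorbid with the cancer, and
similarity-supported when some provenance disease is genetically similar
to it.  "Both" support defaults to the strict reading — a single
provenance disease that is simultaneously comorbid and similar (shared
etiology of one disease pair) — with the looser any-disease reading as an
option.  Enrichment is then fit within conditioning subsets, adjusted for
n_targets only (category is constant across cancers).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import pandas as pd

from .core import Bundle, ComorbidityMap, DrugTargetMap, MendelianDisease
from .enrichment import EnrichmentResult, fit_enrichment

logger = logging.getLogger(__name__)

__all__ = ["STRATUM_LABELS", "stratify_drug_cancer_pairs", "fit_per_stratum"]

STRATUM_LABELS = ("comorbid_and_similar", "comorbid_only", "similar_only", "neither")


def _provenance_diseases(
    drug_targets: DrugTargetMap, mendelian: Mapping[str, MendelianDisease]
) -> dict[str, frozenset[str]]:
    """drug → Mendelian diseases whose causal genes it targets."""
    out: dict[str, frozenset[str]] = {}
    for drug, genes in drug_targets.targets.items():
        out[drug] = frozenset(
            m.id for m in mendelian.values() if m.causal_genes & genes
        )
    return out


def stratify_drug_cancer_pairs(
    drugs: Iterable[str],
    cancer_ids: Iterable[str],
    comorbidity: ComorbidityMap,
    similar: Mapping[tuple[str, str], bool],
    drug_targets: DrugTargetMap,
    mendelian: Mapping[str, MendelianDisease],
    mode: str = "same_disease",
) -> pd.DataFrame:
    """Label every (drug, cancer) pair with its support stratum.

    ``similar`` maps (mendelian_id, cancer_id) to the similarity verdict;
    missing pairs count as not similar.  ``mode`` controls the "both"
    label: ``same_disease`` (default) requires one provenance disease that
    is both comorbid and similar; ``any_disease`` only requires the two
    flags to hold, possibly via different diseases.  Returns one row per
    pair with boolean support flags and a partition label.
    """
    if mode not in ("same_disease", "any_disease"):
        raise ValueError(f"unknown support mode {mode!r}")
    provenance = _provenance_diseases(drug_targets, mendelian)
    rows = []
    for drug in sorted(set(drugs)):
        prov = provenance.get(drug, frozenset())
        for cancer in sorted(set(cancer_ids)):
            com = {m for m in prov if (m, cancer) in comorbidity}
            sim = {m for m in prov if similar.get((m, cancer), False)}
            comorbid_support = bool(com)
            similarity_support = bool(sim)
            if mode == "same_disease":
                both = bool(com & sim)
            else:
                both = comorbid_support and similarity_support
            if both:
                label = "comorbid_and_similar"
            elif comorbid_support:
                label = "comorbid_only"
            elif similarity_support:
                label = "similar_only"
            else:
                label = "neither"
            rows.append(
                {
                    "drug_id": drug,
                    "cancer_id": cancer,
                    "comorbid_support": comorbid_support,
                    "similarity_support": similarity_support,
                    "both_support": both,
                    "label": label,
                }
            )
    out = pd.DataFrame(rows)
    counts = out["label"].value_counts().to_dict()
    logger.info("stratified %d drug-cancer pairs: %s", len(out), counts)
    return out


def fit_per_stratum(
    pair_table: pd.DataFrame,
    strata: pd.DataFrame,
    contrast: str = "similarity_support",
    condition: Mapping[str, object] | None = None,
    adjust: Iterable[str] = ("n_targets",),
) -> EnrichmentResult:
    """Enrichment of the outcome on a support flag within a subset.

    ``pair_table`` must carry (drug_id, complex_id, outcome, n_targets)
    rows for the cancers; it is joined to ``strata`` on
    (drug_id, complex_id == cancer_id).  ``condition`` filters rows by
    exact match (e.g. ``{"comorbid_support": False}``) before fitting
    outcome ~ contrast + n_targets.
    """
    merged = pair_table.merge(
        strata,
        left_on=["drug_id", "complex_id"],
        right_on=["drug_id", "cancer_id"],
        how="inner",
        validate="one_to_one",
    )
    if merged.empty:
        raise ValueError("no overlap between pair table and strata")
    if condition:
        for col, value in condition.items():
            merged = merged[merged[col] == value]
    if merged[contrast].nunique() < 2:
        raise ValueError(f"contrast {contrast!r} has a single level in this subset")
    merged = merged.assign(is_candidate=merged[contrast].astype(int))
    return fit_enrichment(merged, adjust=adjust)


def stratify_bundle(
    bundle: Bundle,
    cancer_ids: Iterable[str],
    similar: Mapping[tuple[str, str], bool],
    drugs: Iterable[str],
    mode: str = "same_disease",
) -> pd.DataFrame:
    """Convenience wrapper over :func:`stratify_drug_cancer_pairs`."""
    return stratify_drug_cancer_pairs(
        drugs,
        cancer_ids,
        bundle.comorbidity,
        similar,
        bundle.drug_targets,
        bundle.mendelian,
        mode=mode,
    )
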