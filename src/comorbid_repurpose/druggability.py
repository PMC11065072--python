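"""Per-Mendelian-disease and per-gene enrichment, and druggability ranking.

Each "unit" is either a Mendelian disease or a single causal gene.  The
unit's candidate flag restricts the global definition to drugs targeting
the unit's genes and complex diseases comorbid with the unit (a gene
inherits the comorbidities of every Mendelian disease listing it).  Units
are gated by the drug-target rewiring null, and significant units are
compared with the rest on the number of drugs targeting them with a
one-sided rank-sum test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .candidates import build_pair_table, drug_universe
from .core import Bundle, ComorbidityMap
from .enrichment import EnrichmentResult, fit_enrichment
from .permutation import (
    PermutationResult,
    permutation_pvalue,
    rewired_drug_targets,
)
from .stat_tests import rank_sum_greater

logger = logging.getLogger(__name__)

__all__ = [
    "UnitResult",
    "unit_genes",
    "unit_comorbid",
    "unit_drugs",
    "per_unit_enrichment",
    "prioritize_units",
    "compare_drug_counts",
    "druggability_permutation_gate",
]


@dataclass(frozen=True)
class UnitResult:
    """Per-unit enrichment, permutation gate, and drug count."""

    unit_id: str
    level: str  # "disease" | "gene"
    n_drugs: int
    enrichment: EnrichmentResult
    perm: PermutationResult | None
    category_dropped: bool = False

    @property
    def significant(self) -> bool:
        return self.perm is not None and self.perm.p_perm < 0.05


def unit_genes(unit_id: str, level: str, bundle: Bundle) -> frozenset[str]:
    """The gene set defining a unit."""
    if level == "disease":
        return bundle.mendelian[unit_id].causal_genes
    if level == "gene":
        return frozenset([unit_id])
    raise ValueError(f"unknown unit level {level!r}")


def unit_comorbid(unit_id: str, level: str, bundle: Bundle) -> frozenset[str]:
    """Complex diseases comorbid with the unit.

    A gene inherits the comorbid complex diseases of every Mendelian
    disease carrying it as a causal gene.
    """
    if level == "disease":
        return bundle.comorbidity.complex_for(unit_id)
    out: set[str] = set()
    for m in bundle.mendelian.values():
        if unit_id in m.causal_genes:
            out |= bundle.comorbidity.complex_for(m.id)
    return frozenset(out)


def unit_drugs(
    genes: frozenset[str], gene_to_drugs: Mapping[str, frozenset[str]]
) -> frozenset[str]:
    out: set[str] = set()
    for g in genes:
        out |= gene_to_drugs.get(g, frozenset())
    return frozenset(out)


def _unit_candidate_flag(
    table: pd.DataFrame, drugs: frozenset[str], comorbid: frozenset[str]
) -> np.ndarray:
    return (
        table["drug_id"].isin(drugs) & table["complex_id"].isin(comorbid)
    ).to_numpy(dtype=int)


def _unit_or(
    table: pd.DataFrame,
    drugs: frozenset[str],
    comorbid: frozenset[str],
    adjust: tuple[str, ...],
    weights: str,
) -> float:
    """Refit the unit model with a replacement candidate flag; NaN on
    separation (so permutation replicates are excluded, not counted)."""
    sub = table.assign(is_candidate=_unit_candidate_flag(table, drugs, comorbid))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        res = fit_enrichment(sub, adjust=adjust, weights=weights)
    if res.separated:
        return float("nan")
    return res.odds_ratio


def per_unit_enrichment(
    unit_id: str,
    level: str,
    bundle: Bundle,
    base_table: pd.DataFrame | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    weights: str = "none",
) -> UnitResult:
    """Enrichment of the unit's drugs among evidence for its comorbid
    diseases, gated by the drug-target rewiring null.

    The pair table is the full drug x disease universe with the candidate
    flag redefined for this unit.  The category covariate is dropped when
    the unit's comorbid diseases fall in a single category (the flag would
    be nested in it); ``n_targets`` is always kept and is held at its
    observed values under rewiring (an intrinsic drug property).
    """
    genes = unit_genes(unit_id, level, bundle)
    comorbid = unit_comorbid(unit_id, level, bundle)
    if not comorbid:
        raise ValueError(f"unit {unit_id!r} has no comorbid complex diseases")
    gene_to_drugs = bundle.drug_targets.gene_to_drugs
    drugs = unit_drugs(genes, gene_to_drugs)
    if not drugs:
        raise ValueError(f"unit {unit_id!r} is targeted by no drug")

    if base_table is None:
        from .candidates import build_candidate_set

        base_table = build_pair_table(
            drug_universe(bundle),
            bundle.complex,
            build_candidate_set(bundle),
            bundle.evidence,
            bundle.drug_targets,
        )

    categories = {bundle.complex[c].category for c in comorbid}
    drop_category = len(categories) < 2
    adjust = ("n_targets",) if drop_category else ("category", "n_targets")
    if drop_category:
        logger.debug("unit %s: category covariate dropped (single category)", unit_id)

    table = base_table.assign(
        is_candidate=_unit_candidate_flag(base_table, drugs, comorbid)
    )
    enr = fit_enrichment(table, adjust=adjust, weights=weights)

    all_drugs = sorted(set(base_table["drug_id"]))

    def analysis(rng: np.random.Generator) -> float:
        g2d = rewired_drug_targets(bundle.drug_targets, genes, all_drugs, rng)
        return _unit_or(base_table, unit_drugs(genes, g2d), comorbid, adjust, weights)

    perm = None
    if n_perm > 0 and not enr.separated:
        perm = permutation_pvalue(enr.odds_ratio, analysis, n_perm=n_perm, seed=seed)
    return UnitResult(
        unit_id=unit_id,
        level=level,
        n_drugs=len(drugs),
        enrichment=enr,
        perm=perm,
        category_dropped=drop_category,
    )


def _iter_units(level: str, bundle: Bundle) -> list[str]:
    if level == "disease":
        return sorted(bundle.mendelian)
    if level == "gene":
        return sorted(bundle.mendelian_genes)
    raise ValueError(f"unknown unit level {level!r}")


def prioritize_units(
    bundle: Bundle,
    level: str,
    n_perm: int = 1000,
    seed: int = 0,
    base_table: pd.DataFrame | None = None,
) -> list[UnitResult]:
    """Run :func:`per_unit_enrichment` over every drugged unit.

    Units with no targeting drug or no comorbid disease, and units whose
    observed fit fails, are skipped with a warning.
    """
    if base_table is None:
        from .candidates import build_candidate_set

        base_table = build_pair_table(
            drug_universe(bundle),
            bundle.complex,
            build_candidate_set(bundle),
            bundle.evidence,
            bundle.drug_targets,
        )
    results: list[UnitResult] = []
    ss = np.random.SeedSequence(seed)
    for unit_id, unit_seed in zip(
        _iter_units(level, bundle), ss.generate_state(len(_iter_units(level, bundle)))
    ):
        try:
            results.append(
                per_unit_enrichment(
                    unit_id,
                    level,
                    bundle,
                    base_table=base_table,
                    n_perm=n_perm,
                    seed=int(unit_seed),
                )
            )
        except ValueError as exc:
            logger.warning("unit %s skipped: %s", unit_id, exc)
    return results


def compare_drug_counts(
    significant_counts: Iterable[int], other_counts: Iterable[int]
) -> float:
    """One-sided (greater) rank-sum p that significant units are targeted
    by more drugs than the rest.  Exact for small tie-free groups."""
    sig = list(significant_counts)
    other = list(other_counts)
    if not sig or not other:
        raise ValueError("both groups must be non-empty")
    return rank_sum_greater(sig, other)


def _gate_statistic(
    bundle: Bundle,
    level: str,
    base_table: pd.DataFrame,
    gene_to_drugs: Mapping[str, frozenset[str]],
    alpha: float,
) -> float:
    """Rank-sum p comparing drug counts of analytically significant units
    vs the rest, for a (possibly rewired) gene → drugs map."""
    sig: list[int] = []
    other: list[int] = []
    for unit_id in _iter_units(level, bundle):
        genes = unit_genes(unit_id, level, bundle)
        comorbid = unit_comorbid(unit_id, level, bundle)
        drugs = unit_drugs(genes, gene_to_drugs)
        if not drugs or not comorbid:
            continue
        categories = {bundle.complex[c].category for c in comorbid}
        adjust = ("n_targets",) if len(categories) < 2 else ("category", "n_targets")
        sub = base_table.assign(
            is_candidate=_unit_candidate_flag(base_table, drugs, comorbid)
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                res = fit_enrichment(sub, adjust=adjust)
        except ValueError:
            continue
        if res.separated:
            # sentinel classification: perfect enrichment counts as
            # significant, perfect depletion does not
            if np.isinf(res.odds_ratio):
                sig.append(len(drugs))
            else:
                other.append(len(drugs))
            continue
        if res.p_value < alpha and res.odds_ratio > 1:
            sig.append(len(drugs))
        else:
            other.append(len(drugs))
    if not sig or not other:
        raise ValueError("a significance group is empty")
    return rank_sum_greater(sig, other)


def druggability_permutation_gate(
    bundle: Bundle,
    level: str = "disease",
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    base_table: pd.DataFrame | None = None,
) -> PermutationResult:
    """Gate the druggability comparison against drug-target rewiring.

    Per replicate, every Mendelian causal gene's drug set is rewired
    (counts preserved), the significant-unit set is recomputed, and the
    one-sided rank-sum statistic comparing drug counts is re-evaluated.
    The empirical p is the fraction of replicates whose rank-sum p is at
    least as extreme (<=) as the observed one.  Unit significance is
    assessed analytically (Wald p < alpha and OR > 1) in both the observed
    and permuted worlds so the two are comparable; replicates with an
    empty group are excluded and counted.
    """
    if base_table is None:
        from .candidates import build_candidate_set

        base_table = build_pair_table(
            drug_universe(bundle),
            bundle.complex,
            build_candidate_set(bundle),
            bundle.evidence,
            bundle.drug_targets,
        )
    observed_p = _gate_statistic(
        bundle, level, base_table, bundle.drug_targets.gene_to_drugs, alpha
    )
    genes = bundle.mendelian_genes
    all_drugs = sorted(set(base_table["drug_id"]))

    def analysis(rng: np.random.Generator) -> float:
        g2d = rewired_drug_targets(bundle.drug_targets, genes, all_drugs, rng)
        return _gate_statistic(bundle, level, base_table, g2d, alpha)

    # extremity here is a small p-value, so invert both sides for the
    # ">= observed" exceedance rule of permutation_pvalue
    result = permutation_pvalue(
        -observed_p, lambda rng: -analysis(rng), n_perm=n_perm, seed=seed
    )
    return PermutationResult(
        observed_or=observed_p,
        permuted_ors=-result.permuted_ors,
        p_perm=result.p_perm,
        n_perm=result.n_perm,
        n_failed=result.n_failed,
        seed=result.seed,
    )
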