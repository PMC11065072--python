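"""Degree-preserving permutation nulls and empirical p-values.

Two rewiring schemes: (1) comorbidity rewiring resamples, for each
Mendelian disease, which complex diseases it is comorbid with while
preserving its comorbidity count; (2) drug-target rewiring resamples, for
each gene, which drugs target it while preserving the per-gene drug
count.  Sampling is uniform without replacement over the respective
universe.  The empirical p is the fraction of permuted odds ratios at
least as large as the observed one (ties count as exceedances), so p = 0
is possible and is rendered as "<1/n_perm" in human-readable output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

import numpy as np

from .core import Bundle, ComorbidityMap, DrugTargetMap

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationResult",
    "permute_comorbidity",
    "permute_drug_targets",
    "permutation_pvalue",
    "rewire_bundle_comorbidity",
    "rewired_drug_targets",
]


@dataclass(frozen=True)
class PermutationResult:
    """Null OR distribution and empirical p for one observed OR."""

    observed_or: float
    permuted_ors: np.ndarray
    p_perm: float
    n_perm: int
    n_failed: int
    seed: int

    @property
    def significant(self) -> bool:
        return self.p_perm < 0.05

    def describe(self) -> str:
        p = (
            f"<{1.0 / max(len(self.permuted_ors), 1):.4g}"
            if self.p_perm == 0
            else f"{self.p_perm:.4g}"
        )
        return (
            f"observed OR={self.observed_or:.4g}, p_perm={p} "
            f"({len(self.permuted_ors)}/{self.n_perm} replicates usable)"
        )


def permute_comorbidity(
    comorbidity: ComorbidityMap,
    complex_ids: Iterable[str],
    rng: np.random.Generator,
) -> ComorbidityMap:
    """Rewire which complex diseases each Mendelian disease is comorbid with.

    Each Mendelian disease with k comorbidities receives a uniform random
    k-subset of the complex universe; per-Mendelian counts are preserved
    exactly.  A disease comorbid with the whole universe is unchanged.
    """
    universe = sorted(set(complex_ids))
    pairs: set[tuple[str, str]] = set()
    counts = comorbidity.counts_per_mendelian()
    for mid in sorted(counts):
        k = counts[mid]
        if k > len(universe):
            raise ValueError(
                f"Mendelian disease {mid!r} has {k} comorbidities but the "
                f"complex universe has only {len(universe)} diseases"
            )
        chosen = rng.choice(universe, size=k, replace=False)
        pairs.update((mid, c) for c in chosen)
    return ComorbidityMap(pairs=frozenset(pairs))


def permute_drug_targets(
    gene_to_drugs: Mapping[str, frozenset[str]],
    drug_ids: Iterable[str],
    rng: np.random.Generator,
) -> dict[str, frozenset[str]]:
    """Rewire which drugs target each gene, preserving per-gene counts."""
    universe = sorted(set(drug_ids))
    out: dict[str, frozenset[str]] = {}
    for gene in sorted(gene_to_drugs):
        d = len(gene_to_drugs[gene])
        if d > len(universe):
            raise ValueError(
                f"gene {gene!r} is targeted by {d} drugs but the drug "
                f"universe has only {len(universe)}"
            )
        out[gene] = frozenset(rng.choice(universe, size=d, replace=False))
    return out


def rewire_bundle_comorbidity(
    bundle: Bundle, rng: np.random.Generator
) -> Bundle:
    """Bundle with comorbidity rewired; everything else untouched."""
    return Bundle(
        mendelian=bundle.mendelian,
        complex=bundle.complex,
        comorbidity=permute_comorbidity(
            bundle.comorbidity, bundle.complex.keys(), rng
        ),
        drug_targets=bundle.drug_targets,
        evidence=bundle.evidence,
    )


def rewired_drug_targets(
    drug_targets: DrugTargetMap,
    genes: Iterable[str],
    drug_ids: Iterable[str],
    rng: np.random.Generator,
) -> dict[str, frozenset[str]]:
    """Rewire the drug sets of the given genes only; other genes keep
    their original links.  Returns a gene → drugs map."""
    genes = set(genes)
    inverse = drug_targets.gene_to_drugs
    subset = {g: inverse.get(g, frozenset()) for g in genes if g in inverse}
    rewired = permute_drug_targets(subset, drug_ids, rng)
    out = dict(inverse)
    out.update(rewired)
    return out


def permutation_pvalue(
    observed_or: float,
    analysis: Callable[[np.random.Generator], float],
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Empirical p-value from re-running an analysis on permuted inputs.

    ``analysis`` receives a per-replicate RNG (independent substreams
    derived from ``seed``, so replicates are order-independent) and
    returns the permuted odds ratio.  Replicates that raise ``ValueError``
    or return a non-finite/NaN OR (failed fits) are excluded from the
    denominator and counted.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(n_perm)
    ors: list[float] = []
    n_failed = 0
    for child in streams:
        rng = np.random.default_rng(child)
        try:
            value = analysis(rng)
        except ValueError as exc:
            logger.debug("permutation replicate failed: %s", exc)
            n_failed += 1
            continue
        if value is None or np.isnan(value):
            n_failed += 1
            continue
        ors.append(float(value))
    if n_failed:
        logger.warning(
            "%d of %d permutation replicates failed and were excluded",
            n_failed,
            n_perm,
        )
    permuted = np.asarray(ors, dtype=float)
    if permuted.size == 0:
        raise ValueError("all permutation replicates failed; no null distribution")
    p = float(np.mean(permuted >= observed_or))
    return PermutationResult(
        observed_or=float(observed_or),
        permuted_ors=permuted,
        p_perm=p,
        n_perm=n_perm,
        n_failed=n_failed,
        seed=seed,
    )
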