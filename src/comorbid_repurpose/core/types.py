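"""Domain types shared by every pipeline stage.

All identifiers are opaque strings.  The registries (Mendelian and complex
diseases), the comorbidity relation, the drug→target map and the clinical
evidence table are small immutable value objects; cross-reference
validation lives in :mod:`comorbid_repurpose.core.tables`.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from functools import cached_property

from .phases import PhaseGroup, phase_rank

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORIES",
    "MendelianDisease",
    "ComplexDisease",
    "ComorbidityMap",
    "DrugTargetMap",
    "ClinicalEvidence",
    "Bundle",
    "ValidationError",
]

#: The six complex-disease categories.
CATEGORIES = (
    "cardiovascular",
    "hormonal",
    "immune",
    "neoplasms",
    "neurological",
    "ophthalmological",
)


class ValidationError(ValueError):
    """An input table failed cross-reference or schema validation."""


@dataclass(frozen=True)
class MendelianDisease:
    """A monogenic disease with its causal gene set."""

    id: str
    name: str
    causal_genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.causal_genes:
            logger.warning("Mendelian disease %s has no causal genes", self.id)


@dataclass(frozen=True)
class ComplexDisease:
    """A complex disease assigned to one of the six categories."""

    id: str
    name: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"complex disease {self.id!r}: unknown category {self.category!r}; "
                f"expected one of {CATEGORIES}"
            )


@dataclass(frozen=True)
class ComorbidityMap:
    """The binary comorbidity relation between Mendelian and complex diseases."""

    pairs: frozenset[tuple[str, str]]

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.pairs

    def complex_for(self, mendelian_id: str) -> frozenset[str]:
        """Complex diseases comorbid with ``mendelian_id``."""
        return frozenset(c for m, c in self.pairs if m == mendelian_id)

    def mendelian_for(self, complex_id: str) -> frozenset[str]:
        """Mendelian diseases comorbid with ``complex_id``."""
        return frozenset(m for m, c in self.pairs if c == complex_id)

    def counts_per_mendelian(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for m, _ in self.pairs:
            out[m] = out.get(m, 0) + 1
        return out


@dataclass(frozen=True)
class DrugTargetMap:
    """drug_id → set of gene-target symbols; every drug has >= 1 target."""

    targets: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        empty = sorted(d for d, genes in self.targets.items() if not genes)
        if empty:
            raise ValidationError(f"drugs with empty target sets: {empty}")

    def __len__(self) -> int:
        return len(self.targets)

    def n_targets(self, drug_id: str) -> int:
        return len(self.targets[drug_id])

    @cached_property
    def gene_to_drugs(self) -> dict[str, frozenset[str]]:
        """Inverse map: gene symbol → drugs targeting it."""
        inv: dict[str, set[str]] = {}
        for drug, genes in self.targets.items():
            for g in genes:
                inv.setdefault(g, set()).add(drug)
        return {g: frozenset(ds) for g, ds in inv.items()}


@dataclass(frozen=True)
class ClinicalEvidence:
    """Collapsed clinical evidence per (drug, complex disease).

    ``phases`` holds the most advanced trial phase observed for each pair
    (duplicates collapse to the maximum; an informative phase beats
    UNKNOWN).  ``indicated`` is the union of indication sources; every
    pair with a Phase IV trial is also in ``indicated``.
    """

    phases: Mapping[tuple[str, str], PhaseGroup]
    indicated: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        missing = {
            pair
            for pair, ph in self.phases.items()
            if ph is PhaseGroup.INDICATED and pair not in self.indicated
        }
        if missing:
            raise ValidationError(
                f"pairs with INDICATED phase missing from indicated set: {sorted(missing)}"
            )

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, str, PhaseGroup]],
        indicated: Iterable[tuple[str, str]] = (),
    ) -> "ClinicalEvidence":
        """Build from raw trial records, collapsing to the maximum phase."""
        phases: dict[tuple[str, str], PhaseGroup] = {}
        n_dup = 0
        for drug, disease, phase in records:
            key = (drug, disease)
            if key in phases:
                n_dup += 1
                if phase_rank(phase) <= phase_rank(phases[key]):
                    continue
            phases[key] = phase
        if n_dup:
            logger.warning(
                "collapsed %d duplicate evidence records to maximum phase", n_dup
            )
        ind = set(indicated)
        ind.update(k for k, ph in phases.items() if ph is PhaseGroup.INDICATED)
        return cls(phases=phases, indicated=frozenset(ind))

    def max_phase(self, drug_id: str, complex_id: str) -> PhaseGroup | None:
        """Most advanced evidence for the pair, or None if none exists."""
        key = (drug_id, complex_id)
        if key in self.indicated:
            return PhaseGroup.INDICATED
        return self.phases.get(key)

    def has_trial(self, drug_id: str, complex_id: str) -> bool:
        return (drug_id, complex_id) in self.phases


@dataclass(frozen=True)
class Bundle:
    """A validated set of all pipeline inputs."""

    mendelian: Mapping[str, MendelianDisease]
    complex: Mapping[str, ComplexDisease]
    comorbidity: ComorbidityMap
    drug_targets: DrugTargetMap
    evidence: ClinicalEvidence = field(
        default_factory=lambda: ClinicalEvidence(phases={}, indicated=frozenset())
    )

    @property
    def mendelian_genes(self) -> frozenset[str]:
        """Union of causal genes over all Mendelian diseases."""
        out: set[str] = set()
        for m in self.mendelian.values():
            out |= m.causal_genes
        return frozenset(out)
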