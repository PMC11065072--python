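import numpy as np
import pytest

from comorbid_repurpose.core import (
    Bundle,
    ClinicalEvidence,
    ComorbidityMap,
    ComplexDisease,
    DrugTargetMap,
    MendelianDisease,
    PhaseGroup,
)
from comorbid_repurpose.synthetic import SyntheticConfig, generate_world


@pytest.fixture
def tiny_bundle() -> Bundle:
    """3 Mendelian diseases, 2 complex diseases, 4 drugs, hand-checkable.

    Candidates: C1 -> {D1, D4} (via M1's GA/GB), C2 -> {D2, D4} (via M2's GC).
    """
    mendelian = {
        "M1": MendelianDisease("M1", "mendelian one", frozenset({"GA", "GB"})),
        "M2": MendelianDisease("M2", "mendelian two", frozenset({"GC"})),
        "M3": MendelianDisease("M3", "mendelian three", frozenset({"GD"})),
    }
    complex_ = {
        "C1": ComplexDisease("C1", "complex one", "immune"),
        "C2": ComplexDisease("C2", "complex two", "neoplasms"),
    }
    comorbidity = ComorbidityMap(frozenset({("M1", "C1"), ("M2", "C2")}))
    drug_targets = DrugTargetMap(
        {
            "D1": frozenset({"GA"}),
            "D2": frozenset({"GC", "GX"}),
            "D3": frozenset({"GE"}),
            "D4": frozenset({"GB", "GC"}),
        }
    )
    evidence = ClinicalEvidence.from_records(
        [
            ("D1", "C1", PhaseGroup.PHASE_II),
            ("D2", "C2", PhaseGroup.INDICATED),
        ],
        indicated={("D4", "C1")},
    )
    return Bundle(
        mendelian=mendelian,
        complex=complex_,
        comorbidity=comorbidity,
        drug_targets=drug_targets,
        evidence=evidence,
    )


@pytest.fixture(scope="session")
def mini_world():
    """A small synthetic world with a planted positive effect."""
    cfg = SyntheticConfig(
        n_mendelian=8,
        n_complex=12,
        n_genes=40,
        n_drugs=30,
        comorbidity_density=0.3,
        beta_candidate=1.0,
        beta0=-1.5,
        seed=42,
    )
    return generate_world(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
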