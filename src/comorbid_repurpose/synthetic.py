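"""Synthetic input bundles with known ground truth.

``generate_world`` samples disease registries, a comorbidity relation and
a drug-target map, then draws the (drug, disease) outcome from a logistic
model whose candidate flag is computed from the sampled maps the same way
the pipeline computes it — so planted effects are recoverable exactly in
expectation.  ``generate_expression`` plants correlated co-expression
modules containing designated cancer driver genes and Mendelian gene
sets.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .candidates import build_candidate_set, build_pair_table, drug_universe
from .core import (
    CATEGORIES,
    Bundle,
    ClinicalEvidence,
    ComorbidityMap,
    ComplexDisease,
    DrugTargetMap,
    MendelianDisease,
    PhaseGroup,
    group_phase,
    write_tables,
)
from .similarity import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticConfig",
    "World",
    "ExpressionWorld",
    "generate_world",
    "generate_expression",
    "sample_outcomes",
    "write_world",
]

#: Distribution specs: an int (constant) or a tuple
#: ("uniform", lo, hi) / ("geometric", p); geometric is zero-truncated.
CountSpec = int | tuple


def _sample_counts(
    spec: CountSpec, size: int, upper: int, rng: np.random.Generator
) -> np.ndarray:
    if isinstance(spec, int):
        if spec < 1 or spec > upper:
            raise ValueError(f"constant count {spec} outside [1, {upper}]")
        return np.full(size, spec, dtype=int)
    kind = spec[0]
    if kind == "uniform":
        _, lo, hi = spec
        if lo < 1 or hi > upper or lo > hi:
            raise ValueError(f"uniform count range ({lo}, {hi}) outside [1, {upper}]")
        return rng.integers(lo, hi + 1, size=size)
    if kind == "geometric":
        _, p = spec
        draws = rng.geometric(p, size=size)  # support starts at 1: zero-truncated
        return np.minimum(draws, upper)
    raise ValueError(f"unknown count distribution spec {spec!r}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs for the synthetic world and expression generators.

    Defaults mirror the realistic problem scale (90 Mendelian diseases,
    65 complex diseases, hub-skewed drug-target counts); tests shrink
    them.  ``targets_per_drug`` is heavy-tailed by default to emulate hub
    targets.
    """

    n_mendelian: int = 90
    n_complex: int = 65
    n_genes: int = 600
    n_drugs: int = 800
    n_cancers: int = 10
    n_tissues: int = 37
    genes_per_mendelian: CountSpec = ("uniform", 1, 8)
    targets_per_drug: CountSpec = ("geometric", 0.5)
    comorbidity_density: float = 0.3
    beta0: float = -2.0
    beta_candidate: float = 0.7
    beta_ntargets: float = 0.0
    category_effects: dict = field(default_factory=dict)
    module_correlation: float = 0.0
    genes_per_cancer: int = 5
    mendelian_set_size: int = 5
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "n_mendelian",
            "n_complex",
            "n_genes",
            "n_drugs",
            "n_cancers",
            "n_tissues",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.comorbidity_density <= 1.0:
            raise ValueError("comorbidity_density must be in [0, 1]")
        if not 0.0 <= self.module_correlation <= 1.0:
            raise ValueError("module_correlation must be in [0, 1]")
        unknown = set(self.category_effects) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"category_effects for unknown categories: {unknown}")


@dataclass(frozen=True)
class World:
    """A generated input bundle plus its generative ground truth."""

    config: SyntheticConfig
    bundle: Bundle
    pair_table: pd.DataFrame
    ground_truth: dict


@dataclass(frozen=True)
class ExpressionWorld:
    """Generated expression data with planted module membership."""

    config: SyntheticConfig
    expr: ExpressionMatrix
    cancer_genes: dict[str, frozenset[str]]
    mendelian_sets: dict[str, frozenset[str]]
    module_genes: dict[str, frozenset[str]]


def sample_outcomes(
    table: pd.DataFrame, config: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    """Draw 0/1 outcomes from the planted logistic model for a pair table.

    The linear predictor uses the same covariate encoding the enrichment
    module fits: the raw candidate flag, the per-category offset, and the
    untransformed target count.
    """
    cat_effect = table["category"].map(
        lambda c: config.category_effects.get(c, 0.0)
    ).to_numpy(dtype=float)
    eta = (
        config.beta0
        + config.beta_candidate * table["is_candidate"].to_numpy(dtype=float)
        + cat_effect
        + config.beta_ntargets * table["n_targets"].to_numpy(dtype=float)
    )
    prob = 1.0 / (1.0 + np.exp(-eta))
    return (rng.random(len(table)) < prob).astype(int)


def _candidate_flags_direct(
    drugs: list[str],
    complex_ids: list[str],
    comorbidity: ComorbidityMap,
    mendelian: dict[str, MendelianDisease],
    targets: dict[str, frozenset[str]],
) -> dict[tuple[str, str], int]:
    """Ground-truth candidate flags via a direct (mendelian, gene, drug)
    join — deliberately independent of the pipeline's implementation."""
    flags: dict[tuple[str, str], int] = {}
    for drug in drugs:
        tg = targets[drug]
        for cid in complex_ids:
            hit = 0
            for mid in comorbidity.mendelian_for(cid):
                if mendelian[mid].causal_genes & tg:
                    hit = 1
                    break
            flags[(drug, cid)] = hit
    return flags


def generate_world(config: SyntheticConfig) -> World:
    """Sample a complete input bundle with a planted enrichment effect.

    Raises ``ValueError`` on infeasible configurations.  Identical seeds
    give bit-identical worlds.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = [f"G{i:04d}" for i in range(config.n_genes)]

    k_mend = _sample_counts(
        config.genes_per_mendelian, config.n_mendelian, config.n_genes, rng
    )
    mendelian: dict[str, MendelianDisease] = {}
    for i in range(config.n_mendelian):
        mid = f"M{i:03d}"
        causal = rng.choice(genes, size=int(k_mend[i]), replace=False)
        mendelian[mid] = MendelianDisease(
            id=mid, name=f"mendelian disease {i}", causal_genes=frozenset(causal)
        )

    complex_: dict[str, ComplexDisease] = {}
    for i in range(config.n_complex):
        cid = f"C{i:03d}"
        complex_[cid] = ComplexDisease(
            id=cid,
            name=f"complex disease {i}",
            category=CATEGORIES[i % len(CATEGORIES)],
        )

    mask = rng.random((config.n_mendelian, config.n_complex)) < config.comorbidity_density
    pairs = frozenset(
        (f"M{i:03d}", f"C{j:03d}")
        for i in range(config.n_mendelian)
        for j in range(config.n_complex)
        if mask[i, j]
    )
    comorbidity = ComorbidityMap(pairs=pairs)

    k_drug = _sample_counts(
        config.targets_per_drug, config.n_drugs, config.n_genes, rng
    )
    targets: dict[str, frozenset[str]] = {}
    for i in range(config.n_drugs):
        did = f"D{i:04d}"
        targets[did] = frozenset(rng.choice(genes, size=int(k_drug[i]), replace=False))
    drug_targets = DrugTargetMap(targets=targets)

    skeleton = Bundle(
        mendelian=mendelian,
        complex=complex_,
        comorbidity=comorbidity,
        drug_targets=drug_targets,
    )
    universe = drug_universe(skeleton)
    if not universe:
        raise ValueError("no drug targets any Mendelian causal gene; widen the config")

    flags = _candidate_flags_direct(
        universe, sorted(complex_), comorbidity, mendelian, targets
    )
    rows = [
        {
            "drug_id": d,
            "complex_id": c,
            "is_candidate": flags[(d, c)],
            "category": complex_[c].category,
            "n_targets": len(targets[d]),
        }
        for d in universe
        for c in sorted(complex_)
    ]
    truth_table = pd.DataFrame(rows)
    truth_table["outcome"] = sample_outcomes(truth_table, config, rng)

    phase_labels = ("Phase 1", "Phase 2", "Phase 3", "Phase 4")
    positives = truth_table[truth_table["outcome"] == 1]
    chosen = rng.integers(0, len(phase_labels), size=len(positives))
    records = [
        (row.drug_id, row.complex_id, group_phase(phase_labels[chosen[k]]))
        for k, row in enumerate(positives.itertuples())
    ]
    evidence = ClinicalEvidence.from_records(records)

    bundle = Bundle(
        mendelian=mendelian,
        complex=complex_,
        comorbidity=comorbidity,
        drug_targets=drug_targets,
        evidence=evidence,
    )
    pair_table = build_pair_table(
        universe,
        complex_,
        build_candidate_set(bundle),
        evidence,
        drug_targets,
        outcome_def="investigated_or_indicated",
    )
    ground_truth = {
        "seed": config.seed,
        "beta0": config.beta0,
        "beta_candidate": config.beta_candidate,
        "beta_ntargets": config.beta_ntargets,
        "category_effects": dict(config.category_effects),
        "n_drug_universe": len(universe),
        "is_candidate": flags,
        "outcome": dict(
            zip(
                zip(truth_table["drug_id"], truth_table["complex_id"]),
                truth_table["outcome"].tolist(),
            )
        ),
    }
    return World(
        config=config, bundle=bundle, pair_table=pair_table, ground_truth=ground_truth
    )


def generate_expression(config: SyntheticConfig) -> ExpressionWorld:
    """Sample a gene x tissue matrix with planted co-expression modules.

    One module per cancer: its driver genes plus a designated Mendelian
    gene set share a latent tissue profile mixed in at
    ``module_correlation``; background genes are independent.  Values are
    exponentiated Gaussians (non-negative, right-skewed).
    """
    config.validate()
    if config.n_tissues < 3:
        raise ValueError("n_tissues must be >= 3")
    per_module = config.genes_per_cancer + config.mendelian_set_size
    if per_module * config.n_cancers > config.n_genes:
        raise ValueError(
            f"modules need {per_module * config.n_cancers} genes but only "
            f"{config.n_genes} are available"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    genes = [f"X{i:04d}" for i in range(config.n_genes)]
    latent_scale = np.sqrt(config.module_correlation)
    noise_scale = np.sqrt(1.0 - config.module_correlation)
    values = rng.standard_normal((config.n_genes, config.n_tissues))

    order = rng.permutation(config.n_genes)
    cancer_genes: dict[str, frozenset[str]] = {}
    mendelian_sets: dict[str, frozenset[str]] = {}
    module_genes: dict[str, frozenset[str]] = {}
    cursor = 0
    for i in range(config.n_cancers):
        cid = f"K{i:02d}"
        idx = order[cursor : cursor + per_module]
        cursor += per_module
        latent = rng.standard_normal(config.n_tissues)
        values[idx] = latent_scale * latent + noise_scale * values[idx]
        members = [genes[j] for j in idx]
        cancer_genes[cid] = frozenset(members[: config.genes_per_cancer])
        mendelian_sets[cid] = frozenset(members[config.genes_per_cancer :])
        module_genes[cid] = frozenset(members)

    expr = ExpressionMatrix(
        pd.DataFrame(
            np.exp(values),
            index=pd.Index(genes, name="gene"),
            columns=[f"T{t:02d}" for t in range(config.n_tissues)],
        )
    )
    return ExpressionWorld(
        config=config,
        expr=expr,
        cancer_genes=cancer_genes,
        mendelian_sets=mendelian_sets,
        module_genes=module_genes,
    )


def write_world(world: World, directory: str | Path) -> None:
    """Emit the world as the standard TSV bundle plus ground_truth.json."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_tables(world.bundle, d)
    world.pair_table.to_csv(d / "pair_table.tsv", sep="\t", index=False)
    truth = dict(world.ground_truth)
    truth["is_candidate"] = {f"{k[0]}:{k[1]}": v for k, v in truth["is_candidate"].items()}
    truth["outcome"] = {f"{k[0]}:{k[1]}": int(v) for k, v in truth["outcome"].items()}
    truth["config"] = asdict(world.config)
    with open(d / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    logger.info("wrote synthetic world to %s", d)
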