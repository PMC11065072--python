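"""TSV readers and writers for the pipeline input bundle.

The interchange format is plain TSV with fixed headers:

======================  =========================================
table                   columns
======================  =========================================
mendelian.tsv           mendelian_id, name, causal_genes ("|"-joined)
complex_diseases.tsv    complex_id, name, category
comorbidity.tsv         mendelian_id, complex_id
drug_targets.tsv        drug_id, gene          (long form, one row per link)
evidence.tsv            drug_id, complex_id, phase   (free-text phase label)
indicated.tsv           drug_id, complex_id
======================  =========================================

``read_tables`` cross-validates every reference and reports the offending
file, line and identifier on failure; duplicate relation rows are logged
and collapsed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path

import pandas as pd

from .phases import group_phase
from .types import (
    Bundle,
    ClinicalEvidence,
    ComorbidityMap,
    ComplexDisease,
    DrugTargetMap,
    MendelianDisease,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = ["TablePaths", "read_tables", "write_tables"]

GENE_SEP = "|"


@dataclass(frozen=True)
class TablePaths:
    """Locations of the six input tables (evidence/indicated optional)."""

    mendelian: Path
    complex: Path
    comorbidity: Path
    drug_targets: Path
    evidence: Path | None = None
    indicated: Path | None = None

    @classmethod
    def in_dir(cls, directory: str | Path) -> "TablePaths":
        d = Path(directory)
        return cls(
            mendelian=d / "mendelian.tsv",
            complex=d / "complex_diseases.tsv",
            comorbidity=d / "comorbidity.tsv",
            drug_targets=d / "drug_targets.tsv",
            evidence=d / "evidence.tsv",
            indicated=d / "indicated.tsv",
        )


def _read_tsv(path: Path, columns: list[str]) -> pd.DataFrame:
    if not Path(path).exists():
        raise ValidationError(f"{path}: file does not exist")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    return df


def _line(idx: int) -> int:
    # +2: header line plus 1-based numbering
    return idx + 2


def read_tables(paths: TablePaths) -> Bundle:
    """Read, validate and bundle all input tables.

    Raises :class:`ValidationError` naming file, line and identifier for
    any unresolvable cross-reference.  Duplicate comorbidity pairs and
    drug-target links are collapsed with a logged warning.
    """
    mdf = _read_tsv(paths.mendelian, ["mendelian_id", "name", "causal_genes"])
    mendelian: dict[str, MendelianDisease] = {}
    for idx, row in mdf.iterrows():
        mid = row["mendelian_id"]
        if mid in mendelian:
            raise ValidationError(
                f"{paths.mendelian}:{_line(idx)}: duplicate mendelian_id {mid!r}"
            )
        genes = frozenset(g for g in row["causal_genes"].split(GENE_SEP) if g)
        mendelian[mid] = MendelianDisease(id=mid, name=row["name"], causal_genes=genes)
    logger.info("read %d Mendelian diseases from %s", len(mendelian), paths.mendelian)

    cdf = _read_tsv(paths.complex, ["complex_id", "name", "category"])
    complex_: dict[str, ComplexDisease] = {}
    for idx, row in cdf.iterrows():
        cid = row["complex_id"]
        if cid in complex_:
            raise ValidationError(
                f"{paths.complex}:{_line(idx)}: duplicate complex_id {cid!r}"
            )
        try:
            complex_[cid] = ComplexDisease(
                id=cid, name=row["name"], category=row["category"]
            )
        except ValidationError as exc:
            raise ValidationError(f"{paths.complex}:{_line(idx)}: {exc}") from None
    logger.info("read %d complex diseases from %s", len(complex_), paths.complex)

    codf = _read_tsv(paths.comorbidity, ["mendelian_id", "complex_id"])
    pairs: set[tuple[str, str]] = set()
    n_dup = 0
    for idx, row in codf.iterrows():
        m, c = row["mendelian_id"], row["complex_id"]
        if m not in mendelian:
            raise ValidationError(
                f"{paths.comorbidity}:{_line(idx)}: unknown mendelian_id {m!r}"
            )
        if c not in complex_:
            raise ValidationError(
                f"{paths.comorbidity}:{_line(idx)}: unknown complex_id {c!r}"
            )
        if (m, c) in pairs:
            n_dup += 1
            continue
        pairs.add((m, c))
    if n_dup:
        logger.warning("comorbidity table: dropped %d duplicate pairs", n_dup)
    logger.info("read %d comorbidity pairs from %s", len(pairs), paths.comorbidity)

    tdf = _read_tsv(paths.drug_targets, ["drug_id", "gene"])
    targets: dict[str, set[str]] = {}
    n_dup = 0
    for idx, row in tdf.iterrows():
        d, g = row["drug_id"], row["gene"]
        if not g:
            raise ValidationError(
                f"{paths.drug_targets}:{_line(idx)}: empty gene for drug {d!r}"
            )
        bucket = targets.setdefault(d, set())
        if g in bucket:
            n_dup += 1
        bucket.add(g)
    if n_dup:
        logger.warning("drug_targets table: %d duplicate links collapsed", n_dup)
    drug_targets = DrugTargetMap(
        targets={d: frozenset(gs) for d, gs in targets.items()}
    )
    logger.info("read %d drugs from %s", len(drug_targets), paths.drug_targets)

    records: list[tuple[str, str, object]] = []
    if paths.evidence is not None and Path(paths.evidence).exists():
        edf = _read_tsv(paths.evidence, ["drug_id", "complex_id", "phase"])
        for idx, row in edf.iterrows():
            d, c = row["drug_id"], row["complex_id"]
            if d not in drug_targets.targets:
                raise ValidationError(
                    f"{paths.evidence}:{_line(idx)}: unknown drug_id {d!r}"
                )
            if c not in complex_:
                raise ValidationError(
                    f"{paths.evidence}:{_line(idx)}: unknown complex_id {c!r}"
                )
            records.append((d, c, group_phase(row["phase"])))
        logger.info("read %d evidence records from %s", len(records), paths.evidence)

    indicated: set[tuple[str, str]] = set()
    if paths.indicated is not None and Path(paths.indicated).exists():
        idf = _read_tsv(paths.indicated, ["drug_id", "complex_id"])
        for idx, row in idf.iterrows():
            d, c = row["drug_id"], row["complex_id"]
            if d not in drug_targets.targets:
                raise ValidationError(
                    f"{paths.indicated}:{_line(idx)}: unknown drug_id {d!r}"
                )
            if c not in complex_:
                raise ValidationError(
                    f"{paths.indicated}:{_line(idx)}: unknown complex_id {c!r}"
                )
            indicated.add((d, c))
        logger.info("read %d indicated pairs from %s", len(indicated), paths.indicated)

    evidence = ClinicalEvidence.from_records(records, indicated)
    return Bundle(
        mendelian=mendelian,
        complex=complex_,
        comorbidity=ComorbidityMap(pairs=frozenset(pairs)),
        drug_targets=drug_targets,
        evidence=evidence,
    )


def write_tables(bundle: Bundle, directory: str | Path) -> TablePaths:
    """Write a bundle back to the documented TSV layout (inverse of read)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = TablePaths.in_dir(d)

    pd.DataFrame(
        [
            {
                "mendelian_id": m.id,
                "name": m.name,
                "causal_genes": GENE_SEP.join(sorted(m.causal_genes)),
            }
            for m in sorted(bundle.mendelian.values(), key=lambda x: x.id)
        ]
    ).to_csv(paths.mendelian, sep="\t", index=False)

    pd.DataFrame(
        [
            {"complex_id": c.id, "name": c.name, "category": c.category}
            for c in sorted(bundle.complex.values(), key=lambda x: x.id)
        ]
    ).to_csv(paths.complex, sep="\t", index=False)

    pd.DataFrame(
        sorted(bundle.comorbidity.pairs), columns=["mendelian_id", "complex_id"]
    ).to_csv(paths.comorbidity, sep="\t", index=False)

    pd.DataFrame(
        [
            {"drug_id": drug, "gene": g}
            for drug in sorted(bundle.drug_targets.targets)
            for g in sorted(bundle.drug_targets.targets[drug])
        ]
    ).to_csv(paths.drug_targets, sep="\t", index=False)

    pd.DataFrame(
        [
            {"drug_id": drug, "complex_id": c, "phase": ph.label}
            for (drug, c), ph in sorted(bundle.evidence.phases.items())
        ],
        columns=["drug_id", "complex_id", "phase"],
    ).to_csv(paths.evidence, sep="\t", index=False)

    pd.DataFrame(
        sorted(bundle.evidence.indicated), columns=["drug_id", "complex_id"]
    ).to_csv(paths.indicated, sep="\t", index=False)

    return paths


def table_paths_from_config(cfg: dict, base: Path | None = None) -> TablePaths:
    """Resolve the ``tables:`` section of a config mapping into paths."""
    tables = cfg.get("tables", {})
    kwargs = {}
    for f in fields(TablePaths):
        value = tables.get(f.name)
        if value is None:
            kwargs[f.name] = None
            continue
        p = Path(value)
        if base is not None and not p.is_absolute():
            p = base / p
        kwargs[f.name] = p
    for required in ("mendelian", "complex", "comorbidity", "drug_targets"):
        if kwargs[required] is None:
            raise ValidationError(f"config tables section missing {required!r}")
    return TablePaths(**kwargs)
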