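import pandas as pd
import pandas.testing as pdt
import pytest

from comorbid_repurpose.candidates import (
    build_candidate_set,
    build_pair_table,
    candidate_drugs,
    drug_universe,
)
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


def brute_force_candidates(bundle, complex_id):
    """Triple loop over (mendelian, gene, drug) — the independent oracle."""
    out = set()
    prov = set()
    for mid, m in bundle.mendelian.items():
        if (mid, complex_id) not in bundle.comorbidity.pairs:
            continue
        for gene in m.causal_genes:
            for drug, targets in bundle.drug_targets.targets.items():
                if gene in targets:
                    out.add(drug)
                    prov.add((drug, complex_id, mid, gene))
    return out, prov


class TestCandidateDrugs:
    def test_tiny_fixture_candidates(self, tiny_bundle):
        drugs, prov = candidate_drugs(
            "C1", tiny_bundle.comorbidity, tiny_bundle.mendelian, tiny_bundle.drug_targets
        )
        assert drugs == {"D1", "D4"}
        assert ("D1", "C1", "M1", "GA") in prov
        assert ("D4", "C1", "M1", "GB") in prov

    def test_target_of_comorbid_causal_gene_is_candidate_with_provenance(self):
        # a complex disease comorbid with a Mendelian disease whose causal
        # gene is targeted by a drug -> that drug is recommended, with the
        # (mendelian, gene) pair recorded as support
        bundle = Bundle(
            mendelian={
                "Mq": MendelianDisease("Mq", "channelopathy", frozenset({"CACNA1C"}))
            },
            complex={"Cd": ComplexDisease("Cd", "autoimmune", "hormonal")},
            comorbidity=ComorbidityMap(frozenset({("Mq", "Cd")})),
            drug_targets=DrugTargetMap({"Dv": frozenset({"CACNA1C"})}),
        )
        drugs, prov = candidate_drugs(
            "Cd", bundle.comorbidity, bundle.mendelian, bundle.drug_targets
        )
        assert drugs == {"Dv"}
        assert prov == [("Dv", "Cd", "Mq", "CACNA1C")]

    def test_no_comorbid_mendelian_gives_empty_set(self, tiny_bundle):
        bundle = Bundle(
            mendelian=tiny_bundle.mendelian,
            complex={**tiny_bundle.complex, "C3": ComplexDisease("C3", "c3", "immune")},
            comorbidity=tiny_bundle.comorbidity,
            drug_targets=tiny_bundle.drug_targets,
        )
        drugs, prov = candidate_drugs(
            "C3", bundle.comorbidity, bundle.mendelian, bundle.drug_targets
        )
        assert drugs == frozenset()
        assert prov == []

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_join(self, seed):
        world = generate_world(
            SyntheticConfig(
                n_mendelian=5,
                n_complex=6,
                n_genes=15,
                n_drugs=10,
                comorbidity_density=0.4,
                seed=seed,
            )
        )
        cands = build_candidate_set(world.bundle)
        for cid in world.bundle.complex:
            expected, expected_prov = brute_force_candidates(world.bundle, cid)
            assert cands.drugs[cid] == expected
            got_prov = {
                tuple(r)
                for r in cands.provenance[
                    cands.provenance["complex_id"] == cid
                ].itertuples(index=False)
            }
            assert got_prov == expected_prov

    def test_provenance_genes_belong_to_disease_and_drug(self, mini_world):
        cands = build_candidate_set(mini_world.bundle)
        for row in cands.provenance.itertuples():
            assert row.gene in mini_world.bundle.mendelian[row.mendelian_id].causal_genes
            assert row.gene in mini_world.bundle.drug_targets.targets[row.drug_id]
            assert (row.mendelian_id, row.complex_id) in mini_world.bundle.comorbidity


class TestMonotonicity:
    def test_adding_target_gene_grows_candidates(self, tiny_bundle):
        before = build_candidate_set(tiny_bundle)
        grown = DrugTargetMap(
            {**tiny_bundle.drug_targets.targets, "D3": frozenset({"GE", "GA"})}
        )
        bundle = Bundle(
            mendelian=tiny_bundle.mendelian,
            complex=tiny_bundle.complex,
            comorbidity=tiny_bundle.comorbidity,
            drug_targets=grown,
        )
        after = build_candidate_set(bundle)
        for cid in tiny_bundle.complex:
            assert before.drugs[cid] <= after.drugs[cid]
        assert "D3" in after.drugs["C1"]

    def test_removing_comorbidity_shrinks_candidates(self, tiny_bundle):
        before = build_candidate_set(tiny_bundle)
        bundle = Bundle(
            mendelian=tiny_bundle.mendelian,
            complex=tiny_bundle.complex,
            comorbidity=ComorbidityMap(frozenset({("M2", "C2")})),
            drug_targets=tiny_bundle.drug_targets,
        )
        after = build_candidate_set(bundle)
        for cid in tiny_bundle.complex:
            assert after.drugs[cid] <= before.drugs[cid]
        assert after.drugs["C1"] == frozenset()


class TestPairTable:
    def test_cross_product_row_count(self, mini_world):
        b = mini_world.bundle
        n_drugs = len(drug_universe(b))
        assert len(mini_world.pair_table) == n_drugs * len(b.complex)

    def test_empty_evidence_all_zero_outcome(self, tiny_bundle):
        diseases = {
            "C1": tiny_bundle.complex["C1"],
            "C2": tiny_bundle.complex["C2"],
            "C3": ComplexDisease("C3", "c3", "immune"),
        }
        cands = build_candidate_set(tiny_bundle)
        table = build_pair_table(
            ["D1", "D2"],
            diseases,
            cands,
            ClinicalEvidence(phases={}, indicated=frozenset()),
            tiny_bundle.drug_targets,
        )
        assert len(table) == 6
        assert (table["outcome"] == 0).all()

    def test_n_targets_constant_per_drug(self, mini_world):
        per_drug = mini_world.pair_table.groupby("drug_id")["n_targets"].nunique()
        assert (per_drug == 1).all()
        for drug, nt in (
            mini_world.pair_table.groupby("drug_id")["n_targets"].first().items()
        ):
            assert nt == mini_world.bundle.drug_targets.n_targets(drug)

    def test_candidate_flag_matches_candidate_set(self, mini_world):
        cands = build_candidate_set(mini_world.bundle)
        for row in mini_world.pair_table.itertuples():
            assert row.is_candidate == int(cands.is_candidate(row.drug_id, row.complex_id))

    def test_candidate_flag_invariant_to_evidence(self, tiny_bundle):
        cands = build_candidate_set(tiny_bundle)
        kwargs = dict(
            drugs=drug_universe(tiny_bundle),
            diseases=tiny_bundle.complex,
            candidates=cands,
            drug_targets=tiny_bundle.drug_targets,
        )
        with_ev = build_pair_table(evidence=tiny_bundle.evidence, **kwargs)
        without_ev = build_pair_table(
            evidence=ClinicalEvidence(phases={}, indicated=frozenset()), **kwargs
        )
        pdt.assert_series_equal(with_ev["is_candidate"], without_ev["is_candidate"])

    def test_pure_function(self, tiny_bundle):
        cands = build_candidate_set(tiny_bundle)
        args = (
            drug_universe(tiny_bundle),
            tiny_bundle.complex,
            cands,
            tiny_bundle.evidence,
            tiny_bundle.drug_targets,
        )
        pdt.assert_frame_equal(build_pair_table(*args), build_pair_table(*args))

    def test_empty_drug_universe_errors(self, tiny_bundle):
        cands = build_candidate_set(tiny_bundle)
        with pytest.raises(ValueError, match="no druggable Mendelian genes"):
            build_pair_table(
                [],
                tiny_bundle.complex,
                cands,
                tiny_bundle.evidence,
                tiny_bundle.drug_targets,
            )

    def test_unknown_outcome_def_errors(self, tiny_bundle):
        cands = build_candidate_set(tiny_bundle)
        with pytest.raises(ValueError, match="outcome_def"):
            build_pair_table(
                ["D1"],
                tiny_bundle.complex,
                cands,
                tiny_bundle.evidence,
                tiny_bundle.drug_targets,
                outcome_def="phase_9",
            )


class TestOutcomeDefinitions:
    @pytest.fixture
    def evidence(self):
        # D1/C1: phase II trial; D2/C1: unknown-phase trial;
        # D3/C1: indicated only; D4/C1: indicated AND phase I trial
        return ClinicalEvidence.from_records(
            [
                ("D1", "C1", PhaseGroup.PHASE_II),
                ("D2", "C1", PhaseGroup.UNKNOWN),
                ("D4", "C1", PhaseGroup.PHASE_I),
            ],
            indicated={("D3", "C1"), ("D4", "C1")},
        )

    def _outcomes(self, tiny_bundle, evidence, outcome_def, **kw):
        table = build_pair_table(
            ["D1", "D2", "D3", "D4"],
            {"C1": tiny_bundle.complex["C1"]},
            build_candidate_set(tiny_bundle),
            evidence,
            tiny_bundle.drug_targets,
            outcome_def=outcome_def,
            **kw,
        )
        return dict(zip(table["drug_id"], table["outcome"]))

    def test_investigated_or_indicated(self, tiny_bundle, evidence):
        assert self._outcomes(tiny_bundle, evidence, "investigated_or_indicated") == {
            "D1": 1,
            "D2": 1,
            "D3": 1,
            "D4": 1,
        }

    def test_unknown_phase_can_be_excluded(self, tiny_bundle, evidence):
        out = self._outcomes(
            tiny_bundle, evidence, "investigated_or_indicated", include_unknown=False
        )
        assert out == {"D1": 1, "D2": 0, "D3": 1, "D4": 1}

    def test_indicated_only(self, tiny_bundle, evidence):
        assert self._outcomes(tiny_bundle, evidence, "indicated_only") == {
            "D1": 0,
            "D2": 0,
            "D3": 1,
            "D4": 1,
        }

    def test_phase_2_uses_maximal_evidence(self, tiny_bundle, evidence):
        # D4's trial evidence is trumped by its indication
        assert self._outcomes(tiny_bundle, evidence, "phase_2") == {
            "D1": 1,
            "D2": 0,
            "D3": 0,
            "D4": 0,
        }

    def test_phases_1_3_pools_trials_not_indications(self, tiny_bundle, evidence):
        assert self._outcomes(tiny_bundle, evidence, "phases_1_3") == {
            "D1": 1,
            "D2": 0,
            "D3": 0,
            "D4": 0,
        }
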