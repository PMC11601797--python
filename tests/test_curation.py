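"""Curation pipeline tests: each filter against hand-worked chemistry."""

import pytest
from rdkit import Chem

from htscurate.curation import (
    CurationConfig,
    aromatize,
    assign_hierarchical_labels,
    deduplicate,
    filter_druglikeness,
    filter_inorganic,
    filter_pains,
    filter_parse,
    neutralize_charges,
    resolve_mixture,
    run_curation_pipeline,
)
from htscurate.types import CompoundRecord, Outcome, ScreenHierarchy, ScreenNode, Stage


def rec(cid, smiles, outcomes=None, inchi=""):
    return CompoundRecord(compound_id=cid, smiles=smiles, inchi=inchi,
                          outcomes={k: Outcome(v)
                                    for k, v in (outcomes or {}).items()})


@pytest.fixture
def chain_hierarchy():
    return ScreenHierarchy([
        ScreenNode("P", Stage.PRIMARY),
        ScreenNode("C", Stage.CONFIRMATORY, ("P",)),
        ScreenNode("X", Stage.COUNTER, ("C",)),
    ])


class TestDeduplicate:
    def test_same_structure_different_ids_collapse(self):
        inchi = "InChI=1S/C2H6O/c1-2-3/h3H,2H2,1H3"
        records = [rec("130564", "CCO", {"P": "A"}, inchi),
                   rec("5311083", "OCC", {"P": "A"}, inchi)]
        kept, excluded = deduplicate(records)
        assert [r.compound_id for r in kept] == ["130564"]
        assert excluded == [("5311083", "duplicate")]

    def test_all_unique_is_identity(self):
        records = [rec("1", "CCO", {"P": "A"}), rec("2", "CCN", {"P": "I"})]
        kept, excluded = deduplicate(records)
        assert len(kept) == 2 and not excluded

    def test_conflicting_outcomes_exclude_both(self):
        records = [rec("1", "CCO", {"P": "A"}), rec("2", "CCO", {"P": "I"})]
        kept, excluded = deduplicate(records)
        assert not kept
        assert {(cid, reason) for cid, reason in excluded} == {
            ("1", "conflicting-duplicate"), ("2", "conflicting-duplicate")}

    def test_duplicate_by_id_alone(self):
        records = [rec("9", "CCO", {"P": "A"}), rec("9", "CCN", {"P": "A"})]
        kept, excluded = deduplicate(records)
        # same id, different structures, same outcomes: one kept
        assert len(kept) == 1 and len(excluded) == 1


class TestHierarchicalLabels:
    def test_confirmed_not_countered_is_active(self, chain_hierarchy):
        labeled, excluded = assign_hierarchical_labels(
            [rec("1", "CCO", {"P": "A", "C": "A", "X": "I"})],
            chain_hierarchy, CurationConfig())
        assert labeled[0].label == "active" and not excluded

    def test_primary_inactive_is_inactive(self, chain_hierarchy):
        labeled, _ = assign_hierarchical_labels(
            [rec("1", "CCO", {"P": "I"})], chain_hierarchy, CurationConfig())
        assert labeled[0].label == "inactive"

    def test_counter_active_excluded_from_actives(self, chain_hierarchy):
        labeled, excluded = assign_hierarchical_labels(
            [rec("1", "CCO", {"P": "A", "C": "A", "X": "A"})],
            chain_hierarchy, CurationConfig())
        assert not labeled
        assert excluded == [("1", "counter-active")]

    @pytest.mark.parametrize("policy,expect_label", [
        ("drop", None), ("inactive", "inactive")])
    def test_unconfirmed_policy(self, chain_hierarchy, policy, expect_label):
        config = CurationConfig(unconfirmed_policy=policy)
        labeled, excluded = assign_hierarchical_labels(
            [rec("1", "CCO", {"P": "A", "C": "I"})], chain_hierarchy, config)
        if expect_label is None:
            assert excluded == [("1", "unconfirmed-active")]
        else:
            assert labeled[0].label == expect_label

    def test_undeclared_screen_is_hard_error(self, chain_hierarchy):
        with pytest.raises(ValueError, match="undeclared"):
            assign_hierarchical_labels(
                [rec("1", "CCO", {"ZZZ": "A"})], chain_hierarchy,
                CurationConfig())


class TestStructuralFilters:
    @pytest.mark.parametrize("smiles,ok,reason", [
        ("CCO", True, None),
        ("C1CC", False, "parse-error"),
        ("C(C)(C)(C)(C)C", False, "valence"),
    ])
    def test_parse_filter(self, smiles, ok, reason):
        got_ok, got_reason = filter_parse(rec("1", smiles))
        assert got_ok is ok and got_reason == reason

    @pytest.mark.parametrize("smiles,ok", [
        ("[Na+].[Cl-]", False),   # no carbon anywhere
        ("CCO", True),
        ("O=C=O", True),          # carbon rule: CO2 passes (documented edge)
        ("C[Hg]C", False),        # exotic element
    ])
    def test_inorganic_filter(self, smiles, ok):
        assert filter_inorganic(rec("1", smiles))[0] is ok

    def test_mixture_duplicate_components_collapse(self):
        out, reason = resolve_mixture(rec("1", "CCO.CCO"), CurationConfig())
        assert reason is None and out.smiles == "CCO"

    def test_mixture_close_weights_dropped(self):
        # ethanol 46.07 Da vs ethylamine 45.08 Da: gap below 5 Da
        out, reason = resolve_mixture(rec("1", "CCO.CCN"), CurationConfig())
        assert out is None and reason == "ambiguous-mixture"

    def test_salt_resolves_to_organic_component(self):
        out, reason = resolve_mixture(rec("1", "CCO.[Na+].[Cl-]"),
                                      CurationConfig())
        assert reason is None and out.smiles == "CCO"

    def test_mixture_multiple_survivors_keep_heaviest(self):
        out, reason = resolve_mixture(rec("1", "CCO.c1ccccc1CCCCO"),
                                      CurationConfig())
        assert reason is None
        assert out.smiles == Chem.CanonSmiles("c1ccccc1CCCCO")
        assert "mixture-multisurvivor" in out.flags

    @pytest.mark.parametrize("smiles,expected", [
        ("CC(=O)[O-]", "CC(=O)O"),
        ("C[NH3+]", "CN"),
        ("CCO", "CCO"),                      # neutral: identity
        ("C[N+](=O)[O-]", "C[N+](=O)[O-]"),  # nitro: compensated, untouched
    ])
    def test_neutralize_by_atom(self, smiles, expected):
        out, err = neutralize_charges(rec("1", smiles))
        assert err is None
        assert Chem.CanonSmiles(out.smiles) == Chem.CanonSmiles(expected)

    @pytest.mark.parametrize("kekulized,reference", [
        ("C1=CC=CC=C1", "c1ccccc1"),
        ("C1CCCCC1", "C1CCCCC1"),
        ("C1=CC=NC=C1", "c1ccncc1"),
    ])
    def test_aromatize(self, kekulized, reference):
        out, err = aromatize(rec("1", kekulized))
        assert err is None
        assert out.smiles == Chem.CanonSmiles(reference)

    @pytest.mark.parametrize("smiles,ok,family", [
        ("O=C1C=CC(=O)C=C1", False, "quinone"),
        ("Oc1ccccc1O", False, "catechol"),
        ("CCO", True, None),
    ])
    def test_pains_filter(self, smiles, ok, family):
        got_ok, matches = filter_pains(rec("1", smiles), CurationConfig())
        assert got_ok is ok
        if family:
            assert any(family in m for m in matches)

    def test_pains_layer_subsetting(self):
        # quinones live in the promiscuity layer; disabling it passes them
        config = CurationConfig(pains_layers=frozenset(["optical_interference"]))
        ok, _ = filter_pains(rec("1", "O=C1C=CC(=O)C=C1"), config)
        assert ok

    @pytest.mark.parametrize("smiles,ok", [
        ("CC(=O)Oc1ccccc1C(=O)O", True),   # aspirin: zero violations
        ("CCO", True),
        ("C" * 40, False),                 # MW>500 and logP>5: two violations
    ])
    def test_druglikeness(self, smiles, ok):
        got_ok, _ = filter_druglikeness(rec("1", smiles), CurationConfig())
        assert got_ok is ok

    def test_druglikeness_strict_zero_tolerance(self):
        config = CurationConfig(ro5_max_violations=0)
        ok, violations = filter_druglikeness(rec("1", "C" * 25), config)
        assert not ok and violations == ["logP>5"]


class TestPipeline:
    def test_empty_input(self, chain_hierarchy):
        dataset = run_curation_pipeline([], chain_hierarchy)
        assert not dataset.records
        assert all(v == (0, 0, 0) for v in dataset.report.stage_counts.values())

    def test_count_conservation(self, noiseless_campaign, curated_noiseless):
        report = curated_noiseless.report
        n = len(noiseless_campaign.records)
        for stage, (n_in, n_out, n_exc) in report.stage_counts.items():
            assert n_in == n_out + n_exc, stage
            assert n_in == n
            n = n_out
        assert n == len(curated_noiseless.records)

    def test_parse_failures_never_reach_pains(self, chain_hierarchy):
        records = [rec("1", "C1CC", {"P": "I"}),            # broken ring
                   rec("2", "O=C1C=CC(=O)C=C1", {"P": "I"})]
        dataset = run_curation_pipeline(records, chain_hierarchy)
        stages = {cid: stage for cid, stage, _ in dataset.report.exclusions}
        assert stages == {"1": "parse", "2": "pains"}

    def test_labels_binary_and_disjoint(self, curated_noiseless):
        labels = {r.label for r in curated_noiseless.records}
        assert labels <= {"active", "inactive"}
        active = {r.compound_id for r in curated_noiseless.actives}
        inactive = {r.compound_id for r in curated_noiseless.inactives}
        assert not active & inactive

    def test_every_active_confirmed_and_not_countered(self, curated_noiseless):
        from htscurate.synthetic import CONFIRMATORY_SCREEN, COUNTER_SCREEN
        for record in curated_noiseless.actives:
            assert record.outcomes[CONFIRMATORY_SCREEN] is Outcome.ACTIVE
            assert record.outcomes[COUNTER_SCREEN] is not Outcome.ACTIVE

    def test_deterministic(self, noiseless_campaign):
        a = run_curation_pipeline(noiseless_campaign.records,
                                  noiseless_campaign.hierarchy)
        b = run_curation_pipeline(noiseless_campaign.records,
                                  noiseless_campaign.hierarchy)
        assert [(r.compound_id, r.smiles, r.label) for r in a.records] == \
               [(r.compound_id, r.smiles, r.label) for r in b.records]
        assert a.report.exclusions == b.report.exclusions

    def test_inputs_not_mutated(self, chain_hierarchy):
        records = [rec("1", "CC(=O)[O-]", {"P": "I"})]
        before = records[0].smiles
        run_curation_pipeline(records, chain_hierarchy)
        assert records[0].smiles == before and records[0].label is None

    def test_formula_preserved_by_normalization(self, curated_noiseless,
                                                noiseless_campaign):
        """Neutralization/aromatization keep the heavy-atom formula."""
        from rdkit.Chem import rdMolDescriptors
        raw = {r.compound_id: r for r in noiseless_campaign.records}
        checked = 0
        for record in curated_noiseless.records:
            tag = noiseless_campaign.truth[record.compound_id]["artifact"]
            if tag in ("mixture", "salt"):
                continue  # component selection changes the formula by design
            original = Chem.MolFromSmiles(raw[record.compound_id].smiles)
            final = Chem.MolFromSmiles(record.smiles)
            heavy = lambda m: sorted(a.GetSymbol() for a in m.GetAtoms())
            assert heavy(original) == heavy(final)
            checked += 1
        assert checked > 0
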