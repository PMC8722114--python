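"""Concordance cascade: stage semantics, Mendelian engine, end-to-end recovery."""

import itertools

import pytest

from hrrforge.concordance import (
    CascadeConfig,
    aligner_concordance,
    caller_concordance,
    lab_concordance,
    mendelian_consistent,
    mendelian_filter,
    replicate_concordance,
    run_hrv_cascade,
    twin_concordance,
)
from hrrforge.model import CallSet, ConfigurationError, FactorLabels, Pedigree
from hrrforge.simulate import simulate_study, truth_callset
from conftest import callset_at, snv

GENOTYPES = [(0, 0), (0, 1), (1, 1)]


def labeled(positions, sample="S", **labels):
    base = dict(sample=sample, lab="lab1", platform="p", library="l",
                replicate="r1", aligner="alnA", caller="c1")
    base.update(labels)
    return callset_at(positions, sample=sample, labels=FactorLabels(**base))


class TestReplicateConcordance:
    def test_two_of_three_is_concordant_one_of_three_not(self):
        reps = [labeled([10, 20], replicate="r1"),
                labeled([10, 30], replicate="r2"),
                labeled([10], replicate="r3")]
        res = replicate_concordance(reps)
        assert res.concordant.keys() == {("chr1", 10, "A", "G")}
        assert {k[1] for k in res.discordant.keys()} == {20, 30}

    def test_identical_triplicates_nothing_discordant(self):
        reps = [labeled([1, 2, 3], replicate=r) for r in ("r1", "r2", "r3")]
        res = replicate_concordance(reps)
        assert len(res.discordant) == 0 and len(res.concordant) == 3

    def test_single_replicate_rejected(self):
        with pytest.raises(ConfigurationError):
            replicate_concordance([labeled([1])])

    def test_partition_covers_union(self):
        reps = [labeled([1, 2], replicate="r1"), labeled([2, 3], replicate="r2")]
        res = replicate_concordance(reps)
        union = reps[0].keys() | reps[1].keys()
        assert res.concordant.keys() | res.discordant.keys() == union
        assert not (res.concordant.keys() & res.discordant.keys())


class TestLabAlignerCaller:
    def test_lab_minority_filtered(self):
        labs = [labeled([10, 99], lab="lab1"), labeled([10], lab="lab2"),
                labeled([10], lab="lab3")]
        res = lab_concordance(labs)
        assert {k[1] for k in res.discordant.keys()} == {99}

    def test_single_lab_pass_through(self):
        one = labeled([1, 2, 3])
        res = lab_concordance([one])
        assert res.concordant.keys() == one.keys() and len(res.discordant) == 0

    def test_aligner_two_of_four_concordant(self):
        sets = [labeled([5], aligner=a) for a in "wxyz"]
        sets[0].variants.update(labeled([7], aligner="w").variants)
        sets[1].variants.update(labeled([7], aligner="x").variants)
        res = aligner_concordance(sets)
        assert ("chr1", 7, "A", "G") in res.concordant.keys()

    @pytest.mark.parametrize("n_with,expected", [(7, True), (6, False), (9, True)])
    def test_caller_threshold_seven(self, n_with, expected):
        sets = []
        for i in range(9):
            pos = [10] if i < n_with else []
            sets.append(labeled(pos + [100 + i], caller=f"c{i}"))
        res = caller_concordance(sets, min_callers=7)
        assert (("chr1", 10, "A", "G") in res.concordant.keys()) is expected

    def test_too_few_callers_rejected(self):
        with pytest.raises(ConfigurationError):
            caller_concordance([labeled([1]), labeled([2])], min_callers=7)


class TestTwinConcordance:
    def test_identical_twins_no_discordance(self):
        a, b = labeled([1, 2], sample="T1"), labeled([1, 2], sample="T2")
        res = twin_concordance(a, b)
        assert len(res.discordant) == 0 and res.concordant.keys() == a.keys()

    def test_twin_unique_variant_discordant(self):
        res = twin_concordance(labeled([1, 9], sample="T1"), labeled([1], sample="T2"))
        assert {k[1] for k in res.discordant.keys()} == {9}

    def test_strict_mode_genotype_mismatch_discordant(self):
        a = CallSet([snv(10, gt=(0, 1))], sample="T1")
        b = CallSet([snv(10, gt=(1, 1))], sample="T2")
        assert len(twin_concordance(a, b).concordant) == 1
        assert len(twin_concordance(a, b, genotype_strict=True).concordant) == 0


class TestMendelianConsistent:
    def test_exhaustive_against_gamete_enumeration(self):
        """All 27 (F, M, C) combinations vs independent gamete-pair oracle."""
        n_consistent = 0
        for F, M, C in itertools.product(GENOTYPES, repeat=3):
            oracle = any(
                tuple(sorted((a, b))) == C
                for a in F for b in M
            )
            assert mendelian_consistent(F, M, C) is oracle
            n_consistent += oracle
        assert n_consistent == 15  # frozen oracle count

    @pytest.mark.parametrize(
        "F,M,C,expected",
        [
            ((0, 1), (0, 0), (1, 1), False),
            ((0, 1), (0, 1), (1, 1), True),
            ((1, 1), (1, 1), (1, 1), True),
        ],
    )
    def test_spot_cases(self, F, M, C, expected):
        assert mendelian_consistent(F, M, C) is expected


class TestMendelianFilter:
    @pytest.fixture
    def trio(self):
        return Pedigree("f", "F", "M", child="C")

    def test_de_novo_is_violation(self, trio):
        sets = {
            "F": CallSet(sample="F"),
            "M": CallSet(sample="M"),
            "C": CallSet([snv(10)], sample="C"),
        }
        res = mendelian_filter(trio, sets)
        assert len(res["C"].concordant) == 0 and len(res["C"].discordant) == 1

    def test_single_parent_het_transmission_ok(self, trio):
        sets = {
            "F": CallSet([snv(10, gt=(0, 1))], sample="F"),
            "M": CallSet(sample="M"),
            "C": CallSet([snv(10, gt=(0, 1))], sample="C"),
        }
        res = mendelian_filter(trio, sets)
        assert len(res["C"].concordant) == 1 and len(res["F"].concordant) == 1

    def test_quartet_transmission(self):
        ped = Pedigree("q", "F", "M", twinA="T1", twinB="T2")
        het, hom = (0, 1), (0, 0)
        sets = {
            "F": CallSet([snv(10, gt=het)], sample="F"),
            "M": CallSet(sample="M"),
            "T1": CallSet([snv(10, gt=het)], sample="T1"),
            "T2": CallSet([snv(10, gt=het)], sample="T2"),
        }
        res = mendelian_filter(ped, sets)
        assert all(len(res[m].discordant) == 0 for m in ("F", "T1", "T2"))

    def test_violating_variant_discordant_for_carriers_only(self, trio):
        # father 0/1, mother 0/0, child 1/1 is impossible
        sets = {
            "F": CallSet([snv(10, gt=(0, 1)), snv(50)], sample="F"),
            "M": CallSet([snv(50)], sample="M"),
            "C": CallSet([snv(10, gt=(1, 1)), snv(50)], sample="C"),
        }
        res = mendelian_filter(trio, sets)
        assert ("chr1", 10, "A", "G") in res["C"].discordant.keys()
        assert ("chr1", 10, "A", "G") in res["F"].discordant.keys()
        assert ("chr1", 50, "A", "G") in res["M"].concordant.keys()

    def test_missing_parent_set_rejected(self, trio):
        with pytest.raises(ConfigurationError):
            mendelian_filter(trio, {"F": CallSet(), "C": CallSet()})

    def test_presence_mode_allows_untransmitted_parent_allele(self, trio):
        sets = {
            "F": CallSet([snv(10, gt=(0, 1))], sample="F"),
            "M": CallSet([snv(10, gt=(0, 1))], sample="M"),
            "C": CallSet(sample="C"),  # parents het, child without the call
        }
        strict = mendelian_filter(trio, sets)
        relaxed = mendelian_filter(trio, sets, allele_presence_only=True)
        assert len(strict["F"].concordant) == 1  # 0/0 child is a legal outcome
        assert len(relaxed["F"].concordant) == 1


class TestCascade:
    def test_zero_error_recovers_truth_exactly(self, zero_error_config):
        data = simulate_study(zero_error_config)
        out = run_hrv_cascade(
            data.callsets, data.truth.pedigrees, CascadeConfig(min_callers=3)
        )
        for sample, res in out.items():
            truth = truth_callset(data.truth, sample)
            assert res.hrvs.keys() == truth.keys()
            assert len(res.discordant) == 0

    def test_caller_private_fps_never_reach_hrvs(self, small_config):
        data = simulate_study(small_config)
        out = run_hrv_cascade(
            data.callsets, data.truth.pedigrees, CascadeConfig(min_callers=3)
        )
        all_fp = set().union(*data.fp_keys.values())
        for sample, res in out.items():
            assert not (res.hrvs.keys() & all_fp)
            truth = truth_callset(data.truth, sample)
            assert res.hrvs.keys() <= truth.keys()

    def test_singleton_sample_stops_at_caller_stage(self):
        from hrrforge.simulate import SimulationConfig

        cfg = SimulationConfig(
            genome=(("chr1", 80_000),), n_sites=100,
            families=(), extra_singletons=("NA1",),
            labs=("lab1",), replicates=("r1", "r2", "r3"),
            aligners=("alnA", "alnB"), callers=("c1", "c2", "c3"),
            caller_fn=(0.02, 0.02, 0.02), aligner_fn=(0.01, 0.01), seed=2,
        )
        data = simulate_study(cfg)
        out = run_hrv_cascade(data.callsets, data.truth.pedigrees, CascadeConfig(min_callers=3))
        stages = [row["stage"] for row in out["NA1"].stage_table]
        assert "mendelian" not in stages and "twin" not in stages
        assert len(out["NA1"].hrvs) > 0

    def test_permutation_invariance_within_stages(self, small_config):
        data = simulate_study(small_config)
        cfg = CascadeConfig(min_callers=3)
        out1 = run_hrv_cascade(data.callsets, data.truth.pedigrees, cfg)
        out2 = run_hrv_cascade(list(reversed(data.callsets)), data.truth.pedigrees, cfg)
        for sample in out1:
            assert out1[sample].hrvs.keys() == out2[sample].hrvs.keys()
            assert out1[sample].discordant.keys() == out2[sample].discordant.keys()

    def test_raising_min_callers_never_grows_hrvs(self, small_config):
        data = simulate_study(small_config)
        prev = None
        for mc in (2, 3):
            out = run_hrv_cascade(
                data.callsets, data.truth.pedigrees, CascadeConfig(min_callers=mc)
            )
            keys = {s: r.hrvs.keys() for s, r in out.items()}
            if prev is not None:
                for s in keys:
                    assert keys[s] <= prev[s]
            prev = keys

    def test_concordant_subset_of_input_union(self, small_config):
        data = simulate_study(small_config)
        out = run_hrv_cascade(data.callsets, data.truth.pedigrees, CascadeConfig(min_callers=3))
        for sample, res in out.items():
            union = set()
            for cs in data.callsets:
                if cs.sample == sample:
                    union |= cs.keys()
            assert res.hrvs.keys() <= union
            assert res.discordant.keys() <= union
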