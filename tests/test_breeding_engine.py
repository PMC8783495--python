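"""Sire selection, offspring apportionment, mating and meiosis."""

import numpy as np
import pytest
from scipy import stats

from wffsim import breeding_engine as be
from wffsim import founder_genomes as fg
from wffsim import lethal_allele as la
from wffsim import trait_model as tm
from conftest import make_cohort


def _engine_setup(seed=0, n=50, carriers=10):
    """Small map/arch/cohort with a controlled carrier count at the lethal locus."""
    gmap = fg.build_genetic_map(2, 50, 2, 3, seed=seed)
    rng = np.random.default_rng(seed)
    hap = (rng.random((n, 2, gmap.n_loci)) < 0.3).astype(np.int8)
    lethal_locus = int(gmap.neutral_indices[0])
    hap[:, :, lethal_locus] = 0
    rows = rng.choice(n, size=carriers, replace=False)
    hap[rows, 0, lethal_locus] = 1
    arch = tm.draw_qtl_effects(gmap, 0.3, seed=seed)
    arch = tm.calibrate_scaling(arch, hap)
    model = tm.PhenotypeModel()
    cohort = make_cohort(hap, arch, model, seed=seed, lethal_locus=lethal_locus)
    return gmap, arch, model, cohort, lethal_locus


class TestBreedingConfig:
    def test_default_configuration_valid(self):
        config = be.BreedingConfig()
        assert sum(config.split) == 300
        assert (300 // 10) * sum(config.decile_counts) == 6000

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(split=(100, 150)),  # does not sum to n_sires
            dict(n_sires=301, split=(121, 180)),  # not divisible by deciles
            dict(decile_counts=(1, 1, 1, 3, 6, 10, 16, 20, 116, 26)),  # not monotone
            dict(n_offspring=5000),  # inconsistent with decile counts
        ],
    )
    def test_invalid_configurations(self, kwargs):
        with pytest.raises(ValueError):
            be.BreedingConfig(**kwargs)

    def test_policy_validation(self):
        with pytest.raises(ValueError):
            be.ManagementPolicy(mode="cull_everyone")
        with pytest.raises(ValueError):
            be.ManagementPolicy(mode="no_testing", exemption_top_k=10)


class TestSelectSires:
    def _toy_config(self):
        return be.BreedingConfig(
            n_male_candidates=25, n_dams=25, n_sires=10, split=(4, 6),
            n_offspring=10, decile_counts=(1,) * 10,
        )

    def test_matches_sort_oracle(self):
        gmap, arch, model, cohort, _ = _engine_setup(seed=3)
        config = self._toy_config()
        sel = be.select_sires(cohort, be.ManagementPolicy("no_testing"), config)
        # oracle: goal-2 sires are the top 6 viable males on goal-2 phenotype,
        # goal-1 sires the top 4 on goal-1 phenotype among the rest
        males = [i for i in cohort.males() if cohort.status[i] != la.AFFECTED]
        by_g2 = sorted(males, key=lambda i: (-cohort.phenotype[i, 1], cohort.ids[i]))
        goal2 = by_g2[:6]
        rest = [i for i in males if i not in goal2]
        goal1 = sorted(rest, key=lambda i: (-cohort.phenotype[i, 0], cohort.ids[i]))[:4]
        assert sorted(sel.indices[sel.goal == 1].tolist()) == sorted(goal2)
        assert sorted(sel.indices[sel.goal == 0].tolist()) == sorted(goal1)
        assert np.unique(sel.indices).size == 10

    def test_ties_broken_by_id_deterministically(self):
        gmap, arch, model, cohort, _ = _engine_setup(seed=4)
        cohort.phenotype[:] = 42.0  # all identical
        config = self._toy_config()
        sel1 = be.select_sires(cohort, be.ManagementPolicy("no_testing"), config)
        sel2 = be.select_sires(cohort, be.ManagementPolicy("no_testing"), config)
        assert np.array_equal(sel1.indices, sel2.indices)
        males = cohort.males()
        viable = males[cohort.status[males] != la.AFFECTED]
        expected = np.sort(viable[np.argsort(cohort.ids[viable])][:10])
        assert np.array_equal(np.sort(sel1.indices), expected)

    def test_exclusion_without_exemption_bars_all_carriers(self):
        gmap, arch, model, cohort, _ = _engine_setup(seed=5, carriers=20)
        sel = be.select_sires(
            cohort, be.ManagementPolicy("exclude_carrier_sires", 0), self._toy_config()
        )
        assert np.all(cohort.status[sel.indices] != la.CARRIER)

    def test_exemption_ranked_before_exclusion(self):
        gmap, arch, model, cohort, _ = _engine_setup(seed=6, carriers=0)
        males = cohort.males()
        # make one male carrier and force him to the top of goal 1
        star = males[0]
        cohort.status[star] = la.CARRIER
        cohort.phenotype[star, :] = [999.0, -999.0]
        config = self._toy_config()
        sel0 = be.select_sires(cohort, be.ManagementPolicy("exclude_carrier_sires", 0), config)
        assert star not in sel0.indices
        sel1 = be.select_sires(cohort, be.ManagementPolicy("exclude_carrier_sires", 1), config)
        assert star in sel1.indices

    def test_affected_never_selected(self):
        gmap, arch, model, cohort, _ = _engine_setup(seed=7)
        males = cohort.males()
        cohort.status[males[:3]] = la.AFFECTED
        cohort.phenotype[males[:3], :] = 1e6
        sel = be.select_sires(cohort, be.ManagementPolicy("no_testing"), self._toy_config())
        assert not np.any(np.isin(sel.indices, males[:3]))

    def test_infeasible_selection(self):
        gmap, arch, model, cohort, _ = _engine_setup(seed=8, n=12)
        with pytest.raises(be.SelectionInfeasibleError):
            be.select_sires(cohort, be.ManagementPolicy("no_testing"), self._toy_config())


class TestAllocateOffspring:
    def test_default_scheme_quotas(self):
        """Top-decile sires get 116 offspring (58% of the crop), lowest three deciles 1."""
        rng = np.random.default_rng(0)
        config = be.BreedingConfig()
        n = 300
        sel = be.SireSelection(
            indices=np.arange(n, dtype=np.intp), goal=np.repeat([0, 1], [120, 180]).astype(np.int8)
        )
        cohort = type("C", (), {})()
        cohort.phenotype = rng.normal(100, 30, (n, 2))
        cohort.ids = np.arange(n, dtype=np.int64)
        quotas = be.allocate_offspring(sel, cohort, config)
        assert quotas.sum() == 6000
        own = cohort.phenotype[sel.indices, sel.goal.astype(np.intp)]
        order = np.argsort(own)
        assert np.all(quotas[order[-30:]] == 116)
        assert quotas[order[-30:]].sum() / 6000 == pytest.approx(0.58)
        assert np.all(quotas[order[:90]] == 1)

    def test_scaled_toy_allocation(self):
        config = be.BreedingConfig(
            n_male_candidates=20, n_dams=20, n_sires=10, split=(4, 6),
            n_offspring=100, decile_counts=(1, 1, 1, 3, 6, 10, 16, 18, 20, 24),
        )
        rng = np.random.default_rng(1)
        sel = be.SireSelection(np.arange(10, dtype=np.intp), np.zeros(10, dtype=np.int8))
        cohort = type("C", (), {})()
        cohort.phenotype = rng.normal(size=(10, 2))
        cohort.ids = np.arange(10, dtype=np.int64)
        quotas = be.allocate_offspring(sel, cohort, config)
        assert quotas.sum() == 100

    def test_wrong_sire_count(self):
        config = be.BreedingConfig()
        sel = be.SireSelection(np.arange(10, dtype=np.intp), np.zeros(10, dtype=np.int8))
        with pytest.raises(ValueError):
            be.allocate_offspring(sel, None, config)


class TestMate:
    def test_avoidance_forbids_carrier_carrier(self):
        gmap, arch, model, cohort, _ = _engine_setup(seed=9, n=60, carriers=30)
        sel = be.select_sires(
            cohort,
            be.ManagementPolicy("avoid_carrier_mating"),
            be.BreedingConfig(n_male_candidates=30, n_dams=30, n_sires=10, split=(4, 6),
                              n_offspring=100, decile_counts=(2, 2, 4, 6, 8, 10, 12, 14, 20, 22)),
        )
        quotas = np.full(10, 10)
        sires, dams = be.mate(sel, quotas, cohort, be.ManagementPolicy("avoid_carrier_mating"), seed=1)
        both_carrier = (cohort.status[sires] == la.CARRIER) & (cohort.status[dams] == la.CARRIER)
        assert not both_carrier.any()

    def test_single_sire_all_matings(self):
        gmap, arch, model, cohort, _ = _engine_setup(seed=10)
        sel = be.SireSelection(np.array([int(cohort.males()[0])], dtype=np.intp), np.array([0], dtype=np.int8))
        sires, dams = be.mate(sel, np.array([500]), cohort, be.ManagementPolicy("no_testing"), seed=2)
        assert np.all(sires == cohort.males()[0])
        assert sires.size == 500

    def test_dam_use_uniform(self):
        """Dams are drawn uniformly with replacement (chi-square)."""
        gmap, arch, model, cohort, _ = _engine_setup(seed=11, n=60, carriers=0)
        sel = be.SireSelection(np.array([int(cohort.males()[0])], dtype=np.intp), np.array([0], dtype=np.int8))
        sires, dams = be.mate(sel, np.array([30_000]), cohort, be.ManagementPolicy("no_testing"), seed=3)
        counts = np.bincount(dams, minlength=cohort.n)[cohort.females()]
        assert stats.chisquare(counts).pvalue > 0.01

    def test_affected_dams_never_used(self):
        gmap, arch, model, cohort, _ = _engine_setup(seed=12)
        females = cohort.females()
        cohort.status[females[:5]] = la.AFFECTED
        sel = be.SireSelection(np.array([int(cohort.males()[0])], dtype=np.intp), np.array([0], dtype=np.int8))
        _, dams = be.mate(sel, np.array([1000]), cohort, be.ManagementPolicy("no_testing"), seed=4)
        assert not np.any(np.isin(dams, females[:5]))


class TestMeiosis:
    def test_no_crossover_copies_one_haplotype(self):
        """With a vanishing map length the gamete is one parental haplotype."""
        gmap = fg.build_genetic_map(2, 1e-9, 2, 3, seed=0)
        rng = np.random.default_rng(0)
        parent = rng.integers(0, 2, size=(2, gmap.n_loci)).astype(np.int8)
        for _ in range(5):
            gamete = be.meiosis(parent, gmap, rng)
            for sl in gmap.chromosome_slices():
                block = gamete[sl]
                assert np.array_equal(block, parent[0, sl]) or np.array_equal(block, parent[1, sl])

    def test_poisson_crossover_mean(self):
        """Mean crossover count is chrom_length/100 Morgan (1.0 for 100 cM)."""
        gmap = fg.build_genetic_map(1, 100, 1, 10, seed=1)
        rng = np.random.default_rng(5)
        parent = np.zeros((2, gmap.n_loci), dtype=np.int8)
        counts = [len(be.meiosis(parent, gmap, rng, return_crossovers=True)[1][0]) for _ in range(10_000)]
        assert np.mean(counts) == pytest.approx(1.0, abs=0.03)

    def test_switches_exactly_at_crossovers(self):
        """Fully heterozygous parent: allele flips track crossover parity."""
        gmap = fg.build_genetic_map(1, 100, 3, 40, seed=2)
        parent = np.zeros((2, gmap.n_loci), dtype=np.int8)
        parent[1, :] = 1  # haplotype 1 carries the derived allele everywhere
        rng = np.random.default_rng(6)
        for _ in range(50):
            gamete, crossovers = be.meiosis(parent, gmap, rng, return_crossovers=True)
            xo = crossovers[0]
            parity = np.searchsorted(xo, gmap.position_cm) % 2
            # gamete equals either parity or its complement depending on start
            assert np.array_equal(gamete, parity ^ gamete[0] ^ parity[0])

    def test_batch_switch_frequency_matches_haldane(self):
        """Per-interval switch rate in the batch path equals (1-exp(-2d))/2."""
        gmap = fg.build_genetic_map(1, 100, 3, 7, seed=3)
        parent = np.zeros((1, 2, gmap.n_loci), dtype=np.int8)
        parent[0, 1, :] = 1
        parents = np.repeat(parent, 20_000, axis=0)
        rng = np.random.default_rng(7)
        gametes = be.recombine_gametes(parents, gmap, rng)
        d = np.diff(gmap.position_cm) / 100.0
        r = 0.5 * (1 - np.exp(-2 * d))
        observed = (np.diff(gametes, axis=1) != 0).mean(axis=0)
        assert np.allclose(observed, r, atol=4 * np.sqrt(0.25 / 20_000) + 0.002)

    def test_batch_and_single_gamete_agree_in_law(self):
        """Observable switch counts from both meiosis paths have the same mean."""
        gmap = fg.build_genetic_map(1, 100, 3, 40, seed=2)
        parent = np.zeros((2, gmap.n_loci), dtype=np.int8)
        parent[1, :] = 1
        rng = np.random.default_rng(8)
        single = np.array(
            [(np.diff(be.meiosis(parent, gmap, rng)) != 0).sum() for _ in range(4000)]
        )
        batch = (np.diff(be.recombine_gametes(
            np.repeat(parent[None], 4000, axis=0), gmap, rng), axis=1) != 0).sum(axis=1)
        assert abs(single.mean() - batch.mean()) < 4 * np.sqrt(2) * single.std() / np.sqrt(4000)


class TestAdvanceGeneration:
    def _setup(self, seed=0, policy=None):
        gmap, arch, model, cohort, lethal_locus = _engine_setup(seed=seed, n=50, carriers=8)
        spec = la.LethalSpec(
            locus=lethal_locus, locus_id=int(gmap.locus_id[lethal_locus]),
            mode="neutral", founder_carrier_freq=8 / 50,
        )
        config = be.BreedingConfig(
            n_male_candidates=25, n_dams=25, n_sires=20, split=(8, 12),
            n_offspring=50, decile_counts=(1, 1, 1, 1, 2, 2, 3, 3, 4, 7),
        )
        policy = policy or be.ManagementPolicy("avoid_carrier_mating")
        return gmap, arch, model, cohort, spec, config, policy

    def test_offspring_counts_and_sexes(self):
        gmap, arch, model, cohort, spec, config, policy = self._setup()
        rng = np.random.default_rng(1)
        nxt = be.advance_generation(cohort, gmap, arch, spec, model, policy, config, rng)
        assert nxt.n == 50
        assert (nxt.sex == be.MALE).sum() == 25
        assert nxt.generation == 1

    def test_mendelian_consistency(self):
        """Every offspring allele at every locus comes from the recorded parents."""
        gmap, arch, model, cohort, spec, config, policy = self._setup(seed=2)
        rng = np.random.default_rng(2)
        nxt = be.advance_generation(cohort, gmap, arch, spec, model, policy, config, rng)
        id_to_row = {int(i): r for r, i in enumerate(cohort.ids)}
        for child in range(nxt.n):
            s = id_to_row[int(nxt.sire[child])]
            d = id_to_row[int(nxt.dam[child])]
            dosage = nxt.haplotypes[child].sum(axis=0)
            lo = (cohort.haplotypes[s].min(axis=0) + cohort.haplotypes[d].min(axis=0))
            hi = (cohort.haplotypes[s].max(axis=0) + cohort.haplotypes[d].max(axis=0))
            assert np.all(dosage >= lo) and np.all(dosage <= hi)

    def test_quota_conservation(self):
        gmap, arch, model, cohort, spec, config, policy = self._setup(seed=3)
        rng = np.random.default_rng(3)
        sel = be.select_sires(cohort, policy, config)
        quotas = be.allocate_offspring(sel, cohort, config)
        nxt = be.advance_generation(cohort, gmap, arch, spec, model, policy, config,
                                    np.random.default_rng(3))
        realized = {int(s): 0 for s in cohort.ids[sel.indices]}
        for s in nxt.sire:
            realized[int(s)] += 1
        expected = dict(zip((int(i) for i in cohort.ids[sel.indices]), quotas))
        assert realized == expected

    def test_no_affected_under_avoidance(self):
        gmap, arch, model, cohort, spec, config, policy = self._setup(seed=4)
        c = cohort
        rng = np.random.default_rng(4)
        for _ in range(5):
            c = be.advance_generation(c, gmap, arch, spec, model, policy, config, rng)
            assert (c.status == la.AFFECTED).sum() == 0

    def test_transmission_is_unbiased(self):
        """Offspring allele frequency is centred on the parental transmitted mean
        (drift null: with random 'selection' the lethal-locus frequency is a
        martingale)."""
        gmap, arch, model, cohort, spec, config, _ = self._setup(seed=5)
        cohort.phenotype[:] = np.random.default_rng(5).normal(size=cohort.phenotype.shape)
        deltas = []
        for rep in range(200):
            rng = np.random.default_rng((6, rep))
            cohort.phenotype[:] = rng.normal(size=cohort.phenotype.shape)  # random ranking
            sel = be.select_sires(cohort, be.ManagementPolicy("no_testing"), config)
            quotas = be.allocate_offspring(sel, cohort, config)
            sires, dams = be.mate(sel, quotas, cohort, be.ManagementPolicy("no_testing"), rng)
            pat = be.recombine_gametes(cohort.haplotypes[sires], gmap, rng)
            mat = be.recombine_gametes(cohort.haplotypes[dams], gmap, rng)
            parental = 0.5 * (
                cohort.haplotypes[sires, :, spec.locus].mean()
                + cohort.haplotypes[dams, :, spec.locus].mean()
            )
            offspring = 0.5 * (pat[:, spec.locus].mean() + mat[:, spec.locus].mean())
            deltas.append(offspring - parental)
        deltas = np.array(deltas)
        assert abs(deltas.mean()) < 4 * deltas.std() / np.sqrt(len(deltas))

    def test_deterministic_for_seed(self):
        gmap, arch, model, cohort, spec, config, policy = self._setup(seed=7)
        a = be.advance_generation(cohort, gmap, arch, spec, model, policy, config,
                                  np.random.default_rng(77))
        b = be.advance_generation(cohort, gmap, arch, spec, model, policy, config,
                                  np.random.default_rng(77))
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert np.array_equal(a.phenotype, b.phenotype)
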