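"""Synthetic-data generator: determinism, Mendelian oracles, noise model."""

import subprocess

import numpy as np
import pytest

from apomixis_scan.genotypes import HET, HOM_ALT, HOM_REF, MISSING
from apomixis_scan.simulate import (
    ConfigurationError,
    SimConfig,
    apply_sequencing_model,
    simulate_clonal_complex,
    simulate_embryo_scenario,
    simulate_embryo_set,
    simulate_hybrid_apomict,
    simulate_sexual_population,
    truth_annotation,
    write_simulation,
)
from apomixis_scan.vcfio import read_vcf


class TestConfigValidation:
    def test_probabilities_bounded(self):
        with pytest.raises(ConfigurationError):
            SimConfig(genotype_error=1.5)
        with pytest.raises(ConfigurationError):
            SimConfig(p_sexual_embryo=-0.1)

    def test_lineage_sizes_length_checked(self):
        cfg = SimConfig(n_clonal_lineages=3, lineage_sizes=(5, 5),
                        n_chromosomes=1, chrom_length=100_000)
        with pytest.raises(ConfigurationError):
            simulate_clonal_complex(cfg)

    def test_deleterious_fractions_must_cover_classes(self):
        with pytest.raises(ConfigurationError, match="missing classes"):
            SimConfig(deleterious_fractions={"DEL": 0.5, "TOL": 0.5})

    def test_joint_density_bound(self):
        with pytest.raises(ConfigurationError):
            SimConfig(hybrid_divergence=0.7, polymorphism_density=0.2)


class TestSexualPopulation:
    def test_no_polymorphism_all_hom_ref(self):
        cfg = SimConfig(n_chromosomes=1, chrom_length=100_000,
                        polymorphism_density=0.0, seed=1)
        m, _ = simulate_sexual_population(cfg, 2)
        assert m.n_sites == 0 or np.all(m.calls == HOM_REF)

    def test_mean_heterozygosity_matches_founder_diversity(self):
        """Per-site het under the fixed spectrum ~ h_e within 3 SE."""
        cfg = SimConfig(n_chromosomes=2, chrom_length=500_000, seed=2,
                        founder_freq_spectrum="fixed", founder_diversity=0.25)
        m, _ = simulate_sexual_population(cfg, 50)
        obs = (m.calls == HET).mean()
        n = m.calls.size
        se = np.sqrt(0.25 * 0.75 / n)
        assert abs(obs - 0.25) < 3 * se

    def test_no_two_individuals_identical(self):
        cfg = SimConfig(n_chromosomes=1, chrom_length=200_000, seed=3)
        m, _ = simulate_sexual_population(cfg, 10)
        for i in range(10):
            for j in range(i + 1, 10):
                assert not np.array_equal(m.calls[i], m.calls[j])

    def test_determinism_byte_identical_vcf(self, tmp_path):
        cfg = SimConfig(n_chromosomes=1, chrom_length=100_000, seed=9)
        for run in ("a", "b"):
            m, truth = simulate_sexual_population(cfg, 5)
            obs = apply_sequencing_model(m, cfg)
            write_simulation(obs, truth, truth_annotation(m, truth),
                             tmp_path / run / "sim")
        assert (tmp_path / "a" / "sim.vcf").read_bytes() == \
               (tmp_path / "b" / "sim.vcf").read_bytes()


class TestClonalComplex:
    def test_pure_clonality_identical_members(self):
        cfg = SimConfig(n_chromosomes=1, chrom_length=200_000, seed=4,
                        somatic_mutation_rate=0.0,
                        n_clonal_lineages=2, lineage_sizes=(3, 2))
        m, truth = simulate_clonal_complex(cfg)
        for lin in ("L1", "L2"):
            members = [i for i, s in enumerate(m.sample_ids)
                       if truth.clone_assignment[s] == lin]
            for i in members[1:]:
                assert np.array_equal(m.calls[members[0]], m.calls[i])

    def test_somatic_mutation_accumulation_rate(self):
        """Pairwise within-lineage differences ~ 2 * rate * generations."""
        rate, gens = 20.0, 10
        cfg = SimConfig(n_chromosomes=2, chrom_length=500_000, seed=5,
                        somatic_mutation_rate=rate, somatic_generations=gens,
                        n_clonal_lineages=1, lineage_sizes=(6,))
        m, _ = simulate_clonal_complex(cfg)
        diffs = [
            (m.calls[i] != m.calls[j]).sum()
            for i in range(6) for j in range(i + 1, 6)
        ]
        lam = 2 * rate * gens
        assert abs(np.mean(diffs) - lam) < 3 * np.sqrt(lam / len(diffs)) + 0.05 * lam


class TestHybrid:
    def test_fixed_differences_obligate_heterozygous(self):
        cfg = SimConfig(n_chromosomes=1, chrom_length=500_000, seed=6,
                        hybrid_divergence=0.01, polymorphism_density=0.001)
        m, truth = simulate_hybrid_apomict(cfg, 5)
        # expected ~ divergence x length obligate het sites per individual
        fixed = truth.haplotype_origin != "none"
        n_het = (m.calls == HET).sum(axis=1)
        expect = 0.01 * 500_000
        assert np.all(np.abs(n_het - expect) < 5 * np.sqrt(expect))

    def test_divergence_zero_rejected(self):
        cfg = SimConfig(hybrid_divergence=0.0, n_chromosomes=1,
                        chrom_length=100_000)
        with pytest.raises(ConfigurationError):
            simulate_hybrid_apomict(cfg, 3)

    def test_asymmetric_deleterious_origin(self):
        """2:1 E:W DEL fractions -> 2x het-DEL density of E origin.

        The per-origin DEL proportion among heterozygous 0-fold sites is
        the binomially distributed quantity; its ratio estimates the
        configured 2:1 asymmetry. The SE treats each site as one binomial
        draw (class assignment is shared across individuals).
        """
        cfg = SimConfig(
            n_chromosomes=2, chrom_length=2_000_000, seed=7,
            genes_per_chromosome=60,
            deleterious_fractions={
                "E": {"DEL": 0.4, "TOL": 0.5, "LOF": 0.1},
                "W": {"DEL": 0.2, "TOL": 0.7, "LOF": 0.1},
            },
        )
        m, truth = simulate_hybrid_apomict(cfg, 6)
        het = m.calls == HET
        is_del = truth.site_class == "DEL"
        zero = truth.degeneracy == "0-fold"
        props, z_sites = {}, {}
        for pool in ("E", "W"):
            o = truth.haplotype_origin == pool
            base = het[:, zero & o].sum()
            n_del = het[:, zero & o & is_del].sum()
            props[pool] = n_del / base
            z_sites[pool] = int((zero & o & het.any(axis=0)).sum())
        ratio = props["E"] / props["W"]
        log_var = (0.6 / (0.4 * z_sites["E"])) + (0.8 / (0.2 * z_sites["W"]))
        se = 2.0 * np.sqrt(log_var)
        assert abs(ratio - 2.0) < 3 * se


class TestEmbryoSet:
    def _mother(self, rng, n_sites=20_000, n_chrom=1):
        import pandas as pd

        per = n_sites // n_chrom
        frames = []
        for c in range(n_chrom):
            pos = np.sort(rng.choice(1_000_000, size=per, replace=False))
            frames.append(pd.DataFrame(
                {"chrom": f"chr{c + 1}", "pos": pos, "ref": "A", "alt": "T"}
            ))
        sites = pd.concat(frames, ignore_index=True)
        geno = rng.choice([HOM_REF, HET, HOM_ALT], size=len(sites),
                          p=[0.45, 0.3, 0.25]).astype(np.int8)
        return geno, sites

    def test_obligate_apomixis_embryos_equal_mother(self, rng):
        geno, sites = self._mother(rng)
        cfg = SimConfig(n_chromosomes=1, chrom_length=1_000_000,
                        p_sexual_embryo=0.0, seed=8)
        m, truth = simulate_embryo_set(geno, cfg, 10, sites)
        for i in range(10):
            assert np.array_equal(m.calls[i], geno)
        assert all(v != "sexual" for v in truth.clone_assignment.values())

    def test_homozygous_mother_selfing_is_identity(self, rng):
        geno, sites = self._mother(rng)
        geno[geno == HET] = HOM_REF
        cfg = SimConfig(n_chromosomes=1, chrom_length=1_000_000,
                        p_sexual_embryo=1.0, seed=9)
        m, _ = simulate_embryo_set(geno, cfg, 5, sites)
        for i in range(5):
            assert np.array_equal(m.calls[i], geno)

    def test_selfing_halves_heterozygosity(self, rng):
        """Mean retained het over 100 selfed embryos in [0.47, 0.53].

        Four chromosomes with three crossovers per meiosis give enough
        independent segments for the per-embryo retention (mean 1/2) to
        average tightly.
        """
        geno, sites = self._mother(rng, n_sites=40_000, n_chrom=4)
        maternal_het = (geno == HET).sum()
        assert maternal_het >= 10_000
        cfg = SimConfig(n_chromosomes=4, chrom_length=1_000_000,
                        p_sexual_embryo=1.0, crossovers_per_chromosome=3.0,
                        seed=10)
        m, _ = simulate_embryo_set(geno, cfg, 100, sites)
        retained = (m.calls == HET).sum(axis=1) / maternal_het
        assert 0.47 <= retained.mean() <= 0.53

    def test_crossover_count_recovery(self, rng):
        """Breakpoints per sexual embryo ~ Poisson(2 x lam) within 3 SE."""
        geno, sites = self._mother(rng, n_sites=5000)
        lam = 1.5
        cfg = SimConfig(n_chromosomes=1, chrom_length=1_000_000,
                        p_sexual_embryo=1.0, crossovers_per_chromosome=lam,
                        seed=11)
        m, truth = simulate_embryo_set(geno, cfg, 120, sites)
        counts = [len(truth.crossover_breakpoints[s]) for s in m.sample_ids]
        expect = 2 * lam  # two independent meioses
        se = np.sqrt(expect / len(counts))
        assert abs(np.mean(counts) - expect) < 3 * se

    def test_sexual_embryos_homozygous_inside_true_tracts(self, rng):
        geno, sites = self._mother(rng)
        cfg = SimConfig(n_chromosomes=1, chrom_length=1_000_000,
                        p_sexual_embryo=1.0, seed=12)
        m, truth = simulate_embryo_set(geno, cfg, 5, sites)
        pos = sites["pos"].to_numpy()
        for i, s in enumerate(m.sample_ids):
            for chrom, start, end in truth.true_loh_tracts[s]:
                in_tract = (pos >= start) & (pos < end)
                assert not np.any(m.calls[i, in_tract] == HET)

    def test_embryo_count_validated(self, rng):
        geno, sites = self._mother(rng, n_sites=100)
        cfg = SimConfig(n_chromosomes=1, chrom_length=1_000_000)
        with pytest.raises(ConfigurationError):
            simulate_embryo_set(geno, cfg, 0, sites)


class TestSequencingModel:
    def test_noiseless_high_depth_preserves_truth(self):
        cfg = SimConfig(n_chromosomes=1, chrom_length=200_000, seed=13,
                        genotype_error=0.0, missing_rate=0.0,
                        depth_mean_adult=1000.0)
        m, _ = simulate_sexual_population(cfg, 5)
        obs = apply_sequencing_model(m, cfg)
        assert np.array_equal(obs.calls, m.calls)

    def test_all_missing_at_rate_one(self):
        cfg = SimConfig(n_chromosomes=1, chrom_length=100_000, seed=14,
                        missing_rate=1.0)
        m, _ = simulate_sexual_population(cfg, 3)
        obs = apply_sequencing_model(m, cfg)
        assert np.all(obs.calls == MISSING)

    def test_het_allele_balance_binomial_tail(self):
        """Fraction of true hets outside balance 0.1-0.9 matches the
        binomial tail at 10x within 3 SE."""
        cfg = SimConfig(n_chromosomes=2, chrom_length=500_000, seed=15,
                        genotype_error=0.0, missing_rate=0.0,
                        depth_mean_embryo=10.0)
        m, _ = simulate_sexual_population(cfg, 10)
        obs = apply_sequencing_model(m, cfg, tissue="embryo")
        het = (obs.calls == HET) & (m.calls == HET)
        dp = obs.depth[het].astype(float)
        balance = obs.ad_alt[het] / dp
        outside = ((balance < 0.1) | (balance > 0.9)).mean()
        # expected tail: E_depth[P(Bin(d, .5)/d outside [.1,.9])]
        from scipy import stats

        ds = np.arange(1, 40)
        pd_ = stats.poisson.pmf(ds, 10.0) / stats.poisson.sf(0, 10.0)
        tails = []
        for d in ds:
            k = np.arange(0, d + 1)
            frac = k / d
            tails.append(stats.binom.pmf(k, d, 0.5)[(frac < 0.1) | (frac > 0.9)].sum())
        expect = float((pd_ * np.array(tails)).sum())
        se = np.sqrt(expect * (1 - expect) / het.sum())
        assert abs(outside - expect) < 3 * se + 1e-3

    def test_depth_zero_forces_missing(self):
        cfg = SimConfig(n_chromosomes=1, chrom_length=100_000, seed=16,
                        depth_mean_embryo=0.5, missing_rate=0.0,
                        genotype_error=0.0)
        m, _ = simulate_sexual_population(cfg, 3)
        obs = apply_sequencing_model(m, cfg, tissue="embryo")
        assert np.all(obs.calls[obs.depth == 0] == MISSING)


class TestTruthConservation:
    def test_every_site_has_one_class_and_degeneracy(self):
        cfg = SimConfig(n_chromosomes=2, chrom_length=500_000, seed=17)
        m, truth = simulate_sexual_population(cfg, 5)
        assert len(truth.site_class) == m.n_sites
        assert set(truth.site_class) <= {"SYN", "TOL", "DEL", "LOF", "none"}
        assert set(truth.degeneracy) <= {"0-fold", "4-fold", "other", "noncoding"}
        # functional classes only at codon-constrained sites
        coding = truth.degeneracy != "noncoding"
        assert np.all(truth.site_class[~coding] == "none")

    def test_all_samples_in_clone_assignment(self):
        cfg = SimConfig(n_chromosomes=1, chrom_length=200_000, seed=18,
                        n_clonal_lineages=2, lineage_sizes=(2, 3))
        m, truth = simulate_clonal_complex(cfg)
        assert set(m.sample_ids) <= set(truth.clone_assignment)

    def test_embryo_tracts_within_bounds_and_disjoint(self):
        cfg = SimConfig(n_chromosomes=2, chrom_length=400_000, seed=19,
                        p_sexual_embryo=1.0, n_embryos=10,
                        ancestral_loh_fraction=0.0)
        m, truth, _ = simulate_embryo_scenario(cfg)
        for s, tracts in truth.true_loh_tracts.items():
            by_chrom = {}
            for chrom, start, end in tracts:
                assert 0 <= start < end <= 400_000
                by_chrom.setdefault(chrom, []).append((start, end))
            for ivs in by_chrom.values():
                ivs.sort()
                for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                    assert e1 <= s2  # non-overlapping


class TestWriteSimulation:
    def test_round_trip_and_files(self, tmp_path):
        cfg = SimConfig(n_chromosomes=1, chrom_length=100_000, seed=20)
        m, truth = simulate_sexual_population(cfg, 4)
        obs = apply_sequencing_model(m, cfg)
        paths = write_simulation(obs, truth, truth_annotation(m, truth),
                                 tmp_path / "sim")
        again = read_vcf(paths["vcf"])
        assert np.array_equal(obs.calls, again.calls)
        for key in ("sites", "clones", "loh", "samples"):
            assert paths[key].exists()

    def test_vcf_passes_external_validator(self, tmp_path):
        """bcftools accepts the emitted VCF as well-formed."""
        cfg = SimConfig(n_chromosomes=1, chrom_length=100_000, seed=21)
        m, truth = simulate_sexual_population(cfg, 3)
        obs = apply_sequencing_model(m, cfg)
        paths = write_simulation(obs, truth, truth_annotation(m, truth),
                                 tmp_path / "sim")
        res = subprocess.run(
            ["bcftools", "view", str(paths["vcf"])],
            capture_output=True, text=True,
        )
        assert res.returncode == 0, res.stderr
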