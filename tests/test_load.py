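"""Degeneracy classification, polarization, derived-load accounting."""

import itertools

import numpy as np
import pandas as pd
import pytest

from apomixis_scan.genotypes import HET, HOM_ALT, HOM_REF, MISSING
from apomixis_scan.load import (
    GRANTHAM,
    SiteAnnotation,
    _CODE,
    annotate_degeneracy,
    classify_degeneracy,
    codon_position_degeneracy,
    compare_groups,
    derived_dosage,
    grantham_classify,
    grantham_score,
    load_counts,
    load_ratios,
    polarize,
    read_cds_gff3,
    read_fasta,
    zero_four_ratio,
)
from apomixis_scan.simulate import (
    SimConfig,
    add_outgroups,
    apply_sequencing_model,
    simulate_genome,
    simulate_sexual_population,
    truth_annotation,
    write_gff3,
    write_reference_fasta,
)

from conftest import make_matrix

BASES = "ACGT"


class TestDegeneracy:
    def test_exhaustive_codon_oracle(self):
        """Every codon x position agrees with brute-force enumeration."""
        for codon in map("".join, itertools.product(BASES, repeat=3)):
            for pos in range(3):
                aa = _CODE[codon]
                synonymous = sum(
                    _CODE[codon[:pos] + b + codon[pos + 1:]] == aa
                    for b in BASES if b != codon[pos]
                )
                expected = {3: "4-fold", 0: "0-fold"}.get(synonymous, "other")
                assert codon_position_degeneracy(codon, pos) == expected

    def test_known_positions(self):
        # third position of CTx (Leu) is 4-fold; second position always 0-fold
        assert codon_position_degeneracy("CTA", 2) == "4-fold"
        for codon in ("ATG", "GGG", "TTT"):
            assert codon_position_degeneracy(codon, 1) == "0-fold"

    def test_toy_gff_fasta_both_strands(self, tmp_path):
        """classify_degeneracy on a written GFF3+FASTA matches the per-codon
        labels of the generator (dual route, including minus-strand genes)."""
        cfg = SimConfig(n_chromosomes=1, chrom_length=30_000,
                        genes_per_chromosome=4, gene_length=300, seed=42)
        rng = np.random.default_rng(cfg.seed)
        genome = simulate_genome(cfg, rng)
        strands = {f["strand"] for f in genome.cds_features}
        assert strands == {"+", "-"}  # both orientations exercised
        sites = pd.DataFrame({"chrom": [], "pos": [], "ref": [], "alt": []})
        fasta = tmp_path / "ref.fa"
        gff = tmp_path / "genes.gff3"
        write_reference_fasta(genome, sites.assign(pos=pd.Series(dtype=int)),
                              fasta, rng)
        write_gff3(genome, gff)
        labels = classify_degeneracy(read_fasta(fasta), read_cds_gff3(gff))
        assert labels == genome.degeneracy

    def test_cds_not_multiple_of_three_skipped(self):
        ref = {"c": "ATGAAAT"}  # 7 bp CDS
        feats = [{"id": "g1", "chrom": "c", "strand": "+", "exons": [(0, 7)]}]
        with pytest.warns(UserWarning, match="divisible by 3"):
            labels = classify_degeneracy(ref, feats)
        assert labels == {}

    def test_annotate_maps_noncoding(self):
        labels = {("c", 5): "0-fold"}
        sites = pd.DataFrame({"chrom": ["c", "c"], "pos": [5, 99]})
        out = annotate_degeneracy(sites, labels)
        assert out.tolist() == ["0-fold", "noncoding"]


class TestGrantham:
    @pytest.mark.parametrize("score,expected", [(150, "DEL"), (149, "TOL"),
                                                (215, "DEL"), (0, "TOL")])
    def test_threshold_inclusive(self, score, expected):
        assert grantham_classify(score) == expected

    def test_cys_trp_is_maximal(self):
        assert grantham_score("C", "W") == 215
        assert max(GRANTHAM.values()) == 215

    def test_symmetry_and_coverage(self):
        # all 190 unordered amino-acid pairs present, symmetric
        assert len(GRANTHAM) == 380
        for (a, b), d in GRANTHAM.items():
            assert GRANTHAM[(b, a)] == d

    def test_vectorized(self):
        out = grantham_classify(np.array([10, 150, 200]))
        assert out.tolist() == ["TOL", "DEL", "DEL"]


class TestPolarize:
    def test_concordant_outgroups(self):
        m = make_matrix(
            [[HET, HET, HET],
             [HOM_REF, HOM_ALT, HET],
             [HOM_REF, HOM_ALT, HOM_REF]],
            sample_ids=["x", "o1", "o2"],
        )
        anc = polarize(m, ["o1", "o2"])
        assert anc.tolist() == [0, 1, -1]  # ref anc, alt anc, het outgroup

    def test_disagreeing_outgroups_unpolarized(self):
        m = make_matrix([[HET], [HOM_REF], [HOM_ALT]],
                        sample_ids=["x", "o1", "o2"])
        assert polarize(m, ["o1", "o2"])[0] == -1

    def test_missing_outgroup_call_unpolarized(self):
        m = make_matrix([[HET], [MISSING], [HOM_REF]],
                        sample_ids=["x", "o1", "o2"])
        assert polarize(m, ["o1", "o2"])[0] == -1

    def test_absent_outgroup_id_raises(self):
        m = make_matrix([[HET], [HOM_REF]], sample_ids=["x", "o1"])
        with pytest.raises(KeyError):
            polarize(m, ["o1", "nope"])

    def test_simulation_recovery_accuracy(self):
        """>= 99% polarization accuracy at 2% outgroup divergence."""
        cfg = SimConfig(n_chromosomes=2, chrom_length=500_000, seed=23,
                        outgroup_divergence=0.02)
        m, truth = simulate_sexual_population(cfg, 10)
        m2 = add_outgroups(m, truth, cfg)
        anc = polarize(m2, ["OUT1", "OUT2"])
        ok = anc != -1
        acc = (anc[ok] == truth.ancestral_allele[ok]).mean()
        assert acc >= 0.99


class TestLoadCounts:
    def _annotated(self, calls, classes, ancestral=None, origins=None):
        m = make_matrix(calls)
        n = m.n_sites
        ann = SiteAnnotation(pd.DataFrame({
            "chrom": m.sites["chrom"],
            "pos": m.sites["pos"],
            "degeneracy": "0-fold",
            "func_class": classes,
            "ancestral": ancestral if ancestral is not None else np.zeros(n, int),
            "haplotype_origin": origins if origins is not None else "none",
        }))
        return m, ann

    def test_hand_arithmetic(self):
        """12 het + 30 hom DEL -> total 72, pct_hom = 60/72 ~ 83.3%."""
        calls = np.array([[HET] * 12 + [HOM_ALT] * 30], dtype=np.int8)
        m, ann = self._annotated(calls, ["DEL"] * 42)
        out = load_counts(m, ann)
        row = out[out["class"] == "DEL"].iloc[0]
        assert row["n_het"] == 12 and row["n_hom"] == 30
        assert row["total_derived"] == 72
        assert row["pct_hom"] == pytest.approx(60 / 72)

    def test_fully_masked_load(self):
        calls = np.array([[HET] * 10], dtype=np.int8)
        m, ann = self._annotated(calls, ["DEL"] * 10)
        row = load_counts(m, ann).query("`class` == 'DEL'").iloc[0]
        assert row["pct_hom"] == 0

    def test_alt_ancestral_counts_ref_homozygote_as_derived(self):
        calls = np.array([[HOM_REF, HET, HOM_ALT]], dtype=np.int8)
        m, ann = self._annotated(calls, ["DEL"] * 3,
                                 ancestral=np.array([1, 1, 1]))
        row = load_counts(m, ann).query("`class` == 'DEL'").iloc[0]
        # hom-ref = 2 derived, het = 1, hom-alt (ancestral) = 0
        assert row["n_het"] == 1 and row["n_hom"] == 1
        assert row["total_derived"] == 3

    def test_unpolarized_and_missing_excluded(self):
        calls = np.array([[HET, HET, MISSING]], dtype=np.int8)
        m, ann = self._annotated(calls, ["DEL"] * 3,
                                 ancestral=np.array([0, -1, 0]))
        row = load_counts(m, ann).query("`class` == 'DEL'").iloc[0]
        assert row["total_derived"] == 1

    def test_conservation_across_strata(self, rng):
        """Stratum counts sum to the unstratified totals."""
        n = 400
        calls = rng.integers(-1, 3, size=(3, n)).astype(np.int8)
        classes = rng.choice(["SYN", "DEL", "LOF", "TOL"], size=n)
        origins = rng.choice(["E", "W"], size=n)
        m, ann = self._annotated(calls, classes, origins=origins)
        total = load_counts(m, ann)
        origin_arr = ann.table["haplotype_origin"].to_numpy()
        parts = [
            load_counts(m, ann, site_mask=origin_arr == p, stratum=p)
            for p in ("E", "W")
        ]
        combined = pd.concat(parts).groupby(["sample", "class"])[
            ["n_het", "n_hom", "total_derived"]].sum()
        for (s, c), row in combined.iterrows():
            ref = total[(total["sample"] == s) & (total["class"] == c)].iloc[0]
            assert row["n_het"] == ref["n_het"]
            assert row["total_derived"] == ref["total_derived"]
        # identity n_het + 2 n_hom = total everywhere
        assert (total["n_het"] + 2 * total["n_hom"]
                == total["total_derived"]).all()

    def test_ratios_nan_on_zero_denominator(self):
        calls = np.array([[HET, HET]], dtype=np.int8)
        m, ann = self._annotated(calls, ["DEL", "LOF"])
        ratios = load_ratios(load_counts(m, ann))
        assert np.isnan(ratios["het_del_syn"].iloc[0])  # no SYN hets

    def test_pct_hom_invariant_to_duplication(self, rng):
        calls = rng.integers(0, 3, size=(1, 200)).astype(np.int8)
        m1, ann = self._annotated(calls, ["DEL"] * 200)
        m2, _ = self._annotated(np.vstack([calls, calls]), ["DEL"] * 200)
        r1 = load_counts(m1, ann).query("`class` == 'DEL'")["pct_hom"].iloc[0]
        r2 = load_counts(m2, ann).query("`class` == 'DEL'")["pct_hom"]
        assert (r2 == r1).all()


class TestZeroFourRatio:
    def test_equal_rates_ratio_one(self):
        calls = np.array([[HET, HOM_REF, HET, HOM_REF]], dtype=np.int8)
        deg = np.array(["0-fold", "0-fold", "4-fold", "4-fold"])
        out = zero_four_ratio(make_matrix(calls), deg)
        assert out["ratio"].iloc[0] == pytest.approx(1.0)

    def test_zero_at_zero_fold_gives_zero(self):
        calls = np.array([[HOM_REF, HET]], dtype=np.int8)
        deg = np.array(["0-fold", "4-fold"])
        assert zero_four_ratio(make_matrix(calls), deg)["ratio"].iloc[0] == 0

    def test_no_four_fold_hets_gives_nan(self):
        calls = np.array([[HET, HOM_REF]], dtype=np.int8)
        deg = np.array(["0-fold", "4-fold"])
        assert np.isnan(zero_four_ratio(make_matrix(calls), deg)["ratio"].iloc[0])

    def test_construction_oracle_halved_zero_fold_density(self, rng):
        """Thinning 0-fold polymorphism to half the 4-fold rate gives
        a ratio near 0.5."""
        n = 30_000
        p_het4, p_het0 = 0.2, 0.1
        calls4 = (rng.random((8, n)) < p_het4).astype(np.int8)
        calls0 = (rng.random((8, n)) < p_het0).astype(np.int8)
        calls = np.concatenate([calls4, calls0], axis=1)
        deg = np.array(["4-fold"] * n + ["0-fold"] * n)
        m = make_matrix(calls, positions=np.arange(2 * n))
        out = zero_four_ratio(m, deg)
        se = 0.5 * np.sqrt(1 / (p_het0 * n) + 1 / (p_het4 * n))
        assert np.all(np.abs(out["ratio"] - 0.5) < 3 * se)


class TestCompareGroups:
    def test_identical_groups_wilcoxon_p_one(self):
        stat, p, stars = compare_groups([1, 2, 3], [1, 2, 3], test="wilcoxon")
        assert p == pytest.approx(1.0)
        assert stars == "ns"

    def test_separated_groups_welch(self):
        stat, p, stars = compare_groups([1, 2, 3], [11, 12, 13], test="welch")
        # closed form: mean diff 10, pooled se = sqrt(2/3); t ~ 12.2
        assert p < 0.01
        assert stars in ("**", "***")

    def test_welch_matches_closed_form(self):
        a, b = np.array([1.0, 2, 3]), np.array([11.0, 12, 13])
        t_expect = (a.mean() - b.mean()) / np.sqrt(a.var(ddof=1) / 3 + b.var(ddof=1) / 3)
        stat, _, _ = compare_groups(a, b, test="welch")
        assert stat == pytest.approx(t_expect)

    def test_degenerate_group_warns_nan(self):
        with pytest.warns(UserWarning):
            stat, p, _ = compare_groups([1.0], [2.0, 3.0], test="welch")
        assert np.isnan(p)

    def test_unknown_test_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1], [2], test="bayes")
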