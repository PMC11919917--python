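"""Informative-SNP selection, proband-anchored phasing, embryo verdicts."""

import numpy as np
import pytest

from pgtdup.genotypes import GenotypeCall, SnpSite
from pgtdup.linkage import (HIGH_RISK, INCONCLUSIVE, LOW_RISK, PhasingError,
                            InformativeSnp, PhasedPaternalHaplotypes,
                            classify_embryo, compute_distance, linkage_report,
                            phase_paternal, select_informative_snps)
from pgtdup.regions import GenomicRegion
from pgtdup.simulate import (DUP_REGION, SimConfig, simulate_embryo,
                             simulate_pedigree, true_genotypes)


class TestComputeDistance:
    def test_all_printed_distances_reproduced(self, table1, dup_region):
        flanking = {r: d for r, d in table1.printed_distance.items()
                    if d is not None}
        assert len(flanking) == 12
        for site in table1.sites:
            if site.rsid in flanking:
                assert compute_distance(site, dup_region) == flanking[site.rsid]

    def test_inside_and_boundary_positions(self, dup_region):
        at_start = SnpSite("rs_b", "chr1", dup_region.start)
        assert compute_distance(at_start, dup_region) is None
        just_before = SnpSite("rs_a", "chr1", dup_region.start - 1)
        assert compute_distance(just_before, dup_region) == -1

    def test_chromosome_mismatch_is_error(self, dup_region):
        with pytest.raises(ValueError, match="chr2"):
            compute_distance(SnpSite("rs_x", "chr2", 5), dup_region)


class TestSelectInformative:
    def test_fixture_panel_classes(self, table1, dup_region):
        inf = select_informative_snps(
            table1.calls["Male"], table1.calls["Female"],
            table1.calls["Proband"], dup_region)
        assert len(inf) == 22
        sides = {"upstream": 0, "downstream": 0, "inside": 0}
        for s in inf:
            sides[s.side] += 1
        assert sides == {"upstream": 9, "downstream": 3, "inside": 10}
        assert all(s.snp_class == "within_dup" for s in inf
                   if s.side == "inside")

    def test_non_informative_configurations_excluded(self, dup_region):
        pos_flank, pos_in = dup_region.start - 1000, dup_region.start + 1000
        cases = [
            # father homozygous
            (pos_flank, "C/C", "C/C", "C/C"),
            # mother heterozygous
            (pos_flank, "C/G", "C/G", "C/C"),
            # inside but proband het
            (pos_in, "T/C", "T/T", "T/C"),
            # inside, proband hom for the non-maternal allele
            (pos_in, "T/C", "T/T", "C/C"),
        ]
        for pos, f, m, p in cases:
            site = SnpSite("rs_c", "chr1", pos, "C", "G")
            inf = select_informative_snps(
                {site: GenotypeCall.from_string(f)},
                {site: GenotypeCall.from_string(m)},
                {site: GenotypeCall.from_string(p)}, dup_region)
            assert inf == []

    def test_flank_window_is_respected(self, dup_region):
        far = SnpSite("rs_far", "chr1", dup_region.start - 2_000_001, "C", "G")
        near = SnpSite("rs_near", "chr1", dup_region.start - 2_000_000, "C", "G")
        father = {s: GenotypeCall.from_string("C/G") for s in (far, near)}
        mother = {s: GenotypeCall.from_string("C/C") for s in (far, near)}
        inf = select_informative_snps(father, mother, {}, dup_region)
        assert [s.site.rsid for s in inf] == ["rs_near"]


class TestPhasing:
    def test_fixture_haplotypes_match_printed_columns(self, table1,
                                                      phased_table1):
        printed = {r: (h1, table1.printed_hap2[r])
                   for r, h1 in table1.printed_hap1.items() if h1}
        assert len(printed) == 12
        checked = 0
        for snp in phased_table1:
            if snp.site.rsid in printed:
                assert (snp.hap1_allele, snp.hap2_allele) == printed[snp.site.rsid]
                checked += 1
        assert checked == 12

    def test_within_duplication_hap1_is_maternal_allele(self, phased_table1):
        inside = [s for s in phased_table1 if s.snp_class == "within_dup"]
        assert len(inside) == 10
        for s in inside:
            assert s.hap1_allele == s.mother_allele
            assert s.hap2_allele != s.mother_allele

    def test_mendelian_inconsistent_proband_site_dropped(self, dup_region):
        site = SnpSite("rs_m", "chr1", dup_region.start - 500, "C", "G")
        inf = [InformativeSnp(site, "flanking", "upstream", -500,
                              ("C", "G"), "C")]
        with pytest.raises(PhasingError):
            # proband G/G impossible given mother C/C; site dropped, none left
            phase_paternal(inf, {site: GenotypeCall.from_string("C/C")},
                           {site: GenotypeCall.from_string("G/G")})

    def test_noise_free_phasing_recovers_simulated_haplotype(self):
        """On exact genotypes, hap1 equals the duplication-bearing haplotype
        at every phaseable informative site."""
        for seed in range(5):
            cfg = SimConfig(seed=seed, n_snps_flank=40, n_snps_inside=20)
            truth = simulate_pedigree(cfg)
            father = true_genotypes("father", truth)
            mother = true_genotypes("mother", truth)
            proband = true_genotypes("proband", truth)
            inf = select_informative_snps(father, mother, proband,
                                          cfg.dup_region, cfg.flank_bp)
            phased = phase_paternal(inf, mother, proband)
            index = {s: i for i, s in enumerate(truth.snp_panel)}
            for snp in phased:
                i = index[snp.site]
                assert snp.hap1_allele == truth.paternal_hap1[i]
                assert snp.hap2_allele == truth.paternal_hap2[i]


class TestClassifyEmbryo:
    def test_fixture_embryo_verdicts(self, table1, phased_table1):
        expected = {"E1": HIGH_RISK, "E2": LOW_RISK, "E3": HIGH_RISK,
                    "E4": HIGH_RISK, "E5": LOW_RISK}
        for embryo, want in expected.items():
            v = classify_embryo(table1.calls[embryo], phased_table1)
            assert v.status == want, embryo
            assert not v.recombination_flag

    def test_low_risk_embryo_votes_all_hap2(self, table1, phased_table1):
        v = classify_embryo(table1.calls["E2"], phased_table1)
        called = [vote for vote in v.votes.values() if vote != "no_call"]
        assert called and all(vote == "hap2" for vote in called)
        assert v.n_informative_used == 20  # two no-call sites skipped
        assert v.upstream_consistency == v.downstream_consistency == 1.0

    def test_all_no_call_is_inconclusive(self, table1, phased_table1):
        empty = {}
        v = classify_embryo(empty, phased_table1)
        assert v.status == INCONCLUSIVE
        assert v.n_informative_used == 0

    def test_haplotype_relabel_symmetry(self, table1, phased_table1):
        """Swapping hap1/hap2 labels at flanking SNPs flips every verdict.

        Only flanking markers are symmetric under relabelling: the
        within-duplication vote rule is tied to the duplication carrier
        being homozygous like the proband, so it is excluded here.
        """
        flanking = [s for s in phased_table1 if s.snp_class == "flanking"]
        straight = PhasedPaternalHaplotypes(snps=flanking)
        flipped = PhasedPaternalHaplotypes(snps=[
            InformativeSnp(s.site, s.snp_class, s.side, s.distance_bp,
                           s.father_alleles, s.mother_allele,
                           hap1_allele=s.hap2_allele,
                           hap2_allele=s.hap1_allele)
            for s in flanking])
        swap = {HIGH_RISK: LOW_RISK, LOW_RISK: HIGH_RISK,
                INCONCLUSIVE: INCONCLUSIVE}
        for embryo in ("E1", "E2", "E3", "E4", "E5"):
            before = classify_embryo(table1.calls[embryo], straight)
            after = classify_embryo(table1.calls[embryo], flipped)
            assert before.status != INCONCLUSIVE
            assert after.status == swap[before.status]

    def test_flank_disagreement_raises_recombination_flag(self, dup_region):
        sites = {}
        snps = []
        for k, (pos, side) in enumerate([
                (dup_region.start - 1000, "upstream"),
                (dup_region.start - 500, "upstream"),
                (dup_region.end + 500, "downstream"),
                (dup_region.end + 1000, "downstream")]):
            site = SnpSite(f"rs_r{k}", "chr1", pos, "A", "G")
            snps.append(InformativeSnp(site, "flanking", side,
                                       compute_distance(site, dup_region),
                                       ("A", "G"), "A",
                                       hap1_allele="A", hap2_allele="G"))
            # upstream sites vote hap1 (A/A), downstream vote hap2 (A/G)
            sites[site] = GenotypeCall.from_string(
                "A/A" if side == "upstream" else "A/G")
        v = classify_embryo(sites, PhasedPaternalHaplotypes(snps=snps))
        assert v.recombination_flag
        assert v.status == INCONCLUSIVE

    def test_crossover_between_flanks_is_flagged_not_called(self):
        cfg = SimConfig(seed=21, n_snps_flank=20, n_snps_inside=0,
                        recomb_prob=1.0)
        truth = simulate_pedigree(cfg)
        mother = true_genotypes("mother", truth)
        father = true_genotypes("father", truth)
        proband = true_genotypes("proband", truth)
        inf = select_informative_snps(father, mother, proband,
                                      cfg.dup_region, cfg.flank_bp)
        phased = phase_paternal(inf, mother, proband)
        rng = np.random.default_rng(21)
        flagged = 0
        for _ in range(40):
            emb = simulate_embryo(truth, cfg, rng=rng)
            calls = true_genotypes("embryo", truth, emb)
            v = classify_embryo(calls, phased)
            # a crossover between the flanks must never yield a risk call
            # with discordant flank majorities
            if v.recombination_flag:
                flagged += 1
                assert v.status == INCONCLUSIVE
        assert flagged > 0


class TestLinkageReport:
    def test_fixture_report_shape(self, table1, phased_table1):
        verdicts = {e: classify_embryo(table1.calls[e], phased_table1)
                    for e in ("E1", "E2", "E3", "E4", "E5")}
        df = linkage_report(verdicts)
        assert len(df) == 5
        assert set(df["status"]) == {HIGH_RISK, LOW_RISK}
        e2 = df[df["embryo"] == "E2"].iloc[0]
        assert e2["n_no_call"] == 2

    def test_empty_input_keeps_header(self):
        df = linkage_report({})
        assert len(df) == 0
        assert "recombination_flag" in df.columns

    def test_simulated_cohort_row_count(self):
        cfg = SimConfig(seed=22, recomb_prob=0.0)
        truth = simulate_pedigree(cfg)
        phased = phase_paternal(
            select_informative_snps(true_genotypes("father", truth),
                                    true_genotypes("mother", truth),
                                    true_genotypes("proband", truth),
                                    cfg.dup_region, cfg.flank_bp),
            true_genotypes("mother", truth), true_genotypes("proband", truth))
        rng = np.random.default_rng(22)
        verdicts = {
            f"E{i}": classify_embryo(
                true_genotypes("embryo", truth,
                               simulate_embryo(truth, cfg, rng=rng)), phased)
            for i in range(200)
        }
        assert len(linkage_report(verdicts)) == 200
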