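"""Filtering semantics, haplotype enumeration, informative subsets, typing."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from phshap.haplotypes import (Haplotype, assign_to_haplotypes,
                               enumerate_haplotypes, filter_panel,
                               reconstruct_haplotypes, select_informative_snps,
                               site_allele_frequency)
from phshap.synthetic import (SimulationConfig, generate_founder_haplotypes,
                              generate_panel, make_sites)
from phshap.variant_io import (GenotypeMatrix, HET, HOM_ALT, HOM_REF, MISSING)
from tests.conftest import random_matrix, subset_founders


def _matrix(rows, n_sites=None):
    rows = np.array(rows, dtype=np.int8)
    n_sites = rows.shape[1]
    return GenotypeMatrix([f"a{i}" for i in range(rows.shape[0])],
                          make_sites(n_sites, seed=0), rows)


class TestSiteAlleleFrequency:
    def test_monomorphic_is_zero(self):
        m = _matrix([[HOM_REF]] * 10)
        assert site_allele_frequency(m, 0) == 0.0

    def test_hand_counted_minor_frequency(self):
        # 4 hom-alt among 41 accessions, rest hom-ref: 8/82 alt alleles
        m = _matrix([[HOM_ALT]] * 4 + [[HOM_REF]] * 37)
        assert site_allele_frequency(m, 0) == pytest.approx(4 / 41)

    def test_het_counts_one_of_each(self):
        m = _matrix([[HET], [HOM_REF]])
        assert site_allele_frequency(m, 0) == pytest.approx(0.25)

    def test_all_missing_is_zero(self):
        m = _matrix([[MISSING]] * 3)
        assert site_allele_frequency(m, 0) == 0.0

    def test_minor_allele_symmetry(self):
        m = _matrix([[HOM_ALT]] * 9 + [[HOM_REF]])
        assert site_allele_frequency(m, 0) == pytest.approx(0.1)


class TestFilterPanel:
    def test_exact_thresholds_dropped(self):
        # site 0: exactly 5% MAF (1 alt allele in 10 diploid = 1/20);
        # site 1: common. accession a0: exactly 80% homozygous over kept sites.
        calls = np.full((10, 6), HOM_REF, dtype=np.int8)
        calls[:5, 1:6] = HOM_ALT
        calls[0, 0] = HET            # 1/20 alt at site 0 -> MAF 0.05
        calls[0, 1] = HET            # a0: 4 hom of 5 non-missing kept calls
        m = GenotypeMatrix([f"a{i}" for i in range(10)], make_sites(6, 0), calls)
        out, report = filter_panel(m, maf_min=0.05, hom_min=0.80)
        assert report.site_maf[m.sites[0].site_id] == pytest.approx(0.05)
        assert m.sites[0].site_id not in [s.site_id for s in out.sites]
        assert report.accession_homozygosity["a0"] == pytest.approx(0.80)
        assert "a0" not in out.accessions

    def test_survey_panel_reduction(self, survey_matrix):
        out, report = filter_panel(survey_matrix)
        assert (report.sites_in, report.sites_kept) == (51, 39)
        assert (report.accessions_in, report.accessions_kept) == (62, 58)

    def test_empty_result_is_error(self):
        m = _matrix([[HOM_REF, HOM_REF]] * 4)
        with pytest.raises(ValueError):
            filter_panel(m)

    @given(seed=st.integers(0, 10_000))
    def test_monotonic_in_thresholds(self, seed):
        rng = np.random.default_rng(seed)
        m = random_matrix(rng, n_acc=15, n_sites=10)
        try:
            _, lo = filter_panel(m, maf_min=0.05, hom_min=0.6)
        except ValueError:
            return
        for maf_min, hom_min in [(0.10, 0.6), (0.05, 0.8), (0.2, 0.9)]:
            try:
                _, hi = filter_panel(m, maf_min=maf_min, hom_min=hom_min)
            except ValueError:
                continue
            assert hi.sites_kept <= lo.sites_kept
            assert hi.accessions_kept <= lo.accessions_kept


class TestReconstruct:
    def test_all_hom_ref(self):
        m = _matrix([[HOM_REF] * 5])
        strings, un = reconstruct_haplotypes(m)
        assert strings == {"a0": "RRRRR"} and not un

    def test_het_or_missing_unassigned_with_sites(self):
        m = _matrix([[HOM_REF, MISSING, HOM_ALT]])
        strings, un = reconstruct_haplotypes(m)
        assert not strings
        assert un["a0"] == [m.sites[1].site_id]

    def test_noise_free_panel_recovers_founders(self):
        cfg = SimulationConfig(n_founder_haplotypes=6, n_sites=15,
                               n_accessions=24, het_rate=0, missing_rate=0,
                               seed=17)
        founders = generate_founder_haplotypes(cfg)
        panel = generate_panel(founders, cfg)
        strings, un = reconstruct_haplotypes(panel.matrix)
        assert not un
        haps = enumerate_haplotypes(strings)
        assert {h.alleles for h in haps} == {f.alleles for f in founders}
        # membership matches the planted assignment
        truth = {f.alleles: {a for a, fn in panel.founder_of.items()
                             if fn == f.name} for f in founders}
        for h in haps:
            assert set(h.members) == truth[h.alleles]

    @pytest.mark.parametrize("seed", range(100))
    def test_recovery_over_many_seeds(self, seed):
        cfg = SimulationConfig(n_founder_haplotypes=4, n_sites=8,
                               n_accessions=10, het_rate=0, missing_rate=0,
                               maf_floor=0.0, seed=seed)
        founders = generate_founder_haplotypes(cfg)
        panel = generate_panel(founders, cfg)
        strings, _ = reconstruct_haplotypes(panel.matrix)
        assert ({h.alleles for h in enumerate_haplotypes(strings)}
                == {f.alleles for f in founders})


class TestEnumerate:
    def test_grouping_and_descending_names(self):
        haps = enumerate_haplotypes({"x": "RA", "y": "RA", "z": "AA"})
        assert [(h.name, h.alleles, h.n_members) for h in haps] == [
            ("H1", "RA", 2), ("H2", "AA", 1)]

    def test_all_identical_single_haplotype(self):
        haps = enumerate_haplotypes({"x": "RR", "y": "RR"})
        assert len(haps) == 1 and set(haps[0].members) == {"x", "y"}

    def test_partition_property(self):
        strings = {f"a{i}": s for i, s in enumerate(
            ["RA", "AA", "RA", "RR", "AA", "RA"])}
        haps = enumerate_haplotypes(strings)
        members = [a for h in haps for a in h.members]
        assert sorted(members) == sorted(strings)
        assert len(members) == len(set(members))

    def test_tie_break_by_first_occurrence(self):
        haps = enumerate_haplotypes({"b": "AA", "a": "RR"})
        assert haps[0].alleles == "AA"


class TestInformativeSubset:
    def test_single_discriminating_site(self):
        haps = [Haplotype("H1", "RR", members=("a",)),
                Haplotype("H2", "RA", members=("b",))]
        subset, unresolved = select_informative_snps(haps, k=1)
        assert subset == [1] and unresolved == 0

    def test_separates_planted_haplotypes(self, clean_panel):
        strings, _ = reconstruct_haplotypes(clean_panel.matrix)
        haps = enumerate_haplotypes(strings)
        subset, unresolved = select_informative_snps(haps, k=7)
        assert unresolved == 0 and len(subset) <= 7
        # verify distinguishability exhaustively over all haplotype pairs
        for i in range(len(haps)):
            for j in range(i + 1, len(haps)):
                assert any(haps[i].alleles[s] != haps[j].alleles[s]
                           for s in subset)

    def test_greedy_matches_exhaustive_resolution(self):
        founders = subset_founders()
        patterns = list(dict.fromkeys(f.alleles[:6] for f in founders))
        weighted = [Haplotype(f"H{i + 1}", p, members=(f"m{i}",))
                    for i, p in enumerate(patterns)]
        greedy, un_g = select_informative_snps(weighted, k=6, maf_min=0.0)
        exact, un_e = select_informative_snps(weighted, k=6, maf_min=0.0,
                                              exhaustive=True)
        assert un_g == un_e == 0
        assert len(greedy) >= len(exact)

    def test_k_exceeding_candidates_returns_all_useful(self):
        haps = [Haplotype("H1", "RR", members=("a",)),
                Haplotype("H2", "AA", members=("b",))]
        subset, unresolved = select_informative_snps(haps, k=10)
        assert unresolved == 0 and len(subset) == 1  # second site adds no pair

    def test_no_candidates_is_error(self):
        haps = [Haplotype("H1", "R", members=tuple(f"a{i}" for i in range(9))),
                Haplotype("H2", "A", members=("b",))]  # MAF 0.1 < 0.30
        with pytest.raises(ValueError):
            select_informative_snps(haps, k=1)


class TestAssign:
    def _refs(self):
        sites = ["S1", "S2", "S3", "S4"]
        refs = [Haplotype("H1", "RRRR"), Haplotype("H2", "RRRA"),
                Haplotype("H5", "AARR"), Haplotype("H7", "AARA")]
        return refs, sites

    def _panel(self, rows):
        rows = np.array(rows, dtype=np.int8)
        sites = make_sites(rows.shape[1], seed=1)[:2]
        return GenotypeMatrix([f"n{i}" for i in range(rows.shape[0])],
                              sites, rows)

    def test_unique_and_compound_and_novel(self):
        refs, ref_sites = self._refs()
        m = self._panel([[HOM_REF, HOM_REF],   # RR -> H1/H2 collision
                         [HOM_ALT, HOM_ALT],   # AA -> H5/H7 collision
                         [HOM_REF, HOM_ALT],   # RA -> novel
                         [HOM_ALT, HET]])      # het -> unassigned
        subset = [s.site_id for s in m.sites]
        # project references onto the first two sites (S001, S002)
        assigned, unassigned = assign_to_haplotypes(
            m, subset, refs, ["S001", "S002", "S3", "S4"])
        assert assigned["n0"] == "H1/H2"
        assert assigned["n1"] == "H5/H7"
        assert assigned["n2"] == "N1"
        assert "n3" in unassigned

    def test_unique_match_on_full_projection(self):
        refs = [Haplotype("H1", "RR"), Haplotype("H12", "AA")]
        m = self._panel([[HOM_ALT, HOM_ALT]])
        assigned, _ = assign_to_haplotypes(
            m, [s.site_id for s in m.sites], refs,
            [s.site_id for s in m.sites])
        assert assigned["n0"] == "H12"

    def test_projection_soundness_on_generated_panel(self, clean_panel):
        strings, _ = reconstruct_haplotypes(clean_panel.matrix)
        haps = enumerate_haplotypes(strings)
        subset_idx, _ = select_informative_snps(haps, k=10, maf_min=0.0)
        subset_ids = [clean_panel.matrix.sites[j].site_id for j in subset_idx]
        ref_ids = [s.site_id for s in clean_panel.matrix.sites]
        assigned, unassigned = assign_to_haplotypes(
            clean_panel.matrix, subset_ids, haps, ref_ids)
        assert not unassigned
        by_founder = {f.name: f.alleles for f in clean_panel.founders}
        hap_of_string = {h.alleles: h.name for h in haps}
        for acc, label in assigned.items():
            true_name = hap_of_string[by_founder[clean_panel.founder_of[acc]]]
            assert true_name in label.split("/")
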