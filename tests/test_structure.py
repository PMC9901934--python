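"""Structure mapping: categories, on/off split, Mann-Whitney, duplex energies."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ribodms.reference import Genotype, PairedRegion, RibozymeReference
from ribodms.structure import (
    CANONICAL_PAIRS,
    DUPLEX_INIT,
    MismatchCategory,
    STACKS,
    TERMINAL_AU_GU,
    WC_PAIRS,
    classify_double_mutant,
    duplex_mfe,
    is_wc_restoring,
    mann_whitney,
    median_single_ra,
    on_off_diagonal_split,
    stability_correlation,
)


def two_pair_ref(b5a="G", b3a="C", b5b="A", b3b="U"):
    """Reference 'xy..yx' with one region of two pairs (0,5) and (1,4)."""
    seq = b5a + b5b + "AA" + b3b + b3a
    region = PairedRegion("P1", ((0, 5), (1, 4)))
    return RibozymeReference(
        name="r", sequence=seq, leader="GG", paired_regions=[region]
    ), region


class TestClassifyDoubleMutant:
    def test_restored_pair_is_wc_gu(self):
        ref, region = two_pair_ref()
        g = Genotype(((0, "A"), (5, "U")))  # G:C -> A:U
        assert classify_double_mutant(region, g, ref) is MismatchCategory.WC_GU

    def test_one_wobble_one_mismatch(self):
        ref, region = two_pair_ref()
        # G:C -> A:C mismatch; A:U -> G:U wobble
        g = Genotype(((0, "A"), (1, "G")))
        assert classify_double_mutant(region, g, ref) is MismatchCategory.ONE_MISMATCH

    def test_two_broken_pairs(self):
        ref, region = two_pair_ref()
        g = Genotype(((0, "A"), (4, "C")))  # A:C and A:C
        assert classify_double_mutant(region, g, ref) is MismatchCategory.TWO_MISMATCH

    def test_positions_outside_region_are_not_in_region(self):
        ref, region = two_pair_ref()
        g = Genotype(((0, "A"), (2, "C")))  # position 2 is a loop
        assert classify_double_mutant(region, g, ref) is MismatchCategory.NOT_IN_REGION

    def test_requires_order_two(self):
        ref, region = two_pair_ref()
        with pytest.raises(ValueError):
            classify_double_mutant(region, Genotype(((0, "A"),)), ref)

    def test_agrees_with_nine_way_enumeration_on_shipped_refs(self, shipped_ref):
        """Brute-force oracle: for every pair and all 9 partner substitutions,
        count non-canonical results directly."""
        for region in shipped_ref.paired_regions:
            for p5, p3 in region.pairs:
                for a5 in shipped_ref.alternatives(p5):
                    for a3 in shipped_ref.alternatives(p3):
                        g = Genotype(((p5, a5), (p3, a3)))
                        expected = (
                            MismatchCategory.WC_GU
                            if a5 + a3 in CANONICAL_PAIRS
                            else MismatchCategory.ONE_MISMATCH
                        )
                        assert classify_double_mutant(region, g, shipped_ref) is expected

    def test_categories_exhaustive_over_in_region_doubles(self, shipped_ref):
        cats = set()
        for region in shipped_ref.paired_regions:
            positions = sorted(region.positions)
            for p1, p2 in itertools.combinations(positions, 2):
                for a1 in shipped_ref.alternatives(p1):
                    for a2 in shipped_ref.alternatives(p2):
                        g = Genotype(((p1, a1), (p2, a2)))
                        cat = classify_double_mutant(region, g, shipped_ref)
                        assert cat is not MismatchCategory.NOT_IN_REGION
                        cats.add(cat)
        assert cats <= {
            MismatchCategory.WC_GU,
            MismatchCategory.ONE_MISMATCH,
            MismatchCategory.TWO_MISMATCH,
        }


class TestOnOffDiagonal:
    def records_for(self, ref, region, eps_value=0.0):
        rows = []
        positions = sorted(region.positions)
        for p1, p2 in itertools.combinations(positions, 2):
            for a1 in ref.alternatives(p1):
                for a2 in ref.alternatives(p2):
                    rows.append((f"{p1}:{a1}", f"{p2}:{a2}", eps_value))
        return pd.DataFrame(rows, columns=["mut_i", "mut_j", "epsilon"])

    def test_single_gc_pair_has_three_wc_restoring_doubles(self):
        seq = "GAAC"
        region = PairedRegion("P1", ((0, 3),))
        ref = RibozymeReference(
            name="r", sequence=seq, leader="GG", paired_regions=[region]
        )
        restoring = [
            (a5, a3)
            for a5 in ref.alternatives(0)
            for a3 in ref.alternatives(3)
            if is_wc_restoring(region, Genotype(((0, a5), (3, a3))), ref)
        ]
        assert sorted(restoring) == [("A", "U"), ("C", "G"), ("U", "A")]

    def test_wobble_restoring_double_goes_off_diagonal(self):
        ref, region = two_pair_ref()
        g = Genotype(((0, "U"), (5, "G")))  # G:C -> U:G wobble, not strict WC
        assert not is_wc_restoring(region, g, ref)

    def test_all_zero_epsilons_give_zero_means(self):
        ref, region = two_pair_ref()
        records = self.records_for(ref, region, eps_value=0.0)
        split = on_off_diagonal_split(region, records, ref)
        assert split["mu_on"] == 0.0 and split["mu_off"] == 0.0
        assert len(split["on"]) + len(split["off"]) == len(records)


class TestMannWhitney:
    @staticmethod
    def oracle(x, y):
        """Independent enumeration over all C(m+n, m) label assignments."""
        pooled = list(x) + list(y)
        m = len(x)

        def u_of(xs, ys):
            return sum(
                (1.0 if a > b else 0.5 if a == b else 0.0) for a in xs for b in ys
            )

        centre = m * len(y) / 2
        u_obs = u_of(x, y)
        hits = total = 0
        for combo in itertools.combinations(range(len(pooled)), m):
            xs = [pooled[i] for i in combo]
            ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
            total += 1
            if abs(u_of(xs, ys) - centre) >= abs(u_obs - centre) - 1e-12:
                hits += 1
        return u_obs, hits / total

    def test_fully_separated_small_samples(self):
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(2 / 6)

    def test_identical_multisets_give_p_one(self):
        _, p = mann_whitney([1, 2, 2], [1, 2, 2])
        assert p == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    @given(st.data())
    def test_exact_mode_matches_enumeration_oracle(self, data):
        m = data.draw(st.integers(1, 5))
        n = data.draw(st.integers(1, 5))
        x = data.draw(st.lists(st.integers(0, 5), min_size=m, max_size=m))
        y = data.draw(st.lists(st.integers(0, 5), min_size=n, max_size=n))
        u, p = mann_whitney(x, y)
        u_ref, p_ref = self.oracle(x, y)
        assert u == pytest.approx(u_ref)
        assert p == pytest.approx(p_ref)

    def test_asymptotic_close_to_exact_at_n8(self):
        rng = np.random.default_rng(0)
        x = list(rng.normal(0, 1, 8))
        y = list(rng.normal(0.8, 1, 8))
        _, p_exact = mann_whitney(x, y)
        _, p_approx = mann_whitney(x, y, exact_limit=0)
        assert abs(p_exact - p_approx) < 0.02


class TestDuplexMFE:
    def test_two_stacked_gc_pairs_hand_sum(self):
        """(G,C) on (G,C): init 4.10 + GG/CC stack -3.3 = 0.80 kcal/mol."""
        region = PairedRegion("P", ((0, 5), (1, 4)))
        ref = RibozymeReference(
            name="r", sequence="GGAACC", leader="GG", paired_regions=[region]
        )
        assert duplex_mfe(region, ref).delta_g == pytest.approx(
            DUPLEX_INIT + STACKS["GG/CC"]
        )

    def test_self_complementary_duplex_gets_symmetry_correction(self):
        """5'GC with itself: init + GC/CG stack + 0.43 symmetry term."""
        from ribodms.structure import SYMMETRY_CORRECTION

        region = PairedRegion("P", ((0, 5), (1, 4)))
        ref = RibozymeReference(
            name="r", sequence="GCAAGC", leader="GG", paired_regions=[region]
        )
        assert duplex_mfe(region, ref).delta_g == pytest.approx(
            DUPLEX_INIT + STACKS["GC/CG"] + SYMMETRY_CORRECTION
        )

    def test_terminal_au_and_gu_penalties_applied(self):
        region = PairedRegion("P", ((0, 3), (1, 2)))
        ref = RibozymeReference(  # A:U terminal, G:U wobble terminal
            name="r", sequence="AGUU", leader="GG", paired_regions=[region]
        )
        expected = DUPLEX_INIT + STACKS["AG/UU"] + 2 * TERMINAL_AU_GU
        assert duplex_mfe(region, ref).delta_g == pytest.approx(expected)

    def test_single_pair_region_is_initiation_plus_terminals(self):
        region = PairedRegion("P", ((0, 2),))
        ref = RibozymeReference(
            name="r", sequence="GAC", leader="GG", paired_regions=[region]
        )
        assert duplex_mfe(region, ref).delta_g == pytest.approx(DUPLEX_INIT)

    def test_strand_swap_with_reversal_is_invariant(self):
        """Reading the helix from the other strand gives the same delta-G."""
        region_a = PairedRegion("A", ((0, 5), (1, 4)))
        ref_a = RibozymeReference(
            name="a", sequence="GAAAUC", leader="GG", paired_regions=[region_a]
        )
        # swapped: 5' strand is the old 3' strand reversed
        region_b = PairedRegion("B", ((0, 5), (1, 4)))
        ref_b = RibozymeReference(
            name="b", sequence="UCAAGA", leader="GG", paired_regions=[region_b]
        )
        assert duplex_mfe(region_a, ref_a).delta_g == pytest.approx(
            duplex_mfe(region_b, ref_b).delta_g
        )

    def test_unpairable_letters_rejected(self):
        region = PairedRegion("P", ((0, 2),))
        ref = RibozymeReference(
            name="r", sequence="AAC", leader="GG", paired_regions=[region]
        )
        with pytest.raises(ValueError, match="pairable"):
            duplex_mfe(region, ref)

    def test_within_half_kcal_of_viennarna_on_shipped_regions(self, shipped_ref):
        """Independent oracle: ViennaRNA evaluates the same two strands forced
        into the full helix (dangles off)."""
        RNA = pytest.importorskip("RNA")
        md = RNA.md()
        md.dangles = 0
        for region in shipped_ref.paired_regions:
            energy = duplex_mfe(region, shipped_ref)
            n = energy.n_pairs
            fc = RNA.fold_compound(f"{energy.strand5}&{energy.strand3}", md)
            vienna = fc.eval_structure("(" * n + ")" * n)
            assert abs(energy.delta_g - vienna) <= 0.5, (
                shipped_ref.name, region.name, energy.delta_g, vienna,
            )


class TestStabilityCorrelation:
    def frame(self, genotypes, ras):
        return pd.DataFrame(
            {
                "genotype": genotypes,
                "order": [Genotype.from_string(g).order for g in genotypes],
                "mean_RA": ras,
            }
        )

    def setup_regions(self):
        # three regions with distinct delta-G: 2-bp GC stack, lone G:C, lone A:U
        regions = [
            PairedRegion("P1", ((0, 11), (1, 10))),
            PairedRegion("P2", ((3, 8),)),
            PairedRegion("P3", ((5, 7),)),
        ]
        ref = RibozymeReference(
            name="r", sequence="GCAGAAAUCAGC", leader="GG",
            paired_regions=regions,
        )
        return ref, regions

    def test_collinear_descending_gives_minus_one(self):
        ref, regions = self.setup_regions()
        energies = [duplex_mfe(r, ref) for r in regions]
        # plant median RA as a decreasing linear function of delta_g
        genotypes, ras = [], []
        for region, e in zip(regions, energies):
            for p in sorted(region.positions):
                for alt in ref.alternatives(p):
                    genotypes.append(f"{p}:{alt}")
                    ras.append(2.0 - 0.5 * e.delta_g)
        table = self.frame(genotypes, ras)
        r, p = stability_correlation(energies, table, ref)
        assert r == pytest.approx(-1.0)

    def test_constant_median_is_flagged_nan(self):
        ref, regions = self.setup_regions()
        energies = [duplex_mfe(r, ref) for r in regions]
        genotypes = [
            f"{p}:{alt}"
            for region in regions
            for p in sorted(region.positions)
            for alt in ref.alternatives(p)
        ]
        table = self.frame(genotypes, [0.5] * len(genotypes))
        r, p = stability_correlation(energies, table, ref)
        assert math.isnan(r)

    def test_fewer_than_three_regions_rejected(self):
        ref, regions = self.setup_regions()
        energies = [duplex_mfe(r, ref) for r in regions[:2]]
        with pytest.raises(ValueError):
            stability_correlation(energies, self.frame(["WT"], [1.0]), ref)

    def test_median_single_ra_uses_region_positions_only(self):
        ref, regions = self.setup_regions()
        table = self.frame(["0:C", "11:A", "2:C"], [0.1, 0.3, 0.9])
        assert median_single_ra(regions[0], table) == pytest.approx(0.2)
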