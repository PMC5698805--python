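"""Two-point parametric linkage: peeling vs exhaustive enumeration,
closed forms, LOD properties, region extraction."""
import math

import numpy as np
import pytest

from pedexome.linkage import (
    LOD_IMPOSSIBLE,
    DiseaseModel,
    LinkageResult,
    MarkerData,
    MarkerModel,
    ParametricLinkage,
    lod_regions,
    pedigree_likelihood,
    pedigree_loglikelihood,
    two_point_lod,
)
from pedexome.pedigree import Affection, Pedigree

from _oracles import (
    drop_marker_genotypes,
    oracle_loglikelihood,
    random_pedigree,
)
from conftest import make_ind


MM2 = MarkerModel((0.6, 0.4))
DM_DOM = DiseaseModel()                      # affecteds-only, q = 1e-4, (0,1,1)
DM_FULL = DiseaseModel(affecteds_only=False)


class TestPedigreeLikelihood:
    def test_single_affected_founder_closed_form(self):
        """One affected founder, genotype ref/ref: the likelihood is the
        founder-prior mass of marker-homozygous states weighted by
        penetrance, computable by hand."""
        ped = Pedigree("F", [make_ind("x", aff=Affection.AFFECTED)])
        q, p0 = 1e-4, 0.6
        got = pedigree_likelihood(ped, {"x": (0, 0)}, MM2, DM_DOM, theta=0.3)
        # hand enumeration over diplotypes with both marker alleles = 0:
        # dd: q_bar^2 p0^2 * f0 (=0); Dd: 2 q q_bar p0^2 * 1; DD: q^2 p0^2 * 1
        expected = 2 * q * (1 - q) * p0**2 + q**2 * p0**2
        assert got == pytest.approx(expected, rel=1e-12)

    def test_theta_half_factorizes(self, three_gen):
        """At theta = 0.5 the two loci are independent, so the likelihood is
        the product of the disease-only and marker-only likelihoods."""
        g = {"gf": (0, 1), "gm": (0, 0), "p": (0, 1), "sp": (0, 0), "c1": (0, 1)}
        joint = pedigree_loglikelihood(three_gen, g, MM2, DM_FULL, 0.5)
        marker_only = pedigree_loglikelihood(
            three_gen, g, MM2, DiseaseModel(penetrances=(1, 1, 1)), 0.5
        )
        disease_only = pedigree_loglikelihood(three_gen, {}, MM2, DM_FULL, 0.5)
        assert joint == pytest.approx(marker_only + disease_only, rel=1e-12)

    def test_inconsistent_genotypes_zero_not_error(self, trio):
        g = {"dad": (0, 0), "mum": (0, 0), "kid": (1, 1)}
        assert pedigree_likelihood(trio, g, MM2, DM_DOM, 0.1) == 0.0

    @pytest.mark.parametrize("theta", [0.0, 0.1, 0.35, 0.5])
    def test_matches_exhaustive_enumeration(self, rng, theta):
        """Clique peeling equals the naive full-joint-table sum on random
        loop-free pedigrees of up to 8 members."""
        for _ in range(8):
            ped = random_pedigree(rng, int(rng.integers(4, 9)))
            g = drop_marker_genotypes(ped, MM2.freqs, rng)
            ours = pedigree_loglikelihood(ped, g, MM2, DM_DOM, theta)
            ref = oracle_loglikelihood(
                ped, g, MM2.freqs, DM_DOM.q, DM_DOM.penetrances, True, theta
            )
            assert ours == pytest.approx(ref, rel=1e-10)

    def test_affecteds_only_ignores_unaffected_phenotypes(self, rng):
        """Switching any unaffected member to unknown leaves the
        affecteds-only likelihood unchanged."""
        ped = random_pedigree(rng, 7)
        g = drop_marker_genotypes(ped, MM2.freqs, rng)
        before = pedigree_loglikelihood(ped, g, MM2, DM_DOM, 0.1)
        for m in ped.members:
            if m.affection is Affection.UNAFFECTED:
                m.affection = Affection.UNKNOWN
        after = pedigree_loglikelihood(ped, g, MM2, DM_DOM, 0.1)
        assert before == pytest.approx(after, rel=1e-12)

    def test_member_order_invariance(self, three_gen):
        g = {"gf": (0, 1), "gm": (0, 0), "p": (0, 1), "sp": (1, 1), "c1": (0, 1)}
        ll = pedigree_loglikelihood(three_gen, g, MM2, DM_DOM, 0.2)
        shuffled = Pedigree("F", list(reversed(three_gen.members)))
        assert pedigree_loglikelihood(shuffled, g, MM2, DM_DOM, 0.2) == pytest.approx(
            ll, rel=1e-12
        )


class TestTwoPointLod:
    def test_closed_form_ten_meioses(self, informative_cross):
        ped, g = informative_cross
        res = two_point_lod(ped, g, MarkerModel((0.5, 0.5)), DM_FULL)
        assert res.lods[0] == pytest.approx(10 * math.log10(2), abs=1e-9)
        # lod(theta) follows n*log10(2(1-theta)) along the whole grid
        for theta, lod in zip(res.theta_grid, res.lods):
            assert lod == pytest.approx(10 * math.log10(2 * (1 - theta)), abs=1e-9)

    def test_single_recombinant_sentinel(self, informative_cross):
        ped, g = informative_cross
        g = dict(g)
        g["K0"] = (1, 1)  # obligate recombinant
        res = two_point_lod(ped, g, MarkerModel((0.5, 0.5)), DM_FULL)
        assert res.lods[0] == LOD_IMPOSSIBLE
        assert res.lods[-1] == 0.0

    def test_uninformative_family_flat_zero(self, three_gen):
        g = {m.id: (0, 0) for m in three_gen.members}
        res = two_point_lod(three_gen, g, MM2, DM_DOM)
        assert np.allclose(res.lods, 0.0, atol=1e-9)

    def test_lod_zero_at_half_and_additive_over_families(self, informative_cross):
        ped, g = informative_cross
        ped2 = Pedigree("F2", [make_ind(m.id, fam="F2", fa=m.father_id,
                                        mo=m.mother_id, sex=m.sex, aff=m.affection)
                               for m in ped.members])
        res = two_point_lod(
            [ped, ped2],
            {"F": g, "F2": g},
            MarkerModel((0.5, 0.5)),
            DM_FULL,
        )
        assert res.lods[-1] == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(
            res.lods, res.per_family["F"] + res.per_family["F2"], atol=1e-12
        )
        assert res.lods[0] == pytest.approx(20 * math.log10(2), abs=1e-9)

    def test_all_missing_genotypes_zero_lod(self, three_gen):
        res = two_point_lod(three_gen, {}, MM2, DM_DOM)
        assert np.allclose(res.lods, 0.0, atol=1e-9)


class TestLodRegions:
    def _result(self, marker, pos, fam_lods):
        grid = (0.0, 0.5)
        per_fam = {f: np.array([v, 0.0]) for f, v in fam_lods.items()}
        total = np.sum(list(per_fam.values()), axis=0)
        return LinkageResult(marker, grid, total, per_fam, chrom="1", pos=pos)

    def test_no_marker_above_threshold(self):
        rs = [self._result(f"M{i}", 10 * i, {"F": 1.5}) for i in range(1, 6)]
        assert lod_regions(rs, 2.0) == []

    def test_single_high_marker_region_with_flanks(self):
        rs = [self._result(f"M{i}", 10 * i, {"F": 2.95 if i == 3 else 0.5})
              for i in range(1, 6)]
        (reg,) = lod_regions(rs, 2.0)
        assert (reg.start, reg.end) == (20, 40)      # flanking markers
        assert reg.max_lod == pytest.approx(2.95)
        assert reg.family == "F"

    def test_run_at_scan_edge_clamped(self):
        rs = [self._result(f"M{i}", 10 * i, {"F": 2.5 if i <= 2 else 0.0})
              for i in range(1, 6)]
        (reg,) = lod_regions(rs, 2.0)
        assert (reg.start, reg.end) == (10, 30)

    def test_per_family_tracks_are_separate(self):
        rs = [self._result(f"M{i}", 10 * i, {"A": 2.5, "B": 0.0}) for i in range(1, 4)]
        regs = lod_regions(rs, 2.0)
        assert [r.family for r in regs] == ["A"]


class TestModelResultsInterface:
    def test_fit_summary_and_regions(self, informative_cross):
        ped, g = informative_cross
        markers = [
            MarkerData("M1", "1", 1000, MarkerModel((0.5, 0.5)), {"F": g}),
            MarkerData("M2", "1", 2000, MarkerModel((0.5, 0.5)), {"F": {}}),
        ]
        scan = ParametricLinkage([ped], markers, DM_FULL).fit()
        df = scan.summary()
        assert list(df["marker"]) == ["M1", "M2"]
        assert df.loc[0, "max_lod"] == pytest.approx(10 * math.log10(2), abs=1e-9)
        assert df.loc[1, "max_lod"] == pytest.approx(0.0, abs=1e-9)
        regs = scan.lod_regions(2.0)
        assert len(regs) == 1 and regs[0].family == "F"
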