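"""Prioritization strategies on the packaged published-table fixture and
synthetic edge cases."""
import pytest

from pedexome.io import Region
from pedexome.pedigree import Affection, Pedigree, Sex
from pedexome.prioritize import (
    SegregationError,
    is_segregating,
    strategy_cross_family,
    strategy_known_genes,
    strategy_linkage,
)
from pedexome.tables import fixture_study, load_table
from pedexome.variants import Consequence, GenotypeCall, VariantAnnotation, VariantRecord

from conftest import make_ind


@pytest.fixture(scope="module")
def fs():
    return fixture_study()


def small_family(genotypes, fam="F"):
    """n affected sequenced sibs with the given allele pairs (None=missing)."""
    members = [make_ind("f", fam, sex=Sex.MALE, sequenced=False),
               make_ind("m", fam, sex=Sex.FEMALE, sequenced=False)]
    calls = {}
    for i, g in enumerate(genotypes):
        iid = f"{fam}a{i}"
        members.append(make_ind(iid, fam, fa="f", mo="m", aff=Affection.AFFECTED))
        calls[iid] = GenotypeCall(*g) if g is not None else GenotypeCall(None, None)
    ped = Pedigree(fam, members)
    v = VariantRecord("1", 100, "A", "G", calls=calls)
    return v, ped


class TestIsSegregating:
    def test_all_carriers(self):
        v, ped = small_family([(0, 1), (0, 1), (1, 1)])
        assert is_segregating(v, ped)

    def test_one_of_two(self):
        v, ped = small_family([(0, 1), (0, 0)])
        assert not is_segregating(v, ped)

    def test_single_sequenced_affected_trivially_segregates(self):
        v, ped = small_family([(0, 1)])
        assert is_segregating(v, ped)

    def test_missing_calls_excluded_from_denominator(self):
        v, ped = small_family([(0, 1), None, (0, 1)])
        assert is_segregating(v, ped)

    def test_no_sequenced_affecteds_errors(self):
        ped = Pedigree("F", [make_ind("x", aff=Affection.UNAFFECTED)])
        v = VariantRecord("1", 100, "A", "G", calls={})
        with pytest.raises(SegregationError):
            is_segregating(v, ped)


class TestKnownGeneTier:
    def test_fixture_counts(self, fs):
        """The packaged known-gene table yields 14 unique variants across
        10 genes; 7 variants have >= 2 affected carriers in one family and
        4 genes carry multiple distinct variants."""
        rows = strategy_known_genes(fs.variants, fs.annotations, fs.gene_list, fs.pedigrees)
        assert len({r.key for r in rows}) == 14
        assert len({r.gene for r in rows}) == 10
        assert len({r.key for r in rows if len(r.carriers) >= 2}) == 7
        by_gene = {}
        for r in rows:
            by_gene.setdefault(r.gene, set()).add(r.key)
        assert sum(1 for ks in by_gene.values() if len(ks) >= 2) == 4

    def test_maf_boundary_inclusive(self, fs):
        key = ("4", 95170263, "C", "T")          # MAF 0.01808 <= 2% retained
        rows = strategy_known_genes(fs.variants, fs.annotations, fs.gene_list, fs.pedigrees)
        assert key in {r.key for r in rows}
        bumped = dict(fs.annotations)
        bumped[key] = VariantAnnotation(
            gene="UNC5C", consequence=Consequence.MISSENSE, maf=0.021, cadd=33.0
        )
        rows2 = strategy_known_genes(fs.variants, bumped, fs.gene_list, fs.pedigrees)
        assert key not in {r.key for r in rows2}

    def test_segregation_not_required(self, fs):
        rows = strategy_known_genes(fs.variants, fs.annotations, fs.gene_list, fs.pedigrees)
        assert any(not r.segregating for r in rows)

    def test_raising_threshold_is_monotone(self, fs):
        tight = {r.key for r in strategy_known_genes(
            fs.variants, fs.annotations, fs.gene_list, fs.pedigrees, maf_max=0.005)}
        loose = {r.key for r in strategy_known_genes(
            fs.variants, fs.annotations, fs.gene_list, fs.pedigrees, maf_max=0.02)}
        assert tight <= loose


class TestLinkageTier:
    def test_fixture_counts(self, fs):
        """Five variants in five genes across the three LOD>2 families."""
        rows = strategy_linkage(fs.variants, fs.annotations, fs.regions, fs.pedigrees)
        assert len({r.key for r in rows}) == 5
        assert len({r.gene for r in rows}) == 5
        assert {r.family_id for r in rows} == {"757", "911", "1201"}

    def test_low_cadd_retained_but_flagged(self, fs):
        rows = strategy_linkage(fs.variants, fs.annotations, fs.regions, fs.pedigrees)
        clecl1 = next(r for r in rows if r.gene == "CLECL1")
        assert not clecl1.cadd_flag                  # CADD 0.03
        mief1 = next(r for r in rows if r.gene == "MIEF1")
        assert mief1.cadd_flag                       # CADD 34

    def test_variant_outside_regions_removed(self, fs):
        narrowed = {"757": [Region("12", 1, 2)], "911": fs.regions["911"],
                    "1201": fs.regions["1201"]}
        rows = strategy_linkage(fs.variants, fs.annotations, narrowed, fs.pedigrees)
        assert {r.family_id for r in rows} == {"911", "1201"}

    def test_all_rows_segregate(self, fs):
        rows = strategy_linkage(fs.variants, fs.annotations, fs.regions, fs.pedigrees)
        assert all(r.segregating for r in rows)


class TestCrossFamilyTier:
    def test_fixture_counts(self, fs):
        """Four gene clusters, three sharing an identical variant across
        distinct families."""
        clusters = strategy_cross_family(
            fs.variants, fs.annotations, fs.pedigrees, exclude_genes=fs.gene_list
        )
        assert len(clusters) == 4
        assert {c.gene for c in clusters} == {"DAAM2", "MKL2", "PLEKHG5", "THBS2"}
        shared = {c.gene for c in clusters if c.identical_variant_shared}
        assert shared == {"MKL2", "PLEKHG5", "THBS2"}

    def test_known_gene_exclusion(self, fs):
        """Without the exclusion list, a known gene with segregating rare
        damaging variants in two families would also cluster."""
        clusters = strategy_cross_family(fs.variants, fs.annotations, fs.pedigrees)
        assert {c.gene for c in clusters} == {"DAAM2", "INPP5D", "MKL2", "PLEKHG5", "THBS2"}

    def test_single_family_gene_no_cluster(self, fs):
        clusters = strategy_cross_family(
            fs.variants, fs.annotations, fs.pedigrees, exclude_genes=fs.gene_list
        )
        assert "CTNNA1" not in {c.gene for c in clusters}

    def test_needs_two_families(self, fs):
        with pytest.raises(ValueError):
            strategy_cross_family(fs.variants, fs.annotations, fs.pedigrees[:1])

    def test_flags_revalidate_against_annotation(self, fs):
        """Every prioritized row's flags agree with its raw annotation."""
        rows = strategy_known_genes(fs.variants, fs.annotations, fs.gene_list, fs.pedigrees)
        rows += strategy_linkage(fs.variants, fs.annotations, fs.regions, fs.pedigrees)
        for r in rows:
            ann = fs.annotations[r.key]
            assert r.cadd_flag == (ann.cadd is not None and ann.cadd >= 15)
            if ann.maf is None:
                assert r.maf_flag == "maf_missing"
            else:
                limit = 0.02 if r.strategy == "known_gene" else 0.01
                assert ann.maf <= limit


class TestFixtureTables:
    def test_table_shapes(self):
        assert len(load_table(1)) == 15     # one variant appears in two families
        assert len(load_table(2)) == 5
        assert len(load_table(3)) == 8

    def test_table1_unique_keys(self):
        t1 = load_table(1)
        keys = {(str(r["chrom"]), int(r["pos"]), str(r["nucleotide"])) for _, r in t1.iterrows()}
        assert len(keys) == 14
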