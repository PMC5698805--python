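"""QC filters: genotype/site thresholds at their boundaries, call rates,
concordance calibration, LD pruning."""
import numpy as np
import pytest

from pedexome.qc import (
    QCConfig,
    batch_presence,
    concordance,
    filter_genotypes,
    filter_sites,
    ld_prune,
    sample_call_rates,
    snp_call_rate,
)
from pedexome.variants import GenotypeCall, VariantAnnotation, VariantRecord


def variant(calls, pos=100, site_quality=1.0):
    return VariantRecord("1", pos, "A", "G", site_quality=site_quality,
                         calls={k: GenotypeCall(*v) for k, v in calls.items()})


@pytest.fixture
def cfg():
    return QCConfig()


class TestGenotypeFilter:
    def test_depth_boundary(self, cfg):
        v = variant({"a": (0, 1, 4, 99), "b": (0, 1, 5, 20), "c": (0, 1, 5, 19)})
        out = filter_genotypes(v, cfg)
        assert out.calls["a"].is_missing          # depth 4 < 5
        assert not out.calls["b"].is_missing      # exactly at both thresholds
        assert out.calls["c"].is_missing          # gq 19 < 20

    def test_all_passing_unchanged(self, cfg):
        v = variant({"a": (0, 1, 30, 99), "b": (1, 1, 10, 50)})
        out = filter_genotypes(v, cfg)
        assert all(not c.is_missing for c in out.calls.values())


class TestSiteFilter:
    def _ann(self, map35, map20):
        return {("1", 100, "A", "G"): VariantAnnotation(gene="X", map35=map35, map20=map20)}

    def test_mappability_boundaries(self, cfg):
        v = variant({"a": (0, 1, 30, 99)})
        assert filter_sites([v], self._ann(0.5, 1.0), cfg) == []      # map35 must be 1
        assert filter_sites([v], self._ann(1.0, 0.5), cfg) == [v]     # map20 >= 0.5 ok
        assert filter_sites([v], self._ann(1.0, 0.4), cfg) == []

    def test_vqslod_strictly_positive(self, cfg):
        v0 = variant({"a": (0, 1, 30, 99)}, site_quality=0.0)
        vp = variant({"a": (0, 1, 30, 99)}, site_quality=1e-9)
        vnone = variant({"a": (0, 1, 30, 99)}, site_quality=None)
        ann = self._ann(1.0, 1.0)
        assert filter_sites([v0], ann, cfg) == []
        assert filter_sites([vp], ann, cfg) == [vp]
        assert filter_sites([vnone], ann, cfg) == [vnone]   # absent: kept, flagged

    def test_filter_order_independence(self, cfg):
        vs = [
            variant({"a": (0, 1, 4, 99), "b": (0, 1, 50, 99)}, pos=100),
            variant({"a": (0, 1, 50, 99)}, pos=200, site_quality=0.0),
        ]
        ann = {v.key: VariantAnnotation(gene="X") for v in vs}
        a = [filter_genotypes(v, cfg) for v in filter_sites(vs, ann, cfg)]
        b = filter_sites([filter_genotypes(v, cfg) for v in vs], ann, cfg)
        assert [(v.key, {s: c.unordered() for s, c in v.calls.items()}) for v in a] == [
            (v.key, {s: c.unordered() for s, c in v.calls.items()}) for v in b
        ]


class TestCallRates:
    def test_sample_rate_boundary(self):
        vs = [variant({"s": (0, 1, 9, 9)}, pos=100 + i) for i in range(50)]
        vs[0].calls["s"] = GenotypeCall(None, None)
        rates = sample_call_rates(vs)
        assert rates["s"] == pytest.approx(0.98)

    def test_snp_rate(self):
        calls = {f"s{i}": (0, 1, 9, 9) for i in range(50)}
        v = variant(calls)
        for i in range(3):
            v.calls[f"s{i}"] = GenotypeCall(None, None)
        assert snp_call_rate(v) == pytest.approx(0.94)
        assert snp_call_rate(v) < QCConfig().snp_call_rate_min

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            sample_call_rates([])

    def test_batch_presence_rule(self):
        batches = {f"s{i}": ("chipA" if i < 6 else "chipB") for i in range(10)}
        present = {f"s{i}": i < 6 for i in range(10)}
        assert batch_presence(present, batches, 0.60)
        present["s5"] = False
        assert not batch_presence(present, batches, 0.60)


class TestConcordance:
    def test_identical_and_single_mismatch(self):
        key = ("1", 100, "A", "G")
        wes = {(f"s{i}", key): (0, 1) for i in range(10)}
        arr = dict(wes)
        assert concordance(wes, arr) == 1.0
        arr[("s0", key)] = (1, 1)
        assert concordance(wes, arr) == pytest.approx(0.9)

    def test_unordered_genotype_comparison(self):
        key = ("1", 100, "A", "G")
        assert concordance({("s", key): (1, 0)}, {("s", key): (0, 1)}) == 1.0

    def test_no_overlap_errors(self):
        with pytest.raises(ValueError):
            concordance({}, {})

    def test_simulated_error_rate(self, rng):
        """1% genotype-error overlay gives ~99% concordance."""
        n = 20000
        truth = rng.integers(0, 3, size=n)
        noisy = truth.copy()
        flip = rng.random(n) < 0.01
        noisy[flip] = (noisy[flip] + 1 + rng.integers(0, 2, size=flip.sum())) % 3
        to_gt = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
        key = ("1", 1, "A", "G")
        wes = {(f"s{i}", key): to_gt[int(t)] for i, t in enumerate(truth)}
        arr = {(f"s{i}", key): to_gt[int(t)] for i, t in enumerate(noisy)}
        c = concordance(wes, arr)
        se = np.sqrt(0.01 * 0.99 / n)
        assert abs((1 - c) - 0.01) < 3 * se


class TestLDPrune:
    def test_perfectly_correlated_pair(self, cfg):
        g = np.array([[0, 1, 2, 1, 0, 2, 1, 0], [0, 1, 2, 1, 0, 2, 1, 0]], dtype=float)
        assert ld_prune(g, cfg) in ([0], [1])

    def test_independent_markers_all_kept(self, cfg, rng):
        g = rng.integers(0, 3, size=(10, 6)).astype(float)
        # orthogonalize pathological duplicates by checking the property instead:
        kept = ld_prune(g, cfg)
        for a in range(len(kept)):
            for b in range(a + 1, len(kept)):
                i, j = kept[a], kept[b]
                r = np.corrcoef(g[i], g[j])[0, 1]
                assert np.isnan(r) or r * r <= cfg.ld_r2_max + 1e-12

    def test_block_structure_property(self, cfg, rng):
        """After pruning a 200-marker blocky panel, no kept pair within any
        window exceeds the r^2 ceiling (verified exhaustively post hoc)."""
        n_samples = 60
        blocks = []
        for _ in range(40):
            base = rng.integers(0, 3, size=n_samples).astype(float)
            for _ in range(5):
                noisy = base.copy()
                flip = rng.random(n_samples) < 0.1
                noisy[flip] = rng.integers(0, 3, size=flip.sum())
                blocks.append(noisy)
        g = np.array(blocks)
        kept = ld_prune(g, cfg)
        assert 0 < len(kept) < 200
        for w_start in range(0, 200, cfg.ld_step):
            window = [i for i in kept if w_start <= i < w_start + cfg.ld_window]
            for a in range(len(window)):
                for b in range(a + 1, len(window)):
                    x, y = g[window[a]], g[window[b]]
                    if x.std() == 0 or y.std() == 0:
                        continue
                    r = np.corrcoef(x, y)[0, 1]
                    assert r * r <= cfg.ld_r2_max + 1e-9

    def test_deterministic(self, cfg, rng):
        g = rng.integers(0, 3, size=(120, 40)).astype(float)
        assert ld_prune(g, cfg) == ld_prune(g.copy(), cfg)
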