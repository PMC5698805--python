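"""Exact two-point parametric linkage via pedigree likelihood peeling.

The model places a diallelic disease locus (allele frequency ``q``,
penetrances ``(f0, f1, f2)``) at recombination fraction ``theta`` from a
codominant marker with known allele frequencies.  Each individual's latent
state is an unordered pair of two-locus haplotypes (disease allele x
marker allele); founder states follow linkage-equilibrium priors, and
parent-to-child transmissions recombine between the two loci with
probability ``theta``.  The pedigree likelihood is evaluated exactly by
eliminating nuclear-family cliques along :meth:`Pedigree.peeling_order`
(Elston-Stewart peeling), and the two-point LOD score is

    LOD(theta) = log10 L(theta) - log10 L(0.5).

Under the affecteds-only convention (default) unaffected phenotypes
contribute a factor of 1, guarding against incomplete penetrance; their
marker genotypes still inform haplotype flow.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .pedigree import Affection, Pedigree

#: finite sentinel for a likelihood-ratio of zero (obligate recombinant at theta)
LOD_IMPOSSIBLE = -99.0

DEFAULT_THETA_GRID = (0.0, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)

MarkerGenotype = Optional[tuple[int, int]]


@dataclass
class DiseaseModel:
    """Parametric single-locus disease model.

    Defaults encode the affecteds-only rare-dominant analysis: disease
    allele frequency 0.0001 and penetrances (0, 1, 1) — affection requires
    at least one disease allele, no phenocopies — with unaffected and
    unknown phenotypes contributing no likelihood information.
    """

    q: float = 0.0001
    penetrances: tuple[float, float, float] = (0.0, 1.0, 1.0)
    affecteds_only: bool = True

    def __post_init__(self):
        if not 0.0 < self.q < 1.0:
            raise ValueError("disease allele frequency q must be in (0, 1)")
        if any(not 0.0 <= f <= 1.0 for f in self.penetrances):
            raise ValueError("penetrances must lie in [0, 1]")


@dataclass
class MarkerModel:
    """Marker allele frequencies plus the recombination fraction to the
    disease locus (``theta`` is varied over a grid by :func:`two_point_lod`)."""

    freqs: tuple[float, ...]
    theta: float = 0.5

    def __post_init__(self):
        self.freqs = tuple(float(f) for f in self.freqs)
        if any(f <= 0 for f in self.freqs):
            raise ValueError("marker allele frequencies must be positive")
        if abs(sum(self.freqs) - 1.0) > 1e-9:
            raise ValueError("marker allele frequencies must sum to 1")
        if not 0.0 <= self.theta <= 0.5:
            raise ValueError("theta must be in [0, 0.5]")

    @property
    def n_alleles(self) -> int:
        return len(self.freqs)


# ----------------------------------------------------------------------
# Two-locus state space (cached per marker allele count)
# ----------------------------------------------------------------------
class _StateSpace:
    """Unordered diplotypes over haplotypes h = d*k + m.

    Transmission probabilities are symmetric in the two haplotypes, so the
    unordered representation is lossless; with k marker alleles there are
    2k*(2k+1)/2 states.
    """

    def __init__(self, k: int):
        self.k = k
        self.n_hap = 2 * k
        pairs = [(i, j) for i in range(self.n_hap) for j in range(i, self.n_hap)]
        self.n_states = len(pairs)
        self.hap_i = np.array([p[0] for p in pairs])
        self.hap_j = np.array([p[1] for p in pairs])
        hap_d = np.arange(self.n_hap) // k
        hap_m = np.arange(self.n_hap) % k
        self.d_count = hap_d[self.hap_i] + hap_d[self.hap_j]
        mi, mj = hap_m[self.hap_i], hap_m[self.hap_j]
        self.marker_lo = np.minimum(mi, mj)
        self.marker_hi = np.maximum(mi, mj)
        # ordered haplotype pair -> state index
        self.pair_to_state = np.zeros((self.n_hap, self.n_hap), dtype=np.int64)
        for s, (i, j) in enumerate(pairs):
            self.pair_to_state[i, j] = s
            self.pair_to_state[j, i] = s
        self._hap_d, self._hap_m = hap_d, hap_m

    def transmission(self, theta: float) -> np.ndarray:
        """M[s, h] = P(parent in state s transmits gamete haplotype h).

        The full child-state tensor T[sf, sm, sc] = sum over ordered gamete
        pairs (ha, hb) of M[sf, ha] M[sm, hb] [state(ha, hb) = sc] is never
        materialized: eliminations contract through M and the gamete-pair ->
        state index map instead.
        """
        w_same, w_rec = (1.0 - theta) / 2.0, theta / 2.0
        M = np.zeros((self.n_states, self.n_hap))
        hi, hj = self.hap_i, self.hap_j
        d, m = self._hap_d, self._hap_m
        for (w, dsrc, msrc) in (
            (w_same, hi, hi),
            (w_same, hj, hj),
            (w_rec, hi, hj),
            (w_rec, hj, hi),
        ):
            hap = d[dsrc] * self.k + m[msrc]
            np.add.at(M, (np.arange(self.n_states), hap), w)
        return M

    def founder_prior(self, freqs: Sequence[float], q: float) -> np.ndarray:
        pi_h = np.where(self._hap_d == 1, q, 1.0 - q) * np.asarray(freqs)[self._hap_m]
        prior = pi_h[self.hap_i] * pi_h[self.hap_j]
        prior[self.hap_i != self.hap_j] *= 2.0
        return prior


_STATE_CACHE: dict[int, _StateSpace] = {}
_TRANS_CACHE: dict[tuple[int, float], np.ndarray] = {}


def _space(k: int) -> _StateSpace:
    if k not in _STATE_CACHE:
        _STATE_CACHE[k] = _StateSpace(k)
    return _STATE_CACHE[k]


def _trans(k: int, theta: float) -> np.ndarray:
    key = (k, round(float(theta), 12))
    if key not in _TRANS_CACHE:
        _TRANS_CACHE[key] = _space(k).transmission(theta)
    return _TRANS_CACHE[key]


def _obs_vector(
    ss: _StateSpace, affection: Affection, genotype: MarkerGenotype, dm: DiseaseModel
) -> np.ndarray:
    v = np.ones(ss.n_states)
    if genotype is not None:
        lo, hi = min(genotype), max(genotype)
        v = v * ((ss.marker_lo == lo) & (ss.marker_hi == hi))
    f = np.asarray(dm.penetrances)[ss.d_count]
    if affection is Affection.AFFECTED:
        v = v * f
    elif affection is Affection.UNAFFECTED and not dm.affecteds_only:
        v = v * (1.0 - f)
    return v


# ----------------------------------------------------------------------
# Peeling
# ----------------------------------------------------------------------
def pedigree_loglikelihood(
    p: Pedigree,
    genotypes: dict[str, MarkerGenotype],
    mm: MarkerModel,
    dm: DiseaseModel,
    theta: Optional[float] = None,
) -> float:
    """Natural-log pedigree likelihood; ``-inf`` for impossible genotypes.

    ``genotypes`` maps individual id to an unordered marker allele pair
    (ints in 0..k-1) or ``None``/absent for missing.
    """
    theta = mm.theta if theta is None else theta
    ss = _space(mm.n_alleles)
    M = _trans(mm.n_alleles, theta)
    prior = ss.founder_prior(mm.freqs, dm.q)
    p2s = ss.pair_to_state

    onsite: dict[str, np.ndarray] = {}
    for m in p.members:
        v = _obs_vector(ss, m.affection, genotypes.get(m.id), dm)
        if m.is_founder:
            v = v * prior
        onsite[m.id] = v

    order = p.peeling_order()
    in_clique = {i for (fa, mo, kids), _ in order for i in (fa, mo, *kids)}
    log_l = 0.0
    absorbed: dict[str, np.ndarray] = {}
    onsite_done: set[str] = set()

    def take_onsite(ind_id: str) -> np.ndarray:
        if ind_id in onsite_done:
            return np.ones(ss.n_states)
        onsite_done.add(ind_id)
        return onsite[ind_id]

    for (fa, mo, kids), pivot in order:
        u_f = take_onsite(fa) * absorbed.pop(fa, 1.0)
        u_m = take_onsite(mo) * absorbed.pop(mo, 1.0)
        C = np.outer(u_f, u_m)
        pivot_child = None
        for c in kids:
            if c == pivot:
                pivot_child = c
                continue
            vc = take_onsite(c) * absorbed.pop(c, 1.0)
            # sum_sc T[sf,sm,sc] vc[sc] = M V M^T with V the gamete-pair view of vc
            C = C * (M @ vc[p2s] @ M.T)
        if pivot is None:
            total = C.sum()
        elif pivot_child is not None:
            W = M.T @ C @ M  # joint over ordered transmitted gamete pair
            R = np.bincount(p2s.ravel(), weights=W.ravel(), minlength=ss.n_states)
            R = R * take_onsite(pivot_child) * absorbed.pop(pivot_child, 1.0)
            absorbed[pivot] = R
            total = R.max()
        elif pivot == fa:
            R = C.sum(axis=1)
            absorbed[fa] = R
            total = R.max()
        else:  # pivot == mo
            R = C.sum(axis=0)
            absorbed[mo] = R
            total = R.max()
        if total <= 0.0:
            return -math.inf
        if pivot is None:
            log_l += math.log(total)
        else:
            absorbed[pivot] = absorbed[pivot] / total
            log_l += math.log(total)

    # individuals outside every nuclear family (isolated members)
    for m in p.members:
        if m.id not in in_clique:
            s = float((onsite[m.id]).sum())
            if s <= 0.0:
                return -math.inf
            log_l += math.log(s)
    return log_l


def pedigree_likelihood(
    p: Pedigree,
    genotypes: dict[str, MarkerGenotype],
    mm: MarkerModel,
    dm: DiseaseModel,
    theta: Optional[float] = None,
) -> float:
    """Pedigree likelihood as a probability (exp of the log-likelihood)."""
    ll = pedigree_loglikelihood(p, genotypes, mm, dm, theta)
    return 0.0 if ll == -math.inf else math.exp(ll)


# ----------------------------------------------------------------------
# LOD scores
# ----------------------------------------------------------------------
@dataclass
class LinkageResult:
    """Two-point LOD scores for one marker over a theta grid."""

    marker: str
    theta_grid: tuple[float, ...]
    lods: np.ndarray                     # total over families, per theta
    per_family: dict[str, np.ndarray]
    chrom: str = ""
    pos: int = 0

    @property
    def max_lod(self) -> float:
        return float(np.max(self.lods))

    @property
    def best_theta(self) -> float:
        return float(self.theta_grid[int(np.argmax(self.lods))])

    def family_max_lod(self, family_id: str) -> float:
        return float(np.max(self.per_family[family_id]))


def two_point_lod(
    pedigrees: Pedigree | Sequence[Pedigree],
    genotypes: dict[str, dict[str, MarkerGenotype]] | dict[str, MarkerGenotype],
    mm: MarkerModel,
    dm: DiseaseModel,
    theta_grid: Sequence[float] = DEFAULT_THETA_GRID,
    marker: str = "marker",
    chrom: str = "",
    pos: int = 0,
) -> LinkageResult:
    """Two-point LOD over a theta grid; per-family LODs sum to the total.

    ``genotypes`` maps family id to {individual: allele pair} (or is a
    single such map when one pedigree is given).  A family whose genotypes
    are impossible even at theta = 0.5 contributes 0 at every theta; a
    theta where only that theta is impossible scores the ``-99`` sentinel.
    """
    if isinstance(pedigrees, Pedigree):
        pedigrees = [pedigrees]
        if genotypes and not any(isinstance(v, dict) for v in genotypes.values()):
            genotypes = {pedigrees[0].family_id: genotypes}
    grid = tuple(theta_grid)
    if 0.5 not in grid:
        raise ValueError("theta grid must include 0.5 (the null)")
    per_family: dict[str, np.ndarray] = {}
    for ped in pedigrees:
        fam_g = genotypes.get(ped.family_id, {})
        ll_null = pedigree_loglikelihood(ped, fam_g, mm, dm, 0.5)
        lods = np.zeros(len(grid))
        if ll_null != -math.inf:
            for t_i, theta in enumerate(grid):
                if theta == 0.5:
                    continue
                ll = pedigree_loglikelihood(ped, fam_g, mm, dm, theta)
                lods[t_i] = LOD_IMPOSSIBLE if ll == -math.inf else (ll - ll_null) / math.log(10)
        per_family[ped.family_id] = lods
    total = np.sum(list(per_family.values()), axis=0) if per_family else np.zeros(len(grid))
    return LinkageResult(marker, grid, total, per_family, chrom=chrom, pos=pos)


@dataclass
class LodRegion:
    chrom: str
    start: int
    end: int
    max_lod: float
    family: str  # family id, or "combined"


def lod_regions(
    results: Sequence[LinkageResult],
    threshold: float = 2.0,
    families: Optional[Sequence[str]] = None,
    combined: bool = False,
) -> list[LodRegion]:
    """Maximal runs of consecutive markers with max LOD > threshold.

    ``results`` must be position-ordered along one chromosome.  Region
    bounds extend to the flanking (first non-passing) markers, clamped to
    the scanned ends, so a variant landing just beyond the peak marker is
    still localized inside the region.
    """
    out: list[LodRegion] = []
    if not results:
        return out
    chrom = results[0].chrom
    tracks: list[tuple[str, list[float]]] = []
    if combined:
        tracks.append(("combined", [r.max_lod for r in results]))
    fam_ids = families
    if fam_ids is None:
        fam_ids = sorted({f for r in results for f in r.per_family})
    for fam in fam_ids:
        tracks.append((fam, [r.family_max_lod(fam) if fam in r.per_family else -math.inf
                             for r in results]))
    n = len(results)
    for fam, vals in tracks:
        i = 0
        while i < n:
            if vals[i] <= threshold:
                i += 1
                continue
            j = i
            while j + 1 < n and vals[j + 1] > threshold:
                j += 1
            start = results[i - 1].pos if i > 0 else results[i].pos
            end = results[j + 1].pos if j + 1 < n else results[j].pos
            out.append(LodRegion(chrom, start, end, max(vals[i : j + 1]), fam))
            i = j + 1
    return out


# ----------------------------------------------------------------------
# Model / results interface
# ----------------------------------------------------------------------
@dataclass
class MarkerData:
    """One marker's map position, model and per-family genotypes."""

    marker: str
    chrom: str
    pos: int
    model: MarkerModel
    genotypes: dict[str, dict[str, MarkerGenotype]]


class ParametricLinkage:
    """Affecteds-only parametric two-point linkage model over a marker panel.

    Parameters
    ----------
    pedigrees : list of Pedigree
    markers : list of MarkerData, position-ordered within chromosomes
    disease_model : DiseaseModel

    ``fit`` evaluates the exact pedigree likelihood at each grid theta per
    marker and family and returns a results object.
    """

    def __init__(
        self,
        pedigrees: Sequence[Pedigree],
        markers: Sequence[MarkerData],
        disease_model: DiseaseModel = DiseaseModel(),
    ):
        self.pedigrees = list(pedigrees)
        self.markers = sorted(markers, key=lambda m: (m.chrom, m.pos))
        self.disease_model = disease_model

    def fit(self, theta_grid: Sequence[float] = DEFAULT_THETA_GRID) -> "LinkageScanResults":
        results = [
            two_point_lod(
                self.pedigrees,
                md.genotypes,
                md.model,
                self.disease_model,
                theta_grid,
                marker=md.marker,
                chrom=md.chrom,
                pos=md.pos,
            )
            for md in self.markers
        ]
        return LinkageScanResults(self, results, tuple(theta_grid))


class LinkageScanResults:
    """Per-marker two-point LOD scores with region extraction and summary."""

    def __init__(self, model: ParametricLinkage, results: list[LinkageResult],
                 theta_grid: tuple[float, ...]):
        self.model = model
        self.results = results
        self.theta_grid = theta_grid

    def summary(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            row = {
                "marker": r.marker,
                "chrom": r.chrom,
                "pos": r.pos,
                "max_lod": r.max_lod,
                "best_theta": r.best_theta,
            }
            for t, lod in zip(r.theta_grid, r.lods):
                row[f"lod(theta={t:g})"] = lod
            for fam, lods in r.per_family.items():
                row[f"lod[{fam}]"] = float(np.max(lods))
            rows.append(row)
        return pd.DataFrame(rows)

    def lod_regions(self, threshold: float = 2.0, combined: bool = False) -> list[LodRegion]:
        out = []
        for chrom in dict.fromkeys(r.chrom for r in self.results):
            out.extend(
                lod_regions(
                    [r for r in self.results if r.chrom == chrom],
                    threshold=threshold,
                    combined=combined,
                )
            )
        return out
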