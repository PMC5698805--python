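"""Independent reference implementations used only to check the package.

Each oracle recomputes a quantity by a different route than the library:
the pedigree likelihood by materializing the full joint state table (one
axis per individual) instead of clique peeling; kinship by exhaustive
inheritance-vector enumeration instead of the recursive coefficient; IBD
window calls by explicit per-window loops instead of convolution.
"""
from __future__ import annotations

import math

import numpy as np

from pedexome.pedigree import Affection, Individual, Pedigree, Sex

# ----------------------------------------------------------------------
# Naive joint-table pedigree likelihood (ordered two-locus diplotypes)
# ----------------------------------------------------------------------
_LETTERS = "abcdefghijklmnopqrstuvwxyz"


def _topo_order(ped: Pedigree) -> list[Individual]:
    placed: set[str] = set()
    order: list[Individual] = []
    pending = list(ped.members)
    while pending:
        progressed = False
        for m in list(pending):
            if m.is_founder or (m.father_id in placed and m.mother_id in placed):
                order.append(m)
                placed.add(m.id)
                pending.remove(m)
                progressed = True
        if not progressed:
            raise ValueError("cannot topologically order pedigree")
    return order


def _transmit_prob(parent_state, child_hap, haps, theta):
    """P(parent with ordered haplotypes (h1, h2) transmits child_hap)."""
    h1, h2 = haps[parent_state[0]], haps[parent_state[1]]
    c = haps[child_hap]
    p = 0.0
    for (dsrc, msrc), w in (
        ((h1, h1), (1 - theta) / 2),
        ((h1, h2), theta / 2),
        ((h2, h2), (1 - theta) / 2),
        ((h2, h1), theta / 2),
    ):
        if c == (dsrc[0], msrc[1]):
            p += w
    return p


def oracle_loglikelihood(
    ped: Pedigree,
    genotypes: dict,
    freqs,
    q: float,
    penetrances,
    affecteds_only: bool,
    theta: float,
) -> float:
    """Exact likelihood by building the full joint table over all members."""
    k = len(freqs)
    haps = [(d, m) for d in (0, 1) for m in range(k)]
    nh = len(haps)
    prior = np.array([(q if d else 1 - q) * freqs[m] for d, m in haps])

    def pen(aff: Affection, ndis: int) -> float:
        if aff is Affection.AFFECTED:
            return penetrances[ndis]
        if aff is Affection.UNAFFECTED and not affecteds_only:
            return 1 - penetrances[ndis]
        return 1.0

    def allowed_states(ind: Individual):
        g = genotypes.get(ind.id)
        states = []
        for a in range(nh):
            for b in range(nh):
                if g is not None and sorted((haps[a][1], haps[b][1])) != sorted(g):
                    continue
                states.append((a, b))
        return states

    order = _topo_order(ped)
    states = {m.id: allowed_states(m) for m in order}
    axis_letter = {m.id: _LETTERS[i] for i, m in enumerate(order)}
    W = np.array(1.0)
    w_sub = ""
    for m in order:
        S = states[m.id]
        obs = np.array([pen(m.affection, haps[a][0] + haps[b][0]) for a, b in S])
        lc = axis_letter[m.id]
        if m.is_founder:
            vec = np.array([prior[a] * prior[b] for a, b in S]) * obs
            W = np.multiply.outer(W, vec)
        else:
            Sf, Sm = states[m.father_id], states[m.mother_id]
            T = np.zeros((len(Sf), len(Sm), len(S)))
            for i, sf in enumerate(Sf):
                for j, sm in enumerate(Sm):
                    for c, (cp, cm) in enumerate(S):
                        T[i, j, c] = _transmit_prob(sf, cp, haps, theta) * _transmit_prob(
                            sm, cm, haps, theta
                        )
            T = T * obs
            lf, lm = axis_letter[m.father_id], axis_letter[m.mother_id]
            W = np.einsum(f"{w_sub},{lf}{lm}{lc}->{w_sub}{lc}", W, T)
        w_sub += lc
    total = float(W.sum())
    return -math.inf if total <= 0.0 else math.log(total)


# ----------------------------------------------------------------------
# Kinship by inheritance-vector enumeration
# ----------------------------------------------------------------------
def oracle_kinship(ped: Pedigree, a: str, b: str) -> float:
    """phi(a, b) by averaging allele-origin identity over every inheritance
    vector (2 bits per non-founder meiosis), exact for small pedigrees."""
    order = _topo_order(ped)
    founders = [m for m in order if m.is_founder]
    nonfounders = [m for m in order if not m.is_founder]
    founder_alleles = {m.id: (2 * i, 2 * i + 1) for i, m in enumerate(founders)}
    nf_index = {m.id: i for i, m in enumerate(nonfounders)}
    n_bits = 2 * len(nonfounders)
    total = 0.0
    for vec in range(4 ** len(nonfounders)):
        alleles: dict[str, tuple[int, int]] = dict(founder_alleles)
        for m in nonfounders:
            i = nf_index[m.id]
            pat_bit = (vec >> (2 * i)) & 1
            mat_bit = (vec >> (2 * i + 1)) & 1
            alleles[m.id] = (alleles[m.father_id][pat_bit], alleles[m.mother_id][mat_bit])
        aa, bb = alleles[a], alleles[b]
        total += sum(aa[x] == bb[y] for x in (0, 1) for y in (0, 1)) / 4.0
    return total / 4 ** len(nonfounders)


# ----------------------------------------------------------------------
# IBD windows by explicit loops
# ----------------------------------------------------------------------
def oracle_ibd_positive(shared: list[bool], window: int, threshold: float) -> list[bool]:
    n = len(shared)
    if n < window:
        verdict = sum(shared) / n > threshold
        return [verdict] * n
    positive = [False] * n
    for w in range(n - window + 1):
        frac = sum(shared[w : w + window]) / window
        if frac > threshold:
            for i in range(w, w + window):
                positive[i] = True
    return positive


# ----------------------------------------------------------------------
# Random loop-free pedigrees and single-locus genotype drops
# ----------------------------------------------------------------------
def random_pedigree(rng: np.random.Generator, n_members: int, family_id: str = "R") -> Pedigree:
    """Grow a random loop-free pedigree to ~n_members by marrying in
    founder spouses and adding children to existing couples."""
    members = [
        Individual(f"{family_id}1", family_id, sex=Sex.MALE),
        Individual(f"{family_id}2", family_id, sex=Sex.FEMALE),
    ]
    couples = [(members[0].id, members[1].id)]
    next_id = 3
    while len(members) < n_members:
        if len(members) + 1 < n_members and rng.random() < 0.35 and len(members) >= 3:
            # marry a random non-spouse member to a new founder, start a couple
            cand = [m for m in members if not m.is_founder]
            if cand:
                who = cand[int(rng.integers(len(cand)))]
                spouse_sex = Sex.FEMALE if who.sex is Sex.MALE else Sex.MALE
                spouse = Individual(f"{family_id}{next_id}", family_id, sex=spouse_sex)
                next_id += 1
                members.append(spouse)
                pair = (who.id, spouse.id) if who.sex is Sex.MALE else (spouse.id, who.id)
                couples.append(pair)
                continue
        fa, mo = couples[int(rng.integers(len(couples)))]
        child = Individual(
            f"{family_id}{next_id}",
            family_id,
            father_id=fa,
            mother_id=mo,
            sex=Sex.MALE if rng.random() < 0.5 else Sex.FEMALE,
        )
        next_id += 1
        members.append(child)
    for m in members:
        u = rng.random()
        m.affection = (
            Affection.AFFECTED if u < 0.4 else Affection.UNAFFECTED if u < 0.8 else Affection.UNKNOWN
        )
        m.sequenced = True
    return Pedigree(family_id, members)


def drop_marker_genotypes(
    ped: Pedigree, freqs, rng: np.random.Generator
) -> dict[str, tuple[int, int]]:
    """Mendelian-consistent single-locus genotypes by gene dropping."""
    k = len(freqs)
    alleles: dict[str, tuple[int, int]] = {}
    for m in _topo_order(ped):
        if m.is_founder:
            alleles[m.id] = (
                int(rng.choice(k, p=freqs)),
                int(rng.choice(k, p=freqs)),
            )
        else:
            alleles[m.id] = (
                alleles[m.father_id][int(rng.integers(2))],
                alleles[m.mother_id][int(rng.integers(2))],
            )
    return alleles
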