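"""Pedigree data model, validation, kinship, Mendelian checks, peeling order.

Pedigrees are loop-free directed family graphs.  Individuals with both
parents absent are founders; an individual with exactly one recorded
parent violates the data model (both-or-neither rule) and is reported by
``validate`` rather than raised.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

from .variants import VariantRecord


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"

    @classmethod
    def from_ped_code(cls, code: str) -> "Sex":
        return {"1": cls.MALE, "2": cls.FEMALE}.get(str(code), cls.UNKNOWN)

    def to_ped_code(self) -> str:
        return {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}[self]


class Affection(enum.Enum):
    UNAFFECTED = "unaffected"
    AFFECTED = "affected"
    UNKNOWN = "unknown"

    @classmethod
    def from_ped_code(cls, code: str) -> "Affection":
        return {"1": cls.UNAFFECTED, "2": cls.AFFECTED}.get(str(code), cls.UNKNOWN)

    def to_ped_code(self) -> str:
        return {
            Affection.UNAFFECTED: "1",
            Affection.AFFECTED: "2",
            Affection.UNKNOWN: "0",
        }[self]


@dataclass
class Individual:
    id: str
    family_id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: Sex = Sex.UNKNOWN
    affection: Affection = Affection.UNKNOWN
    sequenced: bool = False
    genotyped: bool = True

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


#: one nuclear family unit: (father_id, mother_id, tuple of child ids)
NuclearFamily = tuple[str, str, tuple[str, ...]]


class PedigreeError(ValueError):
    pass


class LoopedPedigreeError(PedigreeError):
    """Raised when a pedigree contains a marriage/consanguinity loop that the
    exact peeling engine does not support."""


@dataclass
class Pedigree:
    family_id: str
    members: list[Individual] = field(default_factory=list)

    def __post_init__(self):
        self._by_id = {m.id: m for m in self.members}
        if len(self._by_id) != len(self.members):
            seen: set[str] = set()
            dups: list[str] = []
            for m in self.members:
                if m.id in seen:
                    dups.append(m.id)
                seen.add(m.id)
            raise PedigreeError(
                f"family {self.family_id}: duplicated individual id(s) {sorted(set(dups))}"
            )

    def __iter__(self):
        return iter(self.members)

    def __len__(self):
        return len(self.members)

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self._by_id

    def get(self, ind_id: str) -> Individual:
        try:
            return self._by_id[ind_id]
        except KeyError:
            raise PedigreeError(f"unknown individual {ind_id!r} in family {self.family_id}")

    @property
    def founders(self) -> list[Individual]:
        return [m for m in self.members if m.is_founder]

    @property
    def nonfounders(self) -> list[Individual]:
        return [m for m in self.members if not m.is_founder]

    def affected(self, sequenced_only: bool = False) -> list[Individual]:
        out = [m for m in self.members if m.affection is Affection.AFFECTED]
        if sequenced_only:
            out = [m for m in out if m.sequenced]
        return out

    def children_of(self, parent_id: str) -> list[Individual]:
        return [m for m in self.members if parent_id in (m.father_id, m.mother_id)]

    def nuclear_families(self) -> list[NuclearFamily]:
        """Group non-founders by parental couple, in stable member order."""
        couples: dict[tuple[str, str], list[str]] = {}
        for m in self.members:
            if m.father_id is not None and m.mother_id is not None:
                couples.setdefault((m.father_id, m.mother_id), []).append(m.id)
        return [(f, mo, tuple(kids)) for (f, mo), kids in couples.items()]

    # ------------------------------------------------------------------
    def validate(self) -> list[str]:
        """Return human-readable invariant violations (empty iff valid)."""
        violations: list[str] = []
        for m in self.members:
            if (m.father_id is None) != (m.mother_id is None):
                violations.append(f"{m.id}: exactly one parent recorded (need both or neither)")
            for role, pid, bad_sex in (
                ("father", m.father_id, Sex.FEMALE),
                ("mother", m.mother_id, Sex.MALE),
            ):
                if pid is None:
                    continue
                if pid == m.id:
                    violations.append(f"{m.id}: listed as its own {role}")
                    continue
                if pid not in self._by_id:
                    violations.append(f"{m.id}: {role} {pid!r} not in family")
                elif self._by_id[pid].sex is bad_sex:
                    violations.append(f"{m.id}: {role} {pid!r} has sex {bad_sex.value}")
        violations.extend(self._find_cycles())
        return violations

    def _find_cycles(self) -> list[str]:
        state: dict[str, int] = {}  # 0 in-progress, 1 done
        out: list[str] = []

        def visit(ind_id: str, stack: set[str]):
            if ind_id in stack:
                out.append(f"{ind_id}: is its own ancestor (parent cycle)")
                return
            if state.get(ind_id) == 1 or ind_id not in self._by_id:
                return
            m = self._by_id[ind_id]
            stack.add(ind_id)
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid != ind_id:
                    visit(pid, stack)
            stack.remove(ind_id)
            state[ind_id] = 1

        for m in self.members:
            visit(m.id, set())
        return out

    # ------------------------------------------------------------------
    def generation_depth(self, ind_id: str) -> int:
        """Longest founder-to-individual path length (founders: 0)."""
        m = self.get(ind_id)
        if m.is_founder or m.father_id not in self._by_id or m.mother_id not in self._by_id:
            return 0
        return 1 + max(self.generation_depth(m.father_id), self.generation_depth(m.mother_id))

    def kinship(self, a: str, b: str) -> float:
        """Recursive kinship coefficient phi(a, b).

        phi(a,a) = 1/2 (1 + F_a) with F_a the inbreeding coefficient
        (kinship of a's parents); founders are assumed unrelated and
        non-inbred.
        """
        self.get(a), self.get(b)
        cache: dict[tuple[str, str], float] = {}

        def phi(x: str, y: str) -> float:
            key = (x, y) if x <= y else (y, x)
            if key in cache:
                return cache[key]
            mx, my = self._by_id[x], self._by_id[y]
            if x == y:
                f = 0.0
                if not mx.is_founder:
                    f = phi(mx.father_id, mx.mother_id)
                val = 0.5 * (1.0 + f)
            else:
                # recurse on the individual further from the founders so the
                # other is never its descendant
                if self.generation_depth(x) < self.generation_depth(y):
                    mx, my = my, mx
                    x, y = y, x
                if mx.is_founder:
                    val = 0.0
                else:
                    val = 0.5 * (phi(mx.father_id, y) + phi(mx.mother_id, y))
            cache[key] = val
            return val

        return phi(a, b)

    # ------------------------------------------------------------------
    def peeling_order(self) -> list[tuple[NuclearFamily, Optional[str]]]:
        """Order nuclear-family cliques for exact likelihood peeling.

        Returns ``[(clique, pivot_id), ...]`` such that when cliques are
        eliminated in sequence, each clique shares at most one individual
        (its pivot) with the not-yet-eliminated remainder; the final clique
        has pivot ``None``.  Raises :class:`LoopedPedigreeError` when no
        such order exists (marriage or consanguinity loop).
        """
        remaining = self.nuclear_families()
        if not remaining:
            return []
        order: list[tuple[NuclearFamily, Optional[str]]] = []
        while remaining:
            membership: dict[str, int] = {}
            for fam in remaining:
                for ind in (fam[0], fam[1], *fam[2]):
                    membership[ind] = membership.get(ind, 0) + 1
            chosen = None
            for fam in remaining:
                shared = [i for i in (fam[0], fam[1], *fam[2]) if membership[i] > 1]
                if len(shared) <= 1:
                    chosen = fam
                    pivot = shared[0] if shared else None
                    break
            if chosen is None:
                raise LoopedPedigreeError(
                    f"family {self.family_id}: pedigree contains a loop; exact peeling unsupported"
                )
            order.append((chosen, pivot))
            remaining.remove(chosen)
        return order


# ----------------------------------------------------------------------
def mendelian_inconsistencies(v: VariantRecord, p: Pedigree) -> list[str]:
    """Ids of children whose genotype is impossible given both parents'.

    Only trios where child and both parents have non-missing calls at the
    biallelic autosomal site are evaluated; the check is invariant to
    allele order within a genotype.
    """
    bad: list[str] = []
    for m in p.members:
        if m.father_id is None or m.mother_id is None:
            continue
        child = v.calls.get(m.id)
        fa = v.calls.get(m.father_id)
        mo = v.calls.get(m.mother_id)
        if child is None or fa is None or mo is None:
            continue
        if child.is_missing or fa.is_missing or mo.is_missing:
            continue
        ok = any(
            tuple(sorted((a, b))) == child.unordered()
            for a in (fa.a1, fa.a2)
            for b in (mo.a1, mo.a2)
        )
        if not ok:
            bad.append(m.id)
    return bad
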