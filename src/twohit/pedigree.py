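"""Pedigree structures for multi-generation CNV-deletion families.

Individuals carry a deletion-carrier status on top of the usual PED
fields; trios are (offspring, carrier parent, noncarrier parent)
triples, the unit of the family-based expression comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

MALE = 1
FEMALE = 2


@dataclass
class Individual:
    sample_id: str
    family_id: str
    father_id: str  # "0" if not in pedigree
    mother_id: str
    sex: int  # 1 male, 2 female, 0 unknown
    carrier: bool
    role: str = ""  # child | parent | grandparent | sibling (descriptive)

    @property
    def has_both_parents(self) -> bool:
        return self.father_id != "0" and self.mother_id != "0"


@dataclass
class Trio:
    """Offspring with one carrier and one noncarrier parent."""

    offspring_id: str
    carrier_parent_id: str
    noncarrier_parent_id: str
    offspring_carrier: bool


@dataclass
class Pedigree:
    individuals: dict[str, Individual] = field(default_factory=dict)

    def add(self, ind: Individual) -> None:
        if ind.sample_id in self.individuals:
            raise ValueError(f"duplicate sample id {ind.sample_id}")
        self.individuals[ind.sample_id] = ind

    def __iter__(self) -> Iterator[Individual]:
        return iter(self.individuals.values())

    def __len__(self) -> int:
        return len(self.individuals)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.individuals

    def __getitem__(self, sample_id: str) -> Individual:
        return self.individuals[sample_id]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.individuals)

    @property
    def families(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self:
            seen.setdefault(ind.family_id, None)
        return list(seen)

    def carriers(self) -> list[str]:
        return [i.sample_id for i in self if i.carrier]

    def noncarriers(self) -> list[str]:
        return [i.sample_id for i in self if not i.carrier]

    def parents_of(self, sample_id: str) -> tuple[Individual | None, Individual | None]:
        ind = self[sample_id]
        father = self.individuals.get(ind.father_id)
        mother = self.individuals.get(ind.mother_id)
        return father, mother

    def validate(self) -> None:
        """Check parent links resolve and parentage is acyclic."""
        for ind in self:
            for pid in (ind.father_id, ind.mother_id):
                if pid != "0" and pid not in self.individuals:
                    raise ValueError(
                        f"{ind.sample_id} references missing parent {pid}"
                    )
        # cycle check by walking ancestry
        for ind in self:
            seen = {ind.sample_id}
            frontier = [ind.sample_id]
            while frontier:
                cur = self[frontier.pop()]
                for pid in (cur.father_id, cur.mother_id):
                    if pid == "0" or pid not in self.individuals:
                        continue
                    if pid in seen:
                        raise ValueError(
                            f"cyclic parentage involving {pid}"
                        )
                    seen.add(pid)
                    frontier.append(pid)


def extract_trios(
    pedigree: Pedigree, include_noncarrier_offspring: bool = False
) -> list[Trio]:
    """All (offspring, carrier parent, noncarrier parent) triples.

    An offspring forms a trio only when both parents are genotyped and
    their carrier statuses differ. Carrier parents with genotyped
    grandparents yield trios too (offspring role is irrelevant; only the
    parent-pair discordance matters). Noncarrier offspring are excluded
    unless ``include_noncarrier_offspring`` is set.
    """
    trios = []
    for ind in pedigree:
        if not ind.has_both_parents:
            continue
        father, mother = pedigree.parents_of(ind.sample_id)
        assert father is not None and mother is not None
        if father.carrier == mother.carrier:
            continue  # concordant parents: no carrier/noncarrier contrast
        if not ind.carrier and not include_noncarrier_offspring:
            continue
        carrier_p, noncarrier_p = (
            (father, mother) if father.carrier else (mother, father)
        )
        trios.append(
            Trio(
                offspring_id=ind.sample_id,
                carrier_parent_id=carrier_p.sample_id,
                noncarrier_parent_id=noncarrier_p.sample_id,
                offspring_carrier=ind.carrier,
            )
        )
    return trios


def replicate_columns(sample_ids: Iterable[str], n_replicates: int) -> list[str]:
    """Column labels ``sample.replicate`` for replicate-level matrices."""
    return [f"{s}.{r + 1}" for s in sample_ids for r in range(n_replicates)]
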