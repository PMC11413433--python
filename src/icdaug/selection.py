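"""Low-resource label selection.

The selection procedure identifies code families worth augmenting:

1. scan for *few-shot* codes common to all three splits, with training
   population between 1 and ``few_shot_max`` (default 5);
2. among the families of those codes, retain families that also contain at
   least one *frequent* code (training population strictly above
   ``frequent_threshold``, default 100) and at least one *zero-shot* code
   (absent from training, present in test);
3. sample ``n_families`` of the retained families uniformly at random;
4. within the chosen families, every code with training population strictly
   below ``generation_pop_cap`` (default 100) that occurs in training
   (few-shot part) or only outside it (zero-shot part) becomes a
   *generation code* — the codes whose population the silver standard will
   raise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .corpus import PopulationTable
from .errors import InsufficientFamiliesError
from .hierarchy import CodeId, FamilyId, family_of


@dataclass(frozen=True)
class SelectionConfig:
    few_shot_max: int = 5
    frequent_threshold: int = 100  # strict >
    n_families: int = 10
    generation_pop_cap: int = 100  # strict <
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.few_shot_max, self.frequent_threshold, self.n_families,
               self.generation_pop_cap) <= 0:
            raise ValueError("all selection counts must be positive")
        if self.few_shot_max >= self.frequent_threshold:
            raise ValueError("few_shot_max must be below frequent_threshold")


@dataclass(frozen=True)
class SelectionResult:
    few_shot_common: frozenset[CodeId]
    retained_families: frozenset[FamilyId]
    chosen_families: frozenset[FamilyId]
    few_shot_generation: frozenset[CodeId]
    zero_shot_generation: frozenset[CodeId]

    @property
    def generation_codes(self) -> frozenset[CodeId]:
        return self.few_shot_generation | self.zero_shot_generation

    def family_codeset(self, pop: PopulationTable) -> set[CodeId]:
        """All observed codes belonging to the chosen families (codeset *f*)."""
        return {c for c in pop.codes() if family_of(c) in self.chosen_families}

    def to_json(self, path) -> None:
        payload = {
            "few_shot_common": sorted(self.few_shot_common),
            "retained_families": sorted(self.retained_families),
            "chosen_families": sorted(self.chosen_families),
            "few_shot_generation": sorted(self.few_shot_generation),
            "zero_shot_generation": sorted(self.zero_shot_generation),
        }
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(payload, handle, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SelectionResult":
        with open(path, "r", encoding="utf-8") as handle:
            payload = json.load(handle)
        return cls(
            frozenset(payload["few_shot_common"]),
            frozenset(payload["retained_families"]),
            frozenset(payload["chosen_families"]),
            frozenset(payload["few_shot_generation"]),
            frozenset(payload["zero_shot_generation"]),
        )


def few_shot_common_codes(
    pop: PopulationTable, cfg: SelectionConfig = SelectionConfig()
) -> set[CodeId]:
    """Codes with train population in [1, few_shot_max] present in dev and test."""
    out = set()
    for code in pop.codes():
        train = pop.count(code, "train")
        if 1 <= train <= cfg.few_shot_max and pop.count(code, "dev") >= 1 \
                and pop.count(code, "test") >= 1:
            out.add(code)
    return out


def retain_families(
    candidates: set[CodeId],
    pop: PopulationTable,
    cfg: SelectionConfig = SelectionConfig(),
) -> set[FamilyId]:
    """Families of candidate codes having both a frequent and a zero-shot member.

    Membership is judged over all codes observed anywhere in the corpus, not
    only the candidates, since the frequent-member clause references codes
    outside the candidate list.
    """
    candidate_families = {family_of(c) for c in candidates}
    members: dict[FamilyId, list[CodeId]] = {f: [] for f in candidate_families}
    for code in pop.codes():
        fam = family_of(code)
        if fam in members:
            members[fam].append(code)
    retained = set()
    for fam, codes in members.items():
        frequent = any(pop.count(c, "train") > cfg.frequent_threshold for c in codes)
        zero_shot = any(
            pop.count(c, "train") == 0 and pop.count(c, "test") >= 1 for c in codes
        )
        if frequent and zero_shot:
            retained.add(fam)
    return retained


def choose_generation_families(
    retained: set[FamilyId],
    cfg: SelectionConfig = SelectionConfig(),
    rng: np.random.Generator | None = None,
) -> set[FamilyId]:
    """Uniform sample without replacement of ``n_families`` retained families."""
    if len(retained) < cfg.n_families:
        raise InsufficientFamiliesError(
            f"need {cfg.n_families} families, have {len(retained)}"
        )
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    ordered = sorted(retained)
    picked = rng.choice(len(ordered), size=cfg.n_families, replace=False)
    return {ordered[i] for i in picked}


def generation_codes(
    chosen: set[FamilyId],
    pop: PopulationTable,
    cfg: SelectionConfig = SelectionConfig(),
    *,
    few_shot_common: set[CodeId] = frozenset(),
    retained: set[FamilyId] = frozenset(),
) -> SelectionResult:
    """Enumerate generation codes within the chosen families.

    A code qualifies when its family was chosen, its training population is
    strictly below ``generation_pop_cap``, and it either occurs in training
    (few-shot part) or occurs in test but not training (zero-shot part).
    """
    few, zero = set(), set()
    for code in pop.codes():
        if family_of(code) not in chosen:
            continue
        train = pop.count(code, "train")
        if train >= cfg.generation_pop_cap:
            continue
        if train >= 1:
            few.add(code)
        elif pop.count(code, "test") >= 1:
            zero.add(code)
    return SelectionResult(
        few_shot_common=frozenset(few_shot_common),
        retained_families=frozenset(retained or chosen),
        chosen_families=frozenset(chosen),
        few_shot_generation=frozenset(few),
        zero_shot_generation=frozenset(zero),
    )


def select(
    pop: PopulationTable,
    cfg: SelectionConfig = SelectionConfig(),
    rng: np.random.Generator | None = None,
) -> SelectionResult:
    """Run the full selection pipeline on a population table."""
    candidates = few_shot_common_codes(pop, cfg)
    retained = retain_families(candidates, pop, cfg)
    chosen = choose_generation_families(retained, cfg, rng)
    return generation_codes(
        chosen, pop, cfg, few_shot_common=candidates, retained=retained
    )
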