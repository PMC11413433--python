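"""Synthetic study conditions: code space, coded corpus, rating fixtures.

The generator reproduces the statistical structure the augmentation study
assumes, so every pipeline stage runs without restricted clinical data or
a hosted model:

* a hierarchical code space with families keyed by three-character heads,
  each family holding a frequent leaf, several few-shot leaves (1-5
  training documents) and a zero-shot leaf (test-only), plus a pool of
  background frequent codes providing the big head of the long-tail label
  distribution;
* label-conditioned text: every document mentions tokens drawn from its
  labels' descriptions (the condition word and the distinctive variant
  word, each independently omitted with a configurable probability but
  never both) amid noise tokens, so a coder can learn the label mapping
  from text that shares vocabulary with the description-driven document
  generator;
* a per-document label-count distribution shared by all three splits;
* ordinal rating fixtures for the agreement module.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._lexicon import CONDITIONS
from .agreement import ITEM_CLASSES, METRICS, RatingTable
from .corpus import Corpus, Document, PopulationTable, label_populations, preprocess_text
from .errors import InfeasibleStrataError
from .hierarchy import CodeId, CodeTable, FamilyId, Hierarchy

STOPWORDS = {"with", "of", "the", "and", "a", "an", "in", "to", "type",
             "other", "unspecified", "1", "2", "form", "state", "pattern",
             "course", "component", "encounter", "sequela", "involvement",
             "segment", "episodes", "exacerbation"}

_PREFIXES = ["hyper", "hypo", "para", "peri", "poly", "brady", "tachy",
             "neo", "dys", "iso"]
_ROOTS = ["cyt", "derm", "nephr", "cardi", "neur", "oste", "hepat",
          "gastr", "pulmon", "angi"]
_SUFFIXES = ["osis", "itis", "emia", "opathy", "algia", "plasia"]


def _term_stream():
    """Unique pseudo-clinical single-token terms (600 available)."""
    for suffix, prefix, root in itertools.product(_SUFFIXES, _PREFIXES, _ROOTS):
        yield f"{prefix}{root}{suffix}"


@dataclass(frozen=True)
class CodeSpaceConfig:
    n_families: int = 12
    leaves_per_family: int = 6
    n_background: int = 20
    #: When True every leaf gets a unique variant term (no shared
    #: "unspecified"/"Other" surface forms) — the fully separable space
    #: used to verify that label-conditioned text is learnable.
    distinct_descriptions: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.leaves_per_family < 3:
            raise ValueError(
                "families need >=3 leaves (frequent + few-shot + zero-shot)"
            )


@dataclass(frozen=True)
class CodeSpace:
    hierarchy: Hierarchy
    code_table: CodeTable
    families: tuple[FamilyId, ...]           # designated augmentation families
    family_leaves: dict[FamilyId, tuple[CodeId, ...]]
    background: tuple[CodeId, ...]           # frequent filler codes

    def designated_roles(self) -> dict[str, tuple[CodeId, ...]]:
        """Leaf roles per family: index 0 frequent, last zero-shot, middle
        few-shot (the 'unspecified' leaf is frequent; one few-shot leaf per
        family carries an 'Other ...' umbrella description)."""
        frequent, few_shot, zero_shot = [], [], []
        for fam in self.families:
            leaves = self.family_leaves[fam]
            frequent.append(leaves[0])
            zero_shot.append(leaves[-1])
            few_shot.extend(leaves[1:-1])
        return {
            "frequent": tuple(frequent),
            "few_shot": tuple(few_shot),
            "zero_shot": tuple(zero_shot),
        }


def make_code_space(cfg: CodeSpaceConfig = CodeSpaceConfig()) -> CodeSpace:
    """Build a synthetic code space with templated descriptions.

    Every designated family gets one leaf described as ``..., unspecified``
    (its frequent member), one ``Other ...`` umbrella leaf, and otherwise
    leaves distinguished by unique pseudo-clinical variant terms, so the
    description-rewriting rules of the document generator are exercised.
    """
    rng = np.random.default_rng(cfg.seed)
    terms = _term_stream()
    heads: list[str] = []
    letters = "ABCDEFGHJKLMNPRSTUVW"
    numbers = rng.permutation(100)
    for i in range(cfg.n_families + cfg.n_background):
        heads.append(f"{letters[i % len(letters)]}{numbers[i] % 100:02d}")
    if len(set(heads)) != len(heads):  # pragma: no cover - 20x100 space
        raise RuntimeError("family head collision")

    entries: dict[str, str] = {}
    families = tuple(heads[: cfg.n_families])
    family_leaves: dict[str, tuple[str, ...]] = {}
    conditions = list(CONDITIONS)
    for i, fam in enumerate(families):
        condition = conditions[i % len(conditions)]
        leaves = []
        for j in range(cfg.leaves_per_family):
            code = f"{fam}.{j}"
            if cfg.distinct_descriptions:
                desc = f"{condition.capitalize()} with {next(terms)}"
            elif j == 0:
                desc = f"{condition.capitalize()}, unspecified"
            elif j == 1:
                desc = f"Other specified {condition}"
            else:
                desc = f"{condition.capitalize()} with {next(terms)}"
            entries[code] = desc
            leaves.append(code)
        family_leaves[fam] = tuple(leaves)

    background = []
    for i, head in enumerate(heads[cfg.n_families:]):
        code = f"{head}.0"
        condition = conditions[(cfg.n_families + i) % len(conditions)]
        entries[code] = f"{condition.capitalize()} with {next(terms)}"
        background.append(code)

    hierarchy = Hierarchy.family_only(entries.keys())
    return CodeSpace(
        hierarchy=hierarchy,
        code_table=CodeTable(entries),
        families=families,
        family_leaves=family_leaves,
        background=tuple(background),
    )


def trigger_tokens(description: str, k: int = 2) -> list[str]:
    """The learnable tokens of a description: the leading condition token
    plus up to ``k - 1`` trailing distinctive tokens (stopwords removed)."""
    tokens = [t for t in preprocess_text(description) if t not in STOPWORDS]
    if not tokens:
        return []
    if len(tokens) == 1 or k == 1:
        return tokens[:1]
    return [tokens[0]] + tokens[-(k - 1):]


@dataclass(frozen=True)
class CorpusConfig:
    n_train: int = 3000
    n_dev: int = 300
    n_test: int = 600
    mean_labels: float = 5.0
    max_labels: int = 12
    popularity_exponent: float = 1.5
    min_frequent_pop: int = 120
    trigger_tokens_per_label: int = 2
    trigger_dropout: float = 0.3
    noise_vocab_size: int = 500
    mean_noise_tokens: float = 15.0
    #: When False, no low-resource strata are planted: every leaf joins the
    #: popularity pool (used for the separable learnability check, where
    #: each label needs enough examples to be learnable at all).
    plant_strata: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_train, self.n_dev, self.n_test) <= 0:
            raise ValueError("split sizes must be positive")
        if not 0.0 <= self.trigger_dropout < 1.0:
            raise ValueError("trigger_dropout must lie in [0, 1)")


@dataclass
class GeneratorManifest:
    populations: PopulationTable
    strata: dict[str, tuple[CodeId, ...]]
    code_space_seed: int
    corpus_seed: int

    def to_json(self, path) -> None:
        payload = {
            "strata": {k: sorted(v) for k, v in self.strata.items()},
            "code_space_seed": self.code_space_seed,
            "corpus_seed": self.corpus_seed,
            "populations": {
                code: {
                    s: int(self.populations.count(code, s))
                    for s in ("train", "dev", "test")
                }
                for code in self.populations.codes()
            },
        }
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(payload, handle, indent=2, sort_keys=True)


def sample_corpus(
    space: CodeSpace, cfg: CorpusConfig = CorpusConfig()
) -> tuple[Corpus, GeneratorManifest]:
    """Sample a coded corpus with planted frequent/few-shot/zero-shot strata.

    Popularity sampling over the frequent pool (designated frequent leaves
    plus background codes) follows a truncated power law; the low-resource
    strata are planted deterministically afterwards so the study's
    preconditions hold exactly: few-shot leaves get 1-5 training documents
    plus at least one dev and one test document, zero-shot leaves appear
    only in test, and each designated family's frequent leaf is topped up
    past ``min_frequent_pop`` training documents.
    """
    rng = np.random.default_rng(cfg.seed)
    roles = space.designated_roles()
    if cfg.plant_strata:
        pool = sorted(set(roles["frequent"]) | set(space.background))
    else:
        roles = {"frequent": (), "few_shot": (), "zero_shot": ()}
        pool = sorted(space.code_table.entries)
    order = rng.permutation(len(pool))
    weights = (np.arange(len(pool)) + 1.0) ** -cfg.popularity_exponent
    weights = weights[np.argsort(order)]
    weights /= weights.sum()

    split_sizes = {"train": cfg.n_train, "dev": cfg.n_dev, "test": cfg.n_test}
    needed_test = len(roles["few_shot"]) + len(roles["zero_shot"])
    if cfg.n_test < needed_test or cfg.n_dev < len(roles["few_shot"]) \
            or cfg.n_train < 5 * len(roles["few_shot"]):
        raise InfeasibleStrataError(
            "document budget cannot host the planted strata"
        )

    labels_per_doc: dict[str, list[set[str]]] = {}
    for split, size in split_sizes.items():
        per_doc = []
        for _ in range(size):
            n_labels = 1 + rng.poisson(max(cfg.mean_labels - 1.0, 0.0))
            n_labels = int(min(n_labels, cfg.max_labels, len(pool)))
            picked = rng.choice(len(pool), size=n_labels, replace=False, p=weights)
            per_doc.append({pool[i] for i in picked})
        labels_per_doc[split] = per_doc

    def plant(split: str, code: str, count: int) -> None:
        docs = labels_per_doc[split]
        free = [i for i in range(len(docs)) if code not in docs[i]]
        take = rng.choice(len(free), size=count, replace=False)
        for i in take:
            docs[free[i]].add(code)

    for code in roles["few_shot"]:
        plant("train", code, int(rng.integers(1, 6)))
        plant("dev", code, int(rng.integers(1, 3)))
        plant("test", code, int(rng.integers(1, 4)))
    for code in roles["zero_shot"]:
        plant("test", code, int(rng.integers(1, 4)))
    for code in roles["frequent"]:
        have = sum(code in doc for doc in labels_per_doc["train"])
        if have <= cfg.min_frequent_pop:
            plant("train", code, cfg.min_frequent_pop + 1 - have)
        for split in ("dev", "test"):
            if not any(code in doc for doc in labels_per_doc[split]):
                plant(split, code, 1)

    triggers = {
        code: trigger_tokens(space.code_table[code], cfg.trigger_tokens_per_label)
        for code in space.code_table.entries
    }
    noise_vocab = [f"zz{i:03d}" for i in range(cfg.noise_vocab_size)]

    documents = []
    counter = 0
    for split in ("train", "dev", "test"):
        for labels in labels_per_doc[split]:
            tokens: list[str] = []
            for code in sorted(labels):
                toks = triggers[code]
                if not toks:
                    continue
                kept = [t for t in toks if rng.random() >= cfg.trigger_dropout]
                # a label always leaves at least its most specific token
                tokens.extend(kept if kept else [toks[-1]])
            n_noise = int(rng.poisson(cfg.mean_noise_tokens))
            tokens += [noise_vocab[i]
                       for i in rng.integers(0, len(noise_vocab), size=n_noise)]
            rng.shuffle(tokens)
            documents.append(
                Document(
                    doc_id=f"syn{counter:06d}",
                    text=" ".join(tokens),
                    labels=frozenset(labels),
                    split=split,
                )
            )
            counter += 1

    corpus = Corpus(documents, provenance="real")
    manifest = GeneratorManifest(
        populations=label_populations(corpus),
        strata={k: tuple(sorted(v)) for k, v in roles.items()},
        code_space_seed=-1,
        corpus_seed=cfg.seed,
    )
    return corpus, manifest


def rating_fixture(
    n_raters: int = 4,
    n_items: int = 20,
    effect_profile: str = "calibrated",
    seed: int = 0,
) -> RatingTable:
    """Ordinal rating fixture for the agreement module.

    Profiles: ``zero-noise`` (unanimous raters, scores varying across
    items), ``uniform`` (independent uniform scores, chance agreement),
    ``calibrated`` (class- and metric-specific means with rater noise,
    shaped like a panel that rates real documents high and synthetic
    documents lower on narrative criteria).
    """
    if n_raters < 2:
        raise ValueError("need at least 2 raters")
    rng = np.random.default_rng(seed)
    base_mu = {
        "real": dict.fromkeys(METRICS, 4.5),
        "synthetic": {
            "correctness_nonlow": 4.4, "correctness_low": 4.5,
            "informativeness_nonlow": 2.8, "informativeness_low": 3.0,
            "authenticity_patient": 3.2, "authenticity_scenario": 2.3,
            "acceptability": 2.2,
        },
    }
    rows = []
    for idx in range(n_items):
        item_class = ITEM_CLASSES[idx % 2] if n_items > 1 else "real"
        item_id = f"doc{idx:03d}"
        for metric in METRICS:
            if effect_profile == "zero-noise":
                bump = (idx // 2) % 2  # vary scores across items within a class
                score = 4 + bump if item_class == "real" else 2 + bump
                scores = [score] * n_raters
            elif effect_profile == "uniform":
                scores = rng.integers(1, 6, size=n_raters).tolist()
            elif effect_profile == "calibrated":
                mu = base_mu[item_class][metric] + rng.normal(0, 0.4)
                scores = np.clip(
                    np.rint(mu + rng.normal(0, 0.7, size=n_raters)), 1, 5
                ).astype(int).tolist()
            else:
                raise ValueError(f"unknown effect profile {effect_profile!r}")
            for r, score in enumerate(scores):
                rows.append(
                    {
                        "item_id": item_id,
                        "item_class": item_class,
                        "rater_id": f"rater{r}",
                        "metric": metric,
                        "score": int(score),
                    }
                )
    return RatingTable(pd.DataFrame(rows))
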