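"""End-to-end study orchestration.

``run_study`` executes the augmentation experiment: synthesize (or load) a
coded corpus, select low-resource code families, build the silver
standard, generate synthetic training documents, train baseline and
augmented coders on identical dev/test splits, and evaluate flat,
hierarchical, and within-/out-of-family metrics on the ``overall``, ``f``
(all codes in chosen families) and ``fgen`` (generation codes) codesets.
All randomness flows from a single global seed through named substreams;
reports serialize deterministically, so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .coder import CoderConfig, TrainedCoder, predict, train_coder
from .corpus import Corpus, Document, label_populations, read_corpus
from .docgen import extract_assigned_codes, generate_document, scrub_codes
from .evaluation import (
    MetricsReport,
    WHCMReport,
    flat_metrics,
    hierarchical_metrics,
    whcm_rates,
)
from .hierarchy import CodeTable, Hierarchy
from .selection import SelectionConfig, SelectionResult, select
from .silver import SilverConfig, SilverSet, build_silver_set
from .synthetic_data import (
    CodeSpace,
    CodeSpaceConfig,
    CorpusConfig,
    make_code_space,
    sample_corpus,
)

logger = logging.getLogger(__name__)

_SUBSTREAMS = ("space", "corpus", "selection", "silver", "docgen",
               "coder_base", "coder_aug")


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


@contextmanager
def _stage(name: str):
    try:
        yield
    except Exception as exc:
        logger.error("stage %s failed: %s", name, exc)
        raise StageError(f"stage {name!r} failed: {exc}") from exc


def substream_seed(global_seed: int, name: str) -> int:
    """Deterministic named child seed below 2**31."""
    if name not in _SUBSTREAMS:
        raise ValueError(f"unknown substream {name!r}")
    ss = np.random.SeedSequence(
        entropy=global_seed, spawn_key=(_SUBSTREAMS.index(name),)
    )
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    arms: str = "both"  # baseline | augmented | both
    corpus_path: str | None = None
    code_table_path: str | None = None
    out_dir: str | None = None
    code_space: CodeSpaceConfig = field(default_factory=CodeSpaceConfig)
    corpus: CorpusConfig = field(default_factory=CorpusConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    silver: SilverConfig = field(default_factory=SilverConfig)
    coder: CoderConfig = field(default_factory=CoderConfig)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        payload = self.as_dict()
        payload.pop("out_dir", None)  # output location is not part of the study
        canon = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key, sub_cls in (
            ("code_space", CodeSpaceConfig), ("corpus", CorpusConfig),
            ("selection", SelectionConfig), ("silver", SilverConfig),
            ("coder", CoderConfig),
        ):
            if key in raw:
                kwargs[key] = sub_cls(**raw.pop(key))
        kwargs.update(raw)
        return cls(**kwargs)


@dataclass
class ArmReport:
    name: str
    metrics: list[MetricsReport]
    whcm: list[WHCMReport]
    n_train_docs: int
    selected_epoch: int
    dev_map_per_epoch: list[float]

    def metric(self, codeset: str, variant: str) -> MetricsReport:
        for report in self.metrics:
            if report.codeset_name == codeset and report.variant == variant:
                return report
        raise KeyError((codeset, variant))

    def whcm_report(self, codeset: str) -> WHCMReport:
        for report in self.whcm:
            if report.codeset_name == codeset:
                return report
        raise KeyError(codeset)

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "n_train_docs": self.n_train_docs,
            "selected_epoch": self.selected_epoch,
            "dev_map_per_epoch": self.dev_map_per_epoch,
            "metrics": [m.as_dict() for m in self.metrics],
            "whcm": [w.as_dict() for w in self.whcm],
        }


@dataclass
class ExperimentSummary:
    seed: int
    config_hash: str
    arms: dict[str, ArmReport]
    n_silver_records: int
    n_generation_codes: int
    chosen_families: list[str]

    def as_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config_hash": self.config_hash,
            "n_silver_records": self.n_silver_records,
            "n_generation_codes": self.n_generation_codes,
            "chosen_families": sorted(self.chosen_families),
            "arms": {name: arm.as_dict() for name, arm in sorted(self.arms.items())},
        }

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(self.as_dict(), sort_keys=True, indent=2) + "\n"
        )


def synthesize_documents(
    silver: SilverSet, code_table: CodeTable, seed: int
) -> list[Document]:
    """Generate, extract, and scrub one training document per silver record.

    Labels of the resulting documents are the codes extracted back out of
    the generated text (falling back to the request's label set when
    extraction finds nothing).
    """
    docs = []
    for i, record in enumerate(silver.records):
        raw = generate_document(record, code_table, seed=seed)
        codes, body = extract_assigned_codes(raw)
        text = scrub_codes(body)
        docs.append(
            Document(
                doc_id=f"gen{i:06d}",
                text=text,
                labels=frozenset(codes) if codes else record.label_set,
                split="train",
            )
        )
    return docs


def _restrict(label_sets, codeset):
    codeset = set(codeset)
    return [set(labels) & codeset for labels in label_sets]


def evaluate_arm(
    name: str,
    coder: TrainedCoder,
    test_docs: list[Document],
    codesets: dict[str, set[str]],
    hierarchy: Hierarchy,
    n_train_docs: int,
) -> ArmReport:
    """All metric suites for one trained coder on the shared test split."""
    preds = predict(coder, test_docs)
    gold = [set(d.labels) for d in test_docs]
    pred = preds.label_sets
    metrics, whcm = [], []
    for cs_name, codeset in sorted(codesets.items()):
        g, p = _restrict(gold, codeset), _restrict(pred, codeset)
        metrics.append(flat_metrics(gold, pred, codeset, codeset_name=cs_name))
        for variant in ("set_based", "cophe"):
            metrics.append(
                hierarchical_metrics(g, p, hierarchy, variant, codeset_name=cs_name)
            )
        if cs_name in ("f", "fgen"):
            whcm.append(whcm_rates(gold, pred, codeset, hierarchy, codeset_name=cs_name))
    return ArmReport(
        name=name,
        metrics=metrics,
        whcm=whcm,
        n_train_docs=n_train_docs,
        selected_epoch=coder.selected_epoch,
        dev_map_per_epoch=coder.dev_map_per_epoch,
    )


def run_study(config: RunConfig = RunConfig()) -> ExperimentSummary:
    """Execute the full augmentation study for one global seed."""
    seed = config.seed
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    with _stage("corpus"):
        if config.corpus_path:
            corpus = read_corpus(config.corpus_path)
            code_table = CodeTable.from_csv(config.code_table_path)
            hierarchy = Hierarchy.family_only(
                corpus.codeset() | set(code_table.entries)
            )
        else:
            space: CodeSpace = make_code_space(
                replace(config.code_space, seed=substream_seed(seed, "space"))
            )
            corpus, _ = sample_corpus(
                space, replace(config.corpus, seed=substream_seed(seed, "corpus"))
            )
            code_table, hierarchy = space.code_table, space.hierarchy

    with _stage("selection"):
        pop = label_populations(corpus)
        sel_cfg = replace(config.selection, seed=substream_seed(seed, "selection"))
        sel: SelectionResult = select(
            pop, sel_cfg, rng=np.random.default_rng(sel_cfg.seed)
        )
        logger.info(
            "selection: %d families chosen, %d generation codes",
            len(sel.chosen_families), len(sel.generation_codes),
        )
        if out:
            sel.to_json(out / "selection.json")

    with _stage("silver"):
        silver = build_silver_set(
            corpus, sel, hierarchy, config.silver,
            rng=np.random.default_rng(substream_seed(seed, "silver")),
        )
        if out:
            from .silver import write_silver_set

            write_silver_set(silver, out / "silver.jsonl")
    with _stage("docgen"):
        synth_docs = synthesize_documents(
            silver, code_table, seed=substream_seed(seed, "docgen")
        )

    train_docs = corpus.split("train")
    dev_docs = corpus.split("dev")
    test_docs = corpus.split("test")

    codesets = {
        "overall": set(pop.codes()),
        "f": sel.family_codeset(pop),
        "fgen": set(sel.generation_codes),
    }

    arms: dict[str, ArmReport] = {}
    if config.arms in ("baseline", "both"):
        with _stage("train_baseline"):
            coder_base = train_coder(
                train_docs, dev_docs,
                replace(config.coder, seed=substream_seed(seed, "coder_base")),
            )
        with _stage("evaluate_baseline"):
            arms["baseline"] = evaluate_arm(
                "baseline", coder_base, test_docs, codesets, hierarchy,
                n_train_docs=len(train_docs),
            )
    if config.arms in ("augmented", "both"):
        with _stage("train_augmented"):
            aug_train = train_docs + synth_docs
            coder_aug = train_coder(
                aug_train, dev_docs,
                replace(config.coder, seed=substream_seed(seed, "coder_aug")),
            )
        with _stage("evaluate_augmented"):
            arms["augmented"] = evaluate_arm(
                "augmented", coder_aug, test_docs, codesets, hierarchy,
                n_train_docs=len(aug_train),
            )

    summary = ExperimentSummary(
        seed=seed,
        config_hash=config.config_hash,
        arms=arms,
        n_silver_records=len(silver),
        n_generation_codes=len(sel.generation_codes),
        chosen_families=sorted(sel.chosen_families),
    )
    if out:
        summary.to_json(out / "summary.json")
        _write_report_csv(summary, out / "metrics.csv")
    return summary


def _write_report_csv(summary: ExperimentSummary, path: Path) -> None:
    import pandas as pd

    rows = []
    for arm_name, arm in sorted(summary.arms.items()):
        for report in arm.metrics:
            row = {"arm": arm_name}
            row.update(report.as_dict())
            rows.append(row)
        for report in arm.whcm:
            row = {"arm": arm_name, "variant": "whcm"}
            row.update(report.as_dict())
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class ReplicationResult:
    """Aggregate of repeated baseline-vs-augmented runs across seeds."""

    seeds: list[int]
    baseline_fgen_macro_f1: list[float]
    augmented_fgen_macro_f1: list[float]
    baseline_fgen_oof: list[float]
    augmented_fgen_oof: list[float]

    @property
    def n_improved(self) -> int:
        return sum(
            a > b for a, b in zip(
                self.augmented_fgen_macro_f1, self.baseline_fgen_macro_f1
            )
        )

    @property
    def mean_oof_change(self) -> float:
        return float(
            np.mean(self.augmented_fgen_oof) - np.mean(self.baseline_fgen_oof)
        )

    def as_dict(self) -> dict:
        return {
            "seeds": self.seeds,
            "baseline_fgen_macro_f1": self.baseline_fgen_macro_f1,
            "augmented_fgen_macro_f1": self.augmented_fgen_macro_f1,
            "baseline_fgen_oof": self.baseline_fgen_oof,
            "augmented_fgen_oof": self.augmented_fgen_oof,
            "n_improved": self.n_improved,
            "mean_oof_change": self.mean_oof_change,
        }


def run_replicated_study(
    config: RunConfig, n_seeds: int = 10, base_seed: int | None = None
) -> ReplicationResult:
    """Run baseline-vs-augmented across seeds and collect the headline
    quantities: macro-F1 and OOF error rate on the generation codeset."""
    base_seed = config.seed if base_seed is None else base_seed
    result = ReplicationResult([], [], [], [], [])
    for i in range(n_seeds):
        run_seed = (base_seed + i) % (2 ** 31)
        summary = run_study(replace(config, seed=run_seed, arms="both", out_dir=None))
        result.seeds.append(run_seed)
        result.baseline_fgen_macro_f1.append(
            summary.arms["baseline"].metric("fgen", "leaf-only").macro_f1
        )
        result.augmented_fgen_macro_f1.append(
            summary.arms["augmented"].metric("fgen", "leaf-only").macro_f1
        )
        result.baseline_fgen_oof.append(
            summary.arms["baseline"].whcm_report("fgen").oof_rate
        )
        result.augmented_fgen_oof.append(
            summary.arms["augmented"].whcm_report("fgen").oof_rate
        )
    return result
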