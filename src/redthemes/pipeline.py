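"""End-to-end orchestration: corpus -> cohort -> encoding -> models -> metrics.

The workflow mirrors the study design it implements: label posts by their
subreddit's theme, build the temporal control set, split 80/20 once, build
the vocabulary from the training split only, encode, train each requested
classifier on the identical split, and report accuracy, per-class
precision/recall/F, and MRR. Every artifact written to a run directory
carries the seeds and a config hash for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import cohort, evaluation, models, preprocess, topics
from .cohort import LabeledCorpus
from .corpus_io import (
    CONTROL_LABEL,
    ThemeMap,
    load_theme_map,
    read_posts_jsonl,
    write_labels_tsv,
    write_posts_jsonl,
)
from .synthetic import GeneratorConfig, generate_corpus

logger = logging.getLogger(__name__)

MENTAL_LABEL = "mental"
BINARY_CLASS_ORDER = (CONTROL_LABEL, MENTAL_LABEL)


@dataclass
class RunConfig:
    """Everything one pipeline run depends on."""

    out_dir: str | Path
    corpus_path: str | Path | None = None
    labels_path: str | Path | None = None
    theme_map_path: str | Path | None = None
    generator: GeneratorConfig | None = None
    tasks: tuple[str, ...] = ("binary", "multiclass")
    classifiers: tuple[str, ...] = ("ff", "cnn", "linear", "svm")
    train_fraction: float = 0.8
    window_days: int = 180
    vocab_size: int = preprocess.DEFAULT_VOCAB_SIZE
    max_len: int = preprocess.DEFAULT_MAX_LEN
    run_topics: bool = False
    n_topics: int = 10
    ablate: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.corpus_path is None and self.generator is None:
            raise ValueError("either corpus_path or a generator config is required")
        for kind in self.classifiers:
            if kind not in ("ff", "cnn", "linear", "svm"):
                raise ValueError(f"unknown classifier {kind!r}")


@dataclass
class ClassifierResult:
    kind: str
    report: evaluation.MetricsReport
    cm: evaluation.ConfusionMatrix
    log: models.TrainingLog | None = None


@dataclass
class TaskResult:
    task: str
    class_order: tuple[str, ...]
    n_train: int
    n_test: int
    vocab_size: int
    results: dict[str, ClassifierResult] = field(default_factory=dict)


def _spec_for(kind: str, n_classes: int, seed: int) -> models.ClassifierSpec:
    return models.ClassifierSpec(kind=kind, n_classes=n_classes, seed=seed)


def run_task(
    corpus: LabeledCorpus,
    class_order: Sequence[str],
    classifiers: Sequence[str] = ("ff", "cnn", "linear", "svm"),
    seed: int = 0,
    train_fraction: float = 0.8,
    vocab_size: int = preprocess.DEFAULT_VOCAB_SIZE,
    max_len: int = preprocess.DEFAULT_MAX_LEN,
    task_name: str = "task",
) -> TaskResult:
    """Split once, encode once, then train and evaluate each classifier.

    All classifiers share the identical split and encoding; the vocabulary
    is built from the training split only.
    """
    class_order = tuple(class_order)
    train_c, test_c = evaluation.split_dataset(corpus, train_fraction, seed)
    vocab = preprocess.build_vocabulary(
        (preprocess.tokenize_post(p) for p in train_c.posts), size=vocab_size
    )
    Xtr = preprocess.encode_corpus(train_c.posts, vocab, max_len)
    Xte = preprocess.encode_corpus(test_c.posts, vocab, max_len)
    truth_idx = np.array([class_order.index(l) for l in test_c.labels])
    out = TaskResult(
        task=task_name,
        class_order=class_order,
        n_train=len(train_c),
        n_test=len(test_c),
        vocab_size=vocab.size,
    )
    for kind in classifiers:
        spec = _spec_for(kind, len(class_order), seed)
        model = models.train(spec, Xtr, train_c.labels, class_order, vocab.n_symbols)
        probs = models.predict_proba(model, Xte)
        predicted = [class_order[i] for i in probs.argmax(axis=1)]
        cm = evaluation.confusion(test_c.labels, predicted, class_order)
        if len(class_order) == 2:
            report = evaluation.binary_metrics(cm, positive_class=class_order[1])
        else:
            report = evaluation.multiclass_metrics(cm)
        report.mrr = evaluation.mean_reciprocal_rank(probs, truth_idx)
        out.results[kind] = ClassifierResult(kind, report, cm, getattr(model, "log", None))
        logger.info(
            "%s/%s: accuracy %.4f, MRR %.4f", task_name, kind, report.accuracy, report.mrr
        )
    return out


def build_datasets(
    corpus_posts: list,
    theme_map: ThemeMap,
    window_days: int = 180,
) -> tuple[LabeledCorpus, LabeledCorpus, LabeledCorpus]:
    """Label posts, build the control set, and derive the two task datasets.

    Returns (labeled, binary_corpus, multiclass_corpus): the binary corpus
    holds every theme post (labeled ``mental``) and every surviving control
    post (labeled ``control``); the multiclass corpus holds the theme posts
    with their theme labels.
    """
    labeled = cohort.label_corpus(corpus_posts, theme_map)
    control = cohort.build_control(corpus_posts, labeled, window_days=window_days)
    mental_posts = [p for p, l in zip(labeled.posts, labeled.labels) if l is not None]
    mental_labels = [l for l in labeled.labels if l is not None]
    binary = LabeledCorpus(
        mental_posts + control,
        [MENTAL_LABEL] * len(mental_posts) + [CONTROL_LABEL] * len(control),
    )
    multiclass = LabeledCorpus(mental_posts, mental_labels)
    return cohort.attach_control_labels(labeled, control), binary, multiclass


def _report_rows(task: TaskResult) -> dict:
    rows = {}
    for kind, res in task.results.items():
        r = res.report
        rows[kind] = {
            "accuracy": r.accuracy,
            "precision": r.weighted_precision if len(task.class_order) > 2
            else r.per_class[task.class_order[1]].precision,
            "recall": r.weighted_recall if len(task.class_order) > 2
            else r.per_class[task.class_order[1]].recall,
            "f_measure": r.weighted_f_measure if len(task.class_order) > 2
            else r.per_class[task.class_order[1]].f_measure,
            "mrr": r.mrr,
        }
    return rows


def _write_confusion(cm: evaluation.ConfusionMatrix, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#actual\\predicted\t" + "\t".join(cm.classes) + "\n")
        for name, row in zip(cm.classes, cm.counts):
            fh.write(name + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow and write artifacts to ``config.out_dir``.

    Returns a manifest-like dict with every task's summary metrics.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    theme_map = load_theme_map(config.theme_map_path)

    if config.generator is not None:
        corpus = generate_corpus(config.generator)
        posts = corpus.posts
        write_posts_jsonl(posts, out / "corpus.jsonl")
        write_labels_tsv(
            {p.post_id: l for p, l in zip(corpus.posts, corpus.labels)},
            out / "ground_truth_labels.tsv",
        )
    else:
        posts = read_posts_jsonl(config.corpus_path)

    labeled, binary, multiclass = build_datasets(posts, theme_map, config.window_days)
    write_labels_tsv(
        {p.post_id: l for p, l in zip(labeled.posts, labeled.labels) if l is not None},
        out / "derived_labels.tsv",
    )

    summary: dict = {
        "seed": config.seed,
        "theme_order": list(theme_map.themes),
        "counts": {
            "posts": len(posts),
            "mental": len(multiclass),
            "control": sum(1 for l in binary.labels if l == CONTROL_LABEL),
        },
        "tasks": {},
    }

    if config.run_topics:
        topic_dir = out / "topics"
        topic_dir.mkdir(exist_ok=True)
        for theme in theme_map.themes:
            theme_posts = [
                p for p, l in zip(multiclass.posts, multiclass.labels) if l == theme
            ]
            if len(theme_posts) < config.n_topics:
                logger.warning("theme %s has too few posts for topics; skipped", theme)
                continue
            result = topics.fit_theme_topics(
                theme_posts, n_topics=config.n_topics, seed=config.seed, theme=theme
            )
            topics.save_topics_tsv(result, topic_dir / f"{theme}.tsv")

    present = set(multiclass.label_counts())
    mc_order = tuple(t for t in theme_map.themes if t in present)
    task_data = {"binary": (binary, BINARY_CLASS_ORDER), "multiclass": (multiclass, mc_order)}
    for task in config.tasks:
        corpus_t, order = task_data[task]
        if config.ablate and task == "multiclass":
            corpus_t = evaluation.ablate_class(corpus_t, config.ablate)
            order = tuple(t for t in order if t != config.ablate)
        result = run_task(
            corpus_t,
            order,
            classifiers=config.classifiers,
            seed=config.seed,
            train_fraction=config.train_fraction,
            vocab_size=config.vocab_size,
            max_len=config.max_len,
            task_name=task,
        )
        summary["tasks"][task] = {
            "class_order": list(result.class_order),
            "n_train": result.n_train,
            "n_test": result.n_test,
            "vocab_size": result.vocab_size,
            "metrics": _report_rows(result),
        }
        for kind, res in result.results.items():
            _write_confusion(res.cm, out / f"confusion_{task}_{kind}.tsv")

    # the hash covers everything that determines the results (not the
    # output location), so identical reruns are recognisable by hash
    payload = {
        "config": {
            k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v)
            for k, v in vars(config).items()
            if k not in ("generator", "out_dir")
        },
        "generator": _generator_payload(config.generator),
    }
    summary["config_hash"] = _config_hash(payload)
    manifest = {**payload, **summary}
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return summary


def _generator_payload(gen: GeneratorConfig | None) -> dict | None:
    if gen is None:
        return None
    d = asdict(gen)
    d["overlap"] = np.asarray(gen.overlap).tolist()
    return d


def run_ablation_experiment(
    multiclass: LabeledCorpus,
    class_order: Sequence[str],
    class_name: str,
    classifiers: Sequence[str] = ("cnn",),
    seed: int = 0,
    **task_kwargs,
) -> tuple[TaskResult, TaskResult]:
    """Run the multiclass task with and without one class, same settings.

    Mirrors the dominant-class removal experiment: compare held-out accuracy
    before and after dropping the most prevalent, comorbid class.
    """
    before = run_task(
        multiclass, class_order, classifiers=classifiers, seed=seed,
        task_name="multiclass", **task_kwargs,
    )
    ablated = evaluation.ablate_class(multiclass, class_name)
    reduced_order = tuple(c for c in class_order if c != class_name)
    after = run_task(
        ablated, reduced_order, classifiers=classifiers, seed=seed,
        task_name=f"multiclass_without_{class_name}", **task_kwargs,
    )
    return before, after
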