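"""End-to-end orchestration: generate/load -> include -> split -> featurize
-> train six classifiers -> evaluate against both reference standards.

Every stage draws its own seed from the single run seed via a stable
stage-name hash, so stages are independently reproducible.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from cxrnlp import __version__
from cxrnlp.corpus import SplitSpec, apply_inclusion, stratified_split, write_corpus
from cxrnlp.embedding import (
    EmbeddingConfig,
    classify_by_embedding,
    default_reference_phrases,
    train_skipgram,
)
from cxrnlp.lexicon import Lexicon, default_lexicon, extract_features, features_to_matrix, normalize_text, tokenize
from cxrnlp.metrics import confusion, metrics
from cxrnlp.models import ModelSpec, default_specs, fit, predict
from cxrnlp.synth import GeneratorConfig, generate_corpus

__all__ = ["RunConfig", "run_pipeline", "stage_seed", "METRIC_COLUMNS"]

METRIC_COLUMNS = [
    "model",
    "reference_standard",
    "seed",
    "sensitivity",
    "sensitivity_lo",
    "sensitivity_hi",
    "specificity",
    "specificity_lo",
    "specificity_hi",
    "ppv",
    "ppv_lo",
    "ppv_hi",
    "npv",
    "npv_lo",
    "npv_hi",
    "lr_pos",
    "lr_pos_lo",
    "lr_pos_hi",
    "lr_neg",
    "lr_neg_lo",
    "lr_neg_hi",
    "accuracy",
    "f1",
]


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed derived from the run seed and the stage name."""
    digest = hashlib.sha256(f"{stage}:{global_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    model_specs: Optional[Sequence[ModelSpec]] = None  # None -> all five families
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    use_embedding: bool = True
    reference_standards: tuple[str, ...] = ("expert", "code")
    train_on: str = "code"  # label source for supervised training

    def __post_init__(self) -> None:
        if not self.reference_standards:
            raise ValueError("at least one reference standard is required")
        unknown = set(self.reference_standards) - {"expert", "code"}
        if unknown:
            raise ValueError(f"unknown reference standards: {sorted(unknown)}")
        if self.train_on not in ("expert", "code"):
            raise ValueError("train_on must be 'expert' or 'code'")
        specs = self.model_specs
        if specs is not None and len(specs) == 0 and not self.use_embedding:
            raise ValueError("no classifier enabled: supply model specs or enable the embedding classifier")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, lexicon: Optional[Lexicon] = None) -> dict:
    """Run the whole workflow on a synthetic corpus; returns the manifest.

    Writes corpus, split corpora, labels, the metric table
    (``metrics.csv``) and a manifest with content hashes into
    ``config.out_dir``; nothing is written elsewhere.
    """
    lexicon = lexicon or default_lexicon()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    gen_cfg = GeneratorConfig(
        **{**config.generator.__dict__, "seed": stage_seed(config.seed, "generate")}
    )
    records = generate_corpus(gen_cfg, lexicon)
    reports = [r.report for r in records]
    truth = {r.report.encounter_id: r.truth_label for r in records}
    code = {r.report.encounter_id: r.code_label for r in records}
    write_corpus(reports, out / "corpus.jsonl")

    included, exclusion_log = apply_inclusion(reports)
    split_spec = SplitSpec(
        validation_fraction=config.split.validation_fraction,
        admitted_share=config.split.admitted_share,
        seed=stage_seed(config.seed, "split"),
    )
    derivation, validation = stratified_split(included, split_spec)
    write_corpus(derivation, out / "derivation.jsonl")
    write_corpus(validation, out / "validation.jsonl")

    feats_train = [extract_features(r, lexicon) for r in derivation]
    feats_eval = [extract_features(r, lexicon) for r in validation]
    X_train, feature_names, _ = features_to_matrix(feats_train)
    X_eval, _, _ = features_to_matrix(feats_eval)
    label_source = truth if config.train_on == "expert" else code
    y_train = np.array([label_source[r.encounter_id] for r in derivation])
    reference = {}
    if "expert" in config.reference_standards:
        reference["expert"] = np.array([truth[r.encounter_id] for r in validation])
    if "code" in config.reference_standards:
        reference["code"] = np.array([code[r.encounter_id] for r in validation])

    model_seed = stage_seed(config.seed, "train")
    specs = list(config.model_specs) if config.model_specs is not None else default_specs(seed=model_seed)
    rows = []
    for spec in specs:
        model = fit(X_train, y_train, spec, feature_names)
        pred, _ = predict(model, X_eval)
        for standard, ref_labels in reference.items():
            ms = metrics(confusion(pred, ref_labels))
            row = {"model": spec.family, "reference_standard": standard, "seed": spec.seed}
            row.update(ms.as_row())
            rows.append(row)

    if config.use_embedding:
        emb_cfg = EmbeddingConfig(**{**config.embedding.__dict__, "seed": stage_seed(config.seed, "embedding")})
        sentences = [tokenize(normalize_text(r.text), r.report_id) for r in derivation]
        model = train_skipgram(sentences, emb_cfg)
        refs = default_reference_phrases(lexicon)
        pred = np.array(
            [classify_by_embedding(tokenize(normalize_text(r.text), r.report_id), model, refs)[0] for r in validation]
        )
        for standard, ref_labels in reference.items():
            ms = metrics(confusion(pred, ref_labels))
            row = {"model": "word_embedding", "reference_standard": standard, "seed": emb_cfg.seed}
            row.update(ms.as_row())
            rows.append(row)

    metrics_path = out / "metrics.csv"
    with open(metrics_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=METRIC_COLUMNS)
        writer.writeheader()
        for row in rows:
            writer.writerow({k: ("" if row.get(k) is None else row.get(k)) for k in METRIC_COLUMNS})

    outputs = ["corpus.jsonl", "derivation.jsonl", "validation.jsonl", "metrics.csv"]
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in ("generate", "split", "train", "embedding")},
        "n_records": len(records),
        "n_included": len(included),
        "exclusions": dict(exclusion_log),
        "n_derivation": len(derivation),
        "n_validation": len(validation),
        "outputs": {name: _sha256(out / name) for name in outputs},
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
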