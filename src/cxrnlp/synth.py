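"""Synthetic chest-radiograph report corpora for pipeline testing.

Generates free-text reports with the conventional section structure
(exam type, clinical prompt, findings, impression), seeding each record
with lexicon phrases consistent with its ground-truth label, plus
optional hedging, negation, and phrase-free distractor sentences.
Diagnosis-code labels are produced by degrading the truth at a
configurable sensitivity/specificity operating point.

Template wording deliberately avoids every lexicon phrase and negation
cue outside the designated slot, so with distractors enabled and hedging
off the rule-based labeler recovers the generating label exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from datetime import datetime, timedelta
from typing import Optional

import numpy as np

from cxrnlp.corpus import Report
from cxrnlp.lexicon import DEFAULT_NEGATION_CUES, Lexicon, default_lexicon

__all__ = ["GeneratorConfig", "SyntheticRecord", "generate_corpus", "generate_report_text", "write_manifest"]


@dataclass(frozen=True)
class GeneratorConfig:
    n: int = 1000
    prevalence: float = 0.156
    hedge_rate: float = 0.05
    negation_rate: float = 0.5
    distractor_rate: float = 0.3
    code_sensitivity: float = 0.933
    code_specificity: float = 0.692
    admitted_rate: float = 0.35
    seed: int = 0
    section_style: str = "full"  # or "impression_only"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name in (
            "prevalence",
            "hedge_rate",
            "negation_rate",
            "distractor_rate",
            "code_sensitivity",
            "code_specificity",
            "admitted_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a proportion in [0, 1], got {v}")
        if self.section_style not in ("full", "impression_only"):
            raise ValueError("section_style must be 'full' or 'impression_only'")


@dataclass(frozen=True)
class SyntheticRecord:
    report: Report
    truth_label: int
    code_label: int
    provenance: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.provenance:
            raise ValueError("provenance must be non-empty")


_EXAM_LINES = (
    "chest radiograph two views frontal and lateral",
    "portable chest radiograph single frontal view",
    "chest radiograph pa and lateral views",
    "single view chest radiograph",
    "two view chest series",
)

_PROMPT_LINES = (
    "cough and fever for three days",
    "fever and tachypnea",
    "respiratory distress",
    "wheezing and cough",
    "shortness of breath",
    "fever of unknown source",
    "chest pain and cough",
    "evaluate for foreign body aspiration",
)

# Frames that wrap a pneumonia-indicating phrase. They must not introduce
# any lexicon phrase or negation cue of their own.
_POSITIVE_TEMPLATES = (
    "there is {phrase} in the right lower lobe",
    "there is {phrase} in the left lower lobe",
    "{phrase} is present in the right middle lobe",
    "{phrase} is seen in the retrocardiac region",
    "findings are consistent with {phrase}",
    "persistent {phrase} compared with the prior study",
    "{phrase} is identified in the lingula",
    "new {phrase} involving the right upper lobe",
    "there is {phrase} obscuring the right heart border",
    "hazy {phrase} is noted bilaterally",
    "{phrase} with associated volume loss",
    "developing {phrase} is suspected",
    "interval worsening of {phrase}",
    "{phrase} is again demonstrated",
    "dense {phrase} at the left base",
)

# Frames that wrap an absence-indicating phrase verbatim.
_NEGATIVE_PLAIN_TEMPLATES = (
    "{phrase}",
    "{phrase} bilaterally",
    "impression {phrase}",
    "study shows {phrase}",
    "{phrase} on today s exam",
    "{phrase} as before",
    "stable exam with {phrase}",
    "{phrase} again noted",
)

# Frames where a negation cue immediately precedes an expandable
# pneumonia phrase, e.g. "no focal consolidation is seen".
_NEGATIVE_NEGATED_TEMPLATES = (
    "{cue} {phrase} is seen",
    "{cue} {phrase} is identified",
    "there is {cue} {phrase}",
    "{cue} {phrase} on the current study",
    "{cue} {phrase} to suggest an acute process",
    "{cue} {phrase} in either lung",
    "{cue} {phrase} is appreciated",
)

# Anatomy / lines-and-tubes / comparison filler. Free of lexicon phrases,
# negation cues, and of any token that could complete a lexicon phrase
# across a sentence boundary after punctuation is stripped.
_DISTRACTOR_SENTENCES = (
    "the cardiomediastinal silhouette is unremarkable",
    "the heart size is at the upper end of the expected range",
    "bony structures are intact",
    "the trachea is midline",
    "an enteric tube terminates in the stomach",
    "a peripherally inserted central catheter tip projects over the svc",
    "comparison is made with the prior examination",
    "the visualized upper abdomen is unremarkable",
    "soft tissues are unremarkable",
    "the costophrenic angles are sharp",
    "mild rotation is noted on this study",
    "the diaphragms are well defined",
    "pulmonary vascularity is within expected range for age",
    "an endotracheal tube is in satisfactory position",
    "surgical clips project over the mediastinum",
    "the thymus has a typical appearance for age",
    "degree of inspiration is adequate",
    "there has been interval removal of the nasogastric tube",
    "osseous mineralization appears appropriate for age",
    "incidental note is made of a healed rib fracture",
)

_HEDGED_PHRASE = "pneumonia cannot be excluded"


def _phrases(lexicon: Lexicon, polarity: str, expandable_only: bool = False) -> list[str]:
    return [e.phrase for e in lexicon.entries if e.polarity == polarity and (e.expandable or not expandable_only)]


def generate_report_text(
    truth: int,
    config: GeneratorConfig,
    rng: np.random.Generator,
    lexicon: Optional[Lexicon] = None,
) -> tuple[str, tuple[str, ...]]:
    """One report text plus the ids of the templates used."""
    lexicon = lexicon or default_lexicon()
    provenance: list[str] = []

    def pick(pool, tag):
        i = int(rng.integers(len(pool)))
        provenance.append(f"{tag}:{i}")
        return pool[i]

    pos_phrases = _phrases(lexicon, "indicates_pneumonia")
    neg_phrases = _phrases(lexicon, "indicates_no_pneumonia")
    expandable = _phrases(lexicon, "indicates_pneumonia", expandable_only=True)

    if truth:
        if rng.random() < config.hedge_rate:
            key_sentence = _HEDGED_PHRASE
            provenance.append("hedge:0")
        else:
            template = pick(_POSITIVE_TEMPLATES, "pos")
            key_sentence = template.format(phrase=pick(pos_phrases, "pos_phrase"))
    else:
        if rng.random() < config.negation_rate:
            template = pick(_NEGATIVE_NEGATED_TEMPLATES, "negx")
            cue = pick(DEFAULT_NEGATION_CUES, "cue")
            key_sentence = template.format(cue=cue, phrase=pick(expandable, "negx_phrase"))
        else:
            template = pick(_NEGATIVE_PLAIN_TEMPLATES, "neg")
            key_sentence = template.format(phrase=pick(neg_phrases, "neg_phrase"))

    distractors = [s for s in _DISTRACTOR_SENTENCES if rng.random() < config.distractor_rate]
    for s in distractors:
        provenance.append(f"distractor:{_DISTRACTOR_SENTENCES.index(s)}")

    if config.section_style == "impression_only":
        text = f"IMPRESSION: {key_sentence.capitalize()}."
    else:
        findings = distractors + [key_sentence]
        text = (
            f"EXAM: {pick(_EXAM_LINES, 'exam').capitalize()}.\n"
            f"INDICATION: {pick(_PROMPT_LINES, 'prompt').capitalize()}.\n"
            f"FINDINGS: {'. '.join(s.capitalize() for s in findings)}.\n"
            f"IMPRESSION: {key_sentence.capitalize()}."
        )
    return text, tuple(provenance)


def generate_corpus(config: GeneratorConfig, lexicon: Optional[Lexicon] = None) -> list[SyntheticRecord]:
    """Deterministic synthetic corpus of ``config.n`` labelled reports."""
    lexicon = lexicon or default_lexicon()
    rng = np.random.default_rng(config.seed)
    base = datetime(2010, 1, 1)
    records: list[SyntheticRecord] = []
    for i in range(config.n):
        truth = int(rng.random() < config.prevalence)
        text, provenance = generate_report_text(truth, config, rng, lexicon)
        if truth:
            code = int(rng.random() < config.code_sensitivity)
        else:
            code = int(rng.random() >= config.code_specificity)
        age = int(np.clip(round(float(np.exp(rng.uniform(np.log(3), np.log(216))))), 3, 216))
        acquired = base + timedelta(minutes=int(rng.integers(0, 3 * 365 * 24 * 60)))
        report = Report(
            report_id=f"r{i:06d}",
            encounter_id=f"e{i:06d}",
            acquired_at=acquired.isoformat(),
            age_months=age,
            disposition="admitted" if rng.random() < config.admitted_rate else "discharged",
            text=text,
            site=f"site_{int(rng.integers(6))}",
        )
        records.append(SyntheticRecord(report=report, truth_label=truth, code_label=code, provenance=provenance))
    labels = {r.truth_label for r in records}
    if len(labels) == 1:
        import warnings

        warnings.warn(f"synthetic corpus contains a single class ({labels.pop()})", stacklevel=2)
    return records


def write_manifest(config: GeneratorConfig, path) -> None:
    """JSON manifest recording the generator settings and template-bank hash."""
    import hashlib

    bank = "\n".join(
        _EXAM_LINES + _PROMPT_LINES + _POSITIVE_TEMPLATES + _NEGATIVE_PLAIN_TEMPLATES
        + _NEGATIVE_NEGATED_TEMPLATES + _DISTRACTOR_SENTENCES + (_HEDGED_PHRASE,)
    )
    manifest = {
        "config": asdict(config),
        "template_bank_sha256": hashlib.sha256(bank.encode()).hexdigest(),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
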