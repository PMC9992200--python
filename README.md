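# cxrnlp

Classification of pediatric chest-radiograph (CXR) free-text reports as
positive or negative for pneumonia, with the surrounding machinery needed to
study such classifiers end to end: cohort construction, annotation
adjudication, keyword featurization with negation handling, six
classification methods, diagnostic-accuracy statistics, and a synthetic
report generator so everything runs without access to protected clinical
data.

## What's inside

| Module | Purpose |
| --- | --- |
| `cxrnlp.corpus` | Report/label data model, JSONL/CSV I/O, inclusion filtering (age window, first-CXR-per-encounter dedup), seeded disposition-stratified splitting, dual-reviewer adjudication |
| `cxrnlp.lexicon` | Text normalization, tokenization, the keyword lexicon (shipped as `data/lexicon.csv`), negation expansion ("no infiltrate"), longest-match phrase counting, rule-based reference labeling |
| `cxrnlp.embedding` | Self-contained skip-gram trainer (negative sampling, numpy, bit-reproducible under a seed), phrase embedding by token averaging, sliding-window max-cosine classification |
| `cxrnlp.models` | Uniform fit/predict over five supervised families: depth-3 gradient-boosted trees (lr 0.3), 31-leaf histogram boosting (lr 0.05), linear-kernel SVM, Gaussian naive Bayes, L2 logistic regression |
| `cxrnlp.metrics` | Confusion matrices; sensitivity/specificity/PPV/NPV/accuracy/F1; likelihood ratios; Clopper–Pearson and log-method CIs; unweighted Cohen's kappa; integer confusion-matrix reconstruction from rounded published marginals |
| `cxrnlp.synth` | Template-based synthetic report corpora with configurable prevalence, hedging, negation, distractors, and diagnosis-code label noise |
| `cxrnlp.pipeline` / `cxrnlp.cli` | End-to-end orchestration and the `cxrnlp` command-line tool |

The two gradient-boosting families are backed by scikit-learn
(`GradientBoostingClassifier`, `HistGradientBoostingClassifier`) behind the
same hyperparameter contract, and the skip-gram trainer is implemented here
directly, so the package has no dependencies beyond the scientific-Python
stack.

## Command line

```bash
# synthetic corpus + labels
cxrnlp generate --n 5000 --seed 7 --out out/corpus

# inclusion rules + stratified derivation/validation split
cxrnlp split --corpus out/corpus/corpus.jsonl --fraction 0.01 --out out/split

# keyword feature matrix
cxrnlp featurize --corpus out/split/validation.jsonl --out out/features.csv

# diagnostic-accuracy panel from a 2x2 matrix (tp,fp,fn,tn)
cxrnlp evaluate --cm 113,14,72,1151

# inter-rater agreement between two reviewer label files
cxrnlp kappa --r1 r1.csv --r2 r2.csv

# full pipeline: generate -> split -> featurize -> train all six methods -> evaluate
cxrnlp run --n 5000 --seed 7 --out out/run
```

`cxrnlp run` writes `metrics.csv` (one row per model x reference standard,
with 95% CIs) and a `manifest.json` with content hashes of every output;
reruns with the same seed are byte-identical.

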