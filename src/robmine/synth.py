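"""Synthetic methods-section corpora with known gold labels.

The generator assembles short methods-like documents from neutral filler
sentences and plants reporting statements for randomization, blinded outcome
assessment and sample size calculation at a configured prevalence.  Planted
positives come from a phrase bank at one of three hardness levels:

* 0 — verbatim phrases from the default detector lexicon (every phrase is
  matched by the shipped patterns, so a correct detector scores perfectly);
* 1 — paraphrases sharing keywords with the lexicon (most, not all, match:
  realistic methods prose);
* 2 — paraphrases that avoid the lexicon keywords entirely (coin toss,
  drawing lots, concealed codes), the hard ceiling for any keyword detector.

Gold-negative documents contain no positive phrase, but with probability
``confounder_rate`` carry a confusable phrase (random hexamer primers,
high-power fields, blind-ended catheters, citations of clinical trials) that
stresses specificity the way real manuscripts do.

Counts of positives are exact by assignment — ``round(n_docs * prevalence)``
per item, not Bernoulli draws — so prevalence targets are testable at small
n.  A single integer seed drives one pseudo-random stream and generation
order is fixed, so identical configs produce byte-identical corpora.
"""

from __future__ import annotations

import csv
import dataclasses
import datetime
from pathlib import Path
from typing import Mapping

import numpy as np

from .corpus import ITEMS, Corpus, Document, GoldAnnotation
from .detect import classify_corpus
from .evaluate import PerformanceMetrics, confusion, metrics
from .patterns import PatternSet, default_pattern_sets

# Phrases matched verbatim by the shipped lexicon.
_HARDNESS0 = {
    "randomization": (
        "animals were randomly allocated to treatment groups",
        "mice were randomly assigned to experimental groups",
        "allocation used a random number table",
        "a randomization schedule was prepared in advance",
        "random allocation was used to form the groups",
    ),
    "blinding": (
        "outcome was assessed in a blinded fashion",
        "a blinded observer performed all assessments",
        "scoring was done in a blinded manner",
        "the assessor was masked to the treatment group",
        "an observer-blind protocol was followed",
    ),
    "samplesize": (
        "a sample size calculation was performed",
        "we performed a power analysis to determine group sizes",
        "an a priori power calculation determined the number of animals",
        "sample size was calculated before the experiment",
        "sample size estimation was performed in advance",
    ),
}

# Paraphrases sharing keywords with the lexicon; one phrase per item is a
# deliberate near-miss, as in real prose.
_HARDNESS1 = {
    "randomization": (
        "rats were randomly assigned to one of the experimental groups",
        "the animals were randomly divided into four groups",
        "mice were randomized into treatment and control groups",
        "group allocation was performed using a random number table",
        "a computer generated randomisation sequence determined group assignment",
        "animals were allocated to groups by simple randomization",
        "random allocation to surgery or sham was employed",
        "subjects were randomly distributed among the study arms",
        "the randomization schedule was generated before any surgery",
        "treatment order was randomised using a random number generator",
    ),
    "blinding": (
        "outcome assessment was performed in a blinded fashion",
        "an investigator blinded to treatment allocation scored the neurological deficits",
        "infarct volumes were measured by a blinded observer",
        "all analyses were conducted in a blinded manner",
        "the examiner was unaware of the treatment assignment",
        "histological evaluation was carried out by an assessor masked to the group allocation",
        "behavioural testing was scored by observers blinded to group",
        "in a blinded design outcomes were evaluated at 24 h",
        "the surgeon was masked to the treatment condition",
        "data were analysed by a blinded examiner",
    ),
    "samplesize": (
        "a sample size calculation was performed prior to the study",
        "sample size was calculated to detect a 30% reduction in infarct volume",
        "a power analysis indicated that ten animals per group were required",
        "group sizes were determined by an a priori power calculation",
        "we performed a power calculation assuming a standard deviation of 20%",
        "the study was designed to detect a difference of 25% with 80% power",
        "sample size estimation was based on previous experiments",
        "the required number of animals per group was estimated beforehand",
        "sample size was determined using dedicated software",
        "assuming a statistical power of 0.9 and alpha of 0.05 eight animals per group were needed",
    ),
}

# Paraphrases avoiding the lexicon keywords entirely.
_HARDNESS2 = {
    "randomization": (
        "animals were assigned to groups by coin toss",
        "group membership was decided by drawing lots",
        "an independent technician allocated the animals using a lottery procedure",
        "sealed opaque envelopes determined the order of surgery",
        "cage numbers were drawn from a hat to form the groups",
    ),
    "blinding": (
        "the assessor had no knowledge of which intervention each animal received",
        "outcome scoring was performed by an investigator kept ignorant of group identity",
        "group codes were concealed from the person measuring infarct size",
        "treatment identity was withheld from the outcome assessors",
        "scoring sheets carried coded labels so the rater could not identify the groups",
    ),
    "samplesize": (
        "the number of animals per group was justified by a formal calculation of the required group size",
        "group sizes were chosen using an estimate of the variance from pilot data",
        "we computed the cohort size needed to demonstrate the expected reduction in lesion volume",
        "the required group size was derived from previously observed effect magnitudes",
        "animal numbers were fixed in advance using a prospective group size justification",
    ),
}

POSITIVE_PHRASES: dict[int, dict[str, tuple[str, ...]]] = {
    0: _HARDNESS0,
    1: _HARDNESS1,
    2: _HARDNESS2,
}

# Confusable phrases planted in gold-negative documents.  Most are either
# covered by the default exclusion patterns or keyword-free; one per item at
# most mimics the "overcalling" seen with keyword detectors (e.g. citing a
# clinical trial's blinded design).
CONFOUNDER_PHRASES: dict[str, tuple[str, ...]] = {
    "randomization": (
        "cdna was synthesized using random hexamer primers",
        "random primer labelling was used for the probes",
        "three randomly selected fields were counted per section",
        "a random-effects model was used for the meta-analysis",
        "samples were randomly distributed across the assay plates",
    ),
    "blinding": (
        "the catheter had a blind-ended tip",
        "cortical blindness was reported in two animals",
        "results of a double-blind clinical trial were cited as background",
        "participants in the cited double-blind placebo controlled study improved",
        "the referenced clinical study used blinded assessment of outcome",
    ),
    "samplesize": (
        "cells were counted in five high-power fields",
        "the power supply was checked before each recording",
        "the microscope was set to high magnification for counting",
        "spss software was used for the statistical analysis",
        "the cited guideline discusses sample sizes in general terms",
    ),
}

# Neutral methods-section filler; contains none of the lexicon keywords.
FILLER_SENTENCES = (
    "adult male sprague-dawley rats weighing 280-320 g were used in this study",
    "focal cerebral ischaemia was induced by occlusion of the middle cerebral artery with an intraluminal filament",
    "animals were housed under a 12 h light-dark cycle with free access to food and water",
    "body temperature was maintained at 37 degrees with a heating pad during surgery",
    "infarct volume was quantified on ttc-stained sections using image analysis software",
    "neurological deficits were scored 24 h after reperfusion",
    "all procedures were approved by the institutional animal care committee",
    "cerebral blood flow was monitored by laser doppler flowmetry",
    "data are presented as mean and standard deviation",
    "statistical comparisons used analysis of variance followed by post hoc tests",
    "reperfusion was established by filament withdrawal after 90 minutes of occlusion",
    "brains were removed and sectioned coronally at 2 mm intervals",
)


class SynthError(ValueError):
    """Invalid generator configuration."""


@dataclasses.dataclass(frozen=True)
class SynthConfig:
    n_docs: int = 200
    prevalence: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {item: 0.5 for item in ITEMS}
    )
    hardness: int = 1
    confounder_rate: float = 0.3
    n_journals: int = 10
    date_range: tuple[datetime.date, datetime.date] = (
        datetime.date(2014, 10, 5),
        datetime.date(2016, 10, 4),
    )
    seed: int = 20161004

    def __post_init__(self) -> None:
        if self.n_docs < 1:
            raise SynthError("n_docs must be >= 1")
        if self.hardness not in (0, 1, 2):
            raise SynthError("hardness must be 0, 1 or 2")
        for item in ITEMS:
            p = self.prevalence.get(item)
            if p is None or not 0.0 <= p <= 1.0:
                raise SynthError(f"prevalence[{item!r}] must be in [0, 1], got {p!r}")
        if not 0.0 <= self.confounder_rate <= 1.0:
            raise SynthError("confounder_rate must be in [0, 1]")
        if self.n_journals < 1:
            raise SynthError("n_journals must be >= 1")
        if self.date_range[0] > self.date_range[1]:
            raise SynthError("date_range start must not be after end")


# The shipped benchmark conditions: a 200-document corpus at 50% prevalence
# per item, realistic paraphrase hardness, and a 30% confounder rate.
BENCHMARK_CONFIG = SynthConfig()

PERFORMANCE_THRESHOLD = 0.80  # minimum acceptable sensitivity and specificity


def _journal_sizes(n_docs: int, n_journals: int) -> list[int]:
    """Skewed (Zipf-like, exponent 2) journal sizes by largest remainder."""
    weights = np.array([1.0 / (j + 1) ** 2 for j in range(n_journals)])
    quotas = n_docs * weights / weights.sum()
    sizes = np.floor(quotas).astype(int)
    rem = n_docs - int(sizes.sum())
    order = np.argsort(-(quotas - sizes), kind="stable")
    for j in order[:rem]:
        sizes[j] += 1
    return sizes.tolist()


def _journal_name(j: int) -> str:
    return f"Journal of Synthetic Stroke Research {chr(ord('A') + j % 26)}{j // 26 or ''}"


def generate(config: SynthConfig) -> tuple[Corpus, list[GoldAnnotation]]:
    """Generate a corpus with metadata and gold labels from one seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_docs
    width = max(4, len(str(n)))
    doc_ids = [f"syn{str(i + 1).zfill(width)}" for i in range(n)]

    # exact positive counts per item, assigned by permutation
    gold_flags = {item: np.zeros(n, dtype=bool) for item in ITEMS}
    for item in ITEMS:
        n_pos = int(np.floor(n * config.prevalence[item] + 0.5))
        perm = rng.permutation(n)
        gold_flags[item][perm[:n_pos]] = True

    sizes = _journal_sizes(n, config.n_journals)
    journal_idx = np.repeat(np.arange(config.n_journals), sizes)
    rng.shuffle(journal_idx)

    start, end = config.date_range
    span = (end - start).days
    day_offsets = rng.integers(0, span + 1, size=n)

    bank = POSITIVE_PHRASES[config.hardness]
    documents: list[Document] = []
    gold: list[GoldAnnotation] = []
    for i in range(n):
        n_filler = int(rng.integers(4, 7))
        filler_idx = rng.choice(len(FILLER_SENTENCES), size=n_filler, replace=False)
        sentences = [FILLER_SENTENCES[j] for j in filler_idx]
        planted: list[str] = []
        for item in ITEMS:
            if gold_flags[item][i]:
                phrases = bank[item]
                planted.append(phrases[int(rng.integers(0, len(phrases)))])
            elif rng.random() < config.confounder_rate:
                conf = CONFOUNDER_PHRASES[item]
                planted.append(conf[int(rng.integers(0, len(conf)))])
        for phrase in planted:
            pos = int(rng.integers(0, len(sentences) + 1))
            sentences.insert(pos, phrase)
        text = ". ".join(s[0].upper() + s[1:] for s in sentences) + ".\n"
        documents.append(Document(
            doc_id=doc_ids[i],
            text=text,
            journal=_journal_name(int(journal_idx[i])),
            record_date=start + datetime.timedelta(days=int(day_offsets[i])),
        ))
        gold.append(GoldAnnotation(
            doc_id=doc_ids[i],
            randomization=bool(gold_flags["randomization"][i]),
            blinding=bool(gold_flags["blinding"][i]),
            samplesize=bool(gold_flags["samplesize"][i]),
        ))
    return Corpus(documents=documents), gold


def write_synth_corpus(corpus: Corpus, gold: list[GoldAnnotation], out_dir: str | Path) -> None:
    """Write a generated corpus as text files + metadata.csv + gold.csv."""
    out_dir = Path(out_dir)
    text_dir = out_dir / "texts"
    text_dir.mkdir(parents=True, exist_ok=True)
    for doc in corpus:
        (text_dir / f"{doc.doc_id}.txt").write_text(doc.text, encoding="utf-8")
    with open(out_dir / "metadata.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["doc_id", "journal", "record_date"])
        for doc in corpus:
            writer.writerow([doc.doc_id, doc.journal, doc.record_date.isoformat()])
    with open(out_dir / "gold.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["doc_id", "randomization", "blinding", "samplesize"])
        for g in gold:
            writer.writerow([g.doc_id, str(g.randomization).lower(),
                             str(g.blinding).lower(), str(g.samplesize).lower()])


@dataclasses.dataclass(frozen=True)
class BenchmarkResult:
    config: SynthConfig
    per_item: dict[str, PerformanceMetrics]
    passed: dict[str, bool]  # min(sensitivity, specificity) >= threshold
    threshold: float = PERFORMANCE_THRESHOLD

    @property
    def all_passed(self) -> bool:
        return all(self.passed.values())


def benchmark(
    config: SynthConfig = BENCHMARK_CONFIG,
    pattern_sets: Mapping[str, PatternSet] | None = None,
    level: float = 0.95,
) -> BenchmarkResult:
    """Generate, classify, evaluate in one call; apply the 0.80 threshold.

    The threshold reflects the performance level at which an automated
    ascertainment tool is considered useful for review work: sensitivity and
    specificity both at least 0.80 for every item.
    """
    if pattern_sets is None:
        pattern_sets = default_pattern_sets()
    corpus, gold = generate(config)
    calls = classify_corpus(corpus, pattern_sets)
    per_item: dict[str, PerformanceMetrics] = {}
    passed: dict[str, bool] = {}
    for item in ITEMS:
        cm, n_excluded = confusion(calls, gold, item)
        m = metrics(cm, level=level, item=item, n_excluded=n_excluded)
        per_item[item] = m
        se = m.sensitivity.value if m.sensitivity.defined else 0.0
        sp = m.specificity.value if m.specificity.defined else 0.0
        passed[item] = min(se, sp) >= PERFORMANCE_THRESHOLD
    return BenchmarkResult(config=config, per_item=per_item, passed=passed)
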