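# Methods

`robmine` automates one step of systematic-review practice for *in vivo*
research: deciding, from the full text of a manuscript, whether the authors
report three measures that reduce risk of bias — randomization of animals to
experimental groups, blinded assessment of outcome, and a sample size
calculation. Manual ascertainment takes about an hour per paper for two
assessors; a rule-based classifier that reaches sensitivity and specificity
of at least 0.80 per item is generally considered useful as a screening or
audit instrument, and that threshold is wired into the benchmark.

## The detector

Each item has a pattern set: an ordered list of inclusion regular
expressions and an ordered list of exclusion regular expressions. Before
matching, text is normalized — lowercased, runs of whitespace collapsed to
single spaces, and hyphen–line-break sequences joined so that words split
across lines ("rando-\nmization") match. An offset map projects normalized
spans back to the raw text.

The call rule is: **positive iff at least one inclusion match survives**,
where an inclusion match is suppressed when its character span overlaps any
exclusion match. Span-overlap suppression was chosen over sentence- or
window-based negation because it is fully auditable and has a trivial
brute-force oracle (enumerate all matches, subtract overlapped ones), which
the test suite runs against the implementation on hundreds of generated
texts. Two monotonicity properties follow directly and are also tested:
adding an inclusion pattern can only flip calls false→true; adding an
exclusion pattern can only flip calls true→false.

Every positive call carries evidence: pattern id, span, and a snippet with
up to 60 characters of context on each side, so a reviewer can audit any
call without rerunning the tool.

The shipped lexicon (`robmine/data/default_patterns.yaml`) is a seed
vocabulary, deliberately small and fully replaceable via `--patterns`:
reporting language is domain specific, and a lexicon tuned on one literature
over- and under-calls on another (typically overcalling randomization and
blinding — citations, "random hexamer primers", "double-blind clinical
trial" — and undercalling sample size calculations, which are phrased very
heterogeneously). Patterns use only the portable regex core (classes,
alternation, bounded repetition; no backreferences or lookaround) so configs
work under any mainstream engine.

The whole document is scanned by default, references included, since no
robust sectioning procedure exists for converted PDFs. Supplementary
materials are out of scope: they are frequently not retrieved with the main
text, and reporting guidance expects these items in the main text anyway.

## Evaluation statistics

Calls are scored against a manual gold standard per item with the usual
screening-test quantities: sensitivity tp/(tp+fn), specificity tn/(tn+fp),
accuracy (tp+tn)/n. The identity

accuracy = p·Se + (1 − p)·Sp,  p = gold prevalence,

holds exactly on every confusion matrix and is asserted property-style in
the tests. A zero-denominator sensitivity or specificity (no gold positives
or negatives) is reported as *undefined* with its count context, never
silently coerced to 0 or 1 — coercion would corrupt any aggregate table
built from the rows.

Every proportion carries a 95% (configurable) Clopper–Pearson exact interval
computed from Beta quantiles: low = B(α/2; k, n−k+1) for k>0 else 0,
high = B(1−α/2; k+1, n−k) for k<n else 1. The tests verify this against
direct bisection of the binomial tail probabilities for all 0 ≤ k ≤ n ≤ 50
at three confidence levels (agreement to 1e−9), against the closed forms at
k=0 and k=n, against `statsmodels`' beta method, and by simulation that
empirical coverage is ≥ the nominal 95% (the interval is conservative).

`reconstruct_counts` inverts a published summary row: from (n, gold
prevalence, Se, Sp) it rebuilds the implied confusion matrix
(round-half-up on expected counts) and the implied accuracy and tool call
rate. Because published inputs are themselves rounded to two digits, implied
metrics are only meaningful to about one percentage point, and that is the
tolerance used wherever they are compared. Report percentages are rounded
half-up to match the display convention of published summary tables (95.5 →
96).

## Prevalence and trend

Prevalence k/n with exact CI is computed for the whole corpus, by journal,
or by time epoch. Journal tables keep only journals with at least
`min_group_size` documents (default 5, the usual plotting cutoff), rank them
by proportion descending with ties broken alphabetically, and pool the rest
into an `other` row so counts are conserved — the conservation is tested.

Two epoch modes exist because both appear in review practice: fixed
calendar-width bins (default 6 months) counted backwards from an anchor
date, used for plotting-style summaries; and date quantiles (default
quartiles), used for the regression. Month arithmetic moves boundaries by
whole calendar months and clamps the day-of-month (Oct-31 minus 6 months →
Apr-30), which is unambiguous and testable. In quantile mode all copies of
an identical date stay in one bin, so realized bin sizes may be unequal.

The trend fit is ordinary least squares of epoch proportion on epoch index,
oldest epoch = index 0, so a positive slope means reporting is improving;
the p value is the two-sided t test of zero slope on (epochs − 2) df. OLS on
epoch proportions is the literal reading of "least squares linear
regression" on grouped data; per-document logistic coding would be a
different model and is deliberately not what this computes. Unweighted OLS
is the default (no weighting is implied by the phrase); `weighted=True`
switches to document-count WLS as a sensitivity analysis for unequal bins.
At least three epochs are required; a constant series is reported with slope
0 and r² = 0.

## The synthetic corpus generator

Real validation corpora of full-text stroke manuscripts cannot be
redistributed, so the system is exercised end-to-end on synthetic
methods-section prose with known gold labels. Each document is a handful of
neutral filler sentences (surgical model, husbandry, histology, statistics —
containing none of the lexicon keywords) into which reporting statements are
planted:

- **Prevalence** per item is exact by assignment — `round(n_docs · prev)`
  documents are positive, chosen by seeded permutation — not Bernoulli
  sampling, so small corpora have exactly the configured counts.
- **Hardness** selects the positive phrase bank: 0 = verbatim lexicon
  phrases (a correct detector must score 1.00/1.00; the suite asserts it);
  1 = paraphrases sharing keywords with the lexicon, of which exactly one
  per item is an engineered near-miss, so expected sensitivity is 0.90;
  2 = paraphrases avoiding the keywords entirely (coin toss, drawing lots,
  concealed codes), the ceiling of any keyword detector, where shipped-
  lexicon sensitivity is ~0. Sensitivity is therefore monotone decreasing
  in hardness, which is tested.
- **Confounders**: each gold-negative document receives, with probability
  `confounder_rate`, a confusable phrase for that item (random hexamer
  primers, high-power fields, blind-ended catheters, a cited double-blind
  clinical trial). Most are neutralized by the default exclusion patterns
  or contain no matching keyword; at most one per item defeats the lexicon,
  reproducing the characteristic overcalling failure mode at a controlled
  rate.
- **Journals** follow a Zipf-like (exponent 2) size distribution over 10
  journals so that both ≥5 and <5 journal groups exist; dates are uniform
  over the configured range (default the two years to 2016-10-04). One
  integer seed drives a single pseudo-random stream with fixed generation
  order, so identical configs are byte-identical.

The shipped benchmark conditions (`BENCHMARK_CONFIG`) are 200 documents,
prevalence 0.5 per item, hardness 1, confounder rate 0.3, seed 20161004.
Under these conditions the default detector is expected at sensitivity
≈ 0.90 and specificity ≈ 0.94–1.00 per item, comfortably above the 0.80
threshold; `benchmark()` reports the per-item pass/fail.

What passing says, and does not say: the generator emulates the *mechanics*
of reporting detection — phrase variation, keyword-sharing paraphrase,
confounder pressure, skewed journal sizes — not the full difficulty of real
manuscripts (OCR noise, tables, section structure, genuinely novel
phrasings, multilingual text). Meeting the 0.80 threshold on the benchmark
shows the machinery is correct and calibrated against the conditions it
defines; field performance on a new literature must be validated against a
manual gold standard for that literature, which is exactly the workflow the
`evaluate` subcommand implements.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale by design:
benchmark corpora of 200 documents, oracle sweeps over 500 generated texts,
exact-interval checks to n = 50, and 10,000-replicate coverage simulations —
sizes at which every oracle (brute-force enumeration, tail bisection,
longhand normal equations) is itself fast and trustworthy. Reconstruction of
published summary rows uses the printed inputs directly and is pure
arithmetic. Ties in evidence ordering are broken by (start, end,
pattern_id); zero-width regex matches are discarded as evidence; duplicate
document ids, unknown boolean tokens, non-ISO dates, dates after the epoch
anchor, and empty call/gold intersections are all fatal with named-row
diagnostics rather than warnings.

## Known limitations

- The detector is a keyword instrument: it cannot see hardness-2 style
  reporting ("assigned by coin toss") without lexicon extension, and it
  inherits every bias of its lexicon.
- No sentence segmentation or negation handling beyond exclusion overlap;
  "we did not randomize" would be called positive.
- Single-annotator gold standards are taken at face value; inter-annotator
  agreement is out of scope.
- PDF-to-text conversion is upstream; garbled input text degrades calls
  silently apart from the de-hyphenation rule.
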