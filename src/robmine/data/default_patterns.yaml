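# Default pattern sets for risk-of-bias reporting detection.
#
# This is a seed lexicon distilled from phrases commonly used in animal-study
# methods sections to report randomization of group allocation, blinded
# assessment of outcome, and sample size calculation.  It is a starting point,
# not a fixed vocabulary: every subcommand accepts --patterns to replace it,
# because reporting language differs between literatures.
#
# Patterns are matched against normalized text (lowercased, whitespace
# collapsed, line-break hyphenation joined).  The dialect is the portable
# regular-expression core: literals, character classes, alternation, bounded
# repetition.  No backreferences or lookaround, so configs stay engine-agnostic.
#
# An include match that overlaps any exclude match is suppressed; the document
# is called positive for an item iff at least one include match survives.

randomization:
  include:
    - id: rand-verb-group
      pattern: "random(ly)? (assigned|allocated|divided|distributed)"
    - id: randomized-into-group
      pattern: "randomi[sz](ed|ation)( in)?to .{0,40}group"
    - id: random-allocation
      pattern: "random allocation"
    - id: randomization-artifact
      pattern: "randomi[sz]ation (schedule|sequence|list)"
    - id: random-number
      pattern: "random number (table|generator)"
  exclude:
    - id: hexamer
      pattern: "random hexamer"
    - id: random-primer
      pattern: "random primer"
    - id: random-field
      pattern: "random(ly)? selected (field|section)"
    - id: random-effects
      pattern: "random[- ]effects?"

blinding:
  include:
    - id: blinded-role
      pattern: "blind(ed)? (fashion|manner|assessment|evaluation|observer|investigator|examiner)"
    - id: in-a-blinded
      pattern: "in a blinded"
    - id: role-blind
      pattern: "(observer|assessor|investigator)[- ]blind"
    - id: masked-to
      pattern: "masked to (the )?(group|treatment)"
    - id: unaware-of
      pattern: "unaware of (the )?(group|treatment) (allocation|assignment)"
  exclude:
    - id: blind-end
      pattern: "blind[- ]end"
    - id: double-blind-clinical
      pattern: "double[- ]blind (placebo|clinical|trial)"
    - id: blindness
      pattern: "blindness"

samplesize:
  include:
    - id: sample-size-calc
      pattern: "sample size (calculation|estimation|was (calculated|determined|estimated))"
    - id: power-calc
      pattern: "power (calculation|analysis)"
    - id: a-priori-power
      pattern: "a priori power"
    - id: stated-power
      pattern: "statistical power of .{0,20}(0\\.[89]\\d*|[89]\\d%)"
    - id: detect-with-power
      pattern: "to detect a (difference|effect) .{0,60}power"
  exclude:
    - id: high-power-field
      pattern: "high[- ]power(ed)? field"
    - id: power-supply
      pattern: "power supply"
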