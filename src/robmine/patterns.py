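"""Pattern-set configuration.

Each risk-of-bias item (randomization, blinding, samplesize) has an ordered
list of inclusion patterns and an ordered list of exclusion patterns, each a
``(pattern_id, regex)`` pair.  Configs are YAML; the shipped default lexicon
lives in ``robmine/data/default_patterns.yaml`` and is fully replaceable via
``--patterns``.

All patterns are compiled at load time so that a malformed expression fails
fast, never mid-classification.
"""

from __future__ import annotations

import dataclasses
import re
from importlib import resources
from pathlib import Path

import yaml

from .corpus import ITEMS


class PatternError(ValueError):
    """Malformed pattern-set configuration."""


@dataclasses.dataclass(frozen=True)
class PatternSet:
    """Inclusion and exclusion patterns for one risk-of-bias item."""

    item: str
    include_patterns: tuple[tuple[str, str], ...]
    exclude_patterns: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if self.item not in ITEMS:
            raise PatternError(f"unknown item {self.item!r}; expected one of {ITEMS}")
        ids = [pid for pid, _ in self.include_patterns] + [
            pid for pid, _ in self.exclude_patterns
        ]
        dupes = {pid for pid in ids if ids.count(pid) > 1}
        if dupes:
            raise PatternError(f"duplicate pattern_id(s) in {self.item} set: {sorted(dupes)}")
        for pid, pat in self.include_patterns + self.exclude_patterns:
            try:
                re.compile(pat)
            except re.error as exc:
                raise PatternError(
                    f"pattern {pid!r} of item {self.item!r} does not compile: {exc}"
                ) from exc

    def compiled(self) -> "CompiledPatternSet":
        return CompiledPatternSet(
            item=self.item,
            include=[(pid, re.compile(pat)) for pid, pat in self.include_patterns],
            exclude=[(pid, re.compile(pat)) for pid, pat in self.exclude_patterns],
        )


@dataclasses.dataclass
class CompiledPatternSet:
    item: str
    include: list[tuple[str, re.Pattern]]
    exclude: list[tuple[str, re.Pattern]]


def _parse_entry_list(entries, item: str, kind: str) -> tuple[tuple[str, str], ...]:
    if entries is None:
        return ()
    out = []
    for entry in entries:
        if not isinstance(entry, dict) or "id" not in entry or "pattern" not in entry:
            raise PatternError(
                f"each {kind} entry of item {item!r} must be a mapping with "
                f"'id' and 'pattern' keys; got {entry!r}"
            )
        out.append((str(entry["id"]), str(entry["pattern"])))
    return tuple(out)


def parse_pattern_config(text: str) -> dict[str, PatternSet]:
    """Parse a YAML pattern config into one :class:`PatternSet` per item."""
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise PatternError("pattern config must be a mapping of item -> {include, exclude}")
    sets: dict[str, PatternSet] = {}
    for item, body in raw.items():
        if item not in ITEMS:
            raise PatternError(f"unknown item {item!r} in pattern config")
        body = body or {}
        sets[item] = PatternSet(
            item=item,
            include_patterns=_parse_entry_list(body.get("include"), item, "include"),
            exclude_patterns=_parse_entry_list(body.get("exclude"), item, "exclude"),
        )
    return sets


def load_pattern_sets(path: str | Path) -> dict[str, PatternSet]:
    """Load pattern sets from a YAML file."""
    return parse_pattern_config(Path(path).read_text(encoding="utf-8"))


def default_pattern_sets() -> dict[str, PatternSet]:
    """The shipped seed lexicon (one set per item)."""
    text = resources.files("robmine.data").joinpath("default_patterns.yaml").read_text("utf-8")
    sets = parse_pattern_config(text)
    missing = [item for item in ITEMS if item not in sets]
    if missing:  # pragma: no cover - shipped config is complete
        raise PatternError(f"default config missing item(s): {missing}")
    return sets
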