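"""Heuristic clinical-relevance rules for newly detected sentences.

The mechanism is an ordered first-match-wins rule list.  Each rule is
either a sentence-kind match (``kind:header``) or a regular expression
against the sentence text.  The shipped defaults encode the two stable
conventions — note headers, footers and signature lines carry no
clinically relevant information, while vital-sign statements always do —
and default everything else to relevant.  Institution-specific rule
lists are loaded from a TSV and replace or extend the defaults.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from .corpus import Sentence

__all__ = ["RelevanceRule", "RelevanceRuleSet", "classify_relevance"]

VERDICTS = ("relevant", "irrelevant")

#: Default vital-sign pattern: a vital abbreviation followed by a number.
VITALS_PATTERN = (
    r"\b(?:BP|HR|RR|T|Temp|SpO2|O2|P|Wt|Ht|BMI)\.?\s*:?\s*\d"
)


@dataclass(frozen=True)
class RelevanceRule:
    rule_id: str
    pattern: str  # "kind:<kind>" or a regular expression over the text
    verdict: str

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(
                f"rule {self.rule_id!r}: verdict {self.verdict!r} not in {VERDICTS}"
            )
        if not self.pattern.startswith("kind:"):
            try:
                re.compile(self.pattern)
            except re.error as exc:
                raise ValueError(
                    f"rule {self.rule_id!r}: malformed pattern: {exc}"
                ) from exc

    def matches(self, sentence: Sentence) -> bool:
        if self.pattern.startswith("kind:"):
            return sentence.kind == self.pattern.split(":", 1)[1]
        return re.search(self.pattern, sentence.text) is not None


@dataclass
class RelevanceRuleSet:
    """Ordered rules with a terminating default verdict."""

    rules: list[RelevanceRule] = field(default_factory=list)
    default_verdict: str = "relevant"

    def __post_init__(self) -> None:
        if self.default_verdict not in VERDICTS:
            raise ValueError(f"bad default verdict {self.default_verdict!r}")

    @classmethod
    def default(cls) -> "RelevanceRuleSet":
        return cls(
            rules=[
                RelevanceRule("header", "kind:header", "irrelevant"),
                RelevanceRule("footer", "kind:footer", "irrelevant"),
                RelevanceRule("signature", "kind:signature", "irrelevant"),
                RelevanceRule("vitals", VITALS_PATTERN, "relevant"),
            ]
        )

    @classmethod
    def from_tsv(cls, path: str | Path, default_verdict: str = "relevant") -> "RelevanceRuleSet":
        """Load ordered rules from a TSV of rule_id, pattern, verdict."""
        rules: list[RelevanceRule] = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                rule_id, pattern, verdict = line.split("\t")
                rules.append(RelevanceRule(rule_id, pattern, verdict))
        return cls(rules=rules, default_verdict=default_verdict)


def classify_relevance(
    sentence: Sentence, rules: RelevanceRuleSet | None = None
) -> str:
    """First matching rule wins; unmatched sentences get the default.

    With the default rule set: headers, footers and signatures are
    irrelevant, vital-sign statements are relevant, and any other body
    sentence falls through to relevant.
    """
    ruleset = rules or RelevanceRuleSet.default()
    for rule in ruleset.rules:
        if rule.matches(sentence):
            return rule.verdict
    return ruleset.default_verdict
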