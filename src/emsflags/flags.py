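"""Keyword-flag feature engineering.

The interpretable featurization at the core of the package: count curated
opioid and overdose keywords in each of the six encounter text fields.
Matching is case-insensitive, regular-expression based, and boundary-aware —
"OD" matches as a standalone token but never inside "body", and "oxy" is
never double-counted inside "oxycodone". "intox" is a left-anchored prefix
so that "intoxicated" and "intoxication" both fire.

The default term sets are the curated surveillance keyword lists: 18 opioid
terms and 7 overdose terms. They overlap substantially with the chief
complaint keyword flags used by CDC's DOSE surveillance system. The opioid
list intentionally includes "crack" and "cocaine" even though they are not
pharmacologically opioids — the curated list is implemented verbatim.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import yaml

from .matrix import FeatureMatrix
from .records import TEXT_FIELDS, Cohort

OPIOID_TERMS = (
    "opioid",
    "opiate",
    "narcan",
    "naloxone",
    "heroin",
    "methadone",
    "fentanyl",
    "percocet",
    "oxycontin",
    "oxycodone",
    "vicodin",
    "morphine",
    "crack",
    "cocaine",
    "tylenol 3",
    "codeine",
    "oxy",
    "tramadol",
)

OVERDOSE_TERMS = (
    "ingestion",
    "substance",
    "abuse",
    "intox",
    "poisoning",
    "od",
    "overdose",
)


@dataclass
class TermSet:
    """A named keyword list with a matching policy.

    ``terms`` are lowercase-normalized and deduplicated; multi-word terms
    match across any single run of whitespace. Every term requires a word
    boundary on both sides except members of ``prefix_terms``, which require
    only a left boundary (so "intox" matches inside "intoxicated"). Numerals
    count as word characters for boundary purposes, so "tylenol 3" will not
    match inside "tylenol 30".
    """

    name: str
    terms: tuple
    prefix_terms: frozenset = frozenset()
    boundary_policy: str = "word_boundaries"
    _pattern: re.Pattern = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        norm = []
        for t in self.terms:
            t = " ".join(str(t).lower().split())
            if not t:
                raise ValueError("empty term")
            if t not in norm:
                norm.append(t)
        if not norm:
            raise ValueError(f"term set {self.name!r} has no terms")
        self.terms = tuple(norm)
        self.prefix_terms = frozenset(
            " ".join(str(t).lower().split()) for t in self.prefix_terms
        )
        unknown = self.prefix_terms - set(self.terms)
        if unknown:
            raise ValueError(f"prefix_terms not in terms: {sorted(unknown)}")
        if self.boundary_policy != "word_boundaries":
            raise ValueError(f"unknown boundary policy {self.boundary_policy!r}")
        self._pattern = self._compile()

    def _compile(self) -> re.Pattern:
        # Longest alternative first: at equal start positions the regex
        # engine then prefers the longest term, and finditer's consume-on-
        # match gives non-overlapping counts.
        alts = []
        for t in sorted(self.terms, key=len, reverse=True):
            body = r"\s+".join(re.escape(w) for w in t.split())
            if t in self.prefix_terms:
                alts.append(rf"(?<!\w){body}")
            else:
                alts.append(rf"(?<!\w){body}(?!\w)")
        return re.compile("|".join(alts), re.IGNORECASE)

    def finditer(self, text: str):
        return self._pattern.finditer(text)


def default_term_sets() -> tuple:
    """The curated (opioid, overdose) term sets."""
    return (
        TermSet(name="opioid", terms=OPIOID_TERMS),
        TermSet(name="overdose", terms=OVERDOSE_TERMS, prefix_terms=frozenset({"intox"})),
    )


def load_term_sets(path) -> list:
    """Load term sets from YAML: a list of {name, terms, prefix_terms?}."""
    with open(path, encoding="utf-8") as fh:
        spec = yaml.safe_load(fh)
    out = []
    for entry in spec:
        out.append(
            TermSet(
                name=entry["name"],
                terms=tuple(entry["terms"]),
                prefix_terms=frozenset(entry.get("prefix_terms", ())),
            )
        )
    return out


def count_term_matches(text: str, term_set: TermSet) -> int:
    """Count non-overlapping keyword matches of ``term_set`` in ``text``.

    Case-insensitive; each text position contributes to at most one term,
    with the longest term preferred at equal start positions.
    """
    return sum(1 for _ in term_set.finditer(text))


def featurize_flags(
    cohort: Cohort,
    term_sets=None,
    fields=TEXT_FIELDS,
) -> FeatureMatrix:
    """Count each term set in each requested field.

    One integer column per (term set x field), named ``<set>__<field>``; the
    default two sets over all six fields give 12 columns.
    """
    if term_sets is None:
        term_sets = default_term_sets()
    fields = tuple(fields)
    for f in fields:
        if f not in TEXT_FIELDS:
            raise ValueError(f"unknown text field {f!r}")
    names = [f"{ts.name}__{f}" for ts in term_sets for f in fields]
    values = np.zeros((len(cohort), len(names)), dtype=float)
    for i, rec in enumerate(cohort):
        j = 0
        for ts in term_sets:
            for f in fields:
                values[i, j] = count_term_matches(getattr(rec, f), ts)
                j += 1
    return FeatureMatrix(cohort.record_ids, names, values)
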