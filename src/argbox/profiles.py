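"""Ternary transcription-profile taxonomy.

Genes that pass the FDR significance gate are grouped by their H_r
5-tuple into five main types (I-V) and 13 subtypes via an ordered rule
table.  Each rule is an H_r pattern over {-1, 0, +1, *} (``*`` matches
anything); the first matching rule wins.  Significant genes matching no
rule are "unclassified"; non-significant genes are never labelled.

The default table (``profile_rules_v1.tsv``, shipped as package data) is
a documented interpretation of the published type/subtype figure — the
original membership rules were defined visually — chosen so that every
subtype corresponds to a sign pattern realizable under the identity
M_c(c5) = M_c(c3) - M_c(c2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = ["Rule", "RuleTable", "load_rules", "assign_profiles",
           "enumerate_hr_combinations"]

WILDCARD = "*"
HR_COLUMNS = ("h1", "h2", "h3", "h4", "h5")


@dataclass(frozen=True)
class Rule:
    """One H_r pattern: entries in {-1, 0, 1, None}; None is a wildcard."""

    pattern: tuple[int | None, ...]
    type_: str
    subtype: str

    def matches(self, hr: tuple[int, ...]) -> bool:
        return all(p is None or p == h for p, h in zip(self.pattern, hr))

    def _compatible(self, other: "Rule") -> bool:
        return all(p is None or q is None or p == q
                   for p, q in zip(self.pattern, other.pattern))

    def _subsumes(self, other: "Rule") -> bool:
        """True if every tuple matching ``other`` also matches ``self``."""
        return all(p is None or (q is not None and p == q)
                   for p, q in zip(self.pattern, other.pattern))


@dataclass
class RuleTable:
    rules: list[Rule]
    version: str = "unversioned"

    def __post_init__(self):
        # Ambiguous overlap: two rules with different labels can match the
        # same tuple and neither is a strict specialization of the other.
        for i, a in enumerate(self.rules):
            for b in self.rules[i + 1:]:
                if a.subtype == b.subtype:
                    continue
                if a._compatible(b) and not (a._subsumes(b) or b._subsumes(a)):
                    warnings.warn(
                        f"rule table {self.version}: patterns for "
                        f"{a.subtype} and {b.subtype} overlap ambiguously; "
                        "first match wins", stacklevel=2)

    def assign(self, hr: tuple[int, ...]) -> tuple[str, str]:
        for rule in self.rules:
            if rule.matches(hr):
                return rule.type_, rule.subtype
        return "unclassified", ""


def load_rules(path=None) -> RuleTable:
    """Load a rule table from TSV; default is the packaged v1 table."""
    if path is None:
        ref = resources.files("argbox.data") / "profile_rules_v1.tsv"
        with resources.as_file(ref) as p:
            return load_rules(p)
    version = "unversioned"
    rules: list[Rule] = []
    with open(path) as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                if "version" in line:
                    version = line.split("version", 1)[1].strip(" ,")
                continue
            if not line:
                continue
            if header is None:
                header = line.split("\t")
                continue
            row = dict(zip(header, line.split("\t")))
            pattern = tuple(
                None if row[c] == WILDCARD else int(row[c]) for c in HR_COLUMNS)
            rules.append(Rule(pattern, row["type"], row["subtype"]))
    if not rules:
        raise ValueError(f"no rules found in {path}")
    return RuleTable(rules, version=version)


def assign_profiles(hr: pd.DataFrame, rules: RuleTable | None = None) -> pd.DataFrame:
    """Label each gene with its profile type and subtype.

    ``hr`` is the output of :func:`argbox.contrasts.classify_hr` (columns
    h1..h5 plus ``significant``).  Non-significant genes get empty labels.
    """
    if rules is None:
        rules = load_rules()
    types = []
    subtypes = []
    hr_vals = hr[list(HR_COLUMNS)].to_numpy()
    sig = hr["significant"].to_numpy() if "significant" in hr.columns \
        else pd.Series(True, index=hr.index).to_numpy()
    for i in range(len(hr)):
        if not sig[i]:
            types.append("")
            subtypes.append("")
            continue
        t, s = rules.assign(tuple(int(v) for v in hr_vals[i]))
        types.append(t)
        subtypes.append(s)
    return pd.DataFrame({"type": types, "subtype": subtypes}, index=hr.index)


def enumerate_hr_combinations(hr: pd.DataFrame,
                              significant_only: bool = True) -> pd.DataFrame:
    """Distinct observed H_r 5-tuples with gene counts.

    The universe of possible tuples has size 3**5 = 243; the observed set
    is typically far smaller.  Sorted by descending count.
    """
    sub = hr
    if significant_only and "significant" in hr.columns:
        sub = hr[hr["significant"]]
    tuples = [tuple(int(v) for v in row)
              for row in sub[list(HR_COLUMNS)].to_numpy()]
    counts = pd.Series(tuples, dtype=object).value_counts()
    return pd.DataFrame({"hr": counts.index.to_list(),
                         "n_genes": counts.to_numpy()})
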