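"""ICD-10 / ICD-10-CM condition-group mapping.

Hospitalizations are labelled with mental-health condition groups by
prefix-matching their diagnosis codes against a code map.  The packaged
default map follows the group structure of the Child and Adolescent Mental
Health Disorders Classification System (CAMHD-CS), restricted to the 16
groups relevant to adolescent inpatient mental health, with US (ICD-10-CM)
and French (ICD-10) pattern sets merged into a single map.  A code may match
more than one group; a hospitalization is mental-health–associated when at
least one of its codes matches any group.

Users may supply their own ``group,pattern`` CSV to override the default,
e.g. to reproduce an exact institutional code list.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources

from .errors import ConfigurationError, ValidationError

#: The 16 condition-group labels of the packaged default map.
DEFAULT_GROUPS: tuple[str, ...] = (
    "Anxiety disorders",
    "Depressive disorders",
    "Suicidality or self-injury",
    "Mental health symptoms",
    "Trauma and stressor-related disorders",
    "Eating disorders",
    "Miscellaneous",
    "Disruptive, impulse control, and conduct disorders",
    "Substance-related and addictive disorders",
    "Somatic symptoms and related disorders",
    "Schizophrenia spectrum and other psychotic disorders",
    "Obsessive-compulsive and related disorders",
    "Bipolar and related disorders",
    "Sleep-wake disorders",
    "Personality disorders",
    "Dissociative disorders",
)

_PATTERN_RE = re.compile(r"^[A-Z0-9]+$")


@dataclass(frozen=True)
class ConditionGroup:
    """A named condition group and its normalized ICD code prefixes."""

    name: str
    patterns: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("condition group name must be nonempty")
        if not self.patterns:
            raise ValidationError(f"group {self.name!r} has no patterns")
        for pat in self.patterns:
            if not _PATTERN_RE.match(pat):
                raise ValidationError(
                    f"group {self.name!r}: pattern {pat!r} is not a "
                    "normalized ICD prefix (uppercase alphanumeric, no dot)"
                )


@dataclass(frozen=True)
class CodeMap:
    """Ordered collection of condition groups plus a dialect label."""

    groups: tuple[ConditionGroup, ...]
    dialect: str = "merged"
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def group_names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.groups)

    def lookup(self, normalized_code: str) -> frozenset[str]:
        """All group names whose patterns prefix-match a normalized code."""
        hit = self._cache.get(normalized_code)
        if hit is None:
            hit = frozenset(
                g.name
                for g in self.groups
                if any(normalized_code.startswith(p) for p in g.patterns)
            )
            self._cache[normalized_code] = hit
        return hit


def normalize_code(code: str) -> str:
    """Normalize a raw ICD string: strip whitespace, uppercase, drop dots.

    >>> normalize_code("f41.1")
    'F411'
    """
    if not isinstance(code, str) or not code.strip():
        raise ValidationError("ICD code must be a nonempty string")
    return code.upper().replace(".", "").strip()


def load_codemap(source: str = "default") -> CodeMap:
    """Load a code map from a ``group,pattern`` CSV or the packaged default.

    Parameters
    ----------
    source
        ``"default"`` for the packaged 16-group map, otherwise a path to a
        CSV file with a header row ``group,pattern``.  Patterns may be dotted
        or undotted; they are normalized on load.
    """
    if source == "default":
        ref = resources.files("propits.data").joinpath("default_codemap.csv")
        with ref.open("r", encoding="utf-8") as fh:
            cmap = _parse_codemap(fh, dialect="merged")
        missing = set(DEFAULT_GROUPS) - set(cmap.group_names)
        if missing:  # packaging defect, not a user error
            raise ConfigurationError(f"packaged codemap missing groups: {missing}")
        return cmap
    with open(source, encoding="utf-8", newline="") as fh:
        return _parse_codemap(fh, dialect="custom")


def _parse_codemap(fh, dialect: str) -> CodeMap:
    reader = csv.DictReader(fh)
    if reader.fieldnames is None or not {"group", "pattern"} <= set(reader.fieldnames):
        raise ConfigurationError("codemap file needs a 'group,pattern' header")
    patterns: dict[str, set[str]] = {}
    order: list[str] = []
    for row in reader:
        group = (row["group"] or "").strip()
        if not group:
            raise ConfigurationError("codemap row with empty group label")
        if group not in patterns:
            patterns[group] = set()
            order.append(group)
        patterns[group].add(normalize_code(row["pattern"]))
    if not order:
        raise ConfigurationError("codemap file contains no mappings")
    groups = tuple(ConditionGroup(name, frozenset(patterns[name])) for name in order)
    return CodeMap(groups=groups, dialect=dialect)


def classify_codes(codes, codemap: CodeMap) -> frozenset[str]:
    """Union of condition groups matched by any of the raw ICD codes.

    Unmatched codes contribute nothing; an empty code list yields the empty
    set.  Classification is a union-homomorphism over code lists.
    """
    out: frozenset[str] = frozenset()
    for code in codes:
        out |= codemap.lookup(normalize_code(code))
    return out


def is_mh_hospitalization(codes, codemap: CodeMap) -> bool:
    """True iff at least one code maps to a mental-health condition group."""
    return any(codemap.lookup(normalize_code(c)) for c in codes)
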