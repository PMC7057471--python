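"""ICD-9-CM code sets and pattern matching.

Claims extracts disagree on decimal usage ("038.9" vs "0389"), so every code
and pattern is reduced to a canonical dotless, uppercase form before any
comparison.  Code sets may contain exact codes or prefix patterns with a
single trailing ``*`` (e.g. ``038*`` matches every septicemia subcode but not
the bare three-digit stem).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "canonicalize",
    "CodeSet",
    "CodeTaxonomy",
    "TaxonomyError",
    "load_taxonomy",
    "code_matches",
    "DEFAULT_TAXONOMY",
]

# canonical code: 3-digit stem (or V## / E###) plus up to two more digits
_CODE_RE = re.compile(r"^(?:\d{3}|V\d{2}|E\d{3})\d{0,2}$")
_PATTERN_RE = re.compile(r"^(?:\d{3}|V\d{2}|E\d{3})\d{0,2}\*?$")


class TaxonomyError(ValueError):
    """Raised for malformed code-list configuration."""


def canonicalize(code: str) -> str:
    """Return the canonical form of an ICD-9 code or pattern.

    Uppercases, removes whitespace and the decimal point.  Idempotent.
    """
    return "".join(code.split()).upper().replace(".", "")


def _validate_pattern(pattern: str, set_name: str = "") -> str:
    canon = canonicalize(pattern)
    if not _PATTERN_RE.match(canon):
        where = f" in set '{set_name}'" if set_name else ""
        raise TaxonomyError(f"malformed ICD-9 pattern {pattern!r}{where}")
    return canon


@dataclass(frozen=True)
class CodeSet:
    """A named set of ICD-9 patterns supporting membership tests."""

    name: str
    exact: frozenset[str]
    prefixes: tuple[str, ...]

    @classmethod
    def from_patterns(cls, name: str, patterns: Iterable[str]) -> "CodeSet":
        exact: set[str] = set()
        prefixes: set[str] = set()
        n = 0
        for p in patterns:
            n += 1
            canon = _validate_pattern(p, name)
            if canon.endswith("*"):
                prefixes.add(canon[:-1])
            else:
                exact.add(canon)
        if n == 0:
            raise TaxonomyError(f"code set '{name}' is empty")
        return cls(name=name, exact=frozenset(exact), prefixes=tuple(sorted(prefixes)))

    def __contains__(self, code: str) -> bool:
        canon = canonicalize(code)
        if canon in self.exact:
            return True
        # a prefix pattern matches strict extensions only, never the bare stem
        return any(canon.startswith(p) and len(canon) > len(p) for p in self.prefixes)

    def matches_any(self, codes: Iterable[str]) -> bool:
        return any(c in self for c in codes)


def code_matches(code: str, patterns: Iterable[str]) -> bool:
    """True iff *code* equals an exact pattern or extends a ``*`` prefix."""
    return code in CodeSet.from_patterns("adhoc", patterns)


_REQUIRED_SETS = (
    "infection_codes",
    "organ_dysfunction_codes",
    "explicit_sepsis_codes",
    "cms_codes",
)


@dataclass(frozen=True)
class CodeTaxonomy:
    """The four ICD-9 code sets the claims algorithms consult.

    ``infection`` and ``organ_dysfunction`` drive the implicit route;
    ``explicit_sepsis`` holds severe-sepsis/septic-shock codes; ``cms`` holds
    the severe sepsis / septic shock measure list.
    """

    infection: CodeSet
    organ_dysfunction: CodeSet
    explicit_sepsis: CodeSet
    cms: CodeSet

    @classmethod
    def from_dict(cls, cfg: Mapping[str, Iterable[str]]) -> "CodeTaxonomy":
        missing = [k for k in _REQUIRED_SETS if k not in cfg]
        if missing:
            raise TaxonomyError(f"taxonomy config missing set(s): {', '.join(missing)}")
        return cls(
            infection=CodeSet.from_patterns("infection_codes", cfg["infection_codes"]),
            organ_dysfunction=CodeSet.from_patterns(
                "organ_dysfunction_codes", cfg["organ_dysfunction_codes"]
            ),
            explicit_sepsis=CodeSet.from_patterns(
                "explicit_sepsis_codes", cfg["explicit_sepsis_codes"]
            ),
            cms=CodeSet.from_patterns("cms_codes", cfg["cms_codes"]),
        )

    def as_dict(self) -> dict[str, list[str]]:
        out = {}
        for key, cs in (
            ("infection_codes", self.infection),
            ("organ_dysfunction_codes", self.organ_dysfunction),
            ("explicit_sepsis_codes", self.explicit_sepsis),
            ("cms_codes", self.cms),
        ):
            out[key] = sorted(cs.exact) + [p + "*" for p in cs.prefixes]
        return out


def load_taxonomy(path: str | Path) -> CodeTaxonomy:
    """Load a taxonomy from a YAML (or JSON — YAML superset) config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise TaxonomyError(f"taxonomy file {path} does not contain a mapping")
    return CodeTaxonomy.from_dict(cfg)


# ---------------------------------------------------------------------------
# Default (placeholder) taxonomy
#
# A representative, synthetic stand-in for the full published inventories of
# infection and acute organ-dysfunction codes; it keeps the pipeline
# self-consistent and is intended to be replaced wholesale via config for any
# real analysis.  All downstream results are relative to the taxonomy in use.
# ---------------------------------------------------------------------------
DEFAULT_TAXONOMY_DICT: dict[str, list[str]] = {
    "infection_codes": [
        "001*", "003*", "008*", "009*",
        "038*",          # septicemia
        "041*",          # bacterial infection in unspecified site
        "054*", "112*",  # herpes simiplex, candidiasis
        "320*",          # bacterial meningitis
        "461*", "462", "463", "466*",  # acute upper/lower respiratory infections
        "480*", "481", "482*", "483*", "485", "486",  # pneumonia
        "510*", "513*",  # empyema, lung abscess
        "540*", "541", "542", "567*",  # appendicitis, peritonitis
        "590*", "5990",  # pyelonephritis, urinary tract infection
        "680*", "681*", "682*", "686*",  # skin and soft-tissue infections
        "711*", "730*",  # septic arthritis, osteomyelitis
        "9959",          # systemic inflammatory response syndrome, unspecified
    ],
    "organ_dysfunction_codes": [
        "2762",          # acidosis
        "2866", "2869",  # defibrination / other coagulopathy
        "2874", "2875",  # thrombocytopenia
        "3481", "3483",  # anoxic brain damage, encephalopathy
        "4275",          # cardiac arrest
        "4580", "4588", "4589",  # hypotension
        "570",           # acute hepatic necrosis
        "5734",          # hepatic infarction
        "584*",          # acute renal failure
        "7855*",         # shock without trauma (incl. septic shock)
        "78001",         # coma
        "5185", "51881", "51882",  # acute respiratory failure / insufficiency
        "7991",          # respiratory arrest
    ],
    "explicit_sepsis_codes": [
        "99592",  # severe sepsis
        "78552",  # septic shock
    ],
    "cms_codes": [
        "99591",  # sepsis
        "99592",  # severe sepsis
        "78552",  # septic shock
    ],
}

DEFAULT_TAXONOMY = CodeTaxonomy.from_dict(DEFAULT_TAXONOMY_DICT)
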