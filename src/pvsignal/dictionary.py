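"""Drug-synonym dictionaries and MedDRA preferred-term query sets.

Verbatim drugname strings in spontaneous reports are noisy (brand names,
development codes, stray whitespace, punctuation).  Matching is therefore
performed on a normalized form: uppercase, trimmed, internal whitespace
collapsed, punctuation stripped — so "ABT-888", "abt 888" and "ABT888" all
meet.  Exact equality of normalized strings is the default; a word-boundary
substring mode exists for sensitivity analyses but is off by default
because it inflates counts irreproducibly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, FrozenSet, Optional, Set

_WS = re.compile(r"\s+")
_PUNCT = re.compile(r"[^\w\s]")


def normalize_name(name: object) -> str:
    """Normalize a drug name for matching (upper, trim, collapse, strip punctuation)."""
    s = "" if name is None else str(name)
    s = _PUNCT.sub("", s.upper())
    return _WS.sub(" ", s).strip()


def normalize_pt(pt: object) -> str:
    """Normalize a MedDRA preferred term: case-insensitive, whitespace-collapsed."""
    s = "" if pt is None else str(pt)
    return _WS.sub(" ", s).strip().lower()


@dataclass
class DrugDictionary:
    """Mapping from generic drug names to their synonym sets.

    Every generic is its own synonym; normalized synonyms must be unique
    across generics (ambiguity would make case counts ill-defined).
    """

    entries: Dict[str, Set[str]]
    name: str = "custom"
    _index: Dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        index: Dict[str, str] = {}
        for generic, synonyms in self.entries.items():
            synonyms.add(generic)
            for syn in synonyms:
                key = normalize_name(syn)
                if not key:
                    continue
                if key in index and index[key] != generic:
                    raise ValueError(
                        f"synonym {syn!r} maps to both {index[key]!r} and {generic!r}")
                index[key] = generic
        self._index = index

    @property
    def generics(self) -> list[str]:
        return list(self.entries)

    def match(self, drugname: object, substring: bool = False) -> Optional[str]:
        """Return the generic for a verbatim drugname, or None."""
        key = normalize_name(drugname)
        if not key:
            return None
        hit = self._index.get(key)
        if hit or not substring:
            return hit
        for syn_key, generic in self._index.items():
            if re.search(rf"(?<!\w){re.escape(syn_key)}(?!\w)", key):
                return generic
        return None

    @classmethod
    def from_file(cls, path: str | Path, name: Optional[str] = None) -> "DrugDictionary":
        """Load ``generic<TAB>synonym`` lines ('#' comments allowed)."""
        entries: Dict[str, Set[str]] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split(None, 1)
            generic = parts[0].strip()
            synonym = parts[1].strip() if len(parts) > 1 else generic
            entries.setdefault(generic, set()).add(synonym)
        return cls(entries=entries, name=name or Path(path).stem)

    @classmethod
    def default_parp(cls) -> "DrugDictionary":
        """The bundled PARP-inhibitor dictionary (generic, brand, dev code)."""
        with resources.as_file(resources.files("pvsignal.data") / "parp_inhibitors.txt") as p:
            return cls.from_file(p, name="parp_inhibitors")


def match_drug(drugname: object, dictionary: DrugDictionary,
               substring: bool = False) -> Optional[str]:
    """Functional alias for :meth:`DrugDictionary.match`."""
    return dictionary.match(drugname, substring=substring)


@dataclass(frozen=True)
class PTQuerySet:
    """A named set of MedDRA preferred terms, stored normalized."""

    name: str
    pts: FrozenSet[str]

    def __post_init__(self) -> None:
        if not self.pts:
            raise ValueError("PT query set must be non-empty")
        object.__setattr__(self, "pts", frozenset(normalize_pt(p) for p in self.pts))

    def __contains__(self, pt: object) -> bool:
        return normalize_pt(pt) in self.pts

    def __len__(self) -> int:
        return len(self.pts)

    @classmethod
    def from_file(cls, path: str | Path, name: Optional[str] = None) -> "PTQuerySet":
        pts = [line.strip() for line in Path(path).read_text(encoding="utf-8").splitlines()
               if line.strip() and not line.lstrip().startswith("#")]
        return cls(name=name or Path(path).stem, pts=frozenset(pts))

    @classmethod
    def default_renal(cls) -> "PTQuerySet":
        """The 12 renal adverse-effect preferred terms."""
        with resources.as_file(resources.files("pvsignal.data") / "renal_pts.txt") as p:
            return cls.from_file(p, name="renal_adverse_effects")


def load_region_map(path: Optional[str | Path] = None) -> Dict[str, str]:
    """country code/name -> continent, from the bundled map or a custom CSV."""
    import pandas as pd
    if path is None:
        with resources.as_file(resources.files("pvsignal.data") / "region_map.csv") as p:
            df = pd.read_csv(p, dtype=str)
    else:
        df = pd.read_csv(path, dtype=str)
    return {str(k).strip().upper(): str(v).strip() for k, v in zip(df.iloc[:, 0], df.iloc[:, 1])}


def load_indication_map(path: Optional[str | Path] = None) -> Dict[str, str]:
    """indication PT -> reporting group (normalized keys)."""
    import pandas as pd
    if path is None:
        with resources.as_file(resources.files("pvsignal.data") / "indication_map.csv") as p:
            df = pd.read_csv(p, dtype=str)
    else:
        df = pd.read_csv(path, dtype=str)
    return {normalize_pt(k): str(v).strip() for k, v in zip(df.iloc[:, 0], df.iloc[:, 1])}
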