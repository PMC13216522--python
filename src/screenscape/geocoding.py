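"""Offline fuzzy geocoding against a building registry.

Address strings are normalized (lower-cased, diacritics and punctuation
stripped, abbreviations expanded, the street number pulled out) and matched
against the registry's normalized street names with the Ratcliff-Obershelp
sequence-similarity ratio 2M/(|a|+|b|) (stdlib ``difflib.SequenceMatcher``).
Matching is two-step: a *quick* pass restricted to entries sharing the
address's postal code, then — if the best similarity falls below the
acceptance threshold (default 0.80) — a *slow* pass over the whole registry.
A matched street without a matching building number resolves to the street
centroid.  Everything below threshold fails.  The procedure is entirely
offline: no network calls, ever.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from difflib import SequenceMatcher

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_ABBREVIATIONS",
    "AddressNormalizationError",
    "normalize_address",
    "similarity",
    "Registry",
    "GeocodeResult",
    "geocode",
    "geocode_table",
    "review_band",
]

#: extensible default abbreviation dictionary (token -> expansion), applied
#: after punctuation stripping, so "ch." arrives as the token "ch"
DEFAULT_ABBREVIATIONS = {
    "ch": "chemin",
    "av": "avenue",
    "bd": "boulevard",
    "r": "rue",
    "rte": "route",
    "pl": "place",
    "imp": "impasse",
    "q": "quai",
    "prom": "promenade",
    "sq": "square",
}

_NUMBER_TOKEN = re.compile(r"^\d+[a-z]*$")


class AddressNormalizationError(ValueError):
    """Raised when an address string is empty after normalization."""


def _strip_diacritics(text: str) -> str:
    return "".join(c for c in unicodedata.normalize("NFKD", text)
                   if not unicodedata.combining(c))


def normalize_address(raw: str, abbreviations: dict[str, str] | None = None
                      ) -> tuple[str, str | None]:
    """Normalize an address string and extract its street number.

    Steps, in order: strip diacritics; lowercase; replace every
    non-alphanumeric character with a space; expand abbreviation tokens from
    the dictionary; pull out number tokens (digits optionally followed by
    letters, e.g. "12" or "12bis") — the last one found is the street
    number.  Returns (normalized street, number or None).

    >>> normalize_address("Ch. des Roses 5")
    ('chemin des roses', '5')
    """
    if not raw or not raw.strip():
        raise AddressNormalizationError("empty address")
    abbreviations = DEFAULT_ABBREVIATIONS if abbreviations is None else abbreviations
    text = _strip_diacritics(raw).lower()
    text = re.sub(r"[^a-z0-9]+", " ", text)
    tokens = [abbreviations.get(t, t) for t in text.split()]
    number = None
    street_tokens = []
    for t in tokens:
        if _NUMBER_TOKEN.match(t):
            number = t
        else:
            street_tokens.append(t)
    street = " ".join(street_tokens)
    if not street and number is None:
        raise AddressNormalizationError(f"address empty after normalization: {raw!r}")
    return street, number


def similarity(a: str, b: str) -> float:
    """Ratcliff-Obershelp ratio 2M/(|a|+|b|), M = characters in the
    recursively found longest matching blocks.  1.0 iff identical."""
    if not a or not b:
        raise ValueError("similarity requires two non-empty strings")
    return SequenceMatcher(None, a, b, autojunk=False).ratio()


@dataclass
class Registry:
    """Indexed building registry.

    Built from a DataFrame with columns street_name, street_number,
    postal_code, x, y.  Street names are normalized on construction; entries
    are indexed by (postal_code, normalized street).
    """

    entries: pd.DataFrame
    abbreviations: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_ABBREVIATIONS))

    def __post_init__(self) -> None:
        if len(self.entries) == 0:
            raise ValueError("registry is empty")
        df = self.entries.copy()
        df["postal_code"] = df["postal_code"].astype(str)
        df["street_number"] = df["street_number"].astype(str)
        norm = [normalize_address(s, self.abbreviations)[0]
                for s in df["street_name"]]
        df["street_norm"] = norm
        self.entries = df
        # (postal, street) -> sub-frame; postal -> sorted unique streets
        self._groups = {key: sub for key, sub in df.groupby(["postal_code", "street_norm"])}
        self._streets_by_postal: dict[str, list[str]] = {}
        self._by_street: dict[str, list[tuple[str, str]]] = {}
        for (postal, street) in sorted(self._groups):
            self._streets_by_postal.setdefault(postal, []).append(street)
            self._by_street.setdefault(street, []).append((postal, street))
        self._all_keys = sorted(self._groups)


@dataclass
class GeocodeResult:
    x: float | None
    y: float | None
    similarity: float | None
    method: str  # quick | slow | street_centroid | failed
    matched_key: tuple[str, str] | None = None


def _best_street(street: str, keys, sim_cache: dict) -> tuple[float, list]:
    """Best similarity over candidate (postal, street) keys, with ties."""
    best = -1.0
    ties: list = []
    for key in keys:
        cand = key[1]
        s = sim_cache.get(cand)
        if s is None:
            s = similarity(street, cand)
            sim_cache[cand] = s
        if s > best + 1e-12:
            best, ties = s, [key]
        elif abs(s - best) <= 1e-12:
            ties.append(key)
    return best, ties


def _resolve(registry: Registry, key: tuple[str, str], number: str | None,
             sim: float, pass_name: str) -> GeocodeResult:
    sub = registry._groups[key]
    if number is not None:
        hit = sub[sub["street_number"] == number]
        if len(hit):
            row = hit.iloc[0]
            return GeocodeResult(float(row["x"]), float(row["y"]), sim,
                                 pass_name, key)
    # number missing or not found on the street -> street centroid
    return GeocodeResult(float(sub["x"].mean()), float(sub["y"].mean()), sim,
                         "street_centroid", key)


def geocode(raw: str, registry: Registry, postal_code: str | None = None,
            threshold: float = 0.80) -> GeocodeResult:
    """Two-step fuzzy geocode of one address.

    Quick pass: only registry streets sharing ``postal_code``.  If the best
    similarity there is below ``threshold``, the slow pass widens the search
    to the whole registry (canton level).  Equal-similarity ties prefer the
    address's own postal code, then the lexicographically smallest
    (postal, street) key.  Below threshold everywhere → method "failed".
    """
    try:
        street, number = normalize_address(raw, registry.abbreviations)
    except AddressNormalizationError:
        return GeocodeResult(None, None, None, "failed")
    if not street:
        return GeocodeResult(None, None, None, "failed")
    sim_cache: dict[str, float] = {}
    postal = None if postal_code is None else str(postal_code)

    if postal is not None and postal in registry._streets_by_postal:
        # exact-name short circuit (equivalent to, but faster than, scanning)
        if (postal, street) in registry._groups:
            return _resolve(registry, (postal, street), number, 1.0, "quick")
        keys = [(postal, s) for s in registry._streets_by_postal[postal]]
        best, ties = _best_street(street, keys, sim_cache)
        if best >= threshold:
            return _resolve(registry, ties[0], number, best, "quick")

    if street in registry._by_street:
        key = registry._by_street[street][0]
        return _resolve(registry, key, number, 1.0, "slow")
    best, ties = _best_street(street, registry._all_keys, sim_cache)
    if best < threshold:
        return GeocodeResult(None, None, best, "failed")
    same_postal = [k for k in ties if k[0] == postal]
    key = (same_postal or ties)[0]
    return _resolve(registry, key, number, best, "slow")


def geocode_table(addresses: pd.DataFrame, registry: Registry,
                  threshold: float = 0.80) -> pd.DataFrame:
    """Geocode a table with columns address (raw string) and postal_code.

    Returns the input ids with x, y, similarity, method columns appended.
    """
    cache: dict[tuple, tuple] = {}
    recs = []
    for raw, postal in zip(addresses["address"], addresses["postal_code"]):
        key = (raw, postal)
        rec = cache.get(key)
        if rec is None:
            r = geocode(raw, registry, postal_code=postal, threshold=threshold)
            rec = cache[key] = (r.x, r.y, r.similarity, r.method)
        recs.append(rec)
    out = addresses.copy()
    out[["x", "y", "similarity", "method"]] = pd.DataFrame(recs, index=out.index)
    return out


def review_band(results: pd.DataFrame, low: float = 0.75,
                high: float = 0.85) -> pd.DataFrame:
    """Rows whose similarity sits near the acceptance threshold.

    Stand-in for interactive manual review: exported so a user can audit
    borderline matches (both false negatives just below and false positives
    just above the cut).
    """
    sim = results["similarity"]
    return results[sim.notna() & (sim >= low) & (sim <= high)]
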