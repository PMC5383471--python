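"""In-silico restriction digestion and mtDNA haplotype calling.

The assay digitalized here: a 389-bp CytB amplicon is digested with
Hinf I (recognition motif GANTC, cut after the leading G), and the
fragment-length pattern read off a gel distinguishes the European
(abietinus) haplotype, the common Siberian (tristis) haplotype, and a
second Siberian haplotype (tristis-2) one substitution away from
tristis. GANTC is its own reverse complement, so a single-strand scan
finds every site.

Coordinates are 0-based between-base cut positions internally (a cut at
coordinate c leaves c bases to its left); user-facing reports are
1-based.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from ._util import percent_of_total

_IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_SEQUENCE_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction endonuclease: IUPAC motif plus cut offset.

    ``cut_offset`` counts bases from the motif start to the cut, so
    Hinf I (G^ANTC) has offset 1.
    """

    name: str
    motif: str
    cut_offset: int

    def __post_init__(self) -> None:
        if len(self.motif) < 1:
            raise ValueError("motif must be non-empty")
        if not 0 <= self.cut_offset <= len(self.motif):
            raise ValueError("cut offset outside motif")
        for ch in self.motif:
            if ch not in _IUPAC:
                raise ValueError(f"{ch!r} is not an IUPAC nucleotide code")


HINF_I = RestrictionEnzyme(name="HinfI", motif="GANTC", cut_offset=1)


@dataclass(frozen=True)
class FragmentPattern:
    """Ordered fragment lengths from a linear digest."""

    lengths: tuple[int, ...]
    source_length: int

    def __post_init__(self) -> None:
        if sum(self.lengths) != self.source_length:
            raise ValueError("fragment lengths must sum to the source length")
        if any(l < 1 for l in self.lengths):
            raise ValueError("fragment lengths must be >= 1")

    @property
    def multiset(self) -> tuple[int, ...]:
        """Lengths sorted ascending — what a gel lane resolves."""
        return tuple(sorted(self.lengths))


@dataclass(frozen=True)
class HaplotypeCall:
    call: str  # haplotype name or "unknown"
    pattern: FragmentPattern

    @property
    def known(self) -> bool:
        return self.call != "unknown"


def _validate_sequence(sequence: str) -> str:
    sequence = sequence.upper()
    bad = set(sequence) - _SEQUENCE_ALPHABET
    if bad:
        raise ValueError(f"sequence contains non-nucleotide characters: {sorted(bad)}")
    return sequence


def _matches(window: str, motif: str) -> bool:
    # A motif N matches any base; a sequence N only matches motif N.
    return all(
        (m == "N") or (s in _IUPAC[m] and s != "N") for s, m in zip(window, motif)
    )


def find_sites(sequence: str, enzyme: RestrictionEnzyme = HINF_I) -> list[int]:
    """All cut positions (0-based, between-base) on a linear sequence.

    Overlapping motif occurrences each contribute a cut; duplicate cut
    coordinates (possible with overlapping occurrences) are collapsed.
    """
    sequence = _validate_sequence(sequence)
    m = len(enzyme.motif)
    cuts = {
        i + enzyme.cut_offset
        for i in range(len(sequence) - m + 1)
        if _matches(sequence[i : i + m], enzyme.motif)
    }
    # cuts flush with either end split nothing
    return sorted(c for c in cuts if 0 < c < len(sequence))


def digest(sequence: str, enzyme: RestrictionEnzyme = HINF_I) -> FragmentPattern:
    """Fragment pattern of a linear digest; lengths sum to the input length."""
    sequence = _validate_sequence(sequence)
    cuts = find_sites(sequence, enzyme)
    bounds = [0, *cuts, len(sequence)]
    lengths = tuple(b - a for a, b in zip(bounds, bounds[1:]))
    return FragmentPattern(lengths=lengths, source_length=len(sequence))


def reference_patterns(
    template, enzyme: RestrictionEnzyme = HINF_I
) -> dict[str, FragmentPattern]:
    """Digest the template's haplotype sequences into reference patterns.

    Raises if two haplotypes share a fragment multiset — such an enzyme/
    template combination cannot discriminate and is a configuration
    error, not a scoring outcome.
    """
    patterns = {
        lineage: digest(template.sequence(lineage), enzyme)
        for lineage in template.lineages
    }
    seen: dict[tuple[int, ...], str] = {}
    for name, pat in patterns.items():
        if pat.multiset in seen:
            raise ValueError(
                f"haplotypes {seen[pat.multiset]!r} and {name!r} give identical "
                f"fragment patterns {pat.multiset}; enzyme cannot discriminate"
            )
        seen[pat.multiset] = name
    return patterns


def call_haplotype(
    observed: FragmentPattern | str,
    references: Mapping[str, FragmentPattern],
    enzyme: RestrictionEnzyme = HINF_I,
) -> HaplotypeCall:
    """Match an observed digest (or raw sequence) against reference patterns.

    Matching is exact on the fragment-length multiset — the digital
    stand-in for scoring discrete gel patterns. No match → "unknown".
    """
    if isinstance(observed, str):
        observed = digest(observed, enzyme)
    for name, pat in references.items():
        if observed.multiset == pat.multiset:
            return HaplotypeCall(call=name, pattern=observed)
    return HaplotypeCall(call="unknown", pattern=observed)


def call_cohort(
    sequences: Iterable, references: Mapping[str, FragmentPattern],
    enzyme: RestrictionEnzyme = HINF_I,
) -> pd.DataFrame:
    """Call haplotypes for Bio SeqRecords (or (id, seq) pairs) -> tidy table."""
    rows = []
    for rec in sequences:
        if hasattr(rec, "seq"):
            sid, seq = rec.id, str(rec.seq)
        else:
            sid, seq = rec
        hc = call_haplotype(seq, references, enzyme)
        rows.append(
            {"id": sid, "call": hc.call, "pattern": "/".join(map(str, hc.pattern.multiset))}
        )
    return pd.DataFrame(rows)


def haplotype_frequencies(
    calls: pd.DataFrame,
    group_tristis: bool = True,
    side_column: str | None = None,
) -> dict:
    """Per-region haplotype counts/percentages, optionally a west/east test.

    ``calls`` needs columns ``call`` and ``region``. With
    ``group_tristis`` the two Siberian haplotypes are merged into a
    single "tristis" class (as when mapping haplotype frequencies across
    the zone). If ``side_column`` names a west/east column, a
    Yates-corrected 2x2 chi-square of abietinus-vs-tristis counts
    between the two sides is included.
    """
    from .popgen import chi2_2x2

    df = calls.copy()
    if group_tristis:
        df["call"] = df["call"].replace({"tristis-2": "tristis"})

    tables = {}
    for region, sub in df.groupby("region", dropna=False):
        counts = Counter(sub["call"])
        total = sum(counts.values())
        tables[region] = pd.DataFrame(
            {
                "call": list(counts),
                "count": list(counts.values()),
                "percent": [percent_of_total(c, total) for c in counts.values()],
            }
        )
    counts = Counter(df["call"])
    total = sum(counts.values())
    tables["total"] = pd.DataFrame(
        {
            "call": list(counts),
            "count": list(counts.values()),
            "percent": [percent_of_total(c, total) for c in counts.values()],
        }
    )

    result: dict = {"tables": tables}
    if side_column is not None and side_column in df.columns:
        sides = [s for s in df[side_column].dropna().unique()]
        if len(sides) == 2:
            s1 = df[df[side_column] == sides[0]]
            s2 = df[df[side_column] == sides[1]]
            a, b = (s1["call"] == "abietinus").sum(), (s1["call"] == "tristis").sum()
            c, d = (s2["call"] == "abietinus").sum(), (s2["call"] == "tristis").sum()
            stat, dof, p = chi2_2x2(int(a), int(b), int(c), int(d), continuity=True)
            result["side_test"] = {
                "sides": tuple(sides), "table": ((int(a), int(b)), (int(c), int(d))),
                "chi2": stat, "df": dof, "p_value": p,
            }
    return result
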