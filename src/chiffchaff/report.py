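"""Per-individual joins and summary tables across all characters.

Joins genotype-derived ancestry, mtDNA haplotype, morphotype and song
call per individual and emits the cohort summary: per-region counts and
one-decimal percentages per categorical character, per-region means of
the nuclear ancestry fractions, and pairwise concordance cross-tabs
(e.g. how often an abietinus-morphotype bird carries tristis mtDNA).
Denominators differ per character — each uses only the individuals
scored for it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from ._util import percent_of_total

CATEGORICAL_CHARACTERS = ("morphotype", "song_call", "mtdna_call")
NUCLEAR_COLUMNS = ("hom_a", "hom_b", "het", "q_hat")


@dataclass(frozen=True)
class IndividualSummary:
    """One male's scored characters; any subset may be missing (None)."""

    id: str
    region: str
    morphotype: str | None = None
    song_call: str | None = None
    mtdna_call: str | None = None
    hom_a: float | None = None
    hom_b: float | None = None
    het: float | None = None
    q_hat: float | None = None

    def __post_init__(self) -> None:
        scored = [
            self.morphotype, self.song_call, self.mtdna_call, self.q_hat,
        ]
        if all(v is None for v in scored):
            raise ValueError(f"individual {self.id!r} has no scored character")


def summaries_to_frame(summaries: Sequence[IndividualSummary]) -> pd.DataFrame:
    ids = [s.id for s in summaries]
    if len(set(ids)) != len(ids):
        raise ValueError("individual ids must be unique")
    return pd.DataFrame([s.__dict__ for s in summaries])


def _categorical_table(df: pd.DataFrame, character: str) -> pd.DataFrame:
    """Counts and percentages per region and total for one character."""
    scored = df[df[character].notna()]
    regions = list(dict.fromkeys(scored["region"])) if len(scored) else []
    levels = list(dict.fromkeys(scored[character])) if len(scored) else []
    rows = []
    for region in regions + ["total"]:
        sub = scored if region == "total" else scored[scored["region"] == region]
        total = len(sub)
        for level in levels:
            n = int((sub[character] == level).sum())
            rows.append(
                {
                    "character": character,
                    "region": region,
                    "level": level,
                    "count": n,
                    "n_scored": total,
                    "percent": percent_of_total(n, total) if total else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def summary_table(
    summaries: Sequence[IndividualSummary] | pd.DataFrame,
) -> dict[str, pd.DataFrame]:
    """Cohort summary: one table per character plus nuclear means.

    Every percentage is recomputed from its emitted count and scored-n
    before returning (self-consistency check).
    """
    df = (
        summaries
        if isinstance(summaries, pd.DataFrame)
        else summaries_to_frame(summaries)
    )
    tables: dict[str, pd.DataFrame] = {}
    for character in CATEGORICAL_CHARACTERS:
        if character in df.columns:
            tables[character] = _categorical_table(df, character)

    if all(c in df.columns for c in NUCLEAR_COLUMNS):
        scored = df[df["q_hat"].notna()]
        if len(scored):
            rows = []
            regions = list(dict.fromkeys(scored["region"]))
            for region in regions + ["total"]:
                sub = scored if region == "total" else scored[scored["region"] == region]
                rows.append(
                    {
                        "region": region,
                        "n_scored": len(sub),
                        **{c: float(sub[c].mean()) for c in NUCLEAR_COLUMNS},
                    }
                )
            tables["nuclear"] = pd.DataFrame(rows)

    _check_self_consistency(tables)
    return tables


def _check_self_consistency(tables: Mapping[str, pd.DataFrame]) -> None:
    for name, table in tables.items():
        if name == "nuclear" or len(table) == 0:
            continue
        for _, row in table.iterrows():
            if row["n_scored"] == 0:
                continue
            expect = percent_of_total(int(row["count"]), int(row["n_scored"]))
            if expect != row["percent"]:  # pragma: no cover - integrity guard
                raise AssertionError(
                    f"{name}: emitted percent {row['percent']} does not "
                    f"recompute from {row['count']}/{row['n_scored']}"
                )


def concordance(
    summaries: Sequence[IndividualSummary] | pd.DataFrame,
    characters: Sequence[str] = CATEGORICAL_CHARACTERS,
) -> dict[tuple[str, str], pd.DataFrame | None]:
    """Pairwise cross-tabulations of categorical characters.

    For each character pair, individuals scored for both are
    cross-tabulated (counts). A pair with empty overlap maps to None —
    the table is omitted rather than fabricated.
    """
    df = (
        summaries
        if isinstance(summaries, pd.DataFrame)
        else summaries_to_frame(summaries)
    )
    out: dict[tuple[str, str], pd.DataFrame | None] = {}
    for i, c1 in enumerate(characters):
        for c2 in characters[i + 1 :]:
            if c1 not in df.columns or c2 not in df.columns:
                continue
            both = df[df[c1].notna() & df[c2].notna()]
            out[(c1, c2)] = (
                pd.crosstab(both[c1], both[c2]) if len(both) else None
            )
    return out


def character_given(
    summaries: pd.DataFrame, condition: str, value: str, character: str
) -> pd.DataFrame:
    """Distribution of ``character`` among individuals where
    ``condition == value`` (counts and percentages) — e.g. the mtDNA
    type of distinctly abietinus-morphotype birds."""
    sub = summaries[
        (summaries[condition] == value) & summaries[character].notna()
    ]
    total = len(sub)
    rows = []
    for level, n in sub[character].value_counts().items():
        rows.append(
            {
                "level": level,
                "count": int(n),
                "percent": percent_of_total(int(n), total),
            }
        )
    return pd.DataFrame(rows)


def mixed_ancestry_mismatches(
    summaries: pd.DataFrame, q_low: float = 0.1, q_high: float = 0.9
) -> pd.DataFrame:
    """Individuals with a pure morphotype but an intermediate hybrid index."""
    df = summaries[summaries["q_hat"].notna()]
    mask = (
        df["morphotype"].isin(["abietinus", "tristis"])
        & (df["q_hat"] > q_low)
        & (df["q_hat"] < q_high)
    )
    return df.loc[mask, ["id", "region", "morphotype", "q_hat"]].reset_index(
        drop=True
    )


def write_tables(tables: Mapping[str, pd.DataFrame], outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, table in tables.items():
        table.to_csv(outdir / f"summary_{name}.tsv", sep="\t", index=False)


def parse_table(path: str | Path) -> pd.DataFrame:
    """Read back an emitted summary TSV (round-trip of counts)."""
    return pd.read_csv(path, sep="\t")
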