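"""Diploid genotype matrix container and VCF / sample-table I/O.

The central in-memory object is :class:`GenotypeMatrix`: biallelic SNP
sites (rows) by samples (columns), genotypes coded as alt-allele counts
0/1/2 with ``-1`` for a missing call, plus optional per-call genotype
quality (GQ) and read depth (DP). Samples carry a population-group label
(e.g. ``allopatric_abietinus``, ``sympatric_north``) and free extra
metadata columns.

VCF reading goes through cyvcf2; writing emits minimal standard
multi-sample VCF v4.2 text (GT, optional GQ/DP), which round-trips
through cyvcf2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING: int = -1

#: cyvcf2 gt_types encoding -> alt-allele count coding used here
_CYVCF2_CODE = {0: 0, 1: 1, 3: 2, 2: MISSING}


@dataclass
class GenotypeMatrix:
    """Sites x samples diploid genotype calls.

    Parameters
    ----------
    sites
        DataFrame with columns ``contig``, ``pos`` (1-based), ``ref``,
        ``alt``; one row per biallelic site, unique by (contig, pos).
    genotypes
        int8 array of shape (n_sites, n_samples); 0 = hom-ref,
        1 = het, 2 = hom-alt, -1 = missing.
    samples
        DataFrame with at least ``id`` and ``group`` columns; extra
        columns (region, morphotype, true ancestry fraction ...) ride
        along untouched.
    gq, dp
        Optional per-call genotype quality / depth arrays, same shape
        as ``genotypes``.
    """

    sites: pd.DataFrame
    genotypes: np.ndarray
    samples: pd.DataFrame
    gq: np.ndarray | None = None
    dp: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"genotype array shape {self.genotypes.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        for arr_name in ("gq", "dp"):
            arr = getattr(self, arr_name)
            if arr is not None and arr.shape != self.genotypes.shape:
                raise ValueError(f"{arr_name} shape mismatch")
        if self.sites.duplicated(subset=["contig", "pos"]).any():
            raise ValueError("duplicate (contig, pos) site records")
        if "group" not in self.samples.columns or "id" not in self.samples.columns:
            raise ValueError("samples table needs 'id' and 'group' columns")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be in {0, 1, 2, -1}")

    # -- basic geometry -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["id"])

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.samples["group"]))

    def group_mask(self, group: str) -> np.ndarray:
        mask = (self.samples["group"] == group).to_numpy()
        if not mask.any():
            raise KeyError(f"no samples in group {group!r}")
        return mask

    def called(self) -> np.ndarray:
        """Boolean mask of non-missing calls, same shape as genotypes."""
        return self.genotypes != MISSING

    # -- subsetting -----------------------------------------------------
    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the given site rows (bool mask or indices)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            sites=self.sites.iloc[index],
            genotypes=self.genotypes[index],
            samples=self.samples.copy(),
            gq=None if self.gq is None else self.gq[index],
            dp=None if self.dp is None else self.dp[index],
        )

    def take_samples(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            mask = np.flatnonzero(mask)
        return GenotypeMatrix(
            sites=self.sites.copy(),
            genotypes=self.genotypes[:, mask],
            samples=self.samples.iloc[mask],
            gq=None if self.gq is None else self.gq[:, mask],
            dp=None if self.dp is None else self.dp[:, mask],
        )

    # -- per-group summaries used throughout the pipeline ----------------
    def called_counts_by_group(self) -> pd.DataFrame:
        """Per-site count of called genotypes in each group (sites x groups)."""
        data = {}
        for g in self.groups:
            m = self.group_mask(g)
            data[g] = (self.genotypes[:, m] != MISSING).sum(axis=1)
        return pd.DataFrame(data)

    def allele_counts(self, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(alt allele count, called allele total) per site for a sample mask."""
        sub = self.genotypes[:, mask]
        called = sub != MISSING
        alt = np.where(called, sub, 0).sum(axis=1)
        return alt, 2 * called.sum(axis=1)


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal multi-sample VCF v4.2 (GT, plus GQ/DP when present)."""
    path = Path(path)
    has_gq, has_dp = matrix.gq is not None, matrix.dp is not None
    fmt_keys = ["GT"] + (["GQ"] if has_gq else []) + (["DP"] if has_dp else [])
    fmt = ":".join(fmt_keys)
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}

    lines = ["##fileformat=VCFv4.2", "##source=chiffchaff"]
    for contig in dict.fromkeys(matrix.sites["contig"]):
        length = int(matrix.sites.loc[matrix.sites["contig"] == contig, "pos"].max()) + 1
        lines.append(f"##contig=<ID={contig},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if has_gq:
        lines.append('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">')
    if has_dp:
        lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.sample_ids)
    )
    sites = matrix.sites
    for i in range(matrix.n_sites):
        calls = []
        for j in range(matrix.n_samples):
            parts = [gt_str[int(matrix.genotypes[i, j])]]
            if has_gq:
                parts.append(str(int(matrix.gq[i, j])))
            if has_dp:
                parts.append(str(int(matrix.dp[i, j])))
            calls.append(":".join(parts))
        lines.append(
            f"{sites['contig'].iat[i]}\t{sites['pos'].iat[i]}\t.\t"
            f"{sites['ref'].iat[i]}\t{sites['alt'].iat[i]}\t.\tPASS\t.\t{fmt}\t"
            + "\t".join(calls)
        )
    path.write_text("\n".join(lines) + "\n")


def read_vcf(
    path: str | Path,
    sample_groups: Mapping[str, str] | pd.DataFrame | None = None,
) -> GenotypeMatrix:
    """Load a multi-sample VCF into a :class:`GenotypeMatrix`.

    Multiallelic records are dropped (the analysis is defined on biallelic
    SNPs only); a count of dropped records is logged. ``sample_groups``
    maps sample id -> group, or is a samples DataFrame/TSV-shaped frame
    with ``id``/``group`` columns; samples absent from it get group
    ``"unknown"``.
    """
    from cyvcf2 import VCF

    if isinstance(sample_groups, pd.DataFrame):
        sample_groups = dict(zip(sample_groups["id"], sample_groups["group"]))

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    contigs, poss, refs, alts = [], [], [], []
    gts, gqs, dps = [], [], []
    n_multi = 0
    any_gq = any_dp = False
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_multi += 1
            continue
        contigs.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        gts.append([_CYVCF2_CODE[t] for t in rec.gt_types])
        try:
            gq = rec.format("GQ")
        except KeyError:
            gq = None
        try:
            dp = rec.format("DP")
        except KeyError:
            dp = None
        if gq is not None:
            any_gq = True
            gqs.append(gq[:, 0])
        else:
            gqs.append(None)
        if dp is not None:
            any_dp = True
            dps.append(dp[:, 0])
        else:
            dps.append(None)
    vcf.close()
    if n_multi:
        log.warning("dropped %d multiallelic / non-SNP records", n_multi)

    sites = pd.DataFrame({"contig": contigs, "pos": poss, "ref": refs, "alt": alts})
    genotypes = np.asarray(gts, dtype=np.int8).reshape(len(sites), len(ids))

    def _stack(rows, present):
        if not present:
            return None
        out = np.zeros((len(rows), len(ids)), dtype=np.int32)
        for i, r in enumerate(rows):
            if r is not None:
                out[i] = np.where(r < 0, 0, r)  # cyvcf2 encodes missing as INT_MIN
        return out

    groups = [
        (sample_groups or {}).get(s, "unknown") if sample_groups is not None else "unknown"
        for s in ids
    ]
    samples = pd.DataFrame({"id": ids, "group": groups})
    return GenotypeMatrix(
        sites=sites,
        genotypes=genotypes,
        samples=samples,
        gq=_stack(gqs, any_gq),
        dp=_stack(dps, any_dp),
    )


# ---------------------------------------------------------------------------
# Sample-metadata table
# ---------------------------------------------------------------------------

def read_sample_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "id" not in df.columns or "group" not in df.columns:
        raise ValueError("sample table needs 'id' and 'group' columns")
    return df


def write_sample_table(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False)
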