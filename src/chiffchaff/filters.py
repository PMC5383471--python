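"""SNP retention rules and per-genotype quality gates.

Two site-retention regimes are implemented, mirroring the two data sets
the analysis works with:

* **high stringency** — a site is kept only if it has a called genotype
  in at least ``min_called`` (default 9) of the individuals in *every*
  population group (default: all four groups). This is the data set
  used for F_ST and PCA.
* **low stringency** — a site is kept if it is present in at least
  ``min_called`` (default 6) individuals in *each of the two allopatric
  reference groups*; sympatric call counts are unconstrained. This is
  the data set used for fixed/shared/private classification and
  diagnostic-SNP ancestry.

"Present" in the low-stringency rule is read as "genotype called", by
analogy with the high-stringency rule's phrasing; an alternative reading
("carries the alternate allele") is available via ``presence``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class StringencyFilter:
    """A site-retention rule.

    mode
        ``"high"`` (all constrained groups) or ``"low"`` (allopatric
        pair only).
    min_called
        Inclusive per-group threshold; defaults to 9 (high) / 6 (low).
    groups
        Groups the rule constrains. ``None`` means: every group in the
        matrix (high mode) — low mode requires the two reference groups
        to be given explicitly or present as the matrix's allopatric
        groups.
    presence
        ``"called"`` (genotype called, the default reading) or
        ``"alt_carrier"`` (carries >= 1 alternate allele).
    """

    mode: str
    min_called: int | None = None
    groups: tuple[str, ...] | None = None
    presence: str = "called"

    def __post_init__(self) -> None:
        if self.mode not in ("high", "low"):
            raise ValueError(f"unknown stringency mode {self.mode!r}")
        if self.presence not in ("called", "alt_carrier"):
            raise ValueError(f"unknown presence rule {self.presence!r}")
        if self.min_called is not None and self.min_called < 0:
            raise ValueError("min_called must be non-negative")

    @property
    def threshold(self) -> int:
        return self.min_called if self.min_called is not None else (
            9 if self.mode == "high" else 6
        )


def _constrained_groups(matrix: GenotypeMatrix, filt: StringencyFilter) -> list[str]:
    if filt.groups is not None:
        return list(filt.groups)
    if filt.mode == "high":
        return matrix.groups
    allo = [g for g in matrix.groups if g.startswith("allopatric")]
    if len(allo) != 2:
        raise ValueError(
            "low-stringency rule needs its two reference groups; pass "
            "StringencyFilter(groups=...) or use 'allopatric_*' group names"
        )
    return allo


def apply_stringency(
    matrix: GenotypeMatrix, filt: StringencyFilter
) -> GenotypeMatrix:
    """Retain sites meeting the per-group called-sample thresholds."""
    groups = _constrained_groups(matrix, filt)
    thr = filt.threshold
    keep = np.ones(matrix.n_sites, dtype=bool)
    for g in groups:
        m = matrix.group_mask(g)
        if thr > int(m.sum()):
            raise ValueError(
                f"threshold {thr} exceeds size {int(m.sum())} of group {g!r}"
            )
        sub = matrix.genotypes[:, m]
        if filt.presence == "called":
            count = (sub != MISSING).sum(axis=1)
        else:
            count = (sub >= 1).sum(axis=1)
        keep &= count >= thr
    return matrix.take_sites(keep)


def apply_quality_gates(
    matrix: GenotypeMatrix, min_gq: int = 30, min_dp: int = 5
) -> GenotypeMatrix:
    """Mask calls below the GQ/DP gates; drop sites with no call left.

    Calls with genotype quality < ``min_gq`` or depth < ``min_dp`` are
    set to missing. If the matrix carries no GQ/DP annotations the input
    is returned unchanged with a logged warning.
    """
    if min_gq < 0 or min_dp < 0:
        raise ValueError("quality-gate thresholds must be non-negative")
    if matrix.gq is None and matrix.dp is None:
        log.warning("no GQ/DP annotations present; quality gates are a no-op")
        return matrix
    geno = matrix.genotypes.copy()
    fail = np.zeros(geno.shape, dtype=bool)
    if matrix.gq is not None and min_gq > 0:
        fail |= matrix.gq < min_gq
    if matrix.dp is not None and min_dp > 0:
        fail |= matrix.dp < min_dp
    geno[fail] = MISSING
    out = GenotypeMatrix(
        sites=matrix.sites.copy(),
        genotypes=geno,
        samples=matrix.samples.copy(),
        gq=None if matrix.gq is None else matrix.gq.copy(),
        dp=None if matrix.dp is None else matrix.dp.copy(),
    )
    any_called = (geno != MISSING).any(axis=1)
    return out.take_sites(any_called)


def filter_report(
    matrix_in: GenotypeMatrix, matrix_out: GenotypeMatrix, rule: str
) -> pd.DataFrame:
    """One-row TSV-ready accounting of a filtering step."""
    return pd.DataFrame(
        [
            {
                "rule": rule,
                "sites_in": matrix_in.n_sites,
                "sites_retained": matrix_out.n_sites,
                "sites_removed": matrix_in.n_sites - matrix_out.n_sites,
            }
        ]
    )
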