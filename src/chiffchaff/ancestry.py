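"""Diagnostic-SNP ancestry scoring and a two-source admixture EM.

A *diagnostic panel* is the set of sites fixed for different alleles in
the two allopatric reference groups. Each scored individual's called
panel genotypes split into homozygous-lineage-A, homozygous-lineage-B
and heterozygous fractions (the digital twin of a per-bird stacked
ancestry bar), and the hybrid index

    q_hat = (2 * n_homA + n_het) / (2 * n_called)

is the fraction of allele copies of lineage-A origin: 1 for pure A,
0 for pure B, 0.5 for an F1, 0.25/0.75 for first backcrosses.

The unsupervised counterpart is a minimal K=2 admixture EM maximising
the binomial likelihood of 0/1/2 genotypes under per-sample mixing
proportions and two source allele-frequency vectors. It is a
lightweight assignment model in the spirit of model-based clustering
programs, not a reimplementation of any of them, and is exposed
statsmodels-style as ``AdmixtureModel(...).fit() -> AdmixtureResults``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .popgen import classify_sites


# ---------------------------------------------------------------------------
# Diagnostic panel + supervised scoring
# ---------------------------------------------------------------------------

@dataclass
class DiagnosticPanel:
    """Sites fixed between the allopatric references, with lineage alleles.

    ``sites`` has one row per panel site: the source-matrix row index
    (``row``), contig/pos, and ``allele_a`` — the alt-allele count (0 or
    2... coded as the allele index 0/1) carried by lineage A; lineage B
    carries the other allele.
    """

    sites: pd.DataFrame
    group_a: str
    group_b: str

    def __post_init__(self) -> None:
        if len(self.sites) == 0:
            raise ValueError(
                "empty diagnostic panel: no sites are fixed between "
                f"{self.group_a!r} and {self.group_b!r}"
            )

    def __len__(self) -> int:
        return len(self.sites)


@dataclass
class AncestryProfile:
    """One individual's composition over called panel sites."""

    id: str
    region: str | None
    n_hom_a: int
    n_hom_b: int
    n_het: int
    n_missing: int

    @property
    def n_called(self) -> int:
        return self.n_hom_a + self.n_hom_b + self.n_het

    @property
    def hom_a(self) -> float:
        return self.n_hom_a / self.n_called

    @property
    def hom_b(self) -> float:
        return self.n_hom_b / self.n_called

    @property
    def het(self) -> float:
        return self.n_het / self.n_called

    @property
    def q_hat(self) -> float:
        """Hybrid index: fraction of allele copies of lineage-A origin."""
        return (2 * self.n_hom_a + self.n_het) / (2 * self.n_called)

    def as_dict(self) -> dict:
        return {
            "id": self.id,
            "region": self.region,
            "hom_a": self.hom_a,
            "hom_b": self.hom_b,
            "het": self.het,
            "missing": self.n_missing,
            "q_hat": self.q_hat,
        }


def build_panel(
    matrix: GenotypeMatrix, group_a: str, group_b: str
) -> DiagnosticPanel:
    """All sites classified fixed between the references, in genome order."""
    sc = classify_sites(matrix, group_a, group_b)
    rows = np.sort(sc.site_index("fixed"))
    if rows.size == 0:
        raise ValueError(
            f"empty diagnostic panel: no fixed sites between {group_a!r} "
            f"and {group_b!r}"
        )
    ma = matrix.group_mask(group_a)
    alt_a, tot_a = matrix.allele_counts(ma)
    allele_a = (alt_a[rows] == tot_a[rows]).astype(int)  # 1 iff A fixed for alt
    sites = matrix.sites.iloc[rows][["contig", "pos"]].copy()
    sites.insert(0, "row", rows)
    sites["allele_a"] = allele_a
    return DiagnosticPanel(
        sites=sites.reset_index(drop=True), group_a=group_a, group_b=group_b
    )


def score_individual(
    panel: DiagnosticPanel, matrix: GenotypeMatrix, sample_id: str
) -> AncestryProfile:
    """Ancestry fractions and hybrid index for one sample over the panel."""
    try:
        j = matrix.sample_ids.index(sample_id)
    except ValueError:
        raise KeyError(f"sample {sample_id!r} not in matrix") from None
    rows = panel.sites["row"].to_numpy()
    g = matrix.genotypes[rows, j].astype(int)
    hom_a_code = 2 * panel.sites["allele_a"].to_numpy()  # genotype meaning hom-A
    called = g != MISSING
    if not called.any():
        raise ValueError(f"sample {sample_id!r} has no called panel genotypes")
    n_het = int((g[called] == 1).sum())
    n_hom_a = int((g[called] == hom_a_code[called]).sum())
    n_hom_b = int(called.sum()) - n_het - n_hom_a
    region = None
    if "region" in matrix.samples.columns:
        region = matrix.samples["region"].iloc[j]
    return AncestryProfile(
        id=sample_id,
        region=region,
        n_hom_a=n_hom_a,
        n_hom_b=n_hom_b,
        n_het=n_het,
        n_missing=int((~called).sum()),
    )


def score_cohort(
    panel: DiagnosticPanel,
    matrix: GenotypeMatrix,
    sample_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Profile table (one row per individual): hom_a, hom_b, het, q_hat."""
    ids = list(sample_ids) if sample_ids is not None else matrix.sample_ids
    return pd.DataFrame([score_individual(panel, matrix, s).as_dict() for s in ids])


def aggregate_by_region(profiles: pd.DataFrame) -> pd.DataFrame:
    """Unweighted per-region means of the ancestry fractions, plus overall."""
    if len(profiles) == 0:
        raise ValueError("no profiles to aggregate")
    cols = ["hom_a", "hom_b", "het", "q_hat"]
    out = profiles.groupby("region", dropna=False)[cols].mean().reset_index()
    total = profiles[cols].mean().to_frame().T
    total.insert(0, "region", "total")
    out = pd.concat([out, total], ignore_index=True)
    out.insert(1, "n", list(profiles.groupby("region", dropna=False).size()) + [len(profiles)])
    return out


# ---------------------------------------------------------------------------
# K=2 admixture EM (statsmodels-style model/results pair)
# ---------------------------------------------------------------------------

class AdmixtureModel:
    """Two-source binomial admixture model for a genotype matrix.

    Each sample i has a mixing proportion q_i; each site j has source
    allele frequencies f_Aj, f_Bj. A genotype is Binomial(2, pi_ij) with
    pi_ij = q_i f_Aj + (1 - q_i) f_Bj. ``fit`` runs EM over allele-copy
    source assignments (monotone non-decreasing log-likelihood).

    Parameters
    ----------
    matrix
        Genotype matrix (biallelic sites; missing calls allowed).
    anchor_groups
        Optional (group_A, group_B) pair of declared reference groups.
        When given, source frequencies are initialised from their sample
        frequencies and, after fitting, source A is anchored so that the
        declared group-A samples have the higher mean q (resolving label
        switching).
    """

    def __init__(
        self,
        matrix: GenotypeMatrix,
        anchor_groups: tuple[str, str] | None = None,
    ) -> None:
        if matrix.n_samples < 2:
            raise ValueError("need at least two samples")
        self.matrix = matrix
        self.anchor_groups = anchor_groups

    def _init_freqs(self, rng: np.random.Generator) -> np.ndarray:
        m = self.matrix
        if self.anchor_groups is not None:
            f = np.empty((m.n_sites, 2))
            for k, g in enumerate(self.anchor_groups):
                alt, tot = m.allele_counts(m.group_mask(g))
                # light pseudocount keeps initial frequencies off 0/1
                f[:, k] = (alt + 0.5) / (tot + 1.0)
            return f
        return rng.uniform(0.05, 0.95, size=(m.n_sites, 2))

    def fit(
        self, max_iter: int = 1000, tol: float = 1e-5, seed: int = 0
    ) -> "AdmixtureResults":
        m = self.matrix
        g = m.genotypes.astype(float)
        called = g >= 0
        g = np.where(called, g, 0.0)
        n_called = called.sum(axis=0).astype(float)  # per sample
        if (n_called == 0).any():
            raise ValueError("every sample needs at least one called genotype")

        rng = np.random.default_rng(seed)
        f = self._init_freqs(rng)
        q = np.full(m.n_samples, 0.5)

        eps = 1e-12
        loglik_path: list[float] = []
        converged = False
        for _ in range(max_iter):
            fa, fb = f[:, 0:1], f[:, 1:2]           # (S,1)
            qi = q[None, :]                          # (1,N)
            pi = np.clip(qi * fa + (1 - qi) * fb, eps, 1 - eps)
            ll = float(
                (called * (g * np.log(pi) + (2 - g) * np.log1p(-pi))).sum()
            )
            loglik_path.append(ll)
            if len(loglik_path) > 1 and abs(ll - loglik_path[-2]) < tol:
                converged = True
                break
            # E-step: per-copy source responsibilities
            alt_a = qi * fa / pi                         # P(copy from A | alt)
            ref_a = qi * (1 - fa) / (1 - pi)             # P(copy from A | ref)
            w_alt_a = called * g * alt_a
            w_ref_a = called * (2 - g) * ref_a
            # M-step
            q = np.clip((w_alt_a + w_ref_a).sum(axis=0) / (2.0 * n_called), 0.0, 1.0)
            denom_a = (w_alt_a + w_ref_a).sum(axis=1)
            denom_b = (
                called * g * (1 - alt_a) + called * (2 - g) * (1 - ref_a)
            ).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                fa_new = w_alt_a.sum(axis=1) / denom_a
                fb_new = (called * g * (1 - alt_a)).sum(axis=1) / denom_b
            f = np.column_stack(
                [
                    np.where(denom_a > 0, fa_new, f[:, 0]),
                    np.where(denom_b > 0, fb_new, f[:, 1]),
                ]
            )

        flipped = False
        if self.anchor_groups is not None:
            mask_a = m.group_mask(self.anchor_groups[0])
            if q[mask_a].mean() < 0.5:
                q, f, flipped = 1.0 - q, f[:, ::-1], True

        return AdmixtureResults(
            model=self,
            q=pd.Series(q, index=m.sample_ids, name="q_hat"),
            source_freqs=f,
            loglik_path=np.asarray(loglik_path),
            converged=converged,
            n_iter=len(loglik_path),
            label_flipped=flipped,
        )


@dataclass
class AdmixtureResults:
    """Fitted K=2 admixture proportions and source frequencies."""

    model: AdmixtureModel
    q: pd.Series
    source_freqs: np.ndarray
    loglik_path: np.ndarray
    converged: bool
    n_iter: int
    label_flipped: bool

    @property
    def loglik(self) -> float:
        return float(self.loglik_path[-1])

    def summary(self) -> str:
        m = self.model.matrix
        lines = [
            "K=2 binomial admixture EM",
            f"  samples: {m.n_samples}   sites: {m.n_sites}",
            f"  log-likelihood: {self.loglik:.2f}  "
            f"({'converged' if self.converged else 'NOT converged'}, "
            f"{self.n_iter} iterations)",
            "",
            f"  {'sample':<12}{'group':<24}{'q_hat':>8}",
        ]
        for sid, grp, qv in zip(m.sample_ids, m.samples["group"], self.q):
            lines.append(f"  {sid:<12}{grp:<24}{qv:>8.3f}")
        return "\n".join(lines)


def em_admixture_k2(
    matrix: GenotypeMatrix,
    max_iter: int = 1000,
    tol: float = 1e-5,
    seed: int = 0,
    anchor_groups: tuple[str, str] | None = None,
) -> AdmixtureResults:
    """Functional wrapper over :class:`AdmixtureModel` (see its docs)."""
    return AdmixtureModel(matrix, anchor_groups=anchor_groups).fit(
        max_iter=max_iter, tol=tol, seed=seed
    )
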