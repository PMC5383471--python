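"""Population-genetic summaries for a pair of groups.

* :func:`classify_sites` — fixed / shared / private-A / private-B /
  invariant categories for two groups, with counts and percentages
  (percentages are taken over the four polymorphism-relevant classes;
  same-allele invariant sites are reported separately).
* :func:`fst` — Weir & Cockerham (1984) theta from per-site variance
  components combined as a ratio of sums, with a delete-one-block
  jackknife standard error over consecutive windows of SNPs (default
  50) in genome order.
* :func:`chi2_2x2` — Pearson chi-square for a 2x2 table, Yates
  continuity correction by default.
* :func:`pca` — genotype PCA on 0/1/2-coded, column-centred data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._util import percent_of_total
from .genotypes import MISSING, GenotypeMatrix

CATEGORIES = ("fixed", "shared", "private_a", "private_b")


# ---------------------------------------------------------------------------
# Fixed / shared / private classification
# ---------------------------------------------------------------------------

@dataclass
class SiteClassification:
    """Per-site polymorphism categories for one pair of groups."""

    group_a: str
    group_b: str
    categories: pd.Series  # index = site row in the source matrix
    n_invariant: int
    n_excluded: int  # sites with no called genotype in one of the groups

    @property
    def counts(self) -> dict[str, int]:
        vc = self.categories.value_counts()
        return {c: int(vc.get(c, 0)) for c in CATEGORIES}

    @property
    def n_classified(self) -> int:
        return len(self.categories)

    @property
    def percentages(self) -> dict[str, float]:
        """Percentages over the four polymorphism classes, one decimal."""
        total = self.n_classified
        return {c: percent_of_total(n, total) for c, n in self.counts.items()}

    def site_index(self, category: str) -> np.ndarray:
        """Row indices (into the source matrix) of sites in a category."""
        return self.categories.index[self.categories == category].to_numpy()

    def to_frame(self) -> pd.DataFrame:
        counts, pct = self.counts, self.percentages
        return pd.DataFrame(
            {
                "category": list(CATEGORIES),
                "count": [counts[c] for c in CATEGORIES],
                "percent": [pct[c] for c in CATEGORIES],
            }
        )


def classify_sites(
    matrix: GenotypeMatrix, group_a: str, group_b: str
) -> SiteClassification:
    """Classify each site as fixed / shared / private / invariant.

    fixed: each group monomorphic for a different allele; shared:
    polymorphic in both; private: polymorphic in exactly one; invariant:
    both monomorphic for the same allele. Sites with no called genotype
    in either group cannot be classified and are excluded (counted).
    """
    ma, mb = matrix.group_mask(group_a), matrix.group_mask(group_b)
    alt_a, tot_a = matrix.allele_counts(ma)
    alt_b, tot_b = matrix.allele_counts(mb)

    ok = (tot_a > 0) & (tot_b > 0)
    poly_a = (alt_a > 0) & (alt_a < tot_a)
    poly_b = (alt_b > 0) & (alt_b < tot_b)
    # for monomorphic groups the single allele is 1 iff alt_x == tot_x
    mono_allele_a = (alt_a == tot_a).astype(int)
    mono_allele_b = (alt_b == tot_b).astype(int)

    cat = np.full(matrix.n_sites, "", dtype=object)
    cat[ok & poly_a & poly_b] = "shared"
    cat[ok & poly_a & ~poly_b] = "private_a"
    cat[ok & ~poly_a & poly_b] = "private_b"
    both_mono = ok & ~poly_a & ~poly_b
    cat[both_mono & (mono_allele_a != mono_allele_b)] = "fixed"
    invariant = both_mono & (mono_allele_a == mono_allele_b)

    rows = np.flatnonzero(ok & ~invariant)
    return SiteClassification(
        group_a=group_a,
        group_b=group_b,
        categories=pd.Series(cat[rows], index=rows),
        n_invariant=int(invariant.sum()),
        n_excluded=int((~ok).sum()),
    )


# ---------------------------------------------------------------------------
# Weir & Cockerham F_ST with block jackknife
# ---------------------------------------------------------------------------

@dataclass
class FstEstimate:
    fst: float
    se: float
    block_size: int
    n_sites: int
    n_blocks: int
    pseudovalues: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.se < 0:  # pragma: no cover - arithmetic guard
            raise ValueError("standard error cannot be negative")


def weir_cockerham_components(
    matrix: GenotypeMatrix, group_a: str, group_b: str, min_called: int = 2
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-site W&C (1984) variance components (a, b, c) for two groups.

    Uses genotype counts per group: sample sizes n_i (called diploid
    individuals), alt-allele frequencies p_i and observed heterozygote
    frequencies h_i; handles unequal sample sizes through the n_c term.
    Returns (a, b, c, used) where ``used`` marks sites with at least
    ``min_called`` called genotypes in both groups.
    """
    r = 2.0
    used = np.ones(matrix.n_sites, dtype=bool)
    ns, ps, hs = [], [], []
    for g in (group_a, group_b):
        sub = matrix.genotypes[:, matrix.group_mask(g)]
        called = sub != MISSING
        n = called.sum(axis=1).astype(float)
        used &= n >= min_called
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(called, sub, 0).sum(axis=1) / (2.0 * n)
            h = np.where(called, sub == 1, False).sum(axis=1) / n
        ns.append(n)
        ps.append(p)
        hs.append(h)

    n1, n2 = ns
    p1, p2 = ps
    h1, h2 = hs
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0
    for arr in (a, b, c):
        arr[~used] = 0.0
        np.nan_to_num(arr, copy=False)
    return a, b, c, used


def fst(
    matrix: GenotypeMatrix,
    group_a: str,
    group_b: str,
    block_size: int = 50,
    min_called: int = 2,
) -> FstEstimate:
    """Mean W&C F_ST = sum(a) / sum(a+b+c), with block-jackknife SE.

    The jackknife deletes consecutive, non-overlapping blocks of
    ``block_size`` used SNPs in genome order and recomputes the ratio of
    sums; SE is the standard delete-one-block jackknife estimate over
    the leave-one-out values. Needs >= 2 blocks.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    a, b, c, used = weir_cockerham_components(matrix, group_a, group_b, min_called)
    a, d = a[used], (a + b + c)[used]
    total_d = d.sum()
    if not np.any(used) or total_d <= 0:
        raise ValueError(
            "F_ST undefined: no usable polymorphic sites between "
            f"{group_a!r} and {group_b!r}"
        )
    theta = a.sum() / total_d

    n_used = int(used.sum())
    n_blocks = int(np.ceil(n_used / block_size))
    if n_blocks < 2:
        raise ValueError("need at least two jackknife blocks; lower block_size")
    block_id = np.arange(n_used) // block_size
    a_blk = np.bincount(block_id, weights=a, minlength=n_blocks)
    d_blk = np.bincount(block_id, weights=d, minlength=n_blocks)
    loo = (a.sum() - a_blk) / (d.sum() - d_blk)
    g = float(n_blocks)
    se = float(np.sqrt((g - 1.0) / g * ((loo - loo.mean()) ** 2).sum()))
    pseudo = g * theta - (g - 1.0) * loo
    return FstEstimate(
        fst=float(theta),
        se=se,
        block_size=block_size,
        n_sites=n_used,
        n_blocks=n_blocks,
        pseudovalues=pseudo,
    )


# ---------------------------------------------------------------------------
# 2x2 chi-square
# ---------------------------------------------------------------------------

def chi2_2x2(
    a: int, b: int, c: int, d: int, continuity: bool = True
) -> tuple[float, int, float]:
    """Pearson chi-square for the table [[a, b], [c, d]]; df = 1.

    Yates continuity correction is applied by default (the convention
    for 2x2 proportion contrasts on modest counts). Returns
    (statistic, df, p-value).
    """
    table = np.array([[a, b], [c, d]])
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("all marginals must be positive")
    stat, p, dof, _ = stats.chi2_contingency(table, correction=continuity)
    return float(stat), int(dof), float(p)


# ---------------------------------------------------------------------------
# Genotype PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    coordinates: pd.DataFrame  # one row per sample: id, group, PC1..PCk
    explained: np.ndarray      # variance-explained fractions, descending


def pca(
    matrix: GenotypeMatrix,
    n_components: int = 2,
    missing: str = "mean",
    scale: bool = False,
) -> PcaResult:
    """PCA of 0/1/2-coded genotypes.

    Missing policy: ``"mean"`` imputes each site's mean called genotype,
    ``"drop"`` removes sites with any missing call. Columns are centred;
    with ``scale`` they are divided by sqrt(p(1-p)) of the estimated
    allele frequency (monomorphic sites are dropped when scaling).
    Components are ordered by decreasing explained variance.
    """
    from sklearn.decomposition import PCA

    if n_components > matrix.n_samples:
        raise ValueError("more components requested than samples")
    if missing not in ("mean", "drop"):
        raise ValueError(f"unknown missing policy {missing!r}")

    geno = matrix.genotypes.astype(float).T  # samples x sites
    mask = geno < 0
    if missing == "drop":
        keep = ~mask.any(axis=0)
        geno, mask = geno[:, keep], mask[:, keep]
    if geno.shape[1] == 0:
        raise ValueError("no sites left for PCA")
    geno = np.ma.masked_array(geno, mask=mask)
    mean = geno.mean(axis=0)
    centred = (geno - mean).filled(0.0)
    if scale:
        p_hat = np.asarray(mean) / 2.0
        sd = np.sqrt(p_hat * (1.0 - p_hat))
        poly = sd > 0
        centred = centred[:, poly] / sd[poly]

    model = PCA(n_components=n_components, svd_solver="full")
    coords = model.fit_transform(centred)
    frame = matrix.samples[["id", "group"]].copy()
    for k in range(n_components):
        frame[f"PC{k + 1}"] = coords[:, k]
    return PcaResult(coordinates=frame, explained=model.explained_variance_ratio_)
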