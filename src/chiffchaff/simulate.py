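"""Synthetic cohorts for the two-lineage hybrid-zone analysis.

Everything downstream (filtering, F_ST, diagnostic-SNP ancestry, RFLP
haplotyping, song classification) is exercised on data from this module,
which emulates the statistical structure of a secondary contact zone
between two diverged chiffchaff lineages:

* Nuclear SNPs follow a Balding–Nichols divergence model: each site has
  an ancestral allele frequency p, and each lineage's frequency is an
  independent Beta draw with mean p and variance F·p·(1−p), so the
  expected Hudson-type F_ST across sites equals the divergence
  parameter F.
* Admixed individuals are modelled at the allele level: each of the two
  allele copies descends from lineage A with probability q (the
  individual's ancestry fraction); q = 0.5 is an F1, 0.25/0.75 first
  backcrosses.
* The mitochondrial marker is a 389-bp CytB amplicon carrying five
  lineage-diagnostic substitutions, three of which are assayed by Hinf I
  (GANTC) digestion; a second Siberian haplotype (tristis-2) differs
  from the common tristis haplotype at exactly one of those positions.
* Song features per male are note rate (notes/s), note frequency band
  (kHz) and percentage of ascending elements, drawn uniformly inside
  each lineage's documented range; mixed singers fall in the inter-range
  gap and combine both note classes.

All draws are driven by numpy Generators seeded from the model/scenario,
so a fixed seed gives byte-identical VCF/FASTA/TSV output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genotypes import MISSING, GenotypeMatrix

LINEAGE_A = "abietinus"  # European chiffchaff, lineage A throughout
LINEAGE_B = "tristis"    # Siberian chiffchaff, lineage B

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Nuclear SNP divergence model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DivergenceModel:
    """Balding–Nichols two-lineage divergence model.

    Parameters
    ----------
    n_sites
        Number of biallelic loci (≥ 1).
    fst
        Divergence parameter F in [0, 1): the expected between-lineage
        F_ST. F = 0 means both lineages share the ancestral frequency
        exactly.
    ancestral_freq_range
        Bounds of the uniform law for the ancestral allele frequency p.
        Kept away from 0/1 so the Beta parameters stay non-degenerate.
    missing_rate
        Per-genotype probability of a missing call.
    seed
        RNG seed; identical seed + parameters give identical output.
    """

    n_sites: int = 20_000
    fst: float = 0.062
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst (divergence F) must lie in [0, 1)")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")
        lo, hi = self.ancestral_freq_range
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("ancestral_freq_range must satisfy 0 < lo < hi < 1")


class LineageFrequencies(NamedTuple):
    """Per-site allele frequencies: ancestral and one per lineage."""

    ancestral: np.ndarray
    lineage_a: np.ndarray
    lineage_b: np.ndarray


def draw_lineage_frequencies(
    model: DivergenceModel, rng: np.random.Generator | None = None
) -> LineageFrequencies:
    """Draw paired per-site allele frequencies for the two lineages.

    Each lineage frequency is Beta(p(1−F)/F, (1−p)(1−F)/F), i.e. mean p
    and variance F·p·(1−p). With F = 0 the Beta degenerates and both
    lineages inherit p exactly (no division by zero).
    """
    rng = np.random.default_rng(model.seed) if rng is None else rng
    lo, hi = model.ancestral_freq_range
    p = rng.uniform(lo, hi, size=model.n_sites)
    if model.fst == 0.0:
        return LineageFrequencies(p, p.copy(), p.copy())
    ratio = (1.0 - model.fst) / model.fst
    alpha, beta = p * ratio, (1.0 - p) * ratio
    pa = rng.beta(alpha, beta)
    pb = rng.beta(alpha, beta)
    return LineageFrequencies(p, pa, pb)


# ---------------------------------------------------------------------------
# Admixture scenario
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleSpec:
    """One simulated diploid male: id, population group, ancestry fraction q.

    ``cross="f1"`` marks a true first-generation hybrid: one allele copy
    is drawn from each lineage at every site (heterozygous at every
    fixed difference), instead of the default allele-level model where
    each copy independently descends from lineage A with probability q.
    """

    id: str
    group: str
    q: float
    region: str | None = None
    cross: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.q <= 1.0:
            raise ValueError(f"ancestry fraction q={self.q} outside [0, 1]")
        if self.cross not in (None, "f1"):
            raise ValueError(f"unknown cross {self.cross!r}")
        if self.cross == "f1" and self.q != 0.5:
            raise ValueError("an F1 has ancestry fraction q = 0.5")

    @property
    def morphotype(self) -> str:
        """Plumage class implied by ancestry: mostly-A, mostly-B or intermediate."""
        if self.q >= 0.7:
            return LINEAGE_A
        if self.q <= 0.3:
            return LINEAGE_B
        return "intermediate"


# Default sympatric ancestry fractions. The north is strongly biased
# toward tristis (mean q ≈ 0.25), the south less so (mean q ≈ 0.40),
# mirroring the introgression gradient the analysis is designed to
# detect; each set mixes near-pure birds, F1-like birds and backcrosses.
NORTH_Q = (0.9, 0.5, 0.25, 0.25, 0.1, 0.1, 0.05, 0.05, 0.25, 0.0)
SOUTH_Q = (1.0, 0.9, 0.75, 0.5, 0.4, 0.25, 0.1, 0.05, 0.05, 0.0)

GROUP_ALLO_A = f"allopatric_{LINEAGE_A}"
GROUP_ALLO_B = f"allopatric_{LINEAGE_B}"
GROUP_NORTH = "sympatric_north"
GROUP_SOUTH = "sympatric_south"


@dataclass(frozen=True)
class AdmixtureScenario:
    """A cohort of samples with known ancestry fractions."""

    samples: tuple[SampleSpec, ...]

    def __post_init__(self) -> None:
        ids = [s.id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample ids must be unique")
        if not self.samples:
            raise ValueError("scenario needs at least one sample")

    @classmethod
    def default_cohort(
        cls,
        n_per_group: int = 10,
        north_q: Sequence[float] = NORTH_Q,
        south_q: Sequence[float] = SOUTH_Q,
    ) -> "AdmixtureScenario":
        """Four groups of ``n_per_group``: two allopatric references
        (pure q = 1 / q = 0) and two admixed sympatric regions."""

        def cycle(qs: Sequence[float], n: int) -> list[float]:
            return [qs[i % len(qs)] for i in range(n)]

        samples: list[SampleSpec] = []
        samples += [
            SampleSpec(f"A{i + 1}", GROUP_ALLO_A, 1.0, region="allopatry_west")
            for i in range(n_per_group)
        ]
        samples += [
            SampleSpec(f"T{i + 1}", GROUP_ALLO_B, 0.0, region="allopatry_east")
            for i in range(n_per_group)
        ]
        samples += [
            SampleSpec(f"N{i + 1}", GROUP_NORTH, q, region="north")
            for i, q in enumerate(cycle(north_q, n_per_group))
        ]
        samples += [
            SampleSpec(f"S{i + 1}", GROUP_SOUTH, q, region="south")
            for i, q in enumerate(cycle(south_q, n_per_group))
        ]
        return cls(tuple(samples))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [s.id for s in self.samples],
                "group": [s.group for s in self.samples],
                "region": [s.region for s in self.samples],
                "q_true": [s.q for s in self.samples],
                "morphotype": [s.morphotype for s in self.samples],
            }
        )


def simulate_genotypes(
    frequencies: LineageFrequencies,
    scenario: AdmixtureScenario,
    model: DivergenceModel,
    rng: np.random.Generator | None = None,
    mean_depth: float | None = None,
) -> GenotypeMatrix:
    """Draw diploid genotypes for every sample in the scenario.

    Each of a sample's two allele copies comes from lineage A's frequency
    with probability q, else lineage B's; the alt-allele count is the sum
    over copies. Missing calls are injected at ``model.missing_rate``.
    When ``mean_depth`` is given, per-call DP ~ Poisson(mean_depth) and a
    rough GQ in [30, 99] are attached so quality gates can be exercised.
    """
    rng = np.random.default_rng(model.seed + 1) if rng is None else rng
    n_sites = len(frequencies.ancestral)
    n_samples = len(scenario.samples)
    pa, pb = frequencies.lineage_a, frequencies.lineage_b

    geno = np.empty((n_sites, n_samples), dtype=np.int8)
    for j, spec in enumerate(scenario.samples):
        if spec.cross == "f1":
            # true F1: exactly one copy from each lineage
            from_a = np.tile([True, False], (n_sites, 1))
        else:
            # two independent allele copies per site
            from_a = rng.random((n_sites, 2)) < spec.q
        p_copy = np.where(from_a, pa[:, None], pb[:, None])
        alleles = rng.random((n_sites, 2)) < p_copy
        geno[:, j] = alleles.sum(axis=1)

    if model.missing_rate > 0:
        miss = rng.random(geno.shape) < model.missing_rate
        geno[miss] = MISSING

    gq = dp = None
    if mean_depth is not None:
        dp = rng.poisson(mean_depth, size=geno.shape).astype(np.int32)
        gq = np.minimum(99, 30 + rng.integers(0, 70, size=geno.shape)).astype(np.int32)

    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    sites = pd.DataFrame(
        {
            "contig": "1",
            "pos": np.arange(1, n_sites + 1, dtype=np.int64),
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
        }
    )
    return GenotypeMatrix(
        sites=sites, genotypes=geno, samples=scenario.to_frame(), gq=gq, dp=dp
    )


# ---------------------------------------------------------------------------
# mtDNA amplicon template
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MtdnaTemplate:
    """Synthetic 389-bp CytB amplicon with lineage-diagnostic sites.

    ``reference`` carries the abietinus alleles. Five 0-based positions
    are diagnostic between abietinus and tristis; a 3-site subset is
    assayed by Hinf I digestion, and each assayed substitution toggles a
    GANTC occurrence (so it changes the fragment pattern). tristis-2
    equals tristis except at ``tristis2_position`` (one of the assayed
    sites), where it carries the abietinus state.

    The real amplicon's diagnostic coordinates are not published; these
    synthetic coordinates are fixed by :func:`default_template`.
    """

    reference: str
    diagnostic_positions: tuple[int, ...]
    abietinus_alleles: tuple[str, ...]
    tristis_alleles: tuple[str, ...]
    assayed_positions: tuple[int, ...]
    tristis2_position: int

    def __post_init__(self) -> None:
        if len(self.reference) != 389:
            raise ValueError("amplicon must be 389 bp")
        if len(self.diagnostic_positions) != 5:
            raise ValueError("exactly five diagnostic positions required")
        if not set(self.assayed_positions) <= set(self.diagnostic_positions):
            raise ValueError("assayed subset must lie within the diagnostic set")
        if len(self.assayed_positions) != 3:
            raise ValueError("exactly three assayed positions required")
        if self.tristis2_position not in self.assayed_positions:
            raise ValueError("tristis-2 position must be assayed")
        for pos, a, t in zip(
            self.diagnostic_positions, self.abietinus_alleles, self.tristis_alleles
        ):
            if a == t:
                raise ValueError(f"alleles at {pos} are not diagnostic")
            if self.reference[pos] != a:
                raise ValueError("reference must carry the abietinus alleles")

    def sequence(self, lineage: str) -> str:
        """Amplicon sequence for ``abietinus``, ``tristis`` or ``tristis-2``."""
        if lineage == LINEAGE_A:
            return self.reference
        if lineage not in (LINEAGE_B, "tristis-2"):
            raise ValueError(f"unknown lineage {lineage!r}")
        seq = list(self.reference)
        for pos, allele in zip(self.diagnostic_positions, self.tristis_alleles):
            seq[pos] = allele
        if lineage == "tristis-2":
            idx = self.diagnostic_positions.index(self.tristis2_position)
            seq[self.tristis2_position] = self.abietinus_alleles[idx]
        return "".join(seq)

    @property
    def lineages(self) -> tuple[str, ...]:
        return (LINEAGE_A, LINEAGE_B, "tristis-2")


def default_template() -> MtdnaTemplate:
    """Construct the package's standard synthetic amplicon.

    Design: assayed SNPs sit at the second motif base of a planted
    G[A/x]NTC context so exactly one lineage state completes the motif —
    abietinus cuts at positions 60 and 330, tristis at 200 only, and
    tristis-2 (abietinus state restored at 330) at 200 and 330. Two
    further diagnostic SNPs (135, 270) are embedded in T-rich flanks so
    they cannot touch any GANTC occurrence. The backbone is a fixed
    pseudo-random sequence, repaired so no haplotype carries an
    unplanned GANTC; the three fragment patterns are pairwise distinct
    by construction and re-checked here.
    """
    rng = np.random.default_rng(3890)
    seq = list(rng.choice(list("ACGT"), size=389))

    diagnostic = (60, 135, 200, 270, 330)
    assayed = (60, 200, 330)
    abi = ("A", "C", "G", "G", "A")   # reference (abietinus) states
    tri = ("C", "T", "A", "A", "T")   # tristis states

    # planted motif contexts: G at pos-1, N free, T, C after the SNP
    for pos in assayed:
        seq[pos - 1] = "G"
        seq[pos + 1] = "T"  # concrete value for the motif's N slot
        seq[pos + 2] = "T"
        seq[pos + 3] = "C"
    # non-assayed diagnostic sites get inert T-rich flanks
    for pos in (135, 270):
        for k in range(-4, 5):
            if k != 0:
                seq[pos + k] = "T"
    for pos, a in zip(diagnostic, abi):
        seq[pos] = a

    reserved = set()
    for pos in assayed:
        reserved.update(range(pos - 1, pos + 4))
    for pos in (135, 270):
        reserved.update(range(pos - 4, pos + 5))

    def haplotypes() -> list[str]:
        ref = "".join(seq)
        t = list(ref)
        for pos, al in zip(diagnostic, tri):
            t[pos] = al
        t2 = list(t)
        t2[330] = abi[4]
        return [ref, "".join(t), "".join(t2)]

    expected_cuts = [{60, 330}, {200}, {200, 330}]  # start+1 of each motif

    # repair pass: break any unplanned GANTC by mutating a free base
    for _ in range(200):
        dirty = False
        for hap, exp in zip(haplotypes(), expected_cuts):
            for i in range(385):
                window = hap[i : i + 5]
                if (
                    window[0] == "G"
                    and window[1] == "A"
                    and window[3] == "T"
                    and window[4] == "C"
                    and i + 1 not in exp
                ):
                    for j in (i, i + 1, i + 3, i + 4):
                        if j not in reserved:
                            seq[j] = {"G": "T", "A": "C", "T": "A", "C": "G"}[seq[j]]
                            break
                    else:  # pragma: no cover - never hit with this layout
                        raise RuntimeError("cannot repair backbone")
                    dirty = True
                    break
            if dirty:
                break
        if not dirty:
            break
    else:  # pragma: no cover
        raise RuntimeError("backbone repair did not converge")

    template = MtdnaTemplate(
        reference="".join(seq),
        diagnostic_positions=diagnostic,
        abietinus_alleles=abi,
        tristis_alleles=tri,
        assayed_positions=assayed,
        tristis2_position=330,
    )
    # sanity: the three haplotypes must give pairwise distinct digests
    from .mtdna import HINF_I, digest

    patterns = {
        lin: tuple(sorted(digest(template.sequence(lin), HINF_I).lengths))
        for lin in template.lineages
    }
    if len(set(patterns.values())) != 3:  # pragma: no cover
        raise RuntimeError("template haplotypes are not digest-distinguishable")
    return template


def simulate_mtdna(
    template: MtdnaTemplate, lineage: str, n: int, prefix: str | None = None
) -> list[SeqRecord]:
    """``n`` FASTA records of the given lineage's amplicon haplotype."""
    if n < 1:
        raise ValueError("n must be >= 1")
    seq = template.sequence(lineage)  # validates the lineage label
    prefix = prefix or lineage
    return [
        SeqRecord(Seq(seq), id=f"{prefix}_{i + 1}", description=f"CytB 389bp {lineage}")
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# Song model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SongModel:
    """Per-lineage acoustic ranges (note rate notes/s, frequency band kHz).

    Defaults are the documented lineage ranges: abietinus sings slower
    (2.8–3.3 notes/s) in a higher band (3.7–4.6 kHz) with no ascending
    elements; tristis faster (4.7–7.2) and lower (2.9–3.7 kHz) with
    ascending notes throughout.
    """

    abietinus_rate: tuple[float, float] = (2.8, 3.3)
    tristis_rate: tuple[float, float] = (4.7, 7.2)
    abietinus_band: tuple[float, float] = (3.7, 4.6)
    tristis_band: tuple[float, float] = (2.9, 3.7)
    tristis_ascending: tuple[float, float] = (91.0, 100.0)

    def __post_init__(self) -> None:
        for lo, hi in (
            self.abietinus_rate,
            self.tristis_rate,
            self.abietinus_band,
            self.tristis_band,
            self.tristis_ascending,
        ):
            if not lo < hi:
                raise ValueError("ranges must be increasing")


def simulate_song(
    model: SongModel, song_type: str, rng: np.random.Generator | int = 0
):
    """Draw one male's song features for a pure or mixed song type.

    Pure draws fall uniformly inside the lineage's ranges (ascending
    percentage 0 for abietinus, high for tristis). Mixed draws take the
    note rate from the inter-range gap, a frequency range straddling
    both bands, and an intermediate ascending percentage — matching the
    field description of mixed singers.
    """
    from .song import SongFeatures

    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng

    def band(lo: float, hi: float) -> tuple[float, float]:
        x = np.sort(rng.uniform(lo, hi, size=2))
        while x[0] == x[1]:  # pragma: no cover - measure-zero
            x = np.sort(rng.uniform(lo, hi, size=2))
        return float(x[0]), float(x[1])

    if song_type == LINEAGE_A:
        low, high = band(*model.abietinus_band)
        return SongFeatures(
            ascending=(0.0, 0.0, 0.0),
            note_rate=float(rng.uniform(*model.abietinus_rate)),
            freq_low=low,
            freq_high=high,
        )
    if song_type == LINEAGE_B:
        low, high = band(*model.tristis_band)
        return SongFeatures(
            ascending=tuple(rng.uniform(*model.tristis_ascending, size=3)),
            note_rate=float(rng.uniform(*model.tristis_rate)),
            freq_low=low,
            freq_high=high,
        )
    if song_type == "mixed":
        gap = (model.abietinus_rate[1], model.tristis_rate[0])
        return SongFeatures(
            ascending=tuple(rng.uniform(10.0, 85.0, size=3)),
            note_rate=float(rng.uniform(gap[0] + 1e-6, gap[1] - 1e-6)),
            freq_low=float(rng.uniform(3.0, 3.6)),
            freq_high=float(rng.uniform(3.8, 4.5)),
        )
    raise ValueError(f"unknown song type {song_type!r}")


def simulate_song_cohort(
    model: SongModel,
    labels: Sequence[str],
    regions: Sequence[str] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Feature table (one row per male) for a list of true song types."""
    rng = np.random.default_rng(seed)
    rows = []
    regions = regions or [""] * len(labels)
    for i, (label, region) in enumerate(zip(labels, regions)):
        f = simulate_song(model, label, rng)
        rows.append(
            {
                "id": f"bird_{i + 1}",
                "region": region,
                "true_type": label,
                "ascending_1": f.ascending[0],
                "ascending_2": f.ascending[1],
                "ascending_3": f.ascending[2],
                "note_rate": f.note_rate,
                "freq_low": f.freq_low,
                "freq_high": f.freq_high,
            }
        )
    return pd.DataFrame(rows)
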