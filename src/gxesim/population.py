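"""Individual-level genotype and exposure generation.

The disease model downstream assumes Hardy-Weinberg genotype proportions at
each disease-predisposing locus (DPL), statistical independence between the
two DPLs (no cross-locus LD), and a Gaussian causal exposure.  This module
generates populations with exactly that structure, plus optional background
markers organised in LD blocks so that association scans see realistic local
correlation.

Genotype codes follow the 1/2/3 convention throughout: 1 = homozygote for the
low-risk allele, 2 = heterozygote, 3 = homozygote for the high-risk allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import rng_for
from .errors import ValidationError

_NUCLEOTIDES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class LocusSpec:
    """One disease-predisposing locus.

    Parameters
    ----------
    marker_id
        Identifier of the marker among the simulated SNPs.
    high_risk_allele
        The allele (A/C/G/T) whose homozygote carries the highest risk.
    allele_freq
        Population frequency of the high-risk allele, in [0, 1].
    rr
        Genotypic relative risk: penetrance of the high-risk homozygote over
        the low-risk homozygote.  Must be positive.
    w
        Dominance weight in [0, 1] placing the heterozygote risk between the
        homozygote risks: ``w=0`` dominant high-risk allele (heterozygote as
        risky as the high-risk homozygote), ``w=1`` recessive, intermediate
        values co-dominant.
    """

    marker_id: str
    high_risk_allele: str
    allele_freq: float
    rr: float
    w: float

    def __post_init__(self) -> None:
        if self.high_risk_allele not in _NUCLEOTIDES:
            raise ValidationError(
                f"high_risk_allele must be one of {_NUCLEOTIDES}, "
                f"got {self.high_risk_allele!r}"
            )
        if not 0.0 <= self.allele_freq <= 1.0:
            raise ValidationError(f"allele_freq must be in [0,1], got {self.allele_freq}")
        if not self.rr > 0:
            raise ValidationError(f"rr must be > 0, got {self.rr}")
        if not 0.0 <= self.w <= 1.0:
            raise ValidationError(f"dominance weight w must be in [0,1], got {self.w}")


@dataclass(frozen=True)
class GenotypeFrequencies:
    """Probabilities of the three genotype codes (low-homo, het, high-homo)."""

    p: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.p) != 3:
            raise ValidationError("GenotypeFrequencies needs exactly 3 probabilities")
        if any(not 0.0 <= x <= 1.0 for x in self.p):
            raise ValidationError(f"genotype frequencies must be in [0,1], got {self.p}")
        if abs(sum(self.p) - 1.0) > 1e-12:
            raise ValidationError(f"genotype frequencies must sum to 1, got {sum(self.p)}")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.p, dtype=float)


@dataclass(frozen=True)
class EnvironmentSpec:
    """Gaussian causal exposure and its per-unit odds ratio on disease."""

    mean: float = 0.0
    sd: float = 1.0
    or_per_unit: float = 1.0

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValidationError(f"environment sd must be > 0, got {self.sd}")
        if not self.or_per_unit > 0:
            raise ValidationError(
                f"environment odds ratio must be > 0, got {self.or_per_unit}"
            )


@dataclass(frozen=True)
class NoiseVariableSpec:
    """A confounding exposure not linked to disease risk.

    ``family`` is one of ``gaussian`` (params ``mean``, ``sd``), ``uniform``
    (``low``, ``high``) or ``binomial`` (``n``, ``p``).
    """

    name: str
    family: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        fam = self.family
        p = self.params
        if fam == "gaussian":
            if "mean" not in p or "sd" not in p or not p["sd"] > 0:
                raise ValidationError(
                    f"gaussian noise {self.name!r} needs params mean and sd > 0"
                )
        elif fam == "uniform":
            if "low" not in p or "high" not in p or not p["low"] < p["high"]:
                raise ValidationError(
                    f"uniform noise {self.name!r} needs params low < high"
                )
        elif fam == "binomial":
            if (
                "n" not in p
                or "p" not in p
                or int(p["n"]) < 1
                or not 0.0 <= p["p"] <= 1.0
            ):
                raise ValidationError(
                    f"binomial noise {self.name!r} needs params n >= 1 and p in [0,1]"
                )
        else:
            raise ValidationError(
                f"unknown noise family {fam!r} (expected gaussian/uniform/binomial)"
            )

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "gaussian":
            return rng.normal(self.params["mean"], self.params["sd"], size=n)
        if self.family == "uniform":
            return rng.uniform(self.params["low"], self.params["high"], size=n)
        return rng.binomial(int(self.params["n"]), self.params["p"], size=n).astype(float)


@dataclass
class HaplotypePanel:
    """A pool of phased haplotypes over a set of bi-allelic markers.

    ``haplotypes`` is a (pool_size, n_loci) uint8 array; entry 1 means the
    haplotype carries ``alleles[locus][1]`` (the allele whose frequency was
    requested), 0 means ``alleles[locus][0]``.
    """

    marker_ids: list[str]
    positions: np.ndarray
    alleles: list[tuple[str, str]]
    haplotypes: np.ndarray
    block_of: np.ndarray  # block index per locus

    @property
    def n_loci(self) -> int:
        return len(self.marker_ids)

    @property
    def pool_size(self) -> int:
        return self.haplotypes.shape[0]

    def locus_index(self, marker_id: str) -> int:
        try:
            return self.marker_ids.index(marker_id)
        except ValueError:
            raise ValidationError(f"marker {marker_id!r} not present in panel") from None

    def allele_freqs(self) -> np.ndarray:
        """Empirical frequency of allele code 1 at each locus."""
        return self.haplotypes.mean(axis=0)


@dataclass
class Population:
    """Per-individual genotypes, exposures and (eventually) disease status."""

    n: int
    genotype_a: np.ndarray  # codes 1/2/3 at the first DPL
    genotype_b: np.ndarray  # codes 1/2/3 at the second DPL
    marker_haplotypes: np.ndarray | None = None  # (n, 2, n_loci) uint8, phased
    panel: HaplotypePanel | None = None
    exposure: np.ndarray | None = None
    noise_exposures: dict[str, np.ndarray] = field(default_factory=dict)
    gender: np.ndarray | None = None
    status: np.ndarray | None = None
    dpl_a: LocusSpec | None = None
    dpl_b: LocusSpec | None = None

    def __post_init__(self) -> None:
        for name in ("genotype_a", "genotype_b"):
            g = getattr(self, name)
            if g.shape != (self.n,):
                raise ValidationError(f"{name} must have length n={self.n}")
            if g.size and (g.min() < 1 or g.max() > 3):
                raise ValidationError(f"{name} codes must be in {{1,2,3}}")


def hwe_genotype_freqs(allele_freq: float) -> GenotypeFrequencies:
    """Hardy-Weinberg genotype proportions for a high-risk allele frequency q.

    Returns ((1-q)^2, 2q(1-q), q^2).
    """
    if not 0.0 <= allele_freq <= 1.0:
        raise ValidationError(f"allele frequency must be in [0,1], got {allele_freq}")
    q = float(allele_freq)
    return GenotypeFrequencies(((1 - q) ** 2, 2 * q * (1 - q), q**2))


def generate_haplotype_panel(
    n_loci: int,
    block_lengths: list[int],
    within_block_r2: float,
    allele_freqs: list[float] | float,
    seed: int,
    pool_size: int,
    marker_ids: list[str] | None = None,
) -> HaplotypePanel:
    """Generate a pool of phased haplotypes with block-structured LD.

    Within a block, adjacent loci have squared allele correlation close to
    ``within_block_r2`` and correlation decays geometrically with distance
    (first-order Markov mosaic).  Loci in different blocks are independent, so
    placing the two DPLs in different blocks realises the assumption that they
    are not in LD.
    """
    if sum(block_lengths) != n_loci:
        raise ValidationError(
            f"block lengths {block_lengths} must sum to n_loci={n_loci}"
        )
    if any(b < 1 for b in block_lengths):
        raise ValidationError("every block must contain at least one locus")
    if not 0.0 <= within_block_r2 <= 1.0:
        raise ValidationError(f"within_block_r2 must be in [0,1], got {within_block_r2}")
    freqs = np.broadcast_to(np.asarray(allele_freqs, dtype=float), (n_loci,)).copy()
    if np.any((freqs <= 0.0) | (freqs >= 1.0)):
        raise ValidationError("allele frequencies must lie strictly in (0,1)")
    if pool_size < 2:
        raise ValidationError("pool_size must be at least 2")

    rho = float(np.sqrt(within_block_r2))
    rng = rng_for(seed, "panel")

    block_of = np.repeat(np.arange(len(block_lengths)), block_lengths)
    hap = np.empty((pool_size, n_loci), dtype=np.uint8)
    for j in range(n_loci):
        q = freqs[j]
        if j == 0 or block_of[j] != block_of[j - 1]:
            hap[:, j] = rng.random(pool_size) < q
            continue
        p = freqs[j - 1]
        cov = rho * np.sqrt(p * (1 - p) * q * (1 - q))
        p11 = q + cov / p
        p10 = q - cov / (1 - p)
        if not (0.0 <= p11 <= 1.0 and 0.0 <= p10 <= 1.0):
            raise ValidationError(
                f"requested r^2={within_block_r2} is unattainable for adjacent "
                f"frequencies ({p:.3f}, {q:.3f})"
            )
        prev = hap[:, j - 1].astype(bool)
        u = rng.random(pool_size)
        hap[:, j] = np.where(prev, u < p11, u < p10)

    if marker_ids is None:
        marker_ids = [f"snp{j + 1:04d}" for j in range(n_loci)]
    elif len(marker_ids) != n_loci:
        raise ValidationError("marker_ids length must equal n_loci")
    if len(set(marker_ids)) != n_loci:
        raise ValidationError("marker ids must be unique")

    # 1-based positions; blocks are spaced far apart to suggest distinct regions.
    positions = np.empty(n_loci, dtype=np.int64)
    offset_in_block = np.concatenate([np.arange(b) for b in block_lengths])
    positions[:] = 1 + block_of.astype(np.int64) * 10_000_000 + offset_in_block * 5_000

    alleles = []
    for _ in range(n_loci):
        pair = rng.choice(4, size=2, replace=False)
        alleles.append((_NUCLEOTIDES[pair[0]], _NUCLEOTIDES[pair[1]]))

    return HaplotypePanel(
        marker_ids=list(marker_ids),
        positions=positions,
        alleles=alleles,
        haplotypes=hap,
        block_of=block_of,
    )


def _dpl_allele_code(panel: HaplotypePanel, spec: LocusSpec) -> tuple[int, int]:
    """Locus index and the panel allele code (0/1) of the high-risk allele."""
    j = panel.locus_index(spec.marker_id)
    a0, a1 = panel.alleles[j]
    if spec.high_risk_allele == a1:
        return j, 1
    if spec.high_risk_allele == a0:
        return j, 0
    raise ValidationError(
        f"high-risk allele {spec.high_risk_allele!r} of {spec.marker_id!r} is not "
        f"among the panel alleles {a0}/{a1}"
    )


def sample_individuals(
    panel: HaplotypePanel,
    n: int,
    seed: int,
    dpl_a: LocusSpec | None = None,
    dpl_b: LocusSpec | None = None,
) -> Population:
    """Draw ``n`` individuals as random unions of two pool haplotypes.

    Each individual receives two haplotypes drawn independently and uniformly
    (with replacement) from the pool.  DPL genotype codes count copies of the
    high-risk allele: 1 = zero copies, 2 = one, 3 = two.  When a DPL spec is
    omitted the corresponding genotype column defaults to the first (resp.
    second) panel locus with its allele-1 as high risk.
    """
    if panel.pool_size < 1 or panel.n_loci < 1:
        raise ValidationError("panel must contain at least one haplotype and locus")
    if n < 1:
        raise ValidationError(f"population size must be >= 1, got {n}")
    rng = rng_for(seed, "sample")
    idx = rng.integers(0, panel.pool_size, size=(n, 2))
    haps = panel.haplotypes[idx]  # (n, 2, n_loci)

    def genotype_for(spec: LocusSpec | None, default_locus: int) -> np.ndarray:
        if spec is None:
            j, hr = default_locus, 1
        else:
            j, hr = _dpl_allele_code(panel, spec)
        carried = haps[:, :, j]
        copies = (carried == hr).sum(axis=1)
        return (copies + 1).astype(np.int8)

    ga = genotype_for(dpl_a, 0)
    gb = genotype_for(dpl_b, min(1, panel.n_loci - 1))
    return Population(
        n=n,
        genotype_a=ga,
        genotype_b=gb,
        marker_haplotypes=haps,
        panel=panel,
        dpl_a=dpl_a,
        dpl_b=dpl_b,
    )


def sample_hwe_population(
    spec_a: LocusSpec, spec_b: LocusSpec, n: int, seed: int
) -> Population:
    """Draw DPL genotypes directly from Hardy-Weinberg proportions.

    This is the exact generative model the penetrance machinery assumes (HWE
    within locus, independence across loci); use it when background markers
    are not needed.
    """
    if n < 1:
        raise ValidationError(f"population size must be >= 1, got {n}")
    rng = rng_for(seed, "sample")
    out = []
    for spec in (spec_a, spec_b):
        p = hwe_genotype_freqs(spec.allele_freq).as_array()
        out.append(rng.choice(np.array([1, 2, 3], dtype=np.int8), size=n, p=p))
    return Population(
        n=n, genotype_a=out[0], genotype_b=out[1], dpl_a=spec_a, dpl_b=spec_b
    )


def assign_exposures(
    pop: Population,
    env: EnvironmentSpec,
    noise: list[NoiseVariableSpec],
    seed: int,
) -> Population:
    """Assign the causal Gaussian exposure, noise exposures, and gender.

    Gender is Bernoulli(0.5), encoded 1/2; it never enters the risk model and
    is carried only because the output tables report it.  Draws are
    deterministic given ``seed`` and independent of each other.
    """
    names = [nv.name for nv in noise]
    if len(set(names)) != len(names):
        raise ValidationError("noise variable names must be unique")
    pop.exposure = rng_for(seed, "exposure").normal(env.mean, env.sd, size=pop.n)
    pop.noise_exposures = {
        nv.name: nv.sample(pop.n, rng_for(seed, "noise", i))
        for i, nv in enumerate(noise)
    }
    pop.gender = rng_for(seed, "gender").integers(1, 3, size=pop.n).astype(np.int8)
    return pop


def estimate_dpl_freqs(pop: Population, which: str) -> GenotypeFrequencies:
    """Observed genotype-code proportions at DPL ``which`` ('a' or 'b')."""
    if which not in ("a", "b"):
        raise ValidationError(f"locus selector must be 'a' or 'b', got {which!r}")
    g = pop.genotype_a if which == "a" else pop.genotype_b
    if g.size == 0:
        raise ValidationError("cannot estimate genotype frequencies of an empty population")
    counts = np.bincount(g, minlength=4)[1:4]
    # counts/n sums to 1 up to one rounding each; renormalise the last term so
    # the frozen dataclass invariant (sum within 1e-12) always holds.
    p0 = counts[0] / g.size
    p1 = counts[1] / g.size
    return GenotypeFrequencies((p0, p1, max(0.0, 1.0 - p0 - p1)))
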