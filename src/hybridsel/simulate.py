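"""Synthetic hybrid-rice populations with known ground truth.

The generator emulates the study design behind subspecies-introgression
scanning and hybrid genomic selection in rice:

* two differentiated founder subpopulations (an *indica*-like and a
  *japonica*-like reference panel of fully homozygous inbred accessions),
  with a tunable fraction of markers fixed — or nearly fixed, via a purity
  parameter — for opposite alleles between the panels;
* F1 hybrids from inbred x inbred crosses, heterozygous exactly where the
  parents differ;
* F2 individuals produced by meiosis with Poisson crossovers on the
  genetic map (Haldane model, no interference);
* quantitative traits built from per-locus additive effects ``a_j`` and
  dominance effects ``d_j`` plus Gaussian noise calibrated to a target
  narrow+dominance-sense heritability.

Every stage records its truth (marker subspecies origin, true genetic
values) so downstream estimators can be tested against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import rng_for
from ._typing import MISSING, GenotypeMatrix

_BASES = np.array(list("ACGT"))

#: physical scale of the simulated map; rice averages roughly 250 kb per cM
DEFAULT_BP_PER_CM = 250_000


@dataclass
class QtlEffect:
    """One causal locus: marker index, additive effect a, dominance effect d.

    Effects follow the classical F2 parameterization: the two homozygotes
    sit at -a and +a around the midpoint and the heterozygote at d.
    """

    marker: int
    a: float
    d: float = 0.0


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study population."""

    n_chromosomes: int = 2
    markers_per_chromosome: int = 500
    chrom_length_cm: float = 150.0
    diff_fraction: float = 0.6
    purity: float = 0.95
    n_indica: int = 19
    n_japonica: int = 23
    qtl_spec: dict[str, list[QtlEffect]] = field(default_factory=dict)
    heritability: dict[str, float] = field(default_factory=dict)
    bp_per_cm: int = DEFAULT_BP_PER_CM
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.diff_fraction <= 1.0:
            raise ValueError(f"diff_fraction must be in [0,1], got {self.diff_fraction}")
        if not 0.5 < self.purity <= 1.0:
            raise ValueError(f"purity must be in (0.5,1], got {self.purity}")
        for trait, h2 in self.heritability.items():
            if not 0.0 <= h2 <= 1.0:
                raise ValueError(f"heritability[{trait}]={h2} outside [0,1]")
        n_markers = self.n_chromosomes * self.markers_per_chromosome
        for trait, qtls in self.qtl_spec.items():
            for q in qtls:
                if not 0 <= q.marker < n_markers:
                    raise ValueError(
                        f"QTL marker index {q.marker} for trait {trait} out of range"
                    )

    @property
    def n_markers(self) -> int:
        return self.n_chromosomes * self.markers_per_chromosome


@dataclass
class FounderTruth:
    """Per-marker ground truth stored by the founder generator."""

    is_differentiated: np.ndarray  # bool per marker
    indica_major_dosage: np.ndarray  # dosage (0 or 2) of the indica major allele
    japonica_major_dosage: np.ndarray


def make_marker_map(config: SimulationConfig) -> pd.DataFrame:
    """Evenly spaced markers on each chromosome, cM and bp coordinates."""
    if config.markers_per_chromosome < 1:
        raise ValueError("need at least one marker per chromosome")
    rng = rng_for(config.seed, "marker_map")
    frames = []
    for c in range(config.n_chromosomes):
        m = config.markers_per_chromosome
        cm = np.linspace(0.0, config.chrom_length_cm, m)
        alleles = rng.choice(4, size=(m, 2))
        # resample until ref != alt at every site
        clash = alleles[:, 0] == alleles[:, 1]
        while clash.any():
            alleles[clash, 1] = rng.choice(4, size=clash.sum())
            clash = alleles[:, 0] == alleles[:, 1]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": f"chr{c + 1}",
                    "pos": np.round(cm * config.bp_per_cm).astype(np.int64) + 1,
                    "cm": cm,
                    "ref": _BASES[alleles[:, 0]],
                    "alt": _BASES[alleles[:, 1]],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _inbred_from_major(major_dosage: np.ndarray, major_freq: np.ndarray,
                       n: int, rng: np.random.Generator) -> np.ndarray:
    """Fully homozygous individuals; each carries the major allele with
    probability ``major_freq`` at each marker, the other allele otherwise."""
    m = major_dosage.shape[0]
    takes_major = rng.random((n, m)) < major_freq
    minor = 2 - major_dosage
    return np.where(takes_major, major_dosage, minor).astype(np.int8)


def simulate_founders(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, GenotypeMatrix, FounderTruth]:
    """Generate the two inbred reference panels and the marker truth.

    At a random ``diff_fraction`` of markers the panels carry opposite
    major alleles, each at within-panel frequency ``purity``; everywhere
    else both panels share one common allele-frequency distribution, so no
    systematic differentiation exists there.
    """
    markers = make_marker_map(config)
    m = len(markers)
    if m == 0:
        raise ValueError("zero markers requested")
    rng = rng_for(config.seed, "founders")

    is_diff = rng.random(m) < config.diff_fraction
    # dosage of the REF allele: indica major = ref (dosage 2) or alt (0), at random
    indica_major = np.where(rng.random(m) < 0.5, 2, 0).astype(np.int8)
    japonica_major = np.where(is_diff, 2 - indica_major, indica_major).astype(np.int8)

    # undifferentiated markers: shared major-allele frequency in [0.5, 0.95]
    shared_freq = rng.uniform(0.5, 0.95, size=m)
    ind_freq = np.where(is_diff, config.purity, shared_freq)
    jap_freq = np.where(is_diff, config.purity, shared_freq)

    ind_dosage = _inbred_from_major(indica_major, ind_freq, config.n_indica, rng)
    jap_dosage = _inbred_from_major(japonica_major, jap_freq, config.n_japonica, rng)

    indica = GenotypeMatrix(
        ind_dosage, [f"ind_{i:03d}" for i in range(config.n_indica)], markers
    )
    japonica = GenotypeMatrix(
        jap_dosage, [f"jap_{i:03d}" for i in range(config.n_japonica)], markers
    )
    truth = FounderTruth(is_diff, indica_major, japonica_major)
    return indica, japonica, truth


def simulate_inbred_lines(
    n: int,
    markers: pd.DataFrame,
    seed: int,
    ref_freq: np.ndarray | None = None,
    stage: str = "inbreds",
) -> GenotypeMatrix:
    """Random fully homozygous lines, e.g. a commercial parental pool.

    Each line is homozygous for the reference allele with probability
    ``ref_freq`` (default: uniform in [0.1, 0.9] per marker).
    """
    rng = rng_for(seed, stage)
    m = len(markers)
    if ref_freq is None:
        ref_freq = rng.uniform(0.1, 0.9, size=m)
    dosage = np.where(rng.random((n, m)) < ref_freq, 2, 0).astype(np.int8)
    return GenotypeMatrix(dosage, [f"{stage}_{i:04d}" for i in range(n)], markers)


def make_f1(mother: np.ndarray, father: np.ndarray) -> np.ndarray:
    """Genotype of the F1 from two fully inbred parents.

    Heterozygous exactly where the parents carry different alleles,
    homozygous for the shared allele elsewhere, missing wherever either
    parent is missing.
    """
    mother = np.asarray(mother, dtype=np.int8)
    father = np.asarray(father, dtype=np.int8)
    if mother.shape != father.shape:
        raise ValueError("parent genotype rows differ in length")
    het = (mother == 1) | (father == 1)
    if het.any():
        raise ValueError(
            f"{int(het.sum())} heterozygous parent sites; parents must be inbred lines"
        )
    miss = (mother == MISSING) | (father == MISSING)
    f1 = ((mother.astype(np.int16) + father) // 2).astype(np.int8)
    f1[miss] = MISSING
    return f1


def _meiosis_gametes(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    cm: np.ndarray,
    chrom_bounds: list[tuple[int, int]],
    n_gametes: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gametes of a heterozygote with known haplotypes.

    Crossovers per chromosome are Poisson with mean L/100 Morgans and land
    uniformly on the cM map (Haldane: no interference).  Returns an
    (n_gametes, n_markers) array of transmitted alleles in {0, 1} copies of
    the reference allele.
    """
    m = cm.shape[0]
    out = np.empty((n_gametes, m), dtype=np.int8)
    for lo, hi in chrom_bounds:
        c_cm = cm[lo:hi]
        length = c_cm[-1] - c_cm[0]
        if length < 0:
            raise ValueError("non-positive map length")
        n_x = rng.poisson(length / 100.0, size=n_gametes)
        start = rng.integers(0, 2, size=n_gametes)
        for g in range(n_gametes):
            if n_x[g] == 0:
                anc = np.full(hi - lo, start[g])
            else:
                xpos = np.sort(rng.uniform(c_cm[0], c_cm[-1], size=n_x[g]))
                # parity of crossovers to the left of each marker
                anc = (start[g] + np.searchsorted(xpos, c_cm, side="left")) % 2
            seg = np.where(anc == 0, hap_a[lo:hi], hap_b[lo:hi])
            out[g, lo:hi] = seg
    return out


def _chrom_bounds(markers: pd.DataFrame) -> list[tuple[int, int]]:
    bounds = []
    chroms = markers["chrom"].to_numpy()
    start = 0
    for i in range(1, len(chroms) + 1):
        if i == len(chroms) or chroms[i] != chroms[start]:
            bounds.append((start, i))
            start = i
    return bounds


def simulate_f2(
    mother: np.ndarray,
    father: np.ndarray,
    n: int,
    markers: pd.DataFrame,
    seed: int,
    prefix: str = "F2",
    genotype_error_rate: float = 0.0,
) -> GenotypeMatrix:
    """F2 individuals from selfing the F1 of two inbred lines.

    Each F2 genotype is the sum of two independent F1 gametes drawn under
    the Haldane crossover model.  At any marker where the F1 is
    heterozygous, genotype frequencies converge to 1:2:1.  An optional
    symmetric genotyping-error rate flips a call to one of the other two
    genotype classes.
    """
    if n < 1:
        raise ValueError("need n >= 1 F2 individuals")
    make_f1(mother, father)  # validates inbred parents
    rng = rng_for(seed, "f2", prefix)
    hap_m = (np.asarray(mother, dtype=np.int8) // 2).astype(np.int8)
    hap_f = (np.asarray(father, dtype=np.int8) // 2).astype(np.int8)
    cm = markers["cm"].to_numpy()
    bounds = _chrom_bounds(markers)
    gam1 = _meiosis_gametes(hap_m, hap_f, cm, bounds, n, rng)
    gam2 = _meiosis_gametes(hap_m, hap_f, cm, bounds, n, rng)
    dosage = (gam1 + gam2).astype(np.int8)
    miss = (mother == MISSING) | (father == MISSING)
    dosage[:, miss] = MISSING
    if genotype_error_rate > 0.0:
        flip = rng.random(dosage.shape) < genotype_error_rate
        flip &= dosage != MISSING
        shift = rng.integers(1, 3, size=dosage.shape)
        dosage[flip] = ((dosage[flip] + shift[flip]) % 3).astype(np.int8)
    samples = [f"{prefix}_{i:05d}" for i in range(n)]
    return GenotypeMatrix(dosage, samples, markers)


def genetic_values(
    genotypes: GenotypeMatrix, qtls: list[QtlEffect]
) -> np.ndarray:
    """True genetic value g_i = sum_j a_j x_ij + d_j z_ij.

    x is the -1/0/1 additive coding (reference-hom = +1) and z the 0/1
    heterozygosity indicator; missing genotypes contribute the locus mean
    coding of the cohort.
    """
    g = np.zeros(genotypes.n_individuals)
    for q in qtls:
        col = genotypes.dosage[:, q.marker].astype(float)
        miss = col < 0
        x = col - 1.0
        z = (col == 1).astype(float)
        if miss.any():
            x[miss] = np.nanmean(np.where(miss, np.nan, x))
            z[miss] = np.nanmean(np.where(miss, np.nan, z))
        g += q.a * x + q.d * z
    return g


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    qtl_spec: dict[str, list[QtlEffect]],
    heritability: dict[str, float],
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Trait table plus the true genetic values used to build it.

    The residual SD is calibrated on the simulated cohort itself so that
    Var(g)/Var(y) matches the requested heritability exactly in the
    empirical-variance sense (robust to LD among the causal loci).
    ``h2 = 0`` yields pure unit-variance noise; ``h2 = 1`` with no genetic
    variance is an error.
    """
    pheno = pd.DataFrame({"id": genotypes.samples})
    truth = pd.DataFrame({"id": genotypes.samples})
    for trait, qtls in qtl_spec.items():
        h2 = heritability.get(trait, 0.5)
        rng = rng_for(seed, "phenotype", trait)
        g = genetic_values(genotypes, qtls)
        var_g = float(np.var(g))
        if h2 == 0.0:
            y = rng.normal(0.0, 1.0, size=g.shape[0])
        elif var_g == 0.0:
            raise ValueError(
                f"trait {trait}: h2={h2} requested but genetic variance is zero"
            )
        elif h2 == 1.0:
            y = g.copy()
        else:
            sd_e = np.sqrt(var_g * (1.0 - h2) / h2)
            y = g + rng.normal(0.0, sd_e, size=g.shape[0])
        pheno[trait] = y
        truth[trait] = g
    return pheno, truth


def simulate_hybrid_cohort(
    n: int,
    markers: pd.DataFrame,
    seed: int,
    ref_freq: np.ndarray | None = None,
) -> GenotypeMatrix:
    """A panmictic hybrid cohort: each individual is the F1 of two
    gametes drawn independently at the given allele frequencies.

    Genotypes are in Hardy-Weinberg proportions with free recombination
    between markers, mimicking a diverse collection of hybrid cultivars
    whose parents are unrelated; heterozygosity is present so dominance
    kernels are informative.
    """
    rng = rng_for(seed, "hybrid_cohort")
    m = len(markers)
    if ref_freq is None:
        ref_freq = rng.uniform(0.1, 0.9, size=m)
    dosage = (
        (rng.random((n, m)) < ref_freq).astype(np.int8)
        + (rng.random((n, m)) < ref_freq).astype(np.int8)
    )
    return GenotypeMatrix(dosage, [f"hyb_{i:05d}" for i in range(n)], markers)


def simulate_multicross_f2(
    n_crosses: int,
    f2_per_cross: int,
    markers: pd.DataFrame,
    seed: int,
    ref_freq: np.ndarray | None = None,
) -> GenotypeMatrix:
    """A diverse F2 cohort: random inbred founder pairs, one F2 family each.

    Mimics the multi-family segregating populations used for model
    training: heterozygosity is present (so dominance kernels are
    non-degenerate) while long-range LD is broken across families.
    """
    founders = simulate_inbred_lines(
        2 * n_crosses, markers, seed, ref_freq=ref_freq, stage="xfounder"
    )
    cohorts = []
    for c in range(n_crosses):
        fam = simulate_f2(
            founders.dosage[2 * c],
            founders.dosage[2 * c + 1],
            f2_per_cross,
            markers,
            seed,
            prefix=f"fam{c:03d}",
        )
        cohorts.append(fam)
    out = cohorts[0]
    for fam in cohorts[1:]:
        out = out.concat(fam)
    return out
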