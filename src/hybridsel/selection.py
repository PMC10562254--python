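"""Pseudo-combination enumeration, breeding selection index, sterility screen.

Every (female, male) pair of inbred parents defines a pseudo-combination:
the in-silico F1 whose genotype is fully determined by the parents.  The
trained GBLUP model scores each combination per trait; the selection
index then aggregates seven traits:

* yield per plant, seed setting rate, full grain number per panicle and
  valid panicle number are scored against the candidate set's own GEBV
  percentiles — >80th: 40, 60-80th: 30, 40-60th: 20, 20-40th: 10,
  <20th: 0;
* heading date (optimal 80-90 days), plant height (115-125 cm) and grain
  shape (3.0-3.4) score 40 inside the optimal range and 20 outside.

The index therefore lies in [60, 280]; combinations scoring >= 80 are
flagged high-scoring.  Sterility screening removes combinations whose F1
is homozygous for a sterility-causing allele (rf3/rf4 for wild-abortive
cytoplasm, tms5 for the two-line system).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._typing import MISSING, GenotypeMatrix, heterozygosity

logger = logging.getLogger(__name__)

PERCENTILE_TRAITS = (
    "yield_per_plant",
    "seed_setting_rate",
    "full_grain_number",
    "valid_panicle_number",
)
RANGE_TRAITS = {
    "heading_date": (80.0, 90.0),
    "plant_height": (115.0, 125.0),
    "grain_shape": (3.0, 3.4),
}


@dataclass
class SelectionIndexConfig:
    """Scoring rules of the seven-trait breeding selection index."""

    percentile_traits: tuple[str, ...] = PERCENTILE_TRAITS
    range_traits: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(RANGE_TRAITS)
    )
    percentile_edges: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8)
    percentile_scores: tuple[int, ...] = (0, 10, 20, 30, 40)
    in_range_score: int = 40
    out_range_score: int = 20
    high_score_threshold: int = 80

    def __post_init__(self) -> None:
        if len(self.percentile_scores) != len(self.percentile_edges) + 1:
            raise ValueError("need one score per percentile bin")
        for trait, (lo, hi) in self.range_traits.items():
            if not lo < hi:
                raise ValueError(f"range for {trait} must have lo < hi")


@dataclass
class PseudoCombinations:
    """All in-silico F1s of a female x male factorial."""

    females: list[str]
    males: list[str]
    pairs: pd.DataFrame  # columns female, male; one row per combination
    f1_dosage: np.ndarray  # (n_combinations, n_markers) int8
    markers: pd.DataFrame

    def __len__(self) -> int:
        return len(self.pairs)

    def as_genotypes(self) -> GenotypeMatrix:
        names = [
            f"{f}x{m}" for f, m in zip(self.pairs["female"], self.pairs["male"])
        ]
        return GenotypeMatrix(self.f1_dosage, names, self.markers)


def _clean_inbred(dosage: np.ndarray, het_tolerance: float, who: str) -> np.ndarray:
    """Validate near-inbred parents; residual heterozygous sites -> missing."""
    het = heterozygosity(dosage)
    worst = np.nanmax(het) if het.size else 0.0
    if worst > het_tolerance:
        raise ValueError(
            f"{who} parents exceed heterozygosity tolerance "
            f"({worst:.3f} > {het_tolerance})"
        )
    out = dosage.copy()
    out[out == 1] = MISSING
    return out


def enumerate_combinations(
    females: GenotypeMatrix,
    males: GenotypeMatrix,
    het_tolerance: float = 0.02,
) -> PseudoCombinations:
    """Derive the F1 genotype of every female x male pair.

    Parents must be (near-)inbred: individuals with heterozygosity above
    ``het_tolerance`` are rejected, and any residual heterozygous site is
    treated as missing in the derived F1.  The combination count is
    exactly ``len(females) * len(males)``.
    """
    if females.n_individuals == 0 or males.n_individuals == 0:
        raise ValueError("empty parent set")
    if females.n_markers != males.n_markers:
        raise ValueError("parent sets must share a marker panel")
    fd = _clean_inbred(females.dosage, het_tolerance, "female")
    md = _clean_inbred(males.dosage, het_tolerance, "male")
    nf, nm = fd.shape[0], md.shape[0]
    # vectorized make_f1 over the factorial: mean dosage of homozygous parents
    f = np.repeat(fd, nm, axis=0).astype(np.int16)
    m = np.tile(md, (nf, 1)).astype(np.int16)
    f1 = ((f + m) // 2).astype(np.int8)
    f1[(f == MISSING) | (m == MISSING)] = MISSING
    pairs = pd.DataFrame(
        {
            "female": np.repeat(females.samples, nm),
            "male": list(males.samples) * nf,
        }
    )
    return PseudoCombinations(
        females=list(females.samples),
        males=list(males.samples),
        pairs=pairs,
        f1_dosage=f1,
        markers=females.markers,
    )


def _percentile_score(values: np.ndarray, config: SelectionIndexConfig) -> np.ndarray:
    """Score GEBVs against the candidate set's own percentile bins.

    Bins are right-closed: a value exactly at the 80th percentile falls
    in the 60-80% bin.
    """
    edges = np.quantile(values, config.percentile_edges)
    scores = np.asarray(config.percentile_scores)
    # number of edges strictly below the value = bin index
    idx = np.sum(values[:, None] > edges[None, :], axis=1)
    return scores[idx]


def selection_index(
    gebv: pd.DataFrame,
    config: SelectionIndexConfig | None = None,
) -> pd.DataFrame:
    """Seven-trait selection index for a candidate set.

    ``gebv`` has one row per candidate and one column per trait (all
    four percentile traits and all three range traits must be present;
    candidates with any missing trait GEBV are excluded and logged).
    Returns per-trait scores, the summed index and the high-score flag.
    """
    config = config or SelectionIndexConfig()
    needed = list(config.percentile_traits) + list(config.range_traits)
    missing_cols = [t for t in needed if t not in gebv.columns]
    if missing_cols:
        raise ValueError(f"missing trait columns: {missing_cols}")
    ok = np.isfinite(gebv[needed].to_numpy(dtype=float)).all(axis=1)
    if not ok.all():
        logger.warning("excluded %d candidates with missing trait GEBVs", (~ok).sum())
    sub = gebv.loc[ok].copy()
    out = pd.DataFrame(index=sub.index)
    for trait in config.percentile_traits:
        out[f"score_{trait}"] = _percentile_score(
            sub[trait].to_numpy(dtype=float), config
        )
    for trait, (lo, hi) in config.range_traits.items():
        v = sub[trait].to_numpy(dtype=float)
        in_range = (v >= lo) & (v <= hi)
        out[f"score_{trait}"] = np.where(
            in_range, config.in_range_score, config.out_range_score
        )
    out["index"] = out.sum(axis=1)
    out["high_score"] = out["index"] >= config.high_score_threshold
    return pd.concat([sub, out], axis=1)


@dataclass
class SterilityLocus:
    """A locus whose homozygous genotype sterilizes the hybrid.

    ``sterile_dosage`` is the reference-allele dosage (0 or 2) of the
    homozygote carrying the sterility-causing allele; ``system`` names
    the seed-production scheme the rule applies to: 'WA' (wild-abortive
    cytoplasmic sterility; recessive non-restoring rf alleles) or
    'two_line' (environment-sensitive genic sterility, e.g. tms5).
    """

    name: str
    marker: int
    sterile_dosage: int
    system: str = "WA"

    def __post_init__(self) -> None:
        if self.sterile_dosage not in (0, 2):
            raise ValueError("sterile_dosage must be 0 or 2 (a homozygote)")
        if self.system not in ("WA", "two_line"):
            raise ValueError("system must be 'WA' or 'two_line'")


def screen_sterility(
    combinations: PseudoCombinations,
    loci: list[SterilityLocus],
    cytoplasm: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Flag combinations whose F1 is homozygous for a sterility allele.

    ``cytoplasm`` maps each female line to its system ('WA' or
    'two_line'); a locus is only screened in combinations whose female
    matches its system.  With no map, every locus applies to every
    combination.  A missing F1 genotype at a screened locus yields an
    undetermined (NaN) flag for that locus.
    """
    out = combinations.pairs.copy()
    flagged = np.zeros(len(out), dtype=bool)
    undetermined = np.zeros(len(out), dtype=bool)
    for locus in loci:
        geno = combinations.f1_dosage[:, locus.marker]
        if cytoplasm is None:
            applies = np.ones(len(out), dtype=bool)
        else:
            systems = out["female"].map(cytoplasm)
            applies = (systems == locus.system).to_numpy()
        miss = applies & (geno == MISSING)
        hit = applies & (geno == locus.sterile_dosage)
        out[f"sterile_{locus.name}"] = np.where(
            miss, np.nan, np.where(applies, hit.astype(float), 0.0)
        )
        flagged |= hit
        undetermined |= miss
    out["sterile_any"] = flagged
    out["sterility_undetermined"] = undetermined & ~flagged
    return out
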