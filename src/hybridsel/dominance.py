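"""Per-locus dominance analysis and breeding-favorable alleles.

The degree of dominance at a biallelic locus is computed from the three
genotype-class effects: with A and C the effects of the two homozygotes
and M the heterozygote,

    a = |A - C| / 2          (additive effect)
    d = M - (A + C) / 2      (dominance deviation)

and the degree is d/a for traits where a larger value is favorable and
-d/a where a smaller value is favorable, so a positive degree always
means the heterozygote deviates toward the favorable direction.  A locus
is flagged unreliable when either homozygote class holds fewer than 5
observations.  Class effects default to plain genotype-class means.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

MIN_HOMOZYGOTE_OBS = 5

CATEGORIES = (
    "negative_dominance",
    "additive",
    "partial_dominance",
    "complete_dominance",
    "overdominance",
)


@dataclass
class TraitDirection:
    """Which phenotype values breeding prefers for one trait.

    ``rule`` is ``higher_favorable`` (e.g. yield, gel consistency),
    ``lower_favorable`` (e.g. chalkiness, heading date under the
    concentrated-flowering convention) or ``window_favorable`` with an
    optimal interval (e.g. amylose content 13.0-22.0: lower is better but
    only inside the admissible window).
    """

    trait: str
    rule: str = "higher_favorable"
    lo: float | None = None
    hi: float | None = None

    def __post_init__(self) -> None:
        if self.rule not in ("higher_favorable", "lower_favorable", "window_favorable"):
            raise ValueError(f"unknown direction rule {self.rule!r}")
        if self.rule == "window_favorable":
            if self.lo is None or self.hi is None or not self.lo < self.hi:
                raise ValueError("window_favorable needs lo < hi")


def estimate_genotype_effects(
    genotype: np.ndarray, phenotype: np.ndarray
) -> tuple[float, float, float, int, int, int]:
    """Class means (A, M, C) and counts (nA, nM, nC) at one locus.

    A is the reference-homozygote class (dosage 2), C the alternate
    homozygote (dosage 0), M the heterozygote.  Pairs with a missing
    genotype or phenotype are dropped; an empty class yields NaN.
    """
    genotype = np.asarray(genotype)
    phenotype = np.asarray(phenotype, dtype=float)
    keep = (genotype >= 0) & np.isfinite(phenotype)
    g, y = genotype[keep], phenotype[keep]
    out = []
    for dose in (2, 1, 0):
        sel = y[g == dose]
        out.append(float(sel.mean()) if sel.size else float("nan"))
        out.append(sel.size)
    A, nA, M, nM, C, nC = out
    return A, M, C, int(nA), int(nM), int(nC)


def compute_da(
    A: float,
    M: float,
    C: float,
    nA: int,
    nM: int,
    nC: int,
    direction: TraitDirection,
) -> dict:
    """Additive/dominance effects and the signed degree of dominance.

    Returns a record with a, d, degree, validity flag, and the favorable
    homozygote class.  ``degree`` is NaN when a = 0 or a class mean is
    undefined; ``valid`` is False when min(nA, nC) < 5 (class means from
    so few homozygotes are outlier-prone) or the degree is undefined.
    """
    a = abs(A - C) / 2.0
    d = M - (A + C) / 2.0
    if not np.isfinite(a) or not np.isfinite(d) or a == 0.0:
        degree = float("nan")
    elif direction.rule == "lower_favorable":
        degree = -d / a
    else:
        degree = d / a
    valid = min(nA, nC) >= MIN_HOMOZYGOTE_OBS and np.isfinite(degree)
    favorable = define_favorable_allele(A, C, direction)
    return {
        "A": A, "M": M, "C": C, "nA": nA, "nM": nM, "nC": nC,
        "a": a, "d": d, "degree": degree, "valid": valid,
        "favorable_dosage": favorable,
    }


def classify_dominance(
    degree: float,
    additive_band: float = 0.1,
    complete_band: float = 0.1,
) -> str:
    """Verbal dominance category for a finite degree.

    Defaults: |degree| <= 0.1 additive; < -0.1 negative dominance;
    (0.1, 0.9) partial; [0.9, 1.1] complete; > 1.1 overdominance.
    """
    if not np.isfinite(degree):
        raise ValueError("degree must be finite")
    if degree < -additive_band:
        return "negative_dominance"
    if abs(degree) <= additive_band:
        return "additive"
    if degree < 1.0 - complete_band:
        return "partial_dominance"
    if degree <= 1.0 + complete_band:
        return "complete_dominance"
    return "overdominance"


def define_favorable_allele(A: float, C: float, direction: TraitDirection) -> int:
    """Dosage code (2 = reference hom, 0 = alternate hom) of the favorable
    homozygote under the trait's direction rule; -1 when unresolved.

    For a window rule the homozygote inside the optimal window wins; when
    both or neither are inside, the one closer to the window (then the
    lower value, mirroring the lower-is-better reading of the amylose
    rule) wins.
    """
    if not (np.isfinite(A) and np.isfinite(C)):
        return -1
    if direction.rule == "window_favorable":
        lo, hi = direction.lo, direction.hi

        def dist(v: float) -> float:
            return max(lo - v, 0.0, v - hi)

        dA, dC = dist(A), dist(C)
        if dA != dC:
            return 2 if dA < dC else 0
        if A == C:
            return -1
        return 2 if A < C else 0
    if A == C:
        return -1
    if direction.rule == "lower_favorable":
        return 2 if A < C else 0
    return 2 if A > C else 0


class PerLocusDominance(BaseEstimator):
    """Estimate genotype-class effects and dominance degree at every marker.

    scikit-learn style estimator: ``fit(X, y)`` with X an individuals x
    markers dosage matrix (0/1/2, -1 missing) and y the phenotype vector;
    results land in ``estimates_`` (one row per marker).

    Parameters
    ----------
    direction : TraitDirection
        Favorable-direction rule for the trait.
    min_homozygote_obs : int
        Minimum per-homozygote-class count for a locus to be valid.
    additive_band, complete_band : float
        Category half-widths around degree 0 and 1.
    """

    def __init__(
        self,
        direction: TraitDirection | None = None,
        min_homozygote_obs: int = MIN_HOMOZYGOTE_OBS,
        additive_band: float = 0.1,
        complete_band: float = 0.1,
    ):
        self.direction = direction
        self.min_homozygote_obs = min_homozygote_obs
        self.additive_band = additive_band
        self.complete_band = complete_band

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n_individuals, n_markers) matching y")
        direction = self.direction or TraitDirection("trait")
        rows = []
        for j in range(X.shape[1]):
            A, M, C, nA, nM, nC = estimate_genotype_effects(X[:, j], y)
            rec = compute_da(A, M, C, nA, nM, nC, direction)
            rec["locus"] = j
            rec["valid"] = rec["valid"] and min(nA, nC) >= self.min_homozygote_obs
            rec["category"] = (
                classify_dominance(rec["degree"], self.additive_band, self.complete_band)
                if np.isfinite(rec["degree"])
                else "undefined"
            )
            rows.append(rec)
        self.estimates_ = pd.DataFrame(rows).set_index("locus")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X=None) -> pd.DataFrame:
        check_is_fitted(self, "estimates_")
        return self.estimates_


def count_favorable_alleles(
    dosage: np.ndarray, favorable_dosage: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Favorable-allele dosage summed over a loci panel, per individual.

    ``favorable_dosage`` gives, per panel locus, which homozygote (0 or
    2) carries the favorable allele; loci flagged -1 (unresolved) and
    missing genotypes contribute 0 and are tallied separately.  The count
    lies in [0, 2K] for K loci: a homozygous-favorable locus adds 2, a
    heterozygote 1.
    """
    dosage = np.atleast_2d(np.asarray(dosage))
    fav = np.asarray(favorable_dosage)
    resolved = fav >= 0
    obs = dosage >= 0
    # favorable-allele copies: dosage if ref-favored, 2-dosage if alt-favored
    copies = np.where(fav == 2, dosage, 2 - dosage)
    copies = np.where(obs & resolved, copies, 0)
    skipped = (~obs | ~resolved).sum(axis=1)
    return copies.sum(axis=1).astype(int), skipped.astype(int)


def select_top_loci(
    assoc: pd.DataFrame,
    k: int = 100,
    clump_radius_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Top-k independent association signals by ascending p-value.

    Greedy clumping: walk loci from the smallest p-value, keep a locus as
    the representative of its signal, and discard any weaker locus within
    ``clump_radius_bp`` on the same chromosome.  Needs columns chrom,
    pos, p.
    """
    if not np.isfinite(assoc["p"]).all():
        raise ValueError("association table contains non-finite p-values")
    ranked = assoc.sort_values("p", kind="mergesort").reset_index(drop=True)
    kept: list[int] = []
    for i in range(len(ranked)):
        row = ranked.iloc[i]
        clash = any(
            ranked.iloc[jj]["chrom"] == row["chrom"]
            and abs(ranked.iloc[jj]["pos"] - row["pos"]) <= clump_radius_bp
            for jj in kept
        )
        if not clash:
            kept.append(i)
        if len(kept) == k:
            break
    if len(kept) < k:
        warnings.warn(
            f"only {len(kept)} independent signals available, {k} requested",
            stacklevel=2,
        )
    return ranked.iloc[kept].reset_index(drop=True)


def genotype_frequency_trajectory(
    dosage: np.ndarray,
    groups: np.ndarray,
    favorable_dosage: int = 2,
) -> pd.DataFrame:
    """Genotype-class and favorable-allele frequencies per group.

    One row per group (e.g. breeding periods Y1/Y2/Y3) with the
    frequencies of the favorable homozygote, heterozygote and unfavorable
    homozygote over non-missing calls, plus the favorable-allele
    frequency.  Frequencies in each row sum to 1.
    """
    dosage = np.asarray(dosage)
    groups = np.asarray(groups)
    if favorable_dosage not in (0, 2):
        raise ValueError("favorable_dosage must be 0 or 2")
    rows = []
    for grp in pd.unique(groups):
        sel = dosage[groups == grp]
        sel = sel[sel >= 0]
        if sel.size == 0:
            rows.append({"group": grp, "freq_hom_favorable": np.nan,
                         "freq_het": np.nan, "freq_hom_unfavorable": np.nan,
                         "freq_favorable_allele": np.nan, "n": 0})
            continue
        fav_copies = sel if favorable_dosage == 2 else 2 - sel
        rows.append(
            {
                "group": grp,
                "freq_hom_favorable": float((fav_copies == 2).mean()),
                "freq_het": float((fav_copies == 1).mean()),
                "freq_hom_unfavorable": float((fav_copies == 0).mean()),
                "freq_favorable_allele": float(fav_copies.mean() / 2.0),
                "n": int(sel.size),
            }
        )
    return pd.DataFrame(rows)


def compute_bph(
    f1: float, mother: float, father: float, direction: TraitDirection
) -> dict:
    """Better-parent heterosis of one parent-hybrid trio.

    The better parent is the favorable-direction extreme of the two
    parents; BPH is reported both on the trait scale (F1 - best) and
    relative to the better parent, with the indicator on the absolute
    form.  For lower-favorable traits the sign is flipped so positive
    BPH always means the hybrid beats its better parent.
    """
    vals = np.array([f1, mother, father], dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("all three trio phenotypes must be present")
    lower = direction.rule == "lower_favorable"
    best = min(mother, father) if lower else max(mother, father)
    bph = (best - f1) if lower else (f1 - best)
    rel = bph / abs(best) if best != 0 else float("nan")
    return {"bph": bph, "bph_relative": rel, "exceeds_better_parent": bph > 0}


def fraction_exceeding_parents(
    f2_phenotypes: np.ndarray,
    mother: float,
    father: float,
    direction: TraitDirection,
) -> float:
    """Fraction of F2 individuals strictly better than both parents
    (transgressive segregation) under the trait's direction rule."""
    y = np.asarray(f2_phenotypes, dtype=float)
    y = y[np.isfinite(y)]
    if y.size == 0:
        raise ValueError("empty F2 phenotype set")
    if direction.rule == "lower_favorable":
        return float((y < min(mother, father)).mean())
    return float((y > max(mother, father)).mean())
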