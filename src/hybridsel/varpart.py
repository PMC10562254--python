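"""Regional variance partitioning around an association signal.

The phenotypic variance attributable to a candidate region (by default
the 1 Mb window surrounding an association peak) is estimated with a
mixed model carrying four genetic random effects — additive and dominance
kernels built separately from the markers inside and outside the region —
plus an i.i.d. residual:

    y = L b + u_a1 + u_d1 + u_a2 + u_d2 + e

From the REML variance components, the genetic proportion of the region
is (s_a1 + s_d1) / (s_a1 + s_d1 + s_a2 + s_d2) and the proportion of
phenotypic variance explained (PVE) adds the residual to the
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .gblup import build_relationship_matrices
from .reml import reml

COMPONENT_NAMES = ("additive_in", "dominance_in", "additive_out", "dominance_out")


def split_region(
    markers: pd.DataFrame,
    chrom: str,
    peak_bp: int,
    span_bp: int = 1_000_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Partition marker indices into in-region and out-region sets.

    The region is the ``span_bp`` window centered on the peak (half the
    span on each side).  The two sets are disjoint and exhaustive; an
    empty set on either side is an error.
    """
    pos = markers["pos"].to_numpy()
    on_chrom = markers["chrom"].to_numpy() == chrom
    half = span_bp / 2.0
    inside = on_chrom & (np.abs(pos - peak_bp) <= half)
    in_idx = np.where(inside)[0]
    out_idx = np.where(~inside)[0]
    if in_idx.size == 0:
        raise ValueError(f"no markers within {span_bp} bp of {chrom}:{peak_bp}")
    if out_idx.size == 0:
        raise ValueError("candidate region swallows the whole map; nothing outside")
    return in_idx, out_idx


@dataclass
class PveResult:
    """Genetic proportion and PVE of a candidate region."""

    genetic_proportion: float
    pve: float
    defined: bool


def compute_pve(components: dict[str, float]) -> PveResult:
    """The two displayed ratios from the five variance components.

    ``components`` maps the four genetic component names plus
    ``residual`` to their estimates.  Undefined (flagged) when all four
    genetic components are zero.
    """
    s_in = components["additive_in"] + components["dominance_in"]
    s_out = components["additive_out"] + components["dominance_out"]
    s_e = components["residual"]
    total_g = s_in + s_out
    if total_g <= 0:
        return PveResult(float("nan"), float("nan"), False)
    return PveResult(
        genetic_proportion=s_in / total_g,
        pve=s_in / (total_g + s_e),
        defined=True,
    )


class RegionVariancePartitioner(BaseEstimator):
    """Four-kernel REML fit of a candidate region's variance contribution.

    ``fit(X, y)`` takes the full dosage matrix and phenotype; the region
    is specified either by explicit marker indices (``in_region``) or by
    a marker map plus peak coordinates.

    Attributes (after fit)
    ----------------------
    components_ : dict of the five variance components.
    genetic_proportion_, pve_ : the two ratios.
    converged_, loglik_ : REML diagnostics.
    """

    def __init__(
        self,
        in_region: np.ndarray | None = None,
        markers: pd.DataFrame | None = None,
        chrom: str | None = None,
        peak_bp: int | None = None,
        span_bp: int = 1_000_000,
        dominance_denominator: str = "shared",
        max_iter: int = 200,
        tol: float = 1e-6,
        jitter: float = 1e-6,
    ):
        self.in_region = in_region
        self.markers = markers
        self.chrom = chrom
        self.peak_bp = peak_bp
        self.span_bp = span_bp
        self.dominance_denominator = dominance_denominator
        self.max_iter = max_iter
        self.tol = tol
        self.jitter = jitter

    def _region_indices(self, m: int) -> tuple[np.ndarray, np.ndarray]:
        if self.in_region is not None:
            in_idx = np.asarray(self.in_region)
            if in_idx.dtype == bool:
                in_idx = np.where(in_idx)[0]
            mask = np.zeros(m, dtype=bool)
            mask[in_idx] = True
            if not mask.any() or mask.all():
                raise ValueError("region must be a proper non-empty marker subset")
            return np.where(mask)[0], np.where(~mask)[0]
        if self.markers is None or self.chrom is None or self.peak_bp is None:
            raise ValueError("give either in_region or (markers, chrom, peak_bp)")
        return split_region(self.markers, self.chrom, self.peak_bp, self.span_bp)

    def fit(self, X, y, covariates: np.ndarray | None = None):
        X = np.asarray(X)
        y = np.asarray(y, dtype=float).ravel()
        in_idx, out_idx = self._region_indices(X.shape[1])
        design = np.ones((y.shape[0], 1))
        if covariates is not None:
            design = np.column_stack([design, covariates])
        rel_in = build_relationship_matrices(X[:, in_idx], self.dominance_denominator)
        rel_out = build_relationship_matrices(X[:, out_idx], self.dominance_denominator)
        kernels = [rel_in.A, rel_in.D, rel_out.A, rel_out.D]
        res = reml(
            y, kernels, X=design, kernel_names=list(COMPONENT_NAMES),
            max_iter=self.max_iter, tol=self.tol, jitter=self.jitter,
        )
        self.components_ = res.as_dict()
        self.reml_ = res
        self.converged_ = res.converged
        self.loglik_ = res.loglik
        pve = compute_pve(self.components_)
        self.genetic_proportion_ = pve.genetic_proportion
        self.pve_ = pve.pve
        self.pve_defined_ = pve.defined
        self.in_region_idx_ = in_idx
        self.out_region_idx_ = out_idx
        self.n_features_in_ = X.shape[1]
        return self

    def result_(self) -> PveResult:
        check_is_fitted(self, "components_")
        return compute_pve(self.components_)
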