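"""Subspecies-differentiated SNP calling and japonica-introgression scanning.

Differentiated SNPs are markers where the two reference panels (19 indica,
23 temperate japonica accessions by default) are near-fixed for opposite
major alleles: at least ``min_indica`` indica accessions share one
genotype, at least ``min_japonica`` japonica accessions share one
genotype, and the two panel major alleles differ.

A test sample is then labelled at every differentiated SNP as II
(homozygous indica-major), JJ (homozygous japonica-major), IJ
(heterozygous) or missing, and a 199-SNP sliding window with 1-SNP step
calls a window homozygous-japonica when >=120 labels are JJ and
heterozygous-japonica when >=120 are IJ.  Passing windows of one state
are unioned into maximal runs and reported as segments; the 199/120 pair
means no window can pass both states at once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._typing import GenotypeMatrix

logger = logging.getLogger(__name__)

# label codes of an AncestryTrack
II, IJ, JJ, MISS = np.int8(0), np.int8(1), np.int8(2), np.int8(-1)
LABEL_NAMES = {0: "II", 1: "IJ", 2: "JJ", -1: "missing"}
STATE_HOM, STATE_HET = "hom_japonica", "het_japonica"


@dataclass
class DifferentiatedPanel:
    """Markers whose major allele separates the two subspecies panels.

    ``table`` has one row per retained marker: chromosome, 1-based bp
    position, the source-map marker index, the indica- and japonica-major
    alleles as reference-dosage codes (0 or 2) plus their bases, and the
    supporting accession counts in each panel.
    """

    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)

    def chrom_slices(self) -> list[tuple[str, np.ndarray]]:
        """(chromosome, row indices) in map order."""
        out = []
        chroms = self.table["chrom"].to_numpy()
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out.append((chroms[start], np.arange(start, i)))
                start = i
        return out


@dataclass
class AncestryTrack:
    """Per-differentiated-SNP subspecies labels for one individual."""

    individual: str
    labels: np.ndarray  # int8 in {II, IJ, JJ, MISS}, one per panel marker
    panel: DifferentiatedPanel

    def __post_init__(self) -> None:
        if self.labels.shape[0] != len(self.panel):
            raise ValueError("label count must equal panel size")

    def counts(self) -> dict[str, int]:
        vals, cnts = np.unique(self.labels, return_counts=True)
        out = {name: 0 for name in ("II", "IJ", "JJ", "missing")}
        for v, c in zip(vals, cnts):
            out[LABEL_NAMES[int(v)]] = int(c)
        return out


def _modal_genotype(dosage_col: np.ndarray) -> tuple[int, int]:
    """(modal genotype value, count) among non-missing calls; (-1,0) if none."""
    obs = dosage_col[dosage_col >= 0]
    if obs.size == 0:
        return -1, 0
    cnt = np.bincount(obs, minlength=3)
    mode = int(np.argmax(cnt))
    return mode, int(cnt[mode])


def _major_allele_dosage(dosage_col: np.ndarray) -> int:
    """Dosage code (0 or 2) of the panel major allele; -1 on a tie/no data."""
    obs = dosage_col[dosage_col >= 0]
    if obs.size == 0:
        return -1
    ref_count = int(obs.sum())  # reference-allele copies
    alt_count = 2 * obs.size - ref_count
    if ref_count == alt_count:
        return -1
    return 2 if ref_count > alt_count else 0


def call_differentiated_snps(
    indica_panel: GenotypeMatrix,
    japonica_panel: GenotypeMatrix,
    min_indica: int = 17,
    min_japonica: int = 21,
) -> DifferentiatedPanel:
    """Apply the three panel criteria marker by marker.

    A marker is retained iff (1) the modal genotype of the indica panel is
    shared by >= ``min_indica`` accessions, (2) the japonica modal genotype
    by >= ``min_japonica``, and (3) the two panel major alleles differ.
    Missing panel genotypes count toward neither criterion.
    """
    if indica_panel.n_individuals == 0 or japonica_panel.n_individuals == 0:
        raise ValueError("empty reference panel")
    if indica_panel.n_markers != japonica_panel.n_markers or not np.array_equal(
        indica_panel.markers["pos"].to_numpy(),
        japonica_panel.markers["pos"].to_numpy(),
    ):
        raise ValueError("reference panels must share one marker map")

    rows = []
    markers = indica_panel.markers
    for j in range(indica_panel.n_markers):
        ind_col = indica_panel.dosage[:, j]
        jap_col = japonica_panel.dosage[:, j]
        _, n_ind = _modal_genotype(ind_col)
        _, n_jap = _modal_genotype(jap_col)
        if n_ind < min_indica or n_jap < min_japonica:
            continue
        ind_major = _major_allele_dosage(ind_col)
        jap_major = _major_allele_dosage(jap_col)
        if ind_major < 0 or jap_major < 0 or ind_major == jap_major:
            continue
        rec = markers.iloc[j]
        base = {0: rec["alt"], 2: rec["ref"]}
        rows.append(
            {
                "chrom": rec["chrom"],
                "pos": int(rec["pos"]),
                "marker_index": j,
                "indica_major_dosage": ind_major,
                "japonica_major_dosage": jap_major,
                "indica_major_base": base[ind_major],
                "japonica_major_base": base[jap_major],
                "n_indica_support": n_ind,
                "n_japonica_support": n_jap,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "marker_index",
            "indica_major_dosage", "japonica_major_dosage",
            "indica_major_base", "japonica_major_base",
            "n_indica_support", "n_japonica_support",
        ],
    )
    return DifferentiatedPanel(table)


def classify_sites(
    sample: np.ndarray, panel: DifferentiatedPanel, individual: str = "sample"
) -> AncestryTrack:
    """Label one individual at every differentiated SNP.

    ``sample`` is the full-map dosage row; the panel's ``marker_index``
    column selects the differentiated sites.  Homozygous indica-major ->
    II, homozygous japonica-major -> JJ, heterozygous -> IJ, anything
    else -> missing.
    """
    idx = panel.table["marker_index"].to_numpy()
    dose = np.asarray(sample, dtype=np.int8)[idx]
    ind_major = panel.table["indica_major_dosage"].to_numpy()
    jap_major = panel.table["japonica_major_dosage"].to_numpy()
    labels = np.full(len(panel), MISS, dtype=np.int8)
    labels[dose == 1] = IJ
    labels[(dose >= 0) & (dose != 1) & (dose == ind_major)] = II
    labels[(dose >= 0) & (dose != 1) & (dose == jap_major)] = JJ
    n_unknown = int(((dose >= 0) & (labels == MISS)).sum())
    if n_unknown:
        logger.debug("%s: %d calls did not match either major allele", individual, n_unknown)
    return AncestryTrack(individual, labels, panel)


def _window_pass(labels: np.ndarray, code: np.int8, window: int,
                 step: int, min_hits: int) -> np.ndarray:
    """Start indices of passing windows for one state on one chromosome."""
    n = labels.shape[0]
    if n < window:
        return np.empty(0, dtype=np.int64)
    hit = (labels == code).astype(np.int32)
    csum = np.concatenate([[0], np.cumsum(hit)])
    starts = np.arange(0, n - window + 1, step)
    counts = csum[starts + window] - csum[starts]
    return starts[counts >= min_hits]


def _runs_from_coverage(cov: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs (half-open) of strictly positive coverage."""
    pos = cov > 0
    if not pos.any():
        return []
    d = np.diff(pos.astype(np.int8))
    starts = list(np.where(d == 1)[0] + 1)
    ends = list(np.where(d == -1)[0] + 1)
    if pos[0]:
        starts.insert(0, 0)
    if pos[-1]:
        ends.append(pos.shape[0])
    return list(zip(starts, ends))


def scan_introgression(
    track: AncestryTrack,
    window: int = 199,
    step: int = 1,
    min_hits: int = 120,
) -> pd.DataFrame:
    """Sliding-window detection of japonica-origin segments in one track.

    Returns a BED-like frame: individual, chrom, start/end as 0-based
    half-open indices into that chromosome's panel SNPs, bp positions of
    the first and last covered SNP, state, and the number of supporting
    windows.  Windows never span chromosomes; a chromosome with fewer
    panel SNPs than the window yields no calls.  Where runs of the two
    states overlap, each SNP goes to the state with more covering windows
    (ties to the heterozygous state).
    """
    records = []
    for chrom, rows in track.panel.chrom_slices():
        labels = track.labels[rows]
        pos = track.panel.table["pos"].to_numpy()[rows]
        n = labels.shape[0]
        cov = {}
        for state, code in ((STATE_HOM, JJ), (STATE_HET, IJ)):
            starts = _window_pass(labels, code, window, step, min_hits)
            c = np.zeros(n + 1, dtype=np.int32)
            np.add.at(c, starts, 1)
            np.add.at(c, starts + window, -1)
            cov[state] = np.cumsum(c[:-1])
        both = (cov[STATE_HOM] > 0) & (cov[STATE_HET] > 0)
        if both.any():
            # conflict zone: SNP goes to the better-covered state, ties het
            hom_keeps = both & (cov[STATE_HOM] > cov[STATE_HET])
            cov[STATE_HOM] = np.where(both & ~hom_keeps, 0, cov[STATE_HOM])
            cov[STATE_HET] = np.where(hom_keeps, 0, cov[STATE_HET])
        for state in (STATE_HOM, STATE_HET):
            for lo, hi in _runs_from_coverage(cov[state]):
                records.append(
                    {
                        "individual": track.individual,
                        "chrom": chrom,
                        "start_index": int(lo),
                        "end_index": int(hi),
                        "start_bp": int(pos[lo]),
                        "end_bp": int(pos[hi - 1]),
                        "state": state,
                        "n_windows": int(cov[state][lo:hi].max()),
                        "n_snps": int(hi - lo),
                    }
                )
    cols = ["individual", "chrom", "start_index", "end_index",
            "start_bp", "end_bp", "state", "n_windows", "n_snps"]
    out = pd.DataFrame(records, columns=cols)
    return out.sort_values(["chrom", "start_index", "state"]).reset_index(drop=True)


def summarize_introgression(
    segments: pd.DataFrame,
    bins: pd.DataFrame,
    individuals: list[str],
) -> pd.DataFrame:
    """Per-bin fraction of individuals carrying each segment state.

    ``bins`` needs columns chrom, start_bp, end_bp (half-open in bp); a
    segment counts toward a bin when their bp extents overlap.
    """
    if len(individuals) == 0:
        raise ValueError("empty population")
    out = bins.copy().reset_index(drop=True)
    n = len(individuals)
    for state in (STATE_HOM, STATE_HET):
        fracs = np.zeros(len(out))
        sub = segments[segments["state"] == state]
        for b, brow in out.iterrows():
            hits = sub[
                (sub["chrom"] == brow["chrom"])
                & (sub["start_bp"] < brow["end_bp"])
                & (sub["end_bp"] >= brow["start_bp"])
            ]
            fracs[b] = hits["individual"].nunique() / n
        out[f"frac_{state}"] = fracs
    return out


def genome_composition(track: AncestryTrack) -> dict[str, float]:
    """Fractions of II / IJ / JJ sequence over classified panel SNPs.

    The three fractions sum to 1; the missing fraction (over all panel
    SNPs) is reported separately.
    """
    counts = track.counts()
    classified = counts["II"] + counts["IJ"] + counts["JJ"]
    if classified == 0:
        raise ValueError("track has no classified labels")
    total = classified + counts["missing"]
    return {
        "II": counts["II"] / classified,
        "IJ": counts["IJ"] / classified,
        "JJ": counts["JJ"] / classified,
        "missing": counts["missing"] / total,
    }
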