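"""Differentiated-SNP calling and introgression scanning against oracles."""

import numpy as np
import pandas as pd
import pytest

from hybridsel import (
    DifferentiatedPanel,
    call_differentiated_snps,
    classify_sites,
    genome_composition,
    make_f1,
    scan_introgression,
    summarize_introgression,
)
from hybridsel.ancestry import II, IJ, JJ, MISS, STATE_HET, STATE_HOM

from conftest import toy_genotypes


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def oracle_differentiated(ind_dosage, jap_dosage, min_ind, min_jap):
    """Brute-force marker-by-marker application of the three criteria."""
    kept = []
    for j in range(ind_dosage.shape[1]):
        retained = True
        majors = []
        for panel, thresh in ((ind_dosage[:, j], min_ind), (jap_dosage[:, j], min_jap)):
            obs = [g for g in panel if g >= 0]
            if not obs:
                retained = False
                break
            counts = {}
            for g in obs:
                counts[g] = counts.get(g, 0) + 1
            if max(counts.values()) < thresh:
                retained = False
                break
            ref = sum(obs)
            alt = 2 * len(obs) - ref
            if ref == alt:
                retained = False
                break
            majors.append(2 if ref > alt else 0)
        if retained and majors[0] != majors[1]:
            kept.append(j)
    return kept


def oracle_scan(labels, window, min_hits):
    """Exhaustive enumeration of every window, then run extraction.

    Returns {state: list of (start, end) half-open index runs} applying
    the same cross-state conflict rule as the scanner (better-covered
    state wins, ties to het).
    """
    n = len(labels)
    cov = {}
    for state, code in ((STATE_HOM, JJ), (STATE_HET, IJ)):
        c = np.zeros(n, dtype=int)
        for s in range(0, n - window + 1):
            if int((labels[s:s + window] == code).sum()) >= min_hits:
                c[s:s + window] += 1
        cov[state] = c
    hom, het = cov[STATE_HOM].copy(), cov[STATE_HET].copy()
    for i in range(n):
        if hom[i] > 0 and het[i] > 0:
            if hom[i] > het[i]:
                het[i] = 0
            else:
                hom[i] = 0
    out = {}
    for state, c in ((STATE_HOM, hom), (STATE_HET, het)):
        runs, start = [], None
        for i in range(n + 1):
            active = i < n and c[i] > 0
            if active and start is None:
                start = i
            elif not active and start is not None:
                runs.append((start, i))
                start = None
        out[state] = runs
    return out


def panel_from_labels(n, chrom="chr1"):
    """A trivial panel whose markers map II->dosage 2, JJ->dosage 0."""
    table = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": 1000 * np.arange(n) + 1,
            "marker_index": np.arange(n),
            "indica_major_dosage": 2,
            "japonica_major_dosage": 0,
            "indica_major_base": "A",
            "japonica_major_base": "G",
            "n_indica_support": 19,
            "n_japonica_support": 23,
        }
    )
    return DifferentiatedPanel(table)


def track_from_labels(labels, chrom="chr1"):
    from hybridsel.ancestry import AncestryTrack

    labels = np.asarray(labels, dtype=np.int8)
    return AncestryTrack("t", labels, panel_from_labels(len(labels), chrom))


# ---------------------------------------------------------------------------
# differentiated-SNP calling
# ---------------------------------------------------------------------------

class TestDifferentiatedSnps:
    def test_literal_rule_retains_marker(self):
        # 17 indica ref-hom + 2 alt-hom; 22 japonica alt-hom + 1 missing
        ind = np.array([[2]] * 17 + [[0]] * 2, dtype=np.int8)
        jap = np.array([[0]] * 22 + [[-1]], dtype=np.int8)
        panel = call_differentiated_snps(
            toy_genotypes(ind), toy_genotypes(jap), 17, 21
        )
        assert len(panel) == 1
        row = panel.table.iloc[0]
        assert row["indica_major_dosage"] == 2 and row["japonica_major_dosage"] == 0
        assert row["n_indica_support"] == 17 and row["n_japonica_support"] == 22

    def test_identical_major_alleles_rejected(self):
        ind = np.array([[2]] * 19, dtype=np.int8)
        jap = np.array([[2]] * 22 + [[0]], dtype=np.int8)
        panel = call_differentiated_snps(toy_genotypes(ind), toy_genotypes(jap))
        assert len(panel) == 0

    def test_below_threshold_rejected(self):
        ind = np.array([[2]] * 16 + [[0]] * 3, dtype=np.int8)  # mode 16 < 17
        jap = np.array([[0]] * 23, dtype=np.int8)
        panel = call_differentiated_snps(toy_genotypes(ind), toy_genotypes(jap))
        assert len(panel) == 0

    def test_matches_bruteforce_oracle_on_simulation(self, founder_sim):
        _, indica, japonica, _ = founder_sim
        panel = call_differentiated_snps(indica, japonica)
        expected = oracle_differentiated(indica.dosage, japonica.dosage, 17, 21)
        assert panel.table["marker_index"].tolist() == expected
        assert len(panel) > 0

    def test_mismatched_maps_and_empty_panels_error(self, founder_sim):
        _, indica, japonica, _ = founder_sim
        with pytest.raises(ValueError, match="marker map"):
            call_differentiated_snps(indica, japonica.subset_markers(np.arange(10)))
        with pytest.raises(ValueError, match="empty"):
            call_differentiated_snps(indica.subset_individuals([]), japonica)


# ---------------------------------------------------------------------------
# site classification
# ---------------------------------------------------------------------------

class TestClassifySites:
    def test_pure_founders_and_f1(self, fixed_founder_sim):
        _, indica, japonica, _ = fixed_founder_sim
        panel = call_differentiated_snps(indica, japonica)
        assert len(panel) == indica.n_markers  # fully fixed differentiation
        jap_track = classify_sites(japonica.dosage[0], panel)
        assert (jap_track.labels == JJ).all()
        ind_track = classify_sites(indica.dosage[0], panel)
        assert (ind_track.labels == II).all()
        f1 = make_f1(indica.dosage[0], japonica.dosage[0])
        f1_track = classify_sites(f1, panel)
        assert (f1_track.labels == IJ).all()

    def test_labels_match_generator_truth(self, founder_sim):
        _, indica, japonica, truth = founder_sim
        panel = call_differentiated_snps(indica, japonica)
        idx = panel.table["marker_index"].to_numpy()
        # an accession carrying the japonica major allele at a marker
        sample = japonica.dosage[3]
        track = classify_sites(sample, panel)
        expected = np.where(
            sample[idx] == panel.table["japonica_major_dosage"], JJ, II
        )
        np.testing.assert_array_equal(track.labels, expected)

    def test_label_counts_partition_panel(self, founder_sim):
        _, indica, japonica, _ = founder_sim
        panel = call_differentiated_snps(indica, japonica)
        sample = indica.dosage[5].copy()
        sample[panel.table["marker_index"].to_numpy()[:10]] = -1
        track = classify_sites(sample, panel)
        counts = track.counts()
        assert sum(counts.values()) == len(panel)
        assert counts["missing"] >= 10


# ---------------------------------------------------------------------------
# sliding-window scan
# ---------------------------------------------------------------------------

class TestScan:
    def test_all_het_window_yields_full_segment(self):
        segments = scan_introgression(track_from_labels([IJ] * 199))
        assert len(segments) == 1
        seg = segments.iloc[0]
        assert seg["state"] == STATE_HET
        assert (seg["start_index"], seg["end_index"]) == (0, 199)

    def test_below_min_hits_unassigned(self):
        labels = [IJ] * 119 + [II] * 80
        assert scan_introgression(track_from_labels(labels)).empty

    def test_chromosome_shorter_than_window_is_silent(self):
        assert scan_introgression(track_from_labels([JJ] * 150)).empty

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_window_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 1200
        labels = rng.choice([II, IJ, JJ, MISS], size=n,
                            p=[0.45, 0.2, 0.25, 0.1]).astype(np.int8)
        # plant a solid JJ block to guarantee calls
        start = rng.integers(0, n - 320)
        labels[start:start + 300] = JJ
        segments = scan_introgression(track_from_labels(labels))
        expect = oracle_scan(labels, 199, 120)
        for state in (STATE_HOM, STATE_HET):
            got = [
                (r["start_index"], r["end_index"])
                for _, r in segments[segments["state"] == state].iterrows()
            ]
            assert got == expect[state]

    def test_min_hits_monotonicity(self):
        rng = np.random.default_rng(42)
        labels = rng.choice([II, IJ, JJ], size=2000, p=[0.3, 0.3, 0.4]).astype(np.int8)
        lengths = []
        for min_hits in (100, 120, 140, 160):
            seg = scan_introgression(track_from_labels(labels), min_hits=min_hits)
            lengths.append(seg["n_snps"].sum() if len(seg) else 0)
        assert lengths == sorted(lengths, reverse=True)

    def test_missing_counts_toward_neither_state(self):
        # 119 JJ + 80 missing: min_hits=120 not reached over the window
        labels = np.array([JJ] * 119 + [MISS] * 80, dtype=np.int8)
        assert scan_introgression(track_from_labels(labels)).empty

    def test_purity_property_full_coverage(self):
        labels = np.array([JJ] * 500, dtype=np.int8)
        seg = scan_introgression(track_from_labels(labels))
        assert len(seg) == 1
        assert (seg.iloc[0]["start_index"], seg.iloc[0]["end_index"]) == (0, 500)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

class TestSummaries:
    def test_single_segment_bin_fraction(self):
        segments = pd.DataFrame(
            [{"individual": "a", "chrom": "chr1", "start_bp": 100,
              "end_bp": 900, "state": STATE_HOM}]
        )
        bins = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start_bp": [0, 1000], "end_bp": [1000, 2000]}
        )
        out = summarize_introgression(segments, bins, ["a"])
        assert out["frac_hom_japonica"].tolist() == [1.0, 0.0]
        assert out["frac_het_japonica"].tolist() == [0.0, 0.0]

    def test_no_segments_all_zero(self):
        bins = pd.DataFrame({"chrom": ["chr1"], "start_bp": [0], "end_bp": [1000]})
        out = summarize_introgression(
            pd.DataFrame(columns=["individual", "chrom", "start_bp", "end_bp", "state"]),
            bins, ["a", "b"],
        )
        assert (out[["frac_hom_japonica", "frac_het_japonica"]].to_numpy() == 0).all()

    def test_planted_fractions_match_direct_count(self):
        rng = np.random.default_rng(7)
        inds = [f"i{k}" for k in range(50)]
        rows = []
        carriers = set(rng.choice(50, size=20, replace=False).tolist())
        for k in carriers:
            rows.append({"individual": f"i{k}", "chrom": "chr1",
                         "start_bp": 10, "end_bp": 490, "state": STATE_HET})
        segments = pd.DataFrame(rows)
        bins = pd.DataFrame({"chrom": ["chr1"], "start_bp": [0], "end_bp": [500]})
        out = summarize_introgression(segments, bins, inds)
        assert out["frac_het_japonica"].iloc[0] == pytest.approx(len(carriers) / 50)

    def test_genome_composition(self):
        track = track_from_labels([II] * 25 + [IJ] * 50 + [JJ] * 25)
        comp = genome_composition(track)
        assert comp["II"] == 0.25 and comp["IJ"] == 0.5 and comp["JJ"] == 0.25
        with pytest.raises(ValueError, match="classified"):
            genome_composition(track_from_labels([MISS] * 10))

    def test_composition_pure_cases(self, fixed_founder_sim):
        _, indica, japonica, _ = fixed_founder_sim
        panel = call_differentiated_snps(indica, japonica)
        comp_j = genome_composition(classify_sites(japonica.dosage[0], panel))
        assert comp_j["JJ"] == 1.0 and comp_j["II"] == 0.0
        f1 = make_f1(indica.dosage[0], japonica.dosage[0])
        comp_f1 = genome_composition(classify_sites(f1, panel))
        assert comp_f1["IJ"] == 1.0
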