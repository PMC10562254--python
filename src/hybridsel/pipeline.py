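"""End-to-end pipeline: simulate -> scan -> effects -> PVE -> GBLUP -> index.

Driven by a YAML run configuration; every output TSV/JSON is written
deterministically (fixed column order, fixed float formatting, seeds
derived from the one master seed), so two runs of the same config are
byte-identical.  A metadata JSON records the config hash, seeds and
per-stage record counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._rng import rng_for
from .ancestry import (
    call_differentiated_snps,
    classify_sites,
    genome_composition,
    scan_introgression,
)
from .dominance import PerLocusDominance, TraitDirection
from .gblup import GBLUP, cross_validate_gblup
from .io import (
    write_matrix_tsv,
    write_phenotypes,
    write_segments,
    write_truth_json,
    write_vcf,
)
from .selection import (
    SelectionIndexConfig,
    SterilityLocus,
    enumerate_combinations,
    screen_sterility,
    selection_index,
)
from .simulate import (
    QtlEffect,
    SimulationConfig,
    make_f1,
    simulate_founders,
    simulate_hybrid_cohort,
    simulate_inbred_lines,
    simulate_phenotypes,
)
from .varpart import RegionVariancePartitioner

logger = logging.getLogger(__name__)

DEFAULT_TRAITS: dict[str, dict] = {
    "yield_per_plant": {"rule": "higher_favorable", "base": 20.0},
    "seed_setting_rate": {"rule": "higher_favorable", "base": 80.0},
    "full_grain_number": {"rule": "higher_favorable", "base": 150.0},
    "valid_panicle_number": {"rule": "higher_favorable", "base": 9.0},
    "heading_date": {"rule": "lower_favorable", "base": 85.0},
    "plant_height": {"rule": "higher_favorable", "base": 120.0},
    "grain_shape": {"rule": "window_favorable", "lo": 3.0, "hi": 3.4, "base": 3.2},
}


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict) or "seed" not in cfg:
        raise ValueError("run config must be a mapping with at least a 'seed'")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _trait_directions(cfg: dict) -> dict[str, TraitDirection]:
    traits = cfg.get("traits") or DEFAULT_TRAITS
    out = {}
    for name, spec in traits.items():
        out[name] = TraitDirection(
            name, spec.get("rule", "higher_favorable"),
            lo=spec.get("lo"), hi=spec.get("hi"),
        )
    return out


def _draw_qtls(cfg: dict, n_markers: int, seed: int) -> dict[str, list[QtlEffect]]:
    """Per-trait causal architectures drawn from the master seed."""
    traits = cfg.get("traits") or DEFAULT_TRAITS
    n_qtl = int(cfg.get("training", {}).get("n_qtl_per_trait", 20))
    spec = {}
    for name in traits:
        rng = rng_for(seed, "qtl", name)
        loci = rng.choice(n_markers, size=min(n_qtl, n_markers), replace=False)
        a = rng.normal(0.0, 1.0, size=loci.shape[0])
        d = rng.normal(0.0, 0.5, size=loci.shape[0])
        spec[name] = [QtlEffect(int(m), float(av), float(dv))
                      for m, av, dv in zip(np.sort(loci), a, d)]
    return spec


def run_pipeline(cfg: dict, output_dir: str | Path) -> dict:
    """Execute all stages; returns the metadata bundle that was written."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    meta: dict = {
        "tool": "hybridsel",
        "version": __version__,
        "config_hash": config_hash(cfg),
        "seed": seed,
        "stages": {},
    }

    def stage(name):
        def wrap(fn):
            try:
                meta["stages"][name] = fn()
            except Exception as exc:  # noqa: BLE001 - rethrown with stage name
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        return wrap

    sim_cfg = SimulationConfig(seed=seed, **cfg.get("simulation", {}))
    directions = _trait_directions(cfg)
    scan_cfg = cfg.get("scan", {})

    # --- founders and differentiated-SNP panel -------------------------
    indica, japonica, truth = simulate_founders(sim_cfg)

    @stage("simulate_founders")
    def _():
        write_vcf(indica, out / "panel_indica.vcf")
        write_vcf(japonica, out / "panel_japonica.vcf")
        write_truth_json(
            {
                "is_differentiated": truth.is_differentiated,
                "indica_major_dosage": truth.indica_major_dosage,
                "japonica_major_dosage": truth.japonica_major_dosage,
            },
            out / "founder_truth.json",
        )
        return {"n_indica": indica.n_individuals, "n_japonica": japonica.n_individuals,
                "n_markers": indica.n_markers}

    panel = call_differentiated_snps(
        indica, japonica,
        min_indica=int(scan_cfg.get("min_indica", 17)),
        min_japonica=int(scan_cfg.get("min_japonica", 21)),
    )

    @stage("differentiated_panel")
    def _():
        panel.table.to_csv(out / "differentiated_panel.tsv", sep="\t", index=False)
        return {"n_differentiated": len(panel)}

    # --- introgression scan on an indica x japonica F1 -----------------
    f1_row = make_f1(indica.dosage[0], japonica.dosage[0])
    track = classify_sites(f1_row, panel, individual="demo_F1")
    segments = scan_introgression(
        track,
        window=int(scan_cfg.get("window", 199)),
        step=int(scan_cfg.get("step", 1)),
        min_hits=int(scan_cfg.get("min_hits", 120)),
    )

    @stage("introgression_scan")
    def _():
        write_segments(segments, out / "introgression_segments.tsv")
        comp = genome_composition(track)
        pd.DataFrame([comp]).to_csv(
            out / "genome_composition.tsv", sep="\t", index=False,
            float_format="%.6f",
        )
        return {"n_segments": len(segments)}

    # --- training cohort with known QTLs -------------------------------
    train_cfg = cfg.get("training", {})
    qtls = _draw_qtls(cfg, sim_cfg.n_markers, seed)
    markers = indica.markers
    cohort = simulate_hybrid_cohort(
        int(train_cfg.get("n_hybrids", 250)), markers, seed
    )
    h2 = {t: float(train_cfg.get("heritability", 0.5)) for t in qtls}
    pheno, genetic = simulate_phenotypes(cohort, qtls, h2, seed)
    traits_cfg = cfg.get("traits") or DEFAULT_TRAITS
    for t in qtls:
        pheno[t] = pheno[t] + float(traits_cfg[t].get("base", 0.0))

    @stage("training_cohort")
    def _():
        write_matrix_tsv(cohort, out / "training_genotypes.tsv")
        write_phenotypes(pheno, out / "training_phenotypes.tsv")
        return {"n_individuals": cohort.n_individuals}

    # --- per-locus dominance on the first trait ------------------------
    focus = next(iter(qtls))

    @stage("dominance_effects")
    def _():
        est = PerLocusDominance(direction=directions[focus]).fit(
            cohort.dosage, pheno[focus].to_numpy()
        )
        table = est.estimates_.reset_index()
        table.to_csv(out / f"dominance_{focus}.tsv", sep="\t", index=False,
                     float_format="%.6g")
        return {"trait": focus, "n_valid": int(table["valid"].sum())}

    # --- regional variance partition around the strongest QTL ----------
    @stage("variance_partition")
    def _():
        top = max(qtls[focus], key=lambda q: abs(q.a))
        part = RegionVariancePartitioner(
            markers=markers,
            chrom=str(markers.iloc[top.marker]["chrom"]),
            peak_bp=int(markers.iloc[top.marker]["pos"]),
            span_bp=int(cfg.get("pve", {}).get("span_bp", 1_000_000)),
        ).fit(cohort.dosage, pheno[focus].to_numpy())
        rec = dict(part.components_)
        rec.update(
            genetic_proportion=part.genetic_proportion_, pve=part.pve_,
            converged=part.converged_, trait=focus,
        )
        pd.DataFrame([rec]).to_csv(out / "pve.tsv", sep="\t", index=False,
                                   float_format="%.6g")
        return {"pve": round(float(part.pve_), 4), "converged": bool(part.converged_)}

    # --- GBLUP per trait, CV, candidate scoring ------------------------
    gs_cfg = cfg.get("gblup", {})
    idx_cfg = cfg.get("index", {})
    @stage("genomic_selection")
    def _():
        females = simulate_inbred_lines(
            int(idx_cfg.get("n_females", 12)), markers, seed, stage="female"
        )
        males = simulate_inbred_lines(
            int(idx_cfg.get("n_males", 8)), markers, seed, stage="male"
        )
        combos = enumerate_combinations(females, males)
        gebv = pd.DataFrame(index=range(len(combos)))
        cv_report = {}
        for t in qtls:
            model = GBLUP(use_dominance=bool(gs_cfg.get("use_dominance", False))).fit(
                cohort.dosage, pheno[t].to_numpy()
            )
            gebv[t] = model.predict(combos.f1_dosage)
            cv = cross_validate_gblup(
                cohort.dosage, pheno[t].to_numpy(),
                k=int(gs_cfg.get("k_folds", 6)),
                iterations=int(gs_cfg.get("iterations", 3)),
                seed=seed,
            )
            cv_report[t] = round(cv["accuracy"], 4)
        gebv.insert(0, "male", combos.pairs["male"].to_numpy())
        gebv.insert(0, "female", combos.pairs["female"].to_numpy())
        write_phenotypes(gebv, out / "candidate_gebv.tsv")
        (out / "cv_report.json").write_text(
            json.dumps(cv_report, indent=1, sort_keys=True)
        )
        scored = selection_index(gebv, SelectionIndexConfig())
        loci = [
            SterilityLocus("rf3", 0, 0, "WA"),
            SterilityLocus("rf4", 1, 0, "WA"),
            SterilityLocus("tms5", 2, 0, "two_line"),
        ]
        flags = screen_sterility(combos, loci)
        scored = scored.merge(
            flags, on=["female", "male"], how="left", sort=False
        )
        scored.to_csv(out / "selection_index.tsv", sep="\t", index=False,
                      float_format="%.6g")
        return {
            "n_combinations": len(combos),
            "n_high_score": int(scored["high_score"].sum()),
            "cv_accuracy": cv_report,
        }

    (out / "metadata.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    return meta
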