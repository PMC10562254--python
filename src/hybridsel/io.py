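"""Reading and writing genotypes, phenotypes, panels and segments.

Genotypes travel either as a minimal VCF v4.2 (GT field only, 1-based
positions, './.' for missing) or as a plain matrix TSV (markers as
columns ``chrom:pos``, dosage values with NA for missing).  Segment
tables are BED-like: 0-based half-open bp intervals.  VCF parsing uses
cyvcf2; multiallelic and non-SNP records are skipped with a logged
count.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from ._typing import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1"}  # dosage of REF -> GT of ALT copies


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Minimal VCF v4.2 with GT only.

    Note the dosage convention: dosage counts REF-allele copies, so
    dosage 2 is written 0/0 and dosage 0 is 1/1.
    """
    path = Path(path)
    markers = genotypes.markers
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in markers["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        cols = "\t".join(genotypes.samples)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        dosage = genotypes.dosage
        for j in range(genotypes.n_markers):
            rec = markers.iloc[j]
            gts = "\t".join(
                _GT_CODE[2 - int(d)] if d != MISSING else "./."
                for d in dosage[:, j]
            )
            fh.write(
                f"{rec['chrom']}\t{rec['pos']}\t{rec['chrom']}:{rec['pos']}\t"
                f"{rec['ref']}\t{rec['alt']}\t.\t.\t.\tGT\t{gts}\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Load biallelic SNP records with GT from a VCF.

    Multiallelic or non-SNP records are skipped (count logged).  Phased
    and unphased separators parse identically; genetic-map positions are
    reconstructed as NaN (unknown) unless the caller supplies them later.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, dose = [], []
    skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or not rec.is_snp:
            skipped += 1
            continue
        gts = rec.genotype.array()
        alt_copies = np.where(
            (gts[:, 0] < 0) | (gts[:, 1] < 0), -1, gts[:, 0] + gts[:, 1]
        )
        ref_dosage = np.where(alt_copies < 0, MISSING, 2 - alt_copies)
        dose.append(ref_dosage.astype(np.int8))
        rows.append(
            {"chrom": rec.CHROM, "pos": rec.POS, "cm": np.nan,
             "ref": rec.REF, "alt": rec.ALT[0]}
        )
    if skipped:
        logger.info("skipped %d multiallelic/non-SNP records", skipped)
    if not rows:
        raise ValueError(f"no usable biallelic SNP records in {path}")
    markers = pd.DataFrame(rows)
    return GenotypeMatrix(np.array(dose, dtype=np.int8).T, samples, markers)


def write_matrix_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Plain dosage matrix: rows = individuals, columns = chrom:pos."""
    cols = [
        f"{c}:{p}" for c, p in zip(genotypes.markers["chrom"], genotypes.markers["pos"])
    ]
    df = pd.DataFrame(genotypes.dosage, index=genotypes.samples, columns=cols)
    df = df.replace(int(MISSING), pd.NA)
    df.to_csv(path, sep="\t", index_label="id", na_rep="NA")


def read_matrix_tsv(path: str | Path, markers: pd.DataFrame | None = None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="id", na_values="NA")
    dosage = df.to_numpy(dtype=float)
    dosage = np.where(np.isfinite(dosage), dosage, MISSING).astype(np.int8)
    if markers is None:
        chrom_pos = [c.split(":") for c in df.columns]
        markers = pd.DataFrame(
            {
                "chrom": [c for c, _ in chrom_pos],
                "pos": [int(p) for _, p in chrom_pos],
                "cm": np.nan,
                "ref": "N",
                "alt": "N",
            }
        )
    return GenotypeMatrix(dosage, list(df.index.astype(str)), markers)


def read_genotypes(path: str | Path, fmt: str | None = None) -> GenotypeMatrix:
    """Dispatch on format ('vcf' or 'matrix-tsv'; guessed from suffix)."""
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix == ".vcf" else "matrix-tsv"
    if fmt == "vcf":
        return read_vcf(path)
    if fmt == "matrix-tsv":
        return read_matrix_tsv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values="NA")
    if "id" not in df.columns:
        raise ValueError("phenotype table needs an 'id' column")
    return df


def write_segments(segments: pd.DataFrame, path: str | Path) -> None:
    """BED-like segment table: 0-based half-open bp intervals."""
    bed = segments.copy()
    # end_bp in segment frames is the position of the last covered SNP
    # (1-based, inclusive); BED convention is 0-based half-open
    bed["start"] = bed["start_bp"] - 1
    bed["end"] = bed["end_bp"]
    cols = ["chrom", "start", "end", "individual", "state", "n_snps", "n_windows"]
    bed[cols].to_csv(path, sep="\t", index=False)


def read_segments(path: str | Path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t")
    bed["start_bp"] = bed["start"] + 1
    bed["end_bp"] = bed["end"]
    return bed


def write_truth_json(truth: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating, np.bool_)):
            return o.item()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(truth, indent=1, default=default, sort_keys=True))


def read_truth_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
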