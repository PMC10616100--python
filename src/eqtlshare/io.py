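"""Readers and writers for the pipeline's interchange formats.

TSV is the canonical interchange (association tables, phenotypes, truth,
modules, annotations, loci); genotype panels can additionally be written as
minimal VCF (GT fields, dosage 0/0.5/1 <-> 0/0, 0/1, 1/1) and read back.
Every report written by :func:`write_reports` carries a header comment with
the configuration hash and seed, and outputs are byte-deterministic for a
given input.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .synth import GenotypePanel


class SchemaError(ValueError):
    """A required column is missing or a row is malformed."""


ASSOCIATION_COLUMNS = ["variant", "chrom", "pos", "beta", "se", "p", "maf", "n"]


def read_association_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a TSV association table.

    Requires columns variant, chrom, pos, beta, se, p, maf, n (ref/alt kept if
    present); enforces pos >= 1 and p in (0, 1] (p = 0 rows are clamped to the
    smallest positive double with a warning); rejects duplicate variant keys.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in ASSOCIATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    bad_pos = df.index[df["pos"] < 1]
    if len(bad_pos):
        raise SchemaError(f"{path}: pos < 1 at line {bad_pos[0] + 2}")
    bad_p = df.index[(df["p"] < 0) | (df["p"] > 1)]
    if len(bad_p):
        raise SchemaError(f"{path}: p outside [0, 1] at line {bad_p[0] + 2}")
    n_zero = int((df["p"] == 0).sum())
    if n_zero:
        warnings.warn(f"{path}: clamped {n_zero} p-value(s) of 0 to the smallest double")
        df.loc[df["p"] == 0, "p"] = np.finfo(float).tiny
    if df.duplicated(subset=["variant"]).any():
        raise SchemaError(f"{path}: duplicated variant key")
    return df


def write_table(df: pd.DataFrame, path: str | Path, header_meta: dict | None = None) -> None:
    """Write a TSV with deterministic column order and an optional '#' header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_meta:
            fh.write("# " + json.dumps(header_meta, sort_keys=True) + "\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def write_dosage_tsv(panel: GenotypePanel, path: str | Path) -> None:
    """Dosage matrix as TSV: variant metadata columns then one column per sample."""
    meta = panel.variants[["id", "chrom", "pos", "ref", "alt"]].copy()
    dos = pd.DataFrame(
        panel.dosages.T, columns=panel.sample_ids, index=meta.index
    )
    write_table(pd.concat([meta, dos], axis=1), path)


_GT = {0.0: "0/0", 0.5: "0/1", 1.0: "1/1"}


def write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Minimal VCF 4.2 with GT fields only."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        for j, (_, v) in enumerate(panel.variants.iterrows()):
            gts = "\t".join(
                _GT.get(d, "./.") if not np.isnan(d) else "./."
                for d in panel.dosages[:, j]
            )
            fh.write(
                f"{v['chrom']}\t{v['pos']}\t{v['id']}\t{v['ref']}\t{v['alt']}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


def read_vcf(path: str | Path) -> GenotypePanel:
    """Read a VCF with GT fields back into a panel (via cyvcf2).

    Diploid genotypes map to dosages 0 / 0.5 / 1; missing calls to NaN.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows, cols = [], []
    for rec in vcf:
        gt = np.asarray(rec.gt_types, dtype=float)  # 0/1/2 alt copies, 3 missing
        gt[gt == 3] = np.nan
        cols.append(gt / 2.0)
        rows.append(
            {"id": rec.ID or f"{rec.CHROM}:{rec.POS}", "chrom": str(rec.CHROM),
             "pos": int(rec.POS), "ref": rec.REF, "alt": rec.ALT[0] if rec.ALT else ".",
             "gene": "", "block": -1}
        )
    vcf.close()
    variants = pd.DataFrame(rows)
    dosages = np.array(cols, dtype=float).T if cols else np.empty((len(samples), 0))
    genes = pd.DataFrame(columns=["gene", "chrom", "body_start", "body_end"])
    return GenotypePanel(samples, variants, dosages, genes)


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED intervals (0-based half-open, kept as such internally)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=["chrom", "start", "end"],
    )
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_reports(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    config: PipelineConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Write every table to ``out_dir`` with a config-hash header; returns the
    manifest (file, rows). Row order is made deterministic by sorting on all
    columns before writing."""
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    meta = {"config_hash": config.config_hash(), "seed": seed}
    manifest_rows = []
    for name in sorted(tables):
        df = tables[name]
        if len(df):
            df = df.sort_values(list(df.columns), kind="mergesort").reset_index(drop=True)
        path = out_dir / f"{name}.tsv"
        write_table(df, path, meta)
        manifest_rows.append({"file": path.name, "rows": len(df)})
    manifest = pd.DataFrame(manifest_rows, columns=["file", "rows"])
    write_table(manifest, out_dir / "manifest.tsv", meta)
    return manifest
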