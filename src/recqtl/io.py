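"""Readers and writers for the formats the pipeline touches.

Phased genotypes travel as VCF with '|'-separated GT fields (1-based
positions, biallelic records); tables as TSV with named headers.  Round
trips are identity transforms and coordinates never shift.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .errors import MissingGenotypeError, ParseError, PhaseError, SchemaError
from .hapscan import AssocResult, ScanResult, Window
from .panel import HaplotypePanel, VariantTable


# ---------------------------------------------------------------------------
# phased VCF


def write_phased_vcf(panel: HaplotypePanel, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in panel.chromosomes:
            sl_lo, sl_hi = panel._chrom_offsets[c]
            fh.write(f"##contig=<ID={c},length={int(panel.pos[sl_hi - 1]) + 1}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.ids)
            + "\n"
        )
        a = panel.alleles
        for j in range(panel.n_snps):
            gts = "\t".join(
                f"{a[i, 0, j]}|{a[i, 1, j]}" for i in range(panel.n_individuals)
            )
            fh.write(
                f"{panel.chrom[j]}\t{panel.pos[j]}\t{panel.snp_ids[j]}\t"
                f"{panel.ref[j]}\t{panel.alt[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_phased_vcf(path) -> HaplotypePanel:
    """Read a phased VCF into a panel.

    Raises :class:`PhaseError` on any '/'-separated genotype (naming the
    record) and :class:`MissingGenotypeError` on missing calls: the panel
    substrate is imputed and phased, hence complete.
    """
    vcf = VCF(str(path))
    ids = list(vcf.samples)
    chroms, poss, snp_ids, refs, alts, rows = [], [], [], [], [], []
    for rec in vcf:
        geno = rec.genotype.array()  # (N, 3): allele0, allele1, phased flag
        if np.any(geno[:, :2] < 0):
            raise MissingGenotypeError(
                f"missing genotype at {rec.CHROM}:{rec.POS}"
            )
        if np.any(geno[:, 2] == 0):
            raise PhaseError(f"unphased genotype at {rec.CHROM}:{rec.POS}")
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        snp_ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        refs.append(rec.REF)
        alts.append(rec.ALT[0] if rec.ALT else ".")
        rows.append(geno[:, :2].astype(np.uint8))
    alleles = np.stack(rows, axis=2) if rows else np.empty((len(ids), 2, 0), np.uint8)
    return HaplotypePanel(
        ids=ids,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        snp_ids=np.array(snp_ids, dtype=object),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        alleles=alleles,
    )


# ---------------------------------------------------------------------------
# generic typed tables


def read_table(path, schema: dict[str, type]) -> pd.DataFrame:
    """TSV reader with header and cell validation.

    ``schema`` maps required column names to types (float, int, str, bool).
    Missing columns raise :class:`SchemaError` listing them; a malformed
    numeric cell raises :class:`ParseError` with its line number (1-based,
    header is line 1).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    out = {}
    for col, typ in schema.items():
        s = df[col]
        if typ is str:
            out[col] = s
            continue
        if typ is bool:
            out[col] = s.map({"True": True, "False": False, "1": True, "0": False})
            if out[col].isna().any() and s.notna().any():
                bad = int(np.flatnonzero(out[col].isna() & s.notna())[0])
                raise ParseError(
                    f"malformed boolean in column {col!r} at line {bad + 2}"
                )
            continue
        converted = pd.to_numeric(s, errors="coerce")
        bad_mask = converted.isna() & s.notna()
        if bad_mask.any():
            bad = int(np.flatnonzero(bad_mask)[0])
            raise ParseError(
                f"malformed numeric in column {col!r} at line {bad + 2}: {s.iloc[bad]!r}"
            )
        out[col] = converted if typ is float else converted.astype("Int64")
    extra = [c for c in df.columns if c not in schema]
    for c in extra:
        out[c] = df[c]
    return pd.DataFrame(out)


PHENOTYPE_SCHEMA = {"id": str, "phenotype": float, "cohort": str}


def write_phenotypes(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return read_table(path, PHENOTYPE_SCHEMA)


# ---------------------------------------------------------------------------
# scan results


SCAN_COLUMNS = [
    "chrom",
    "start",
    "end",
    "start_bp",
    "end_bp",
    "alleles",
    "frequency",
    "mode",
    "n_hom",
    "beta",
    "se",
    "p",
    "n_used",
    "status",
]


def write_scan_results(results, path) -> None:
    """Results TSV: window geometry, allele string, frequency, mode, test stats."""
    if isinstance(results, ScanResult):
        results = results.results
    rows = []
    for r in results:
        w = r.window
        rows.append(
            {
                "chrom": w.chrom if w else "",
                "start": w.start if w else "",
                "end": w.end if w else "",
                "start_bp": w.start_bp if w else "",
                "end_bp": w.end_bp if w else "",
                "alleles": r.target,
                "frequency": r.frequency,
                "mode": r.mode,
                "n_hom": r.n_hom,
                "beta": r.beta,
                "se": r.se,
                "p": r.p,
                "n_used": r.n_used,
                "status": r.status,
            }
        )
    pd.DataFrame(rows, columns=SCAN_COLUMNS).to_csv(path, sep="\t", index=False)


def read_scan_results(path) -> list[AssocResult]:
    df = read_table(
        path,
        {
            "chrom": str,
            "start": int,
            "end": int,
            "start_bp": int,
            "end_bp": int,
            "alleles": str,
            "frequency": float,
            "mode": str,
            "n_hom": int,
            "beta": float,
            "se": float,
            "p": float,
            "n_used": int,
            "status": str,
        },
    )
    results = []
    for _, row in df.iterrows():
        window = None
        if pd.notna(row["chrom"]) and row["chrom"] != "":
            window = Window(
                str(row["chrom"]),
                int(row["start"]),
                int(row["end"]),
                start_bp=int(row["start_bp"]),
                end_bp=int(row["end_bp"]),
            )
        results.append(
            AssocResult(
                target=str(row["alleles"]),
                window=window,
                mode=str(row["mode"]),
                frequency=float(row["frequency"]),
                n_hom=None if pd.isna(row["n_hom"]) else int(row["n_hom"]),
                beta=float(row["beta"]) if pd.notna(row["beta"]) else math.nan,
                se=float(row["se"]) if pd.notna(row["se"]) else math.nan,
                p=float(row["p"]) if pd.notna(row["p"]) else math.nan,
                n_used=int(row["n_used"]),
                status=str(row["status"]),
            )
        )
    return results


# ---------------------------------------------------------------------------
# variant tables


def write_variants(variants: VariantTable, path) -> None:
    """Variant TSV: metadata columns then one dosage column per individual."""
    data = {
        "variant_id": variants.variant_ids,
        "chrom": variants.chrom,
        "pos": variants.pos,
        "ref": variants.ref,
        "alt": variants.alt,
        "af": variants.alt_freq,
        "imp_r2": variants.imp_r2,
    }
    for i, ind in enumerate(variants.individual_ids):
        data[ind] = variants.dosages[:, i]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_variants(path) -> VariantTable:
    meta = {"variant_id": str, "chrom": str, "pos": int, "ref": str, "alt": str,
            "af": float, "imp_r2": float}
    df = read_table(path, meta)
    individual_ids = [c for c in df.columns if c not in meta]
    dosages = df[individual_ids].to_numpy(dtype=str).astype(np.uint8)
    return VariantTable(
        variant_ids=list(df["variant_id"]),
        chrom=df["chrom"].to_numpy(dtype=object),
        pos=df["pos"].to_numpy(dtype=np.int64),
        ref=df["ref"].to_numpy(dtype=object),
        alt=df["alt"].to_numpy(dtype=object),
        dosages=dosages,
        imp_r2=df["imp_r2"].to_numpy(dtype=float),
        individual_ids=individual_ids,
    )
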