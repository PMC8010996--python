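"""Carrier-compatibility fine-mapping of sequence variants at a haplotype QTL.

For a top haplotype, each individual's carrier status (0/1/2 copies) is
inferred by exact string matching in the window.  Sequence variants within a
margin (default +/- 3 Mb) of the haplotype are then screened for allele
frequencies compatible with complete linkage to a recessive haplotype:

* > 0.8 in homozygous haplotype carriers,
* within [0.4, 0.6] in heterozygous carriers,
* < 0.05 in non-carriers,

for at least one allele orientation (the haplotype-linked allele may be the
reference or the alternate).  A complementary recessive association test is
run on variants passing minor-allele-frequency (> 0.05) and imputation-
quality (r^2 > 0.4) filters, coding each variant as the indicator of
homozygosity for its minor allele, with the same least-squares machinery as
the haplotype scan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import IdMismatchError, InvalidConfigError
from .hapscan import AssocResult, HaplotypeCall, _Projector
from .panel import HaplotypePanel, VariantTable, Window, aligned_phenotype


@dataclass
class CompatibilityResult:
    variant_id: str
    af_hom: float  # alt-allele frequency in homozygous carriers (NaN if class empty)
    af_het: float
    af_noncarrier: float
    compatible: bool
    orientation: str | None  # "alt" or "ref" when compatible, else None
    indeterminate: bool = False


def carrier_status(panel: HaplotypePanel, call: HaplotypeCall) -> np.ndarray:
    """Copies (0/1/2) of the call's haplotype per individual, by string match."""
    return panel.haplotype_copies(call.window, call.alleles)


def class_allele_frequencies(
    variants: VariantTable, status: np.ndarray
) -> np.ndarray:
    """Alt-allele frequency per carrier class for every variant.

    Returns an array of shape (V, 3) ordered (hom, het, non-carrier).  An
    empty class yields NaN (an undefined marker, distinct from 0).
    """
    status = np.asarray(status)
    if len(status) != len(variants.individual_ids):
        raise IdMismatchError("carrier status length does not match variant table")
    if len(status) == 0:
        raise InvalidConfigError("no individuals")
    out = np.full((variants.n_variants, 3), np.nan)
    for col, cls in enumerate((2, 1, 0)):
        mask = status == cls
        n = int(mask.sum())
        if n:
            out[:, col] = variants.dosages[:, mask].sum(axis=1) / (2 * n)
    return out


def _orientation_ok(
    hom: float, het: float, non: float, slack: float
) -> bool:
    return (
        hom > 0.8 - slack
        and 0.4 - slack <= het <= 0.6 + slack
        and non < 0.05 + slack
    )


def compatibility_filter(
    variants: VariantTable,
    status: np.ndarray,
    chrom: str,
    region_start: int,
    region_end: int,
    slack: float = 0.0,
) -> list[CompatibilityResult]:
    """Variants in the region whose class frequencies fit recessive linkage.

    The region is given in base pairs (caller typically extends the haplotype
    bounds by 3 Mb).  Boundary semantics are strict for > 0.8 and < 0.05 and
    inclusive for [0.4, 0.6]; ``slack`` relaxes all three (a crude allowance
    for genotyping error, default exact).  Variants with an empty carrier
    class are marked indeterminate, not compatible.
    """
    freqs = class_allele_frequencies(variants, status)
    results = []
    for v in range(variants.n_variants):
        if variants.chrom[v] != chrom:
            continue
        if not region_start <= variants.pos[v] <= region_end:
            continue
        hom, het, non = freqs[v]
        if any(math.isnan(f) for f in (hom, het, non)):
            results.append(
                CompatibilityResult(
                    variants.variant_ids[v], hom, het, non,
                    compatible=False, orientation=None, indeterminate=True,
                )
            )
            continue
        orientation = None
        if _orientation_ok(hom, het, non, slack):
            orientation = "alt"
        elif _orientation_ok(1 - hom, 1 - het, 1 - non, slack):
            orientation = "ref"
        results.append(
            CompatibilityResult(
                variants.variant_ids[v], hom, het, non,
                compatible=orientation is not None, orientation=orientation,
            )
        )
    return results


def variant_recessive_assoc(
    variants: VariantTable,
    phenotypes,
    pcs=None,
    conditional: np.ndarray | None = None,
    maf_min: float = 0.05,
    r2_min: float = 0.4,
) -> tuple[list[AssocResult], list[str]]:
    """Recessive association of sequence variants with the phenotype.

    Variants failing the MAF (> maf_min) or imputation-quality (> r2_min)
    filters are excluded and their ids reported.  Each retained variant is
    coded as the indicator of homozygosity for its *minor* allele and tested
    with OLS conditional on the principal components (and an optional
    covariate), exactly as in the haplotype scan.
    """
    import pandas as pd

    if isinstance(phenotypes, pd.DataFrame):
        table = phenotypes.set_index("id")["phenotype"]
        missing = [s for s in variants.individual_ids if s not in table.index]
        if missing:
            raise IdMismatchError(f"phenotype missing for: {missing[:5]}")
        y = table.loc[variants.individual_ids].to_numpy(dtype=float)
    else:
        y = np.asarray(phenotypes, dtype=float)
    n = len(variants.individual_ids)
    if len(y) != n:
        raise IdMismatchError("phenotype length does not match variant table")

    cov_cols = []
    if pcs is not None:
        cov_cols.append(np.asarray(getattr(pcs, "vectors", pcs), dtype=float))
    if conditional is not None:
        cov_cols.append(np.asarray(conditional, dtype=float)[:, None])
    cov = np.column_stack(cov_cols) if cov_cols else None
    proj = _Projector(cov, n)
    y_r = proj.residualize(y)

    af = variants.alt_freq
    maf = np.minimum(af, 1 - af)
    results: list[AssocResult] = []
    excluded: list[str] = []
    for v in range(variants.n_variants):
        if maf[v] <= maf_min or variants.imp_r2[v] <= r2_min:
            excluded.append(variants.variant_ids[v])
            continue
        minor_is_alt = af[v] <= 0.5
        x = (
            (variants.dosages[v] == 2) if minor_is_alt else (variants.dosages[v] == 0)
        ).astype(float)
        window = Window(
            str(variants.chrom[v]), 1, 1,
            start_bp=int(variants.pos[v]), end_bp=int(variants.pos[v]),
        )
        if np.ptp(x) == 0:
            results.append(
                AssocResult(
                    variants.variant_ids[v], window, "recessive",
                    float(maf[v]), int(x.sum()),
                    math.nan, math.nan, math.nan, n, status="degenerate",
                )
            )
            continue
        x_r = proj.residualize(x)
        beta, se, p = proj.fast_fit(y_r, x_r)
        status = "ok" if math.isfinite(p) else "perfect_fit"
        results.append(
            AssocResult(
                variants.variant_ids[v], window, "recessive",
                float(maf[v]), int(x.sum()), beta, se, p, n, status=status,
            )
        )
    return results, excluded


def ld_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (NaN if constant)."""
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return math.nan
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)
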