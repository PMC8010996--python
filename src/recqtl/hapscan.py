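"""Sliding-window haplotype association scan under additive or recessive inheritance.

The scan shifts a fixed-size window (default 50 contiguous SNPs, step 15)
along the phased autosomal haplotypes.  Within each window every distinct
haplotype with frequency above 1% (among the 2N phased chromosomes) is tested
one-vs-rest for association with the phenotype using the linear model

    y = mu + sum_j a_j PC_j + b * HT + c * k + e

where PC_j are principal components of the genomic relationship matrix, HT is
the haplotype dosage (copy count under additive coding, homozygosity
indicator under recessive coding) and k is an optional conditional covariate
(e.g. the recessively coded carrier status of a previously mapped haplotype).
Recessive tests require the haplotype to be homozygous in at least 0.5% of
individuals.  p-values come from the two-sided t-test on b with residual
degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InvalidConfigError
from .panel import HaplotypePanel, Window, aligned_phenotype

CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, 1))  # ~0.4549


@dataclass(frozen=True)
class HaplotypeCall:
    """One distinct haplotype observed in a window."""

    window: Window
    alleles: str
    frequency: float  # among the 2N phased haplotypes
    n_hom: int  # individuals carrying two copies


@dataclass
class AssocResult:
    """One association test of a haplotype (or sequence variant)."""

    target: str  # haplotype allele string or variant id
    window: Window | None
    mode: str  # "additive" | "recessive"
    frequency: float
    n_hom: int | None
    beta: float
    se: float
    p: float
    n_used: int
    status: str = "ok"  # ok | degenerate | perfect_fit


@dataclass
class ScanResult:
    """All association results of one genome scan plus the realized test count."""

    results: list[AssocResult]
    n_tests: int
    mode: str
    params: dict = field(default_factory=dict)

    def top_hit(self) -> AssocResult:
        """Smallest p; ties broken by higher frequency, then allele string."""
        valid = [r for r in self.results if r.status == "ok"]
        if not valid:
            raise InvalidConfigError("scan produced no valid tests")
        return min(valid, key=lambda r: (r.p, -r.frequency, r.target))

    def p_values(self) -> np.ndarray:
        return np.array([r.p for r in self.results if r.status == "ok"])

    def bonferroni(self, alpha: float = 0.05) -> float:
        return bonferroni_threshold(self.n_tests, alpha)

    def genomic_lambda(self) -> float:
        return genomic_lambda(self.p_values())


# ---------------------------------------------------------------------------
# window geometry


def enumerate_windows(
    n_snps_per_chrom: dict[str, int],
    window_size: int = 50,
    step: int = 15,
) -> list[Window]:
    """Fixed-size windows per chromosome; trailing partial windows are dropped.

    Starts are 1, 1+step, 1+2*step, ... while a full window fits.
    """
    if window_size < 1 or step < 1:
        raise InvalidConfigError("window_size and step must be positive")
    windows = []
    for chrom, m in n_snps_per_chrom.items():
        start = 1
        while start + window_size - 1 <= m:
            windows.append(Window(chrom, start, start + window_size - 1))
            start += step
    return windows


def windows_for_panel(
    panel: HaplotypePanel, window_size: int = 50, step: int = 15
) -> list[Window]:
    """Windows over a panel, with base-pair bounds filled in."""
    counts = {c: panel.n_snps_on(c) for c in panel.chromosomes}
    return [panel.with_bp(w) for w in enumerate_windows(counts, window_size, step)]


# ---------------------------------------------------------------------------
# haplotype extraction and coding


def _encode_haplotypes(haps: np.ndarray) -> np.ndarray:
    """Pack 0/1 rows into uint64 chunk codes (one column per 32 SNPs)."""
    n, w = haps.shape
    n_chunks = (w + 31) // 32
    codes = np.empty((n, n_chunks), dtype=np.uint64)
    for c in range(n_chunks):
        block = haps[:, c * 32 : (c + 1) * 32].astype(np.uint64)
        weights = (np.uint64(1) << np.arange(block.shape[1], dtype=np.uint64))
        codes[:, c] = block @ weights
    return codes


def _window_calls(
    panel: HaplotypePanel, window: Window, min_freq: float
) -> tuple[list[HaplotypeCall], list[np.ndarray]]:
    """Eligible calls in a window plus per-individual copy counts for each.

    Shared by :func:`window_haplotypes` and :func:`scan`; the unique/inverse
    decomposition is computed once per window so dosages come for free.
    """
    window = panel.with_bp(window)
    sub = panel.window_alleles(window)  # (N, 2, w)
    n = sub.shape[0]
    haps = sub.reshape(2 * n, -1)
    codes = _encode_haplotypes(haps)
    if codes.shape[1] == 1:
        uniq_codes, first, inverse, counts = np.unique(
            codes[:, 0], return_index=True, return_inverse=True, return_counts=True
        )
    else:
        _, first, inverse, counts = np.unique(
            codes, axis=0, return_index=True, return_inverse=True,
            return_counts=True,
        )
    pair = inverse.reshape(n, 2)
    hom_counts = np.bincount(
        pair[pair[:, 0] == pair[:, 1], 0], minlength=len(counts)
    )
    calls, copies = [], []
    for i in range(len(counts)):
        freq = counts[i] / (2 * n)
        if freq <= min_freq:
            continue
        alleles = "".join(chr(ord("0") + int(a)) for a in haps[first[i]])
        calls.append(
            HaplotypeCall(window, alleles, float(freq), int(hom_counts[i]))
        )
        copies.append((pair == i).sum(axis=1).astype(np.int64))
    order = sorted(range(len(calls)), key=lambda j: (-calls[j].frequency, calls[j].alleles))
    return [calls[j] for j in order], [copies[j] for j in order]


def window_haplotypes(
    panel: HaplotypePanel, window: Window, min_freq: float = 0.01
) -> list[HaplotypeCall]:
    """Distinct haplotypes in a window with frequency strictly above ``min_freq``.

    Frequencies are exact counts over the 2N phased haplotypes; ``n_hom`` is
    the number of individuals whose two haplotypes both match.  Calls are
    sorted by descending frequency, ties by allele string.
    """
    calls, _ = _window_calls(panel, window, min_freq)
    return calls


def haplotype_dosage(
    panel: HaplotypePanel,
    call: HaplotypeCall,
    mode: str,
    min_hom_frac: float = 0.005,
) -> np.ndarray | None:
    """Per-individual dosage of a haplotype under the chosen inheritance model.

    Additive: copy count in {0, 1, 2}.  Recessive: indicator of two copies,
    produced only when the homozygote fraction reaches ``min_hom_frac``
    (otherwise ``None``, marking the haplotype ineligible for a recessive
    test).
    """
    if mode not in ("additive", "recessive"):
        raise InvalidConfigError(f"unknown inheritance mode {mode!r}")
    copies = panel.haplotype_copies(call.window, call.alleles)
    if mode == "additive":
        return copies.astype(np.float64)
    n = panel.n_individuals
    if (copies == 2).sum() / n < min_hom_frac:
        return None
    return (copies == 2).astype(np.float64)


# ---------------------------------------------------------------------------
# model fitting


def fit_association(
    y: np.ndarray,
    dosage: np.ndarray,
    covariates: np.ndarray | None = None,
    target: str = "",
    window: Window | None = None,
    mode: str = "additive",
    frequency: float = math.nan,
    n_hom: int | None = None,
) -> AssocResult:
    """Ordinary least squares of y on [intercept, covariates, dosage].

    The p-value is the two-sided t-test on the dosage coefficient with
    n - (number of fitted coefficients) residual degrees of freedom.
    Constant dosage yields a degenerate result (no p-value); rank-deficient
    covariates raise an error.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(dosage, dtype=float)
    n = len(y)
    if len(x) != n:
        raise InvalidConfigError("phenotype and dosage lengths differ")
    cols = [np.ones(n)]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        cols.append(cov)
    design_cov = np.column_stack(cols)
    if np.linalg.matrix_rank(design_cov) < design_cov.shape[1]:
        raise InvalidConfigError("covariate matrix is rank deficient")
    if np.ptp(x) == 0:
        return AssocResult(
            target, window, mode, frequency, n_hom,
            math.nan, math.nan, math.nan, n, status="degenerate",
        )
    design = np.column_stack([design_cov, x])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    k = design.shape[1]
    resid = y - design @ coef
    rss = float(resid @ resid)
    df = n - k
    if df <= 0:
        raise InvalidConfigError("not enough observations for the model")
    beta = float(coef[-1])
    xtx_inv = np.linalg.inv(design.T @ design)
    sigma2 = rss / df
    if sigma2 <= np.finfo(float).eps * max(1.0, float(y @ y)):
        return AssocResult(
            target, window, mode, frequency, n_hom,
            beta, 0.0, math.nan, n, status="perfect_fit",
        )
    se = math.sqrt(sigma2 * xtx_inv[-1, -1])
    t = beta / se
    p = float(2 * stats.t.sf(abs(t), df))
    p = max(p, np.nextafter(0, 1))  # keep p in (0, 1]
    return AssocResult(target, window, mode, frequency, n_hom, beta, se, p, n)


class _Projector:
    """Residualizer onto the orthogonal complement of the covariate space.

    Exploits the Frisch-Waugh-Lovell theorem: regressing residualized y on
    residualized x reproduces the full-model coefficient, and the residual
    sum of squares equals the full model's, so t-tests with the full-model
    degrees of freedom are exact.
    """

    def __init__(self, covariates: np.ndarray | None, n: int):
        cols = [np.ones((n, 1))]
        if covariates is not None:
            cov = np.asarray(covariates, dtype=float)
            if cov.ndim == 1:
                cov = cov[:, None]
            cols.append(cov)
        c = np.column_stack(cols)
        if np.linalg.matrix_rank(c) < c.shape[1]:
            raise InvalidConfigError("covariate matrix is rank deficient")
        self.q, _ = np.linalg.qr(c)
        self.n_cov = c.shape[1]
        self.n = n

    def residualize(self, v: np.ndarray) -> np.ndarray:
        return v - self.q @ (self.q.T @ v)

    def fast_fit(self, y_r: np.ndarray, x_r: np.ndarray) -> tuple[float, float, float]:
        """(beta, se, p) for one residualized regressor; x_r must be non-null."""
        sxx = float(x_r @ x_r)
        sxy = float(x_r @ y_r)
        beta = sxy / sxx
        rss = float(y_r @ y_r) - beta * sxy
        df = self.n - self.n_cov - 1
        sigma2 = max(rss, 0.0) / df
        if sigma2 <= 0:
            return beta, 0.0, math.nan
        se = math.sqrt(sigma2 / sxx)
        p = float(2 * stats.t.sf(abs(beta / se), df))
        return beta, se, max(p, np.nextafter(0, 1))


def scan(
    panel: HaplotypePanel,
    phenotypes,
    pcs=None,
    mode: str = "recessive",
    conditional: np.ndarray | None = None,
    window_size: int = 50,
    step: int = 15,
    min_freq: float = 0.01,
    min_hom_frac: float = 0.005,
) -> ScanResult:
    """Genome-wide sliding-window haplotype association scan.

    Parameters
    ----------
    phenotypes : DataFrame (id, phenotype, cohort) or array in panel order.
    pcs : PCSet or (N, k) array of principal components, optional.
    conditional : per-individual covariate in panel order (e.g. recessive
        carrier status of a known haplotype), optional.

    Every eligible haplotype in every window is tested; ``n_tests`` records
    the realized number of tests.  Results are ordered by chromosome, window
    start, then descending haplotype frequency.
    """
    import pandas as pd

    if isinstance(phenotypes, pd.DataFrame):
        y = aligned_phenotype(panel, phenotypes)
    else:
        y = np.asarray(phenotypes, dtype=float)
        if len(y) != panel.n_individuals:
            raise InvalidConfigError("phenotype length does not match panel")
    cov_cols = []
    if pcs is not None:
        vectors = getattr(pcs, "vectors", pcs)
        cov_cols.append(np.asarray(vectors, dtype=float))
    if conditional is not None:
        cov_cols.append(np.asarray(conditional, dtype=float)[:, None])
    cov = np.column_stack(cov_cols) if cov_cols else None
    proj = _Projector(cov, panel.n_individuals)
    y_r = proj.residualize(y)

    n = panel.n_individuals
    yty = float(y_r @ y_r)
    df = n - proj.n_cov - 1
    pending: list[tuple[HaplotypeCall, Window, float, float]] = []
    for window in windows_for_panel(panel, window_size, step):
        calls, copies = _window_calls(panel, window, min_freq)
        for call, cnt in zip(calls, copies):
            if mode == "recessive":
                if call.n_hom / n < min_hom_frac:
                    continue
                dose = (cnt == 2).astype(np.float64)
            else:
                dose = cnt.astype(np.float64)
            if dose.min() == dose.max():
                continue
            x_r = proj.residualize(dose)
            sxx = float(x_r @ x_r)
            if sxx <= 0:
                continue
            beta = float(x_r @ y_r) / sxx
            rss = yty - beta * beta * sxx
            se = math.sqrt(max(rss, 0.0) / df / sxx) if rss > 0 else 0.0
            pending.append((call, window, beta, se))
    # batch two-sided t-test p-values
    betas = np.array([b for _, _, b, _ in pending])
    ses = np.array([s for _, _, _, s in pending])
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(ses > 0, betas / np.where(ses > 0, ses, 1.0), np.inf)
    pvals = 2 * stats.t.sf(np.abs(tvals), df) if len(pending) else np.empty(0)
    pvals = np.maximum(pvals, np.nextafter(0, 1))
    results: list[AssocResult] = []
    for (call, window, beta, se), p in zip(pending, pvals):
        status = "ok" if se > 0 else "perfect_fit"
        results.append(
            AssocResult(
                call.alleles, window, mode, call.frequency, call.n_hom,
                beta, se, float(p) if se > 0 else math.nan, n, status=status,
            )
        )
    return ScanResult(
        results,
        len(results),
        mode,
        params={
            "window_size": window_size,
            "step": step,
            "min_freq": min_freq,
            "min_hom_frac": min_hom_frac,
        },
    )


# ---------------------------------------------------------------------------
# multiple testing and calibration


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise InvalidConfigError("n_tests must be at least 1")
    return alpha / n_tests


def genomic_lambda(p_values: np.ndarray) -> float:
    """Genomic inflation factor: median 1-df chi-square statistic over its null median."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise InvalidConfigError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise InvalidConfigError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_MEDIAN_1DF)
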