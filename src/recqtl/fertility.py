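"""Bull-fertility phenotype from insemination records, and carrier contrasts.

The fertility of an artificial-insemination sire is derived from 0/1
non-return outcomes of first inseminations (y = 1: the cow was not
re-inseminated within 56 days) with the linear mixed model

    y = mu + MO + PA + PR + (BS x BK) + TE + herd + bull + e,

where month, parity, price class, breed combination and technician are fixed
effects and herd and bull are random.  The model is fitted on the observed
scale via Henderson's mixed-model equations; bull solutions are deviations
from the average non-return rate.  Estimates are standardized to 100 +/- 12,
low outliers (> 5 SD below the mean) removed, and cohorts merged after
within-cohort z-standardization.  Carrier contrasts (homozygous-load t-test,
heterozygote-vs-non-carrier regression) quantify the impact of recessive
haplotypes on the derived phenotype.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.linalg import spsolve

from .errors import IdMismatchError, InvalidConfigError, SingularDesignError
from .hapscan import AssocResult, fit_association

FIXED_FACTORS = ("month", "parity", "price", "breed_combo", "technician")


@dataclass
class MMEResult:
    """Solutions of the non-return-rate mixed model."""

    estimates: pd.DataFrame  # bull, raw_effect, n_inseminations
    herd_effects: pd.DataFrame  # herd, effect
    fixed_effects: pd.DataFrame  # term, effect
    variance_ratios: dict


def _fixed_design(records: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    cols = [pd.Series(1.0, index=records.index, name="intercept")]
    for f in FIXED_FACTORS:
        d = pd.get_dummies(records[f].astype(str), prefix=f, drop_first=True)
        cols.append(d.astype(float))
    x = pd.concat(cols, axis=1)
    return x.to_numpy(dtype=float), list(x.columns)


def _aliased_columns(x: np.ndarray, names: list[str]) -> list[str]:
    """Columns that do not increase the rank of the design, in order."""
    aliased = []
    basis = np.empty((x.shape[0], 0))
    for j, name in enumerate(names):
        cand = np.column_stack([basis, x[:, j]])
        if np.linalg.matrix_rank(cand) > basis.shape[1]:
            basis = cand
        else:
            aliased.append(name)
    return aliased


def solve_nrr_mme(
    records: pd.DataFrame,
    variance_ratios: dict | None = None,
) -> MMEResult:
    """Henderson mixed-model equations for the 0/1 non-return outcome.

    ``variance_ratios`` maps 'herd' and 'bull' to lambda = sigma_e^2 /
    sigma_u^2 (defaults 9 and 19; the source evaluation reports no
    components, so these are configuration).  Returns bull solutions as
    deviations from the average non-return rate.
    """
    required = {"bull", "herd", "outcome", *FIXED_FACTORS}
    missing = required - set(records.columns)
    if missing:
        raise InvalidConfigError(f"missing record fields: {sorted(missing)}")
    ratios = {"herd": 9.0, "bull": 19.0}
    if variance_ratios:
        ratios.update(variance_ratios)
    if any(v <= 0 for v in ratios.values()):
        raise InvalidConfigError("variance ratios must be positive")

    y = records["outcome"].to_numpy(dtype=float)
    x, names = _fixed_design(records)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise SingularDesignError(
            f"aliased fixed-effect levels: {_aliased_columns(x, names)}"
        )
    herd_codes, herds = pd.factorize(records["herd"], sort=True)
    bull_codes, bulls = pd.factorize(records["bull"], sort=True)
    n = len(records)
    zh = sparse.csr_matrix(
        (np.ones(n), (np.arange(n), herd_codes)), shape=(n, len(herds))
    )
    zs = sparse.csr_matrix(
        (np.ones(n), (np.arange(n), bull_codes)), shape=(n, len(bulls))
    )
    xs = sparse.csr_matrix(x)
    w = sparse.hstack([xs, zh, zs], format="csr")
    lhs = (w.T @ w).tolil()
    p = x.shape[1]
    h = len(herds)
    for i in range(h):
        lhs[p + i, p + i] += ratios["herd"]
    for i in range(len(bulls)):
        lhs[p + h + i, p + h + i] += ratios["bull"]
    rhs = w.T @ y
    sol = spsolve(lhs.tocsc(), rhs)
    fixed = sol[:p]
    herd_sol = sol[p : p + h]
    bull_sol = sol[p + h :]
    counts = records.groupby("bull").size()
    estimates = pd.DataFrame(
        {
            "bull": list(bulls),
            "raw_effect": bull_sol,
            "n_inseminations": counts.loc[list(bulls)].to_numpy(),
        }
    )
    return MMEResult(
        estimates=estimates,
        herd_effects=pd.DataFrame({"herd": list(herds), "effect": herd_sol}),
        fixed_effects=pd.DataFrame({"term": names, "effect": fixed}),
        variance_ratios=ratios,
    )


def standardize_fertility(
    estimates: pd.DataFrame,
    mean: float = 100.0,
    sd: float = 12.0,
    column: str = "raw_effect",
) -> pd.DataFrame:
    """Affine rescale of bull effects to the target mean and SD (default 100 +/- 12)."""
    if len(estimates) < 2:
        raise InvalidConfigError("need at least 2 bulls to standardize")
    v = estimates[column].to_numpy(dtype=float)
    s = v.std(ddof=1)
    if s == 0:
        raise InvalidConfigError("zero variance among bull effects")
    out = estimates.copy()
    out["fertility"] = mean + sd * (v - v.mean()) / s
    return out


def remove_low_outliers(
    estimates: pd.DataFrame, k: float = 5.0, column: str = "fertility"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop bulls strictly more than k SD below the mean; returns (kept, removed)."""
    v = estimates[column].to_numpy(dtype=float)
    s = v.std(ddof=1)
    if s == 0:
        raise InvalidConfigError("zero variance among fertility values")
    low = v < v.mean() - k * s
    return estimates.loc[~low].copy(), estimates.loc[low].copy()


def merge_cohorts(estimates: pd.DataFrame, column: str = "fertility") -> pd.DataFrame:
    """Within-cohort z-standardization, then concatenation into one table.

    Input needs columns bull, cohort, and the fertility column; the output is
    the standard phenotype table (id, phenotype, cohort).
    """
    if "cohort" not in estimates.columns:
        raise InvalidConfigError("cohort labels required")
    frames = []
    for cohort, grp in estimates.groupby("cohort", sort=True):
        if len(grp) < 2:
            raise InvalidConfigError(f"cohort {cohort!r} has fewer than 2 bulls")
        v = grp[column].to_numpy(dtype=float)
        s = v.std(ddof=1)
        if s == 0:
            raise InvalidConfigError(f"cohort {cohort!r} has zero variance")
        frames.append(
            pd.DataFrame(
                {
                    "id": grp["bull"].to_numpy(),
                    "phenotype": (v - v.mean()) / s,
                    "cohort": cohort,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out.set_index("id").loc[estimates["bull"]].reset_index()


def homozygous_load(
    statuses: list[np.ndarray],
) -> tuple[np.ndarray, dict[int, int]]:
    """Per-bull count of QTL at which the bull is a homozygous carrier.

    ``statuses`` holds one carrier-status vector (0/1/2) per QTL over the
    same bulls in the same order.  Returns the load vector and a class tally
    {load: count} whose values sum to the cohort size.
    """
    if not statuses:
        raise InvalidConfigError("no status vectors given")
    lengths = {len(s) for s in statuses}
    if len(lengths) != 1:
        raise IdMismatchError("status vectors cover different numbers of bulls")
    stacked = np.stack([np.asarray(s) for s in statuses])
    load = (stacked == 2).sum(axis=0)
    tally = {
        k: int(c)
        for k, c in enumerate(np.bincount(load, minlength=len(statuses) + 1))
    }
    return load, tally


def load_contrast_ttest(
    group_a: np.ndarray, group_b: np.ndarray
) -> tuple[float, float]:
    """Welch two-sample t-test (two-tailed) between two groups of NRR values."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InvalidConfigError("each group needs at least 2 observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise InvalidConfigError("zero variance in both groups")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def welch_from_summary(
    n1: int, mean1: float, sd1: float, n2: int, mean2: float, sd2: float
) -> tuple[float, float]:
    """Welch t and two-sided p from group summaries (n, mean, SD)."""
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    t = (mean1 - mean2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = float(2 * stats.t.sf(abs(t), df))
    return float(t), p


def het_vs_noncarrier_test(
    y: np.ndarray,
    status: np.ndarray,
    pcs=None,
    conditional: np.ndarray | None = None,
) -> AssocResult:
    """Heterozygote-vs-non-carrier contrast among bulls with 0 or 1 copies.

    Homozygotes are excluded; the phenotype is regressed on the heterozygote
    indicator with optional principal components and a conditional covariate.
    Under purely recessive inheritance the p-value is null-distributed.
    """
    y = np.asarray(y, dtype=float)
    status = np.asarray(status)
    mask = status < 2
    sub_status = status[mask]
    if not (sub_status == 1).any():
        raise InvalidConfigError("no heterozygous individuals")
    if not (sub_status == 0).any():
        raise InvalidConfigError("no non-carrier individuals")
    cov_cols = []
    if pcs is not None:
        cov_cols.append(np.asarray(getattr(pcs, "vectors", pcs), dtype=float)[mask])
    if conditional is not None:
        cov_cols.append(np.asarray(conditional, dtype=float)[mask, None])
    cov = np.column_stack(cov_cols) if cov_cols else None
    return fit_association(
        y[mask],
        (sub_status == 1).astype(float),
        covariates=cov,
        target="het_vs_noncarrier",
        mode="het_contrast",
    )
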