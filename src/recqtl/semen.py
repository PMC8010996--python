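"""Semen-quality filter cascade, per-bull trait means, and sperm-morphology traits.

Routine fresh-semen records pass a fixed cascade of plausibility and
protocol filters (age window, known inter-collection interval, recorded
volume, unmixed, processed, interval <= 8 days, first ejaculate per day,
motility >= 70%, plausible anomaly scores, >= 15 million sperm per straw and
not sex-sorted, known collector/handler, genotype available, >= 8 surviving
records per bull).  Sperm-morphology exams count sperm across 16 defect
categories; category 0-2 are non-compensatory (head shape, vacuoles,
condensed DNA) and the remainder compensatory, each labelled major or minor.
Aggregate traits are per-exam percentages averaged per bull, and a
breeding-suitability rule classifies exams from the percentage of normal
sperm and of non-compensatory defects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, SchemaError

EJACULATE_FIELDS = (
    "bull",
    "date",
    "age_days",
    "interval_days",
    "volume_ml",
    "mixed",
    "processed",
    "motility_pct",
    "head_score",
    "tail_score",
    "sperm_per_straw_mio",
    "sex_sorted",
    "collector",
    "handler",
    "genotype_available",
)

N_DEFECTS = 16
DEFECT_COLS = tuple(f"defect_{k}" for k in range(N_DEFECTS))
# breeding-soundness classification of the 16 defect categories
NON_COMPENSATORY = frozenset({0, 1, 2})
COMPENSATORY = frozenset(range(3, 16))
MAJOR = frozenset({0, 1, 2, 5, 7, 8, 9, 12, 14})
MINOR = frozenset({3, 4, 6, 10, 11, 13, 15})
HEAD_SHAPE = 0


def _require(records: pd.DataFrame, fields) -> None:
    missing = [f for f in fields if f not in records.columns]
    if missing:
        raise SchemaError(f"missing fields: {missing}")


def filter_ejaculates(
    records: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the ejaculate filter cascade; returns (survivors, step counts).

    Steps run in fixed order; the count table reports the number of bulls and
    ejaculates remaining after each step.  Boundaries: age strictly inside
    (400, 1000) days, motility and sperm per straw inclusive (>= 70, >= 15).
    'First ejaculate per day' keeps the earliest record per bull and day
    (ties broken by input order).
    """
    _require(records, EJACULATE_FIELDS)
    df = records.copy()
    counts = [("raw data", df["bull"].nunique(), len(df))]

    def step(name: str, mask: pd.Series) -> None:
        nonlocal df
        df = df.loc[mask]
        counts.append((name, df["bull"].nunique(), len(df)))

    step("age 400-1000 days", (df["age_days"] > 400) & (df["age_days"] < 1000))
    step("interval known", df["interval_days"].notna())
    step("volume recorded", df["volume_ml"].notna())
    step("no mixed ejaculates", ~df["mixed"].astype(bool))
    step("processed only", df["processed"].astype(bool))
    step("interval <= 8 days", df["interval_days"] <= 8)
    # first ejaculate per bull and day, earliest record wins
    first = ~df.duplicated(subset=["bull", "date"], keep="first")
    step("first ejaculate per day", first)
    step("motility >= 70%", df["motility_pct"] >= 70)
    plausible = df["head_score"].isin([0, 1, 2, 3]) & df["tail_score"].isin(
        [0, 1, 2, 3]
    )
    step("anomaly score plausible", plausible)
    step(
        "sperm per straw >= 15M, not sex-sorted",
        (df["sperm_per_straw_mio"] >= 15) & ~df["sex_sorted"].astype(bool),
    )
    step(
        "collector and handler known",
        df["collector"].notna() & df["handler"].notna(),
    )
    step("genotype available", df["genotype_available"].astype(bool))
    per_bull = df.groupby("bull")["bull"].transform("size")
    step(">= 8 records per bull", per_bull >= 8)
    table = pd.DataFrame(counts, columns=["step", "n_bulls", "n_ejaculates"])
    return df.copy(), table


def bull_mean_traits(
    surviving: pd.DataFrame, min_records: int = 8
) -> pd.DataFrame:
    """Arithmetic per-bull means of the quantitative semen traits.

    Bulls with fewer than ``min_records`` surviving ejaculates are excluded.
    """
    traits = [
        "volume_ml",
        "motility_pct",
        "sperm_per_straw_mio",
        "head_score",
        "tail_score",
    ]
    if "concentration" in surviving.columns:
        traits.append("concentration")
    _require(surviving, ["bull", *traits])
    grouped = surviving.groupby("bull")
    means = grouped[traits].mean()
    means["n_ejaculates"] = grouped.size()
    means = means.loc[means["n_ejaculates"] >= min_records]
    return means.reset_index()


def derive_morphology_traits(
    exams: pd.DataFrame, min_assessed: int = 150
) -> pd.DataFrame:
    """Per-bull sperm-morphology trait means from exam counts.

    Each qualifying exam (total assessed >= ``min_assessed``) contributes
    percentages of normal sperm, of each defect category, and of the
    major / minor / compensatory / non-compensatory aggregates; these are
    averaged per bull.  Exams below the threshold are excluded from the
    proportion traits but still counted in ``n_exams`` (the examination-
    number trait).  Normal count = assessed - sum of defects.
    """
    _require(exams, ["bull", "total_assessed", *DEFECT_COLS])
    counts = exams[list(DEFECT_COLS)].to_numpy(dtype=float)
    total = exams["total_assessed"].to_numpy(dtype=float)
    if np.any(counts.sum(axis=1) > total):
        raise InvalidConfigError("defect counts exceed total assessed")
    pct = 100.0 * counts / total[:, None]
    per_exam = pd.DataFrame(pct, columns=[f"pct_{c}" for c in DEFECT_COLS])
    per_exam.insert(0, "bull", exams["bull"].to_numpy())
    per_exam["pct_normal"] = 100.0 - pct.sum(axis=1)
    for name, cats in (
        ("pct_non_compensatory", NON_COMPENSATORY),
        ("pct_compensatory", COMPENSATORY),
        ("pct_major", MAJOR),
        ("pct_minor", MINOR),
    ):
        per_exam[name] = pct[:, sorted(cats)].sum(axis=1)
    per_exam["pct_head_shape"] = pct[:, HEAD_SHAPE]

    n_exams = exams.groupby("bull").size().rename("n_exams")
    qualifying = per_exam.loc[total >= min_assessed]
    means = qualifying.groupby("bull").mean()
    out = pd.concat([n_exams, means], axis=1).reset_index()
    return out


@dataclass(frozen=True)
class SuitabilityResult:
    category: str  # suitable | process_with_compensation | fail
    passed: bool  # passed the examination (normal >= 65 and non-comp <= 20)


def breeding_suitability(
    pct_normal: float, pct_non_compensatory: float
) -> SuitabilityResult:
    """Breeding-suitability rule on one exam's normal / non-compensatory percentages.

    Suitable: >= 75% normal and <= 20% non-compensatory.  Between 65% and 75%
    normal with <= 20% non-compensatory: processed, but the reduced quality
    is compensated with more sperm per dose.  Otherwise the exam fails.
    """
    if not (0 <= pct_normal <= 100 and 0 <= pct_non_compensatory <= 100):
        raise InvalidConfigError("percentages must lie in [0, 100]")
    ok_noncomp = pct_non_compensatory <= 20
    if pct_normal >= 75 and ok_noncomp:
        category = "suitable"
    elif 65 <= pct_normal < 75 and ok_noncomp:
        category = "process_with_compensation"
    else:
        category = "fail"
    return SuitabilityResult(category, passed=pct_normal >= 65 and ok_noncomp)
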