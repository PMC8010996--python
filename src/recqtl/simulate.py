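"""Synthetic breeding-population generator.

Real SNP-array and insemination data for artificial-insemination sires are
access-restricted, so the pipeline is exercised on synthetic data whose
statistical structure mirrors what the analysis assumes:

* phased SNP panels with block linkage disequilibrium, built as mosaics of a
  small set of founder haplotypes (a configurable per-SNP switch rate
  controls block length);
* a causal recessive haplotype embedded at a configurable frequency
  (default 0.18, matching the mapped fertility-decreasing haplotype), with
  diplotypes assigned independently per individual so homozygote counts are
  approximately Hardy-Weinberg;
* fertility phenotypes on the latent scale (variance ~1 in phenotypic-SD
  units): homozygote effect (default -0.80 SD) + polygenic term with SNP
  heritability (default 0.10) + Gaussian residual;
* imputed sequence variants in the QTL region whose LD with the causal
  haplotype decays with distance, one designated variant in perfect LD;
* per-bull binomial 56-day non-return outcomes around a 65% mean with
  logit-scale fixed and random effects;
* ejaculate records carrying every field of the semen-quality filter cascade
  and sperm-morphology exams as multinomial counts over 16 defect
  categories, with homozygous carriers drawing roughly twice the baseline
  head-shape defect probability.

Every generator is seeded and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InvalidConfigError
from .panel import HaplotypePanel, VariantTable, Window, make_phenotype_table

_HAP_CHUNK = 512  # haplotypes simulated per block to bound memory


@dataclass(frozen=True)
class SimConfig:
    """Panel-simulation settings.

    switch_rate is the per-SNP probability that a simulated haplotype
    switches to a different founder template; smaller values give longer
    LD blocks.  maf_floor bounds the founder allele frequencies away from
    0 and 1.
    """

    n_individuals: int
    chrom_sizes: list[int]
    n_founders: int = 8
    switch_rate: float = 0.005
    maf_floor: float = 0.05
    mean_spacing_bp: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.n_founders < 1:
            raise InvalidConfigError("counts must be positive")
        if not self.chrom_sizes or any(m < 1 for m in self.chrom_sizes):
            raise InvalidConfigError("chromosome sizes must be positive")
        if not 0 <= self.switch_rate <= 1:
            raise InvalidConfigError("switch_rate must lie in [0, 1]")
        if not 0 <= self.maf_floor < 0.5:
            raise InvalidConfigError("maf_floor must lie in [0, 0.5)")


@dataclass(frozen=True)
class CausalSpec:
    """A recessive causal haplotype embedded in a panel."""

    chromosome: str
    window: Window
    allele_string: str
    realized_frequency: float
    effect_hom_sd: float = -0.8
    causal_variant_id: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.realized_frequency <= 1:
            raise InvalidConfigError("realized frequency must lie in [0, 1]")
        if len(self.allele_string) != self.window.size:
            raise InvalidConfigError("allele string length must equal window size")


# ---------------------------------------------------------------------------
# phased panel


def founder_templates(config: SimConfig) -> list[np.ndarray]:
    """Founder haplotypes per chromosome (n_founders x m uint8 arrays).

    Deterministic in the config seed and independent of the mosaic stream,
    so the founder set can be regenerated for validation.
    """
    out = []
    for ci, m in enumerate(config.chrom_sizes):
        rng = np.random.default_rng([1, config.seed, ci])
        p = rng.uniform(config.maf_floor, 1 - config.maf_floor, size=m)
        out.append((rng.random((config.n_founders, m)) < p).astype(np.uint8))
    return out


def simulate_panel(config: SimConfig) -> HaplotypePanel:
    """Phased panel of founder-mosaic haplotypes with block LD.

    Each simulated haplotype copies one founder template and switches to a
    uniformly drawn founder with probability ``switch_rate`` at every SNP,
    so nearby SNPs share founder origin and show LD.
    """
    n = config.n_individuals
    n_hap = 2 * n
    founders_by_chrom = founder_templates(config)
    chroms, poss, refs, alts, snp_ids, blocks = [], [], [], [], [], []
    for ci, m in enumerate(config.chrom_sizes):
        name = f"chr{ci + 1}"
        founders = founders_by_chrom[ci]
        rng = np.random.default_rng([2, config.seed, ci])
        alleles = np.empty((n_hap, m), dtype=np.uint8)
        col = np.arange(m)
        for lo in range(0, n_hap, _HAP_CHUNK):
            hi = min(lo + _HAP_CHUNK, n_hap)
            h = hi - lo
            switch = rng.random((h, m)) < config.switch_rate
            switch[:, 0] = True
            choice = rng.integers(0, config.n_founders, size=(h, m), dtype=np.int32)
            last = np.maximum.accumulate(
                np.where(switch, col[None, :], -1), axis=1
            )
            tmpl = choice[np.arange(h)[:, None], last]
            alleles[lo:hi] = founders[tmpl, col[None, :]]
        spacing = rng.integers(
            max(1, config.mean_spacing_bp // 2),
            config.mean_spacing_bp * 3 // 2 + 1,
            size=m,
        )
        poss.append(np.cumsum(spacing))
        chroms.append(np.full(m, name, dtype=object))
        refs.append(np.full(m, "A", dtype=object))
        alts.append(np.full(m, "G", dtype=object))
        snp_ids.append(np.array([f"{name}_snp{j + 1}" for j in range(m)], dtype=object))
        blocks.append(alleles)
    all_alleles = np.concatenate(blocks, axis=1).reshape(n_hap, -1)
    return HaplotypePanel(
        ids=[f"bull{i + 1}" for i in range(n)],
        chrom=np.concatenate(chroms),
        pos=np.concatenate(poss),
        snp_ids=np.concatenate(snp_ids),
        ref=np.concatenate(refs),
        alt=np.concatenate(alts),
        alleles=all_alleles.reshape(n, 2, -1),
    )


def embed_recessive_qtl(
    panel: HaplotypePanel,
    chromosome: str,
    window: Window,
    target_freq: float,
    tolerance: float = 0.02,
    seed: int = 0,
    effect_hom_sd: float = -0.8,
) -> CausalSpec:
    """Overwrite a window so one allele string segregates at the target frequency.

    Copies per individual are drawn i.i.d. Binomial(2, q), then minimally
    adjusted so the realized haplotype frequency lands within ``tolerance``
    of ``target_freq`` (exact Hardy-Weinberg proportions are therefore not
    forced).  Carrier haplotypes receive the designated allele string; any
    non-carrier haplotype that happens to match it is perturbed at one SNP.
    The panel is modified in place.
    """
    if not 0 < target_freq < 1:
        raise InvalidConfigError("target_freq must lie in (0, 1)")
    window = panel.with_bp(window)
    if window.chrom != chromosome:
        raise InvalidConfigError("window chromosome does not match")
    rng = np.random.default_rng(seed)
    n = panel.n_individuals
    two_n = 2 * n
    lo_count = int(np.ceil((target_freq - tolerance) * two_n))
    hi_count = int(np.floor((target_freq + tolerance) * two_n))
    if tolerance == 0 and abs(target_freq * two_n - round(target_freq * two_n)) > 1e-9:
        raise InvalidConfigError(
            "tolerance 0 requires target_freq to be a multiple of 1/(2N)"
        )
    lo_count = max(lo_count, 0)
    hi_count = min(hi_count, two_n)
    if lo_count > hi_count:
        raise InvalidConfigError(
            f"frequency {target_freq} +/- {tolerance} unattainable with 2N={two_n}"
        )
    copies = rng.binomial(2, target_freq, size=n)
    total = int(copies.sum())
    # minimal adjustment toward the admissible count range
    while total > hi_count:
        i = rng.choice(np.flatnonzero(copies > 0))
        copies[i] -= 1
        total -= 1
    while total < lo_count:
        i = rng.choice(np.flatnonzero(copies < 2))
        copies[i] += 1
        total += 1

    sl = panel.window_slice(window)
    w = window.size
    # designate an existing haplotype string as the causal one
    donor = rng.integers(0, two_n)
    sub = panel.alleles[:, :, sl].reshape(two_n, w)
    causal = sub[donor].copy()
    # assign carrier chromosomes
    which = rng.integers(0, 2, size=n)  # carried chromosome for heterozygotes
    for i in range(n):
        if copies[i] == 2:
            panel.alleles[i, :, sl] = causal
        elif copies[i] == 1:
            panel.alleles[i, which[i], sl] = causal
    # perturb accidental matches among non-carrier haplotypes
    sub = panel.alleles[:, :, sl].reshape(two_n, w)
    matches = (sub == causal[None, :]).all(axis=1).reshape(n, 2)
    for i in range(n):
        for hap in range(2):
            carried = copies[i] == 2 or (copies[i] == 1 and which[i] == hap)
            if matches[i, hap] and not carried:
                j = rng.integers(0, w)
                panel.alleles[i, hap, sl.start + j] ^= 1
    allele_string = "".join(chr(ord("0") + int(a)) for a in causal)
    realized = panel.haplotype_copies(window, allele_string).sum() / two_n
    return CausalSpec(
        chromosome, window, allele_string, float(realized), effect_hom_sd
    )


def simulate_fertility(
    panel: HaplotypePanel,
    causal: CausalSpec | None,
    beta_hom: float = -0.8,
    h2: float = 0.1,
    seed: int = 0,
    cohort: str = "cohort1",
) -> pd.DataFrame:
    """Latent-scale fertility phenotype: QTL effect + polygenic term + residual.

    y = beta_hom * 1[homozygous carrier] + g + e, where g is a sum of i.i.d.
    per-SNP effects scaled to sample variance h2 (SNPs inside the causal
    window excluded) and e ~ N(0, 1 - h2), so the marginal variance is ~1
    before the QTL effect.
    """
    if not 0 <= h2 < 1:
        raise InvalidConfigError("h2 must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n = panel.n_individuals
    y = rng.normal(0.0, np.sqrt(1 - h2), size=n)
    if h2 > 0:
        mask = np.ones(panel.n_snps, dtype=bool)
        if causal is not None:
            sl = panel.window_slice(causal.window)
            mask[sl] = False
        idx = np.flatnonzero(mask)
        d = panel.dosages(idx)
        d -= d.mean(axis=0)
        u = rng.normal(size=len(idx))
        g = d @ u
        sd = g.std(ddof=0)
        if sd == 0:
            raise InvalidConfigError("polygenic term degenerate (monomorphic panel)")
        y += g / sd * np.sqrt(h2)
    if causal is not None and beta_hom != 0:
        copies = panel.haplotype_copies(causal.window, causal.allele_string)
        y += beta_hom * (copies == 2)
    return make_phenotype_table(list(panel.ids), y, cohort)


# ---------------------------------------------------------------------------
# sequence variants


def simulate_sequence_variants(
    panel: HaplotypePanel,
    causal: CausalSpec,
    region_margin: int = 3_000_000,
    n_variants: int = 200,
    seed: int = 0,
    ld_scale_bp: float = 500_000.0,
    n_unlinked: int = 0,
) -> tuple[VariantTable, CausalSpec]:
    """Sequence variants around the causal window, LD decaying with distance.

    One designated variant is perfectly concordant with the causal haplotype
    (r^2 = 1, imputation r^2 = 1); the others copy the causal-haplotype
    indicator with probability exp(-distance / ld_scale_bp) and otherwise
    draw an independent allele.  ``n_unlinked`` extra variants are placed on
    a different chromosome with independent alleles.  Returns the variant
    table and the causal spec updated with the designated variant id.
    """
    rng = np.random.default_rng(seed)
    window = panel.with_bp(causal.window)
    n = panel.n_individuals
    copies = panel.haplotype_copies(window, causal.allele_string)
    # haplotype-level carrier indicator (N, 2)
    sl = panel.window_slice(window)
    target = np.frombuffer(causal.allele_string.encode(), dtype=np.uint8) - ord("0")
    hap_carrier = (
        (panel.alleles[:, :, sl] == target[None, None, :]).all(axis=2)
    ).astype(np.uint8)

    lo = max(1, window.start_bp - region_margin)
    hi = window.end_bp + region_margin
    pos = np.sort(rng.choice(np.arange(lo, hi), size=n_variants - 1, replace=False))
    mid = (window.start_bp + window.end_bp) // 2
    causal_pos = int(rng.integers(window.start_bp, window.end_bp + 1))

    rows_chrom, rows_pos, dosages, r2s, ids = [], [], [], [], []
    # designated causal variant: alt allele == causal haplotype
    ids.append("var_causal")
    rows_chrom.append(window.chrom)
    rows_pos.append(causal_pos)
    dosages.append(copies.astype(np.uint8))
    r2s.append(1.0)
    for k, p_bp in enumerate(pos):
        rho = np.exp(-abs(int(p_bp) - mid) / ld_scale_bp)
        base_freq = rng.uniform(0.05, 0.95)
        copy_mask = rng.random((n, 2)) < rho
        noise = (rng.random((n, 2)) < base_freq).astype(np.uint8)
        hap = np.where(copy_mask, hap_carrier, noise)
        ids.append(f"var{k + 1}")
        rows_chrom.append(window.chrom)
        rows_pos.append(int(p_bp))
        dosages.append(hap.sum(axis=1).astype(np.uint8))
        r2s.append(float(rng.uniform(0.3, 1.0)))
    if n_unlinked:
        other = [c for c in panel.chromosomes if c != window.chrom]
        off_chrom = other[0] if other else window.chrom + "_unlinked"
        for k in range(n_unlinked):
            f = rng.uniform(0.1, 0.9)
            hap = (rng.random((n, 2)) < f).astype(np.uint8)
            ids.append(f"unlinked{k + 1}")
            rows_chrom.append(off_chrom)
            rows_pos.append(int(rng.integers(1, 10_000_000)))
            dosages.append(hap.sum(axis=1).astype(np.uint8))
            r2s.append(float(rng.uniform(0.3, 1.0)))
    order = np.lexsort((np.array(rows_pos), np.array(rows_chrom, dtype=object)))
    table = VariantTable(
        variant_ids=[ids[i] for i in order],
        chrom=np.array(rows_chrom, dtype=object)[order],
        pos=np.array(rows_pos)[order],
        ref=np.full(len(ids), "A", dtype=object),
        alt=np.full(len(ids), "G", dtype=object),
        dosages=np.stack([dosages[i] for i in order]),
        imp_r2=np.array(r2s)[order],
        individual_ids=list(panel.ids),
    )
    return table, replace(causal, causal_variant_id="var_causal")


# ---------------------------------------------------------------------------
# insemination records


INSEM_FACTORS = ("month", "parity", "price", "breed_combo", "technician", "herd")
_FACTOR_LEVELS = {
    "month": 12,
    "parity": 2,
    "price": 3,
    "breed_combo": 4,
    "technician": 25,
    "herd": 60,
}


def simulate_inseminations(
    bull_effects: dict[str, float],
    n_per_bull: dict[str, int] | int,
    base_rate: float = 0.65,
    factor_sds: dict[str, float] | None = None,
    seed: int = 0,
    n_levels: dict[str, int] | None = None,
) -> pd.DataFrame:
    """First-insemination records with 0/1 non-return outcomes.

    Outcome ~ Bernoulli(logistic(logit(base_rate) + bull + herd + fixed
    factor effects)); y = 1 means no re-insemination within 56 days
    (non-return, i.e. presumed success).  Every record carries all factor
    levels (insemination month, parity class, semen price class, breed
    combination, technician, herd).
    """
    if not bull_effects:
        raise InvalidConfigError("bull list must not be empty")
    if not 0 < base_rate < 1:
        raise InvalidConfigError("base_rate must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    sds = {f: 0.05 for f in INSEM_FACTORS}
    if factor_sds:
        unknown = set(factor_sds) - set(INSEM_FACTORS)
        if unknown:
            raise InvalidConfigError(f"unknown factors: {sorted(unknown)}")
        sds.update(factor_sds)
    levels = dict(_FACTOR_LEVELS)
    if n_levels:
        levels.update(n_levels)
    effects = {
        f: rng.normal(0.0, sds[f], size=levels[f]) for f in INSEM_FACTORS
    }
    bulls = list(bull_effects)
    if isinstance(n_per_bull, int):
        n_per_bull = {b: n_per_bull for b in bulls}
    base_logit = np.log(base_rate / (1 - base_rate))
    frames = []
    for b in bulls:
        nrec = int(n_per_bull[b])
        draw = {f: rng.integers(0, levels[f], size=nrec) for f in INSEM_FACTORS}
        logit = base_logit + bull_effects[b]
        for f in INSEM_FACTORS:
            logit = logit + effects[f][draw[f]]
        prob = 1.0 / (1.0 + np.exp(-logit))
        outcome = (rng.random(nrec) < prob).astype(np.int8)
        frame = pd.DataFrame({"bull": b, "outcome": outcome})
        for f in INSEM_FACTORS:
            frame[f] = [f"{f}{v + 1}" for v in draw[f]]
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# ejaculates and sperm morphology


@dataclass(frozen=True)
class EjaculateParams:
    """Field distributions for the routine fresh-semen assessment."""

    n_per_bull_mean: float = 20.0
    age_low: int = 350
    age_high: int = 1100
    volume_mean: float = 4.5
    volume_sd: float = 1.5
    volume_missing: float = 0.01
    concentration_mean: float = 1200.0
    concentration_sd: float = 300.0
    motility_mean: float = 80.0
    motility_sd: float = 8.0
    sperm_per_straw_mean: float = 20.0
    sperm_per_straw_sd: float = 3.0
    mixed_frac: float = 0.05
    unprocessed_frac: float = 0.08
    sex_sorted_frac: float = 0.03
    bad_score_frac: float = 0.005
    collector_missing: float = 0.02
    handler_missing: float = 0.02
    genotype_missing: float = 0.05
    interval_mean_days: float = 4.0

    def __post_init__(self) -> None:
        for name in ("volume_sd", "concentration_sd", "motility_sd", "sperm_per_straw_sd"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be non-negative")


def simulate_ejaculates(
    bulls: list[str],
    params: EjaculateParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Ejaculate records populating every field of the filter cascade."""
    p = params or EjaculateParams()
    rng = np.random.default_rng(seed)
    frames = []
    for b in bulls:
        nrec = max(1, rng.poisson(p.n_per_bull_mean))
        start_age = rng.integers(p.age_low, p.age_low + 150)
        intervals = np.maximum(
            1, rng.poisson(p.interval_mean_days, size=nrec)
        ).astype(float)
        # occasionally collect twice on one day
        same_day = rng.random(nrec) < 0.05
        intervals[same_day] = 0.0
        days = start_age + np.cumsum(intervals)
        interval_col = intervals.copy()
        interval_col[0] = np.nan  # interval to preceding ejaculate unknown
        volume = rng.normal(p.volume_mean, p.volume_sd, size=nrec).clip(0.5)
        volume[rng.random(nrec) < p.volume_missing] = np.nan
        scores = rng.choice([0, 1, 2, 3], size=(nrec, 2), p=[0.7, 0.2, 0.07, 0.03])
        scores = scores.astype(float)
        bad = rng.random(nrec) < p.bad_score_frac
        scores[bad, 0] = 9.0  # implausible score
        collector = np.array(
            [f"c{v}" for v in rng.integers(1, 6, size=nrec)], dtype=object
        )
        collector[rng.random(nrec) < p.collector_missing] = None
        handler = np.array(
            [f"h{v}" for v in rng.integers(1, 6, size=nrec)], dtype=object
        )
        handler[rng.random(nrec) < p.handler_missing] = None
        frames.append(
            pd.DataFrame(
                {
                    "bull": b,
                    "age_days": days.astype(int),
                    "date": days.astype(int),  # one synthetic day index
                    "interval_days": interval_col,
                    "volume_ml": volume,
                    "concentration": rng.normal(
                        p.concentration_mean, p.concentration_sd, size=nrec
                    ).clip(100),
                    "mixed": rng.random(nrec) < p.mixed_frac,
                    "processed": rng.random(nrec) >= p.unprocessed_frac,
                    "motility_pct": rng.normal(
                        p.motility_mean, p.motility_sd, size=nrec
                    ).clip(0, 100),
                    "head_score": scores[:, 0],
                    "tail_score": scores[:, 1],
                    "sperm_per_straw_mio": rng.normal(
                        p.sperm_per_straw_mean, p.sperm_per_straw_sd, size=nrec
                    ).clip(5),
                    "sex_sorted": rng.random(nrec) < p.sex_sorted_frac,
                    "collector": collector,
                    "handler": handler,
                    "genotype_available": rng.random(nrec) >= p.genotype_missing,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out["genotype_available"] = out["genotype_available"].astype(bool)
    return out


@dataclass(frozen=True)
class MorphologyParams:
    """Per-category defect probabilities for the sperm-morphology exam.

    The 16 categories follow the breeding-soundness classification: 0-2 are
    non-compensatory (head shape, vacuoles, condensed DNA), 3-15
    compensatory.  Defaults put non-carriers near 76% normal sperm with
    ~5.4% head-shape defects; homozygous carriers of the fertility-reducing
    haplotype double the head-shape probability.
    """

    defect_probs: tuple = (
        0.0542,  # 0 abnormal head shape (non-compensatory, major)
        0.0025,  # 1 vacuoles
        0.0012,  # 2 condensed DNA
        0.0112,  # 3 micro-/macrocephaly
        0.0112,  # 4 loose heads
        0.0165,  # 5 knobbed acrosome
        0.0112,  # 6 detached acrosome
        0.0165,  # 7 dag defect
        0.0165,  # 8 curled tail
        0.0165,  # 9 middle-piece knobbed
        0.0112,  # 10 tail abaxial
        0.0112,  # 11 tail end loop
        0.0165,  # 12 droplet proximal
        0.0112,  # 13 droplet distal
        0.0165,  # 14 underdeveloped
        0.0112,  # 15 double form
    )
    head_shape_hom_multiplier: float = 2.0
    n_assessed_low: int = 150
    n_assessed_high: int = 200
    fail_exam_frac: float = 0.02  # exams where only ~50 sperm are classified
    exams_mean_noncarrier: float = 2.5
    exams_mean_hom: float = 5.0

    def __post_init__(self) -> None:
        if len(self.defect_probs) != 16:
            raise InvalidConfigError("16 defect categories required")
        if any(q < 0 for q in self.defect_probs):
            raise InvalidConfigError("defect probabilities must be non-negative")


def simulate_morphology(
    bulls: list[str],
    carrier_status: np.ndarray,
    params: MorphologyParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Sperm-morphology exams as multinomial counts over normal + 16 defects."""
    p = params or MorphologyParams()
    if len(carrier_status) != len(bulls):
        raise InvalidConfigError("carrier status length does not match bulls")
    rng = np.random.default_rng(seed)
    rows = []
    for b, status in zip(bulls, carrier_status):
        probs = np.array(p.defect_probs, dtype=float)
        if status == 2:
            probs[0] *= p.head_shape_hom_multiplier
        if probs.sum() > 1:
            raise InvalidConfigError("defect probabilities exceed 1")
        mean_exams = p.exams_mean_hom if status == 2 else p.exams_mean_noncarrier
        n_exams = max(1, rng.poisson(mean_exams))
        for e in range(n_exams):
            if rng.random() < p.fail_exam_frac:
                total = 50
            else:
                total = int(rng.integers(p.n_assessed_low, p.n_assessed_high + 1))
            full = np.concatenate([[1 - probs.sum()], probs])
            counts = rng.multinomial(total, full)
            row = {"bull": b, "exam": f"{b}_e{e + 1}", "total_assessed": total}
            for k in range(16):
                row[f"defect_{k}"] = int(counts[k + 1])
            rows.append(row)
    return pd.DataFrame(rows)
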