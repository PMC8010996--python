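"""Core in-memory containers for phased genotype panels and sequence variants.

The phased panel is the substrate of every downstream analysis: an
``individuals x 2 x SNPs`` array of biallelic alleles (0 = reference,
1 = alternate) with per-SNP chromosome/position metadata.  Coordinates are
1-based and inclusive throughout, following VCF convention; haplotype allele
strings are concatenations of the 0/1 digits in SNP order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, IdMismatchError


@dataclass(frozen=True)
class Window:
    """A run of contiguous SNPs on one chromosome.

    ``start`` and ``end`` are 1-based SNP indices *within the chromosome*,
    both inclusive, so the window covers ``end - start + 1`` SNPs.  Base-pair
    bounds are carried along once known (first and last SNP position).
    """

    chrom: str
    start: int
    end: int
    start_bp: int | None = None
    end_bp: int | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise InvalidConfigError(
                f"invalid window bounds [{self.start}, {self.end}]"
            )

    @property
    def size(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "Window") -> bool:
        """SNP-index overlap on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass
class HaplotypePanel:
    """Phased, complete, biallelic genotypes for a cohort.

    Attributes
    ----------
    ids : list of str
        Individual identifiers, in panel order.
    chrom, pos, snp_ids, ref, alt : arrays of length M
        Per-SNP metadata.  SNPs of one chromosome must be contiguous and
        their positions strictly increasing.
    alleles : uint8 array of shape (N, 2, M)
        Allele of each individual's two phased haplotypes at each SNP.
    """

    ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    snp_ids: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    alleles: np.ndarray
    _chrom_offsets: dict[str, tuple[int, int]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        n, two, m = self.alleles.shape
        if two != 2:
            raise InvalidConfigError("allele array must have shape (N, 2, M)")
        if n != len(self.ids):
            raise InvalidConfigError("number of ids does not match allele array")
        if len(set(self.ids)) != n:
            raise InvalidConfigError("individual ids must be unique")
        for arr, name in [
            (self.chrom, "chrom"),
            (self.pos, "pos"),
            (self.snp_ids, "snp_ids"),
            (self.ref, "ref"),
            (self.alt, "alt"),
        ]:
            if len(arr) != m:
                raise InvalidConfigError(f"{name} length does not match SNP count")
        if self.alleles.size and self.alleles.max() > 1:
            raise InvalidConfigError("alleles must be 0 (ref) or 1 (alt)")
        # chromosome contiguity + strictly increasing positions
        offsets: dict[str, tuple[int, int]] = {}
        i = 0
        while i < m:
            c = self.chrom[i]
            j = i
            while j < m and self.chrom[j] == c:
                j += 1
            if c in offsets:
                raise InvalidConfigError(
                    f"SNPs of chromosome {c} are not contiguous"
                )
            p = self.pos[i:j]
            if np.any(np.diff(p) <= 0):
                raise InvalidConfigError(
                    f"positions not strictly increasing on chromosome {c}"
                )
            offsets[c] = (i, j)
            i = j
        object.__setattr__(self, "_chrom_offsets", offsets)

    # -- geometry ---------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[2]

    @property
    def chromosomes(self) -> list[str]:
        return list(self._chrom_offsets)

    def n_snps_on(self, chrom: str) -> int:
        lo, hi = self._chrom_offsets[chrom]
        return hi - lo

    def window_slice(self, window: Window) -> slice:
        """Global SNP-array slice covered by a window (validates bounds)."""
        if window.chrom not in self._chrom_offsets:
            raise InvalidConfigError(f"chromosome {window.chrom} not in panel")
        lo, hi = self._chrom_offsets[window.chrom]
        if window.end > hi - lo:
            raise InvalidConfigError(
                f"window [{window.start}, {window.end}] exceeds chromosome "
                f"{window.chrom} ({hi - lo} SNPs)"
            )
        return slice(lo + window.start - 1, lo + window.end)

    def with_bp(self, window: Window) -> Window:
        """Return the window with base-pair bounds filled from the panel."""
        sl = self.window_slice(window)
        return Window(
            window.chrom,
            window.start,
            window.end,
            start_bp=int(self.pos[sl.start]),
            end_bp=int(self.pos[sl.stop - 1]),
        )

    # -- allele access ----------------------------------------------------

    def window_alleles(self, window: Window) -> np.ndarray:
        """View of shape (N, 2, window size)."""
        return self.alleles[:, :, self.window_slice(window)]

    def haplotype_copies(self, window: Window, allele_string: str) -> np.ndarray:
        """Per-individual copy count (0/1/2) of an allele string in a window."""
        target = np.frombuffer(allele_string.encode(), dtype=np.uint8) - ord("0")
        if len(target) != window.size:
            raise InvalidConfigError(
                "allele string length does not match window size"
            )
        sub = self.window_alleles(window)
        match = (sub == target[None, None, :]).all(axis=2)
        return match.sum(axis=1).astype(np.int64)

    def dosages(self, snp_indices: np.ndarray | None = None) -> np.ndarray:
        """Alternate-allele dosage matrix (N, M) as float64."""
        a = self.alleles if snp_indices is None else self.alleles[:, :, snp_indices]
        return a.sum(axis=1, dtype=np.float64)

    def reorder(self, ids: list[str]) -> "HaplotypePanel":
        """Panel restricted/reordered to the given individual ids."""
        index = {s: i for i, s in enumerate(self.ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise IdMismatchError(f"ids not in panel: {missing[:5]}")
        rows = np.array([index[s] for s in ids])
        return HaplotypePanel(
            ids=list(ids),
            chrom=self.chrom,
            pos=self.pos,
            snp_ids=self.snp_ids,
            ref=self.ref,
            alt=self.alt,
            alleles=self.alleles[rows],
        )


@dataclass
class VariantTable:
    """Sequence-variant genotypes with imputation quality.

    Dosages count copies of the alternate allele (0/1/2); ``imp_r2`` is the
    imputation accuracy in [0, 1] used for quality filtering.
    """

    variant_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosages: np.ndarray  # (V, N) uint8
    imp_r2: np.ndarray
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=np.uint8)
        self.imp_r2 = np.asarray(self.imp_r2, dtype=np.float64)
        v, n = self.dosages.shape
        if v != len(self.variant_ids) or n != len(self.individual_ids):
            raise InvalidConfigError("dosage matrix shape does not match ids")
        if self.dosages.size and self.dosages.max() > 2:
            raise InvalidConfigError("dosages must be in {0, 1, 2}")
        if np.any((self.imp_r2 < 0) | (self.imp_r2 > 1)):
            raise InvalidConfigError("imputation r2 must lie in [0, 1]")

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[0]

    @property
    def alt_freq(self) -> np.ndarray:
        return self.dosages.mean(axis=1) / 2.0


def make_phenotype_table(
    ids: list[str], values: np.ndarray, cohort: str | list[str] = "cohort1"
) -> pd.DataFrame:
    """Assemble the standard phenotype table (one row per individual)."""
    if len(ids) != len(values):
        raise InvalidConfigError("ids and values differ in length")
    if len(set(ids)) != len(ids):
        raise InvalidConfigError("phenotype ids must be unique")
    cohorts = [cohort] * len(ids) if isinstance(cohort, str) else list(cohort)
    return pd.DataFrame(
        {"id": ids, "phenotype": np.asarray(values, dtype=float), "cohort": cohorts}
    )


def aligned_phenotype(panel: HaplotypePanel, phenotypes: pd.DataFrame) -> np.ndarray:
    """Phenotype vector reordered to panel individual order.

    Raises :class:`IdMismatchError` when the two id sets differ.
    """
    table = phenotypes.set_index("id")["phenotype"]
    missing = [s for s in panel.ids if s not in table.index]
    if missing or len(table) != panel.n_individuals:
        raise IdMismatchError(
            "phenotype ids do not match panel ids "
            f"(missing from phenotypes: {missing[:5]})"
        )
    return table.loc[panel.ids].to_numpy(dtype=float)
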