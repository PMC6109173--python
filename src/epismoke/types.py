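"""Core domain containers shared across the pipeline.

Coordinates follow the BED convention throughout: 0-based, half-open
``[start, end)``.  Two intervals overlap iff they share at least one base,
i.e. ``a.start < b.end and b.start < a.end``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

VALID_STRANDS = ("+", "-", ".")
VALID_DAYS = (1, 2, 4)
VALID_TREATMENTS = ("air", "smoke")
PEAK_CLASSES = ("air_unique", "smoke_unique", "common")
ZONES = ("proximal", "distal", "remote")

#: Zone boundaries (bp from nearest TSS, boundary inclusive in nearer zone).
PROXIMAL_BP = 1_000
DISTAL_BP = 100_000


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        """Reference point used for TSS distances: floor((start+end)/2)."""
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class Peak:
    """A peak region with per-condition read counts and comparison statistics.

    ``x_air`` / ``x_smoke`` are the read counts of the two conditions over the
    interval.  ``M``/``A`` are the log2 ratio and mean log2 intensity,
    ``m_norm`` the normalized M after subtracting the robust M-on-A trend,
    ``p_value`` the conditional-binomial significance of the count difference
    and ``label`` the class (air_unique / smoke_unique / common).
    """

    interval: GenomicInterval
    name: str
    x_air: float
    x_smoke: float
    M: float | None = None
    A: float | None = None
    m_norm: float | None = None
    p_value: float | None = None
    label: str | None = None
    #: names of the input peaks merged into this one (self for unmerged).
    members: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.x_air < 0 or self.x_smoke < 0:
            raise ValueError(f"negative read count on peak {self.name!r}")
        if not self.members:
            self.members = (self.name,)


@dataclass(frozen=True)
class MAFit:
    """Robust linear fit of M on A over common peaks."""

    intercept: float
    slope: float
    n_points: int
    n_iter: int
    mean_weight: float

    def predict(self, a):
        return self.intercept + self.slope * a


@dataclass
class ExpressionStudy:
    """Genes x samples expression matrix plus its sample sheet.

    The sample sheet is indexed by sample_id with columns
    subject / treatment / day / batch; matrix columns are aligned to it.
    """

    matrix: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        sheet = self.samples
        required = {"subject", "treatment", "day", "batch"}
        missing = required - set(sheet.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        if sheet.index.duplicated().any():
            dups = sheet.index[sheet.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids in sheet: {dups}")
        if self.matrix.index.duplicated().any():
            dups = self.matrix.index[self.matrix.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids in matrix: {dups}")
        mat_cols = set(self.matrix.columns)
        sheet_ids = set(sheet.index)
        only_mat = sorted(mat_cols - sheet_ids)
        only_sheet = sorted(sheet_ids - mat_cols)
        if only_mat or only_sheet:
            raise ValueError(
                "matrix / sample sheet mismatch: "
                f"matrix-only={only_mat}, sheet-only={only_sheet}"
            )
        bad_day = sorted(set(sheet["day"]) - set(VALID_DAYS))
        if bad_day:
            raise ValueError(
                f"invalid day values {bad_day}; allowed days are {VALID_DAYS}"
            )
        bad_trt = sorted(set(sheet["treatment"]) - set(VALID_TREATMENTS))
        if bad_trt:
            raise ValueError(
                f"invalid treatment values {bad_trt}; "
                f"allowed are {VALID_TREATMENTS}"
            )
        # canonical column order = sheet row order
        self.matrix = self.matrix[list(sheet.index)]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def subset(self, sample_ids) -> "ExpressionStudy":
        ids = list(sample_ids)
        return ExpressionStudy(self.matrix[ids].copy(), self.samples.loc[ids].copy())


@dataclass(frozen=True)
class MetaTResult:
    """One peak-class vs rest comparison of differential-expression t values."""

    day: int
    peak_class: str
    zone: str
    n_in: int
    n_out: int
    meta_t: float
    p: float
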