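"""Core record types shared by every stage of the pipeline.

All coordinates are 0-based half-open throughout the package; formats with
other conventions (RepeatMasker .out is 1-based inclusive) are converted at
read time so that ``end - start`` is always the base count of a span.
"""

from __future__ import annotations

from dataclasses import dataclass, field

TE_CLASSES = frozenset({"SINE", "LINE", "LTR", "DNA"})
STRANDS = frozenset({"+", "-", "."})


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class TEAnnotation:
    """One repeat copy from a RepeatMasker-style annotation.

    Only the four major transposable-element classes are representable;
    records with other classes are rejected (the readers skip them).
    """

    interval: GenomicInterval
    te_class: str
    family: str
    subfamily: str
    divergence: float | None = None

    def __post_init__(self) -> None:
        if self.te_class not in TE_CLASSES:
            raise ValueError(f"te_class must be one of {sorted(TE_CLASSES)}")


@dataclass(frozen=True)
class BinPair:
    """One normalized Hi-C contact between two fixed-width genomic bins.

    ``start_i < start_j`` is required: self-pairs are excluded because all
    density normalisation assumes a combined two-bin (80 kb) region.
    """

    chrom: str
    start_i: int
    start_j: int
    frequency: float
    bin_size: int = 40_000

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.start_i % self.bin_size or self.start_j % self.bin_size:
            raise ValueError("bin starts must be multiples of bin_size")
        if not self.start_i < self.start_j:
            raise ValueError(
                "start_i must be < start_j (self bin-pairs are excluded)"
            )
        if self.frequency < 0:
            raise ValueError("frequency must be >= 0")


@dataclass(frozen=True)
class Domain:
    """A topological domain: a megabase-scale self-interacting region."""

    interval: GenomicInterval


@dataclass(frozen=True)
class CpGSite:
    """A single assayed CpG with its binary methylation call.

    ``pos`` is the 0-based offset of the C on the plus strand.
    """

    chrom: str
    pos: int
    methylated: bool

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError("pos must be >= 0")


@dataclass(frozen=True)
class Peak:
    """A ChIP-seq peak with optional summit offset and enrichment signal."""

    interval: GenomicInterval
    summit_offset: int | None = None
    signal: float = 0.0

    def __post_init__(self) -> None:
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < len(self.interval)
        ):
            raise ValueError("summit_offset outside the peak")

    @property
    def reference_point(self) -> int:
        """Summit position when known, otherwise the peak midpoint."""
        if self.summit_offset is not None:
            return self.interval.start + self.summit_offset
        return self.interval.midpoint


@dataclass(frozen=True)
class GeneLocus:
    """A gene with its span, symbol, strand and one or more TSS positions."""

    interval: GenomicInterval
    symbol: str
    strand: str
    tss_positions: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError("gene strand must be + or -")
        for tss in self.tss_positions:
            if not (self.interval.start <= tss <= self.interval.end):
                raise ValueError(
                    f"TSS {tss} outside locus {self.interval.chrom}:"
                    f"{self.interval.start}-{self.interval.end}"
                )
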