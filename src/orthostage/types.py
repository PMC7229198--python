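"""Core domain types shared across the pipeline.

Coordinates are 0-based, half-open throughout the package; GTF/GFF input is
converted on read and BED output is written natively in this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded interval on a named chromosome (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", min_bp: int = 1) -> bool:
        if self.chrom != other.chrom:
            return False
        return min(self.end, other.end) - max(self.start, other.start) >= min_bp


@dataclass(frozen=True)
class ExonRecord:
    """One annotated exon: the unit the orthology filters act on."""

    exon_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    species: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"exon {self.exon_id}: start must be < end")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


@dataclass(frozen=True)
class AlignmentHit:
    """One exon-to-genome local alignment.

    ``identity`` is matching bases over aligned columns. ``rank`` is 1 for the
    best hit of a query in a given target genome; ties are broken by longer
    alignment, then leftmost target coordinate (deterministic).
    """

    query_exon_id: str
    target_species: str
    target_chrom: str
    target_start: int
    target_end: int
    target_strand: str
    identity: float
    aligned_length: int
    rank: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity {self.identity} outside [0, 1]")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(
            self.target_chrom, self.target_start, self.target_end, self.target_strand
        )


@dataclass
class Metaexon:
    """Union of overlapping same-gene exons with paired coordinates in both
    species; one row of the ortholog table."""

    metaexon_id: str
    gene_id: str
    intervals_a: list
    intervals_b: list
    constituent_exons: list

    def __post_init__(self) -> None:
        if not self.constituent_exons:
            raise ValueError("metaexon with no constituent exons")
        if not self.intervals_a:
            raise ValueError("metaexon with no species-A interval")

    @property
    def span_a(self) -> GenomicInterval:
        ivs = sorted(self.intervals_a)
        return GenomicInterval(ivs[0].chrom, ivs[0].start, ivs[-1].end, ivs[0].strand)

    @property
    def span_b(self) -> GenomicInterval | None:
        if not self.intervals_b:
            return None
        ivs = sorted(self.intervals_b)
        if ivs[0].chrom != ivs[-1].chrom:
            return None
        return GenomicInterval(ivs[0].chrom, ivs[0].start, ivs[-1].end, ivs[0].strand)


# Reason codes emitted by the filter chain.
LOW_IDENTITY = "low_identity"
NO_RECIPROCAL = "no_reciprocal"
SECOND_HIT = "second_hit"
MULTI_GENE = "multi_gene"
MULTI_CHROM = "multi_chrom"
INTRON_DIFF = "intron_diff"
UNANNOTATED = "unannotated"

REASON_CODES = (
    LOW_IDENTITY,
    NO_RECIPROCAL,
    SECOND_HIT,
    MULTI_GENE,
    MULTI_CHROM,
    INTRON_DIFF,
    UNANNOTATED,
)


@dataclass
class FilterStage:
    name: str
    n_input: int
    n_retained: int
    removed: dict = field(default_factory=dict)  # reason -> list of ids

    @property
    def n_removed(self) -> int:
        return sum(len(v) for v in self.removed.values())

    def check_conservation(self) -> None:
        if self.n_retained + self.n_removed != self.n_input:
            raise AssertionError(
                f"stage {self.name}: retained {self.n_retained} + removed "
                f"{self.n_removed} != input {self.n_input}"
            )


@dataclass
class FilterReport:
    """Audit trail of the filter chain: per-stage counts with reason codes.

    Invariant (asserted): removed + retained == input at every stage.
    """

    stages: list = field(default_factory=list)

    def add_stage(self, name: str, n_input: int, n_retained: int, removed: dict) -> FilterStage:
        stage = FilterStage(name, n_input, n_retained, dict(removed))
        stage.check_conservation()
        self.stages.append(stage)
        return stage

    def removed_with_reason(self, reason: str) -> list:
        out = []
        for stage in self.stages:
            out.extend(stage.removed.get(reason, []))
        return out

    def summary_counts(self) -> dict:
        out: dict = {}
        for stage in self.stages:
            for reason, ids in stage.removed.items():
                out[reason] = out.get(reason, 0) + len(ids)
        return out
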