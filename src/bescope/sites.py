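"""Target-site data model and run configuration.

A target site is a 20-nt protospacer with an NGG PAM, embedded in a fixed
40-nt context: 10 nt upstream + 20 nt protospacer + 3 nt PAM + 7 nt
downstream.  Protospacer positions are numbered 1-20 (5'->3', PAM at
21-23) in every user-facing report; internal slices are 0-based
half-open.  This module is the single place where that coordinate
convention is defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

DNA = set("ACGT")

#: intended transition per editor: reference target base -> product base
TARGET_BASE = {"ABE": "A", "CBE": "C"}
PRODUCT_BASE = {"ABE": "G", "CBE": "T"}

#: default editing windows (1-based, inclusive) per editor
DEFAULT_WINDOW = {"ABE": (5, 7), "CBE": (4, 8)}

#: deaminase- vs nCas9-attributed indel regions (1-based, inclusive)
DEAMINASE_REGION = (1, 11)
NCAS9_REGION = (14, 20)

#: the 12 possible single-base transitions X->Y, X != Y
TRANSITIONS = tuple(
    f"{x}>{y}" for x in "ACGT" for y in "ACGT" if x != y
)

# 0-based slices of the 40-nt context
PROTO_SLICE = slice(10, 30)
PAM_SLICE = slice(30, 33)


class SiteError(ValueError):
    """Raised when a site record violates the data-model invariants."""


def _check_dna(seq: str, what: str, site_id: str = "") -> None:
    if not set(seq) <= DNA:
        raise SiteError(f"{site_id}: {what} contains non-ACGT characters: {seq!r}")


@dataclass(frozen=True)
class TargetSite:
    """One protospacer + context, optionally anchored to a genome.

    ``start`` is the 0-based genomic coordinate of context position 0 on
    the protospacer strand (half-open interval ``[start, start + 40)``).
    Reverse-strand sites are stored already oriented to the protospacer
    strand; ``strand`` records the original genomic strand.
    """

    site_id: str
    editor: str
    context40: str
    chrom: Optional[str] = None
    start: Optional[int] = None
    strand: str = "+"
    dataset: str = "synthetic"

    def __post_init__(self) -> None:
        if self.editor not in TARGET_BASE:
            raise SiteError(f"{self.site_id}: editor must be ABE or CBE, got {self.editor!r}")
        if len(self.context40) != 40:
            raise SiteError(
                f"{self.site_id}: context length {len(self.context40)} != 40"
            )
        _check_dna(self.context40, "context40", self.site_id)
        if self.dataset not in ("endogenous", "integrated", "synthetic"):
            raise SiteError(f"{self.site_id}: unknown dataset {self.dataset!r}")
        if self.strand not in "+-":
            raise SiteError(f"{self.site_id}: strand must be + or -")

    @property
    def protospacer(self) -> str:
        return self.context40[PROTO_SLICE]

    @property
    def pam(self) -> str:
        return self.context40[PAM_SLICE]

    @property
    def target_base(self) -> str:
        return TARGET_BASE[self.editor]

    def base_at(self, position: int) -> str:
        """Reference base at 1-based protospacer position (1-20)."""
        if not 1 <= position <= 20:
            raise SiteError(f"protospacer position {position} out of range 1-20")
        return self.protospacer[position - 1]

    def target_positions(self, window: Optional[tuple[int, int]] = None) -> list[int]:
        """1-based protospacer positions whose reference base is the
        editor's target base, optionally restricted to a window."""
        lo, hi = window if window is not None else (1, 20)
        return [
            p for p in range(lo, hi + 1) if self.protospacer[p - 1] == self.target_base
        ]

    def genomic_interval(self) -> tuple[str, int, int]:
        """Half-open genomic interval of the protospacer (20 bp)."""
        if self.chrom is None or self.start is None:
            raise SiteError(f"{self.site_id}: site has no genomic anchor")
        return self.chrom, self.start + 10, self.start + 30


@dataclass
class AlleleRow:
    """One aligned allele with its read support.

    ``aligned`` has the same length as the (ungapped) reference, with '-'
    marking deleted bases.  Insertions are kept as ``(ref_index, seq)``
    annotations -- the inserted bases sit immediately before the 0-based
    reference index -- so position numbering stays stable.
    """

    aligned: str
    n_reads: int
    n_inserted: int = 0
    n_deleted: int = 0
    insertions: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        if self.n_reads < 0:
            raise SiteError(f"negative read count {self.n_reads}")


@dataclass
class AlleleTable:
    """Read-count-weighted edited alleles for one site and replicate."""

    site_id: str
    replicate_id: str
    reference: str
    rows: list[AlleleRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_dna(self.reference, "reference", self.site_id)
        for row in self.rows:
            if len(row.aligned) != len(self.reference):
                raise SiteError(
                    f"{self.site_id}: allele length {len(row.aligned)} != "
                    f"reference length {len(self.reference)}"
                )
        if self.total_reads <= 0:
            raise SiteError(f"{self.site_id}/{self.replicate_id}: no reads")

    @property
    def total_reads(self) -> int:
        return sum(r.n_reads for r in self.rows)

    def protospacer_offset(self, site: TargetSite) -> int:
        """0-based index of protospacer position 1 in the reference.

        The reference may be the 40-nt context or a longer amplicon; in
        either case positions are computed relative to the protospacer.
        """
        idx = self.reference.find(site.protospacer)
        if idx < 0:
            raise SiteError(
                f"{self.site_id}: protospacer not found in reference "
                f"(reference/site mismatch)"
            )
        return idx


@dataclass
class RunConfig:
    """Analysis configuration shared across modules."""

    editor: str = "ABE"
    window: Optional[tuple[int, int]] = None
    min_coverage: int = 100
    allele_proportion_threshold: float = 0.05
    edited_fraction_threshold: float = 0.9
    kl_pseudocount: float = 0.5
    indel_length_normalization: bool = True
    expression_high_threshold: float = 1.5
    methylation_high_threshold: float = 0.75
    h3k27ac_flank: int = 65
    factor_channels: Sequence[str] = ()
    training: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.editor not in TARGET_BASE:
            raise SiteError(f"editor must be ABE or CBE, got {self.editor!r}")
        if self.window is None:
            self.window = DEFAULT_WINDOW[self.editor]
        lo, hi = self.window
        if not (1 <= lo <= hi <= 20):
            raise SiteError(f"window {self.window} must satisfy 1 <= start <= end <= 20")
        self.window = (int(lo), int(hi))
        self.factor_channels = tuple(self.factor_channels)


def window_positions(window: tuple[int, int]) -> range:
    """1-based positions covered by an inclusive window."""
    return range(window[0], window[1] + 1)
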