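"""Degenerate-consensus operator scanning for CopR-CopY cop-operon repressors.

The CopR-CopY family of copper-sensitive repressors binds a pseudo-palindromic
operator upstream of the bacterial *cop* operon.  The operator was long quoted
as the 10-base core ``KACANNTGTA``; binding data and cross-species alignments
support a 16-base site whose flanks follow a purine-N-pyrimidine (R-N-Y)
pattern.  This module compiles such degenerate IUPAC consensus strings into
per-position base sets, scans promoter sequences on both strands with an
optional mismatch allowance, and summarises occurrences per promoter: operator
count class (none / one / two-or-more), inter-operator spacing, and palindromy.

Coordinates are 0-based, half-open, and always expressed on the forward
strand; a minus-strand hit at ``start`` means the reverse complement of
``seq[start:start+len(pattern)]`` matches the pattern.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IUPAC_SETS",
    "PRESETS",
    "DegeneratePattern",
    "OperatorHit",
    "OperatorReport",
    "SpacingDistribution",
    "PanelSummary",
    "compile_pattern",
    "reverse_complement",
    "scan",
    "count_operators",
    "spacing_distribution",
    "is_palindromic",
    "classify_panel",
]

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

# complementation table for degenerate symbols (R<->Y, K<->M, S/W/N self)
_COMPLEMENT = str.maketrans("ACGTRYKMSWBDHVN", "TGCAYRMKSWVHDBN")

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


class InvalidPatternError(ValueError):
    """Raised when a motif string contains a non-IUPAC symbol."""


class InvalidSequenceError(ValueError):
    """Raised when a subject sequence contains characters outside A/C/G/T."""


@dataclass(frozen=True)
class DegeneratePattern:
    """A compiled IUPAC motif: one allowed base set per position."""

    iupac: str
    allowed_sets: tuple[frozenset[str], ...]
    name: str | None = None

    def __post_init__(self) -> None:
        if len(self.iupac) == 0:
            raise InvalidPatternError("pattern must be non-empty")
        if len(self.allowed_sets) != len(self.iupac):
            raise InvalidPatternError("allowed_sets length mismatch")

    def __len__(self) -> int:
        return len(self.iupac)

    @property
    def match_table(self) -> np.ndarray:
        """Boolean (4, L) table: table[base, pos] == base allowed at pos."""
        tab = np.zeros((4, len(self)), dtype=bool)
        for j, s in enumerate(self.allowed_sets):
            for b in s:
                tab[_BASE_INDEX[b], j] = True
        return tab


def compile_pattern(iupac: str, name: str | None = None) -> DegeneratePattern:
    """Compile an IUPAC DNA string (case-insensitive) into a pattern.

    Raises :class:`InvalidPatternError` naming the offending position for any
    symbol outside the 15-letter IUPAC DNA alphabet.
    """
    if isinstance(iupac, DegeneratePattern):
        return iupac
    text = str(iupac).upper()
    if not text:
        raise InvalidPatternError("pattern must be non-empty")
    sets = []
    for i, ch in enumerate(text):
        try:
            sets.append(IUPAC_SETS[ch])
        except KeyError:
            raise InvalidPatternError(
                f"invalid IUPAC symbol {ch!r} at position {i}"
            ) from None
    return DegeneratePattern(text, tuple(sets), name=name)


#: Named consensus presets.  OLD_CORE is the historical 10-base cop box;
#: MINIMAL_16 is the minimal sufficient operator; the three 16-base degenerate
#: forms are the pneumococcal, family-wide, and intermediate consensus strings.
PRESETS: dict[str, DegeneratePattern] = {
    name: compile_pattern(s, name=name)
    for name, s in {
        "OLD_CORE": "KACANNTGTA",
        "MINIMAL_16": "ATTGACAAATGTAGAT",
        "PNEUMO_16": "RNYKACAAATGTMRNY",
        "FAMILY_16": "RNYKACANNYGTMRNY",
        "INTERMEDIATE_16": "RNYKACANNTGTARNY",
    }.items()
}


def reverse_complement(seq_or_pattern):
    """Reverse complement of a DNA string or a :class:`DegeneratePattern`.

    Degenerate symbols complement as R<->Y, K<->M, S<->S, W<->W, B<->V,
    D<->H, N<->N.
    """
    if isinstance(seq_or_pattern, DegeneratePattern):
        return compile_pattern(
            reverse_complement(seq_or_pattern.iupac),
            name=None,
        )
    s = str(seq_or_pattern).upper()
    bad = set(s) - set("ACGTRYKMSWBDHVN")
    if bad:
        raise InvalidSequenceError(f"invalid symbols {sorted(bad)}")
    return s.translate(_COMPLEMENT)[::-1]


def is_palindromic(site: str) -> bool:
    """True iff an A/C/G/T site equals its own reverse complement."""
    site = site.upper()
    if set(site) - set("ACGT"):
        raise InvalidSequenceError("palindromy is defined for ACGT sites only")
    return site == reverse_complement(site)


@dataclass(frozen=True)
class OperatorHit:
    """One motif occurrence in forward-strand coordinates.

    ``matched`` is always the forward-strand subsequence; for a minus-strand
    hit its reverse complement is what satisfies the pattern.
    """

    start: int
    end: int
    strand: str
    matched: str
    mismatches: int = 0

    @property
    def palindromic(self) -> bool:
        return is_palindromic(self.matched)


def _encode(seq: str) -> np.ndarray:
    s = seq.upper()
    bad = set(s) - set("ACGT")
    if bad:
        raise InvalidSequenceError(
            f"subject sequence contains non-ACGT characters {sorted(bad)}; "
            "ambiguity codes in subjects are not supported"
        )
    return np.frombuffer(s.encode(), dtype=np.uint8)


# ASCII -> 0..3 lookup
_CODE = np.zeros(256, dtype=np.int8)
for _b, _i in _BASE_INDEX.items():
    _CODE[ord(_b)] = _i


def _mismatch_counts(idx: np.ndarray, pattern: DegeneratePattern) -> np.ndarray:
    """Mismatch count of every length-L window of an encoded sequence."""
    L = len(pattern)
    n = idx.size - L + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)
    ok = pattern.match_table[windows, np.arange(L)]
    return (~ok).sum(axis=1)


def scan(
    seq: str,
    pattern: DegeneratePattern | str,
    max_mismatch: int = 0,
    strands: str = "both",
) -> list[OperatorHit]:
    """Report every window matching ``pattern`` with <= ``max_mismatch``.

    Overlapping hits are all reported, sorted by (start, strand); a window
    matching on both strands yields two hits.  ``strands`` is one of
    ``"both"``, ``"forward"``, ``"reverse"``.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    if strands not in ("both", "forward", "reverse"):
        raise ValueError(f"unknown strand mode {strands!r}")
    pattern = compile_pattern(pattern) if isinstance(pattern, str) else pattern
    s = seq.upper()
    idx = _CODE[_encode(s)]
    hits: list[OperatorHit] = []
    jobs = []
    if strands in ("both", "forward"):
        jobs.append(("+", pattern))
    if strands in ("both", "reverse"):
        jobs.append(("-", reverse_complement(pattern)))
    L = len(pattern)
    for strand, pat in jobs:
        mm = _mismatch_counts(idx, pat)
        for start in np.nonzero(mm <= max_mismatch)[0]:
            start = int(start)
            hits.append(
                OperatorHit(
                    start=start,
                    end=start + L,
                    strand=strand,
                    matched=s[start : start + L],
                    mismatches=int(mm[start]),
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def collapse_overlaps(hits: list[OperatorHit]) -> list[OperatorHit]:
    """Greedy left-to-right collapse of overlapping windows.

    Two overlapping windows are one physical site; the leftmost (and, at equal
    start, the forward-strand) hit represents it.
    """
    kept: list[OperatorHit] = []
    for h in sorted(hits, key=lambda h: (h.start, h.strand)):
        if not kept or h.start >= kept[-1].end:
            kept.append(h)
    return kept


@dataclass
class OperatorReport:
    """Per-promoter summary of operator occurrences."""

    promoter_id: str
    hits: list[OperatorHit]
    count_class: int
    spacings: list[int]
    palindromic: list[bool]
    collapsed: list[OperatorHit] = field(default_factory=list)


def count_operators(
    promoter,
    pattern: DegeneratePattern | str,
    max_mismatch: int = 0,
    spacing_convention: str = "end_to_start",
) -> OperatorReport:
    """Scan one promoter and classify it by operator count.

    ``promoter`` is anything with ``id``/``sequence`` attributes (a
    PromoterRecord, a Bio.SeqRecord) or a plain string.  count_class caps at
    2 (meaning >= 2).  Spacing is the number of bases between consecutive
    collapsed hits: exclusive end of the upstream hit to start of the next
    (``end_to_start``); ``start_to_start`` is available as an option.
    """
    if spacing_convention not in ("end_to_start", "start_to_start"):
        raise ValueError(f"unknown spacing convention {spacing_convention!r}")
    if isinstance(promoter, str):
        pid, seq = "seq", promoter
    else:
        pid = str(getattr(promoter, "id", "seq"))
        seq = str(getattr(promoter, "sequence", None) or promoter.seq)
    hits = scan(seq, pattern, max_mismatch=max_mismatch, strands="both")
    kept = collapse_overlaps(hits)
    if spacing_convention == "end_to_start":
        spacings = [b.start - a.end for a, b in zip(kept, kept[1:])]
    else:
        spacings = [b.start - a.start for a, b in zip(kept, kept[1:])]
    return OperatorReport(
        promoter_id=pid,
        hits=hits,
        count_class=min(len(kept), 2),
        spacings=spacings,
        palindromic=[h.palindromic for h in kept],
        collapsed=kept,
    )


@dataclass
class SpacingDistribution:
    """Histogram of inter-operator gaps pooled over promoters.

    ``mode`` is the gap with maximal count, ties broken toward the smaller
    gap; it is None when no gaps were observed.
    """

    histogram: dict[int, int]
    mode: int | None
    n: int


def spacing_distribution(reports: list[OperatorReport]) -> SpacingDistribution:
    gaps: list[int] = []
    for r in reports:
        gaps.extend(r.spacings)
    hist = Counter(gaps)
    if not gaps:
        return SpacingDistribution(histogram={}, mode=None, n=0)
    best = max(hist.values())
    mode = min(g for g, c in hist.items() if c == best)
    return SpacingDistribution(histogram=dict(sorted(hist.items())), mode=mode, n=len(gaps))


@dataclass
class PanelSummary:
    """Aggregate of :func:`count_operators` over a promoter panel."""

    class_counts: dict[int, int]
    spacing: SpacingDistribution
    reports: list[OperatorReport]


def classify_panel(
    promoters,
    pattern: DegeneratePattern | str,
    max_mismatch: int = 0,
) -> PanelSummary:
    """Count operators in every promoter; deterministic order by promoter id."""
    reports = [
        count_operators(p, pattern, max_mismatch=max_mismatch) for p in promoters
    ]
    reports.sort(key=lambda r: r.promoter_id)
    counts = {0: 0, 1: 0, 2: 0}
    for r in reports:
        counts[r.count_class] += 1
    return PanelSummary(
        class_counts=counts,
        spacing=spacing_distribution(reports),
        reports=reports,
    )
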