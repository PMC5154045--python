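"""Detection of perfect and compound microsatellites, and primer screening.

A microsatellite (simple sequence repeat, SSR) is a tandem run of a short
DNA motif (1-6 bp).  This module finds maximal perfect runs in nucleotide
sequences, joins runs separated by short interruptions into compound loci
(e.g. ``(GT)8CA(GT)7``), and screens primer pairs against the design
criteria used for marker development (length, Tm, GC content, product size).

Coordinates are 0-based half-open throughout; human-readable motif strings
render repeat counts the way gel-based marker tables print them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.SeqUtils import MeltingTemp, gc_fraction

DNA_ALPHABET = frozenset("ACGT")
SEQUENCE_ALPHABET = frozenset("ACGTN")

#: Default minimum repeat counts per motif length.  Mononucleotide runs are
#: not searched by default (absent key = motif length not searched).
DEFAULT_MIN_REPEATS: dict[int, int] = {2: 6, 3: 4, 4: 3, 5: 3, 6: 3}

#: Default maximum interruption length (bp) when joining runs into a
#: compound locus.
DEFAULT_MAX_GAP = 4

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class InvalidSequenceError(ValueError):
    """Raised for residues outside the A/C/G/T(/N) alphabet."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence over the alphabet {A, C, G, T, N}."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise InvalidSequenceError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - SEQUENCE_ALPHABET
        if bad:
            raise InvalidSequenceError(
                f"sequence {self.id!r} contains non-DNA characters {sorted(bad)}"
            )

    def reverse_complement(self) -> "SequenceRecord":
        return SequenceRecord(self.id, self.residues.translate(_COMPLEMENT)[::-1])

    def __len__(self) -> int:
        return len(self.residues)


def reverse_complement(unit: str) -> str:
    return unit.upper().translate(_COMPLEMENT)[::-1]


def _rotations(unit: str) -> list[str]:
    return [unit[i:] + unit[:i] for i in range(len(unit))]


@dataclass(frozen=True)
class RepeatMotif:
    """A repeat unit together with its canonical (minimal-rotation) form.

    Canonicalization makes ``(TG)n`` and ``(GT)n`` tally as a single motif
    class when requested; by default it does NOT fold reverse complements,
    matching how repeat-finding tools report motifs as observed on the
    given strand.
    """

    unit: str
    canonical_unit: str

    def __post_init__(self) -> None:
        allowed = _rotations(self.unit) + _rotations(reverse_complement(self.unit))
        if self.canonical_unit not in allowed:
            raise ValueError(
                "canonical_unit must be a rotation of unit (or of its "
                "reverse complement when folding)"
            )


def canonicalize_motif(unit: str, fold_revcomp: bool = False) -> RepeatMotif:
    """Return ``unit`` with its lexicographically minimal rotation.

    With ``fold_revcomp=True`` the minimum is taken over the rotations of
    the unit and of its reverse complement, so e.g. AC and GT share a class.
    """
    unit = unit.upper()
    if not 1 <= len(unit) <= 6:
        raise ValueError(f"motif unit must be 1-6 bp, got {len(unit)}")
    if set(unit) - DNA_ALPHABET:
        raise InvalidSequenceError(f"motif unit {unit!r} contains non-DNA characters")
    candidates = _rotations(unit)
    if fold_revcomp:
        candidates += _rotations(reverse_complement(unit))
    return RepeatMotif(unit=unit, canonical_unit=min(candidates))


def _is_primitive(unit: str) -> bool:
    """True if the unit is not itself a repetition of a shorter unit."""
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return False
    return True


@dataclass(frozen=True)
class SsrPart:
    """One perfect run inside a (possibly compound) locus.

    ``gap_after`` holds the interruption text between this run and the next
    part; it is empty for the final part and for perfect loci.
    """

    motif: RepeatMotif
    count: int
    gap_after: str = ""


@dataclass(frozen=True)
class SsrLocus:
    """A detected repeat locus: a perfect run or a compound of nearby runs."""

    sequence_id: str
    start: int
    end: int
    motif: RepeatMotif
    repeat_count: int
    kind: str = "perfect"  # "perfect" | "compound"
    parts: tuple[SsrPart, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.kind not in ("perfect", "compound"):
            raise ValueError(f"unknown locus kind {self.kind!r}")
        parts = self.parts or (SsrPart(self.motif, self.repeat_count),)
        object.__setattr__(self, "parts", tuple(parts))
        span = sum(len(p.motif.unit) * p.count + len(p.gap_after) for p in self.parts)
        if self.end - self.start != span:
            raise ValueError(
                f"locus span {self.end - self.start} != parts span {span}"
            )
        if self.repeat_count < 2:
            raise ValueError("repeat_count must be >= 2")
        if self.kind == "perfect" and (len(self.parts) != 1 or self.parts[0].gap_after):
            raise ValueError("perfect locus must have a single uninterrupted part")

    @property
    def length(self) -> int:
        return self.end - self.start

    def motif_string(self) -> str:
        """Render like ``(GT)8`` or ``(GT)8CA(GT)7``."""
        return "".join(
            f"({p.motif.unit}){p.count}{p.gap_after}" for p in self.parts
        )


def _match(a: str, b: str) -> bool:
    # N never matches inside a repeat run, not even another N.
    return a == b and a != "N"


def find_perfect_ssrs(
    seq: SequenceRecord,
    min_repeats: Mapping[int, int] | None = None,
) -> list[SsrLocus]:
    """Find maximal perfect tandem repeats meeting per-length thresholds.

    For every motif length L with a threshold, scans for maximal periodic
    intervals (``residues[i] == residues[i+L]``), reports the unit-aligned
    span of each with its repeat count when the count meets the threshold.
    Runs whose unit is a repetition of a shorter unit (e.g. ``ACAC``) are
    suppressed: they belong to the shorter unit's length class.

    Returns loci sorted by start (then end, then unit).
    """
    if min_repeats is None:
        min_repeats = DEFAULT_MIN_REPEATS
    s = seq.residues
    n = len(s)
    loci: list[SsrLocus] = []
    for length, threshold in sorted(min_repeats.items()):
        if not 1 <= length <= 6:
            raise ValueError(f"motif length {length} outside 1-6")
        if threshold is None:
            continue
        i = 0
        while i + length < n:
            if not _match(s[i], s[i + length]):
                i += 1
                continue
            # maximal periodic interval [run_start, j+length)
            run_start = i
            j = i
            while j + length < n and _match(s[j], s[j + length]):
                j += 1
            interval_len = j + length - run_start
            count = interval_len // length
            unit = s[run_start : run_start + length]
            if count >= threshold and _is_primitive(unit):
                loci.append(
                    SsrLocus(
                        sequence_id=seq.id,
                        start=run_start,
                        end=run_start + count * length,
                        motif=canonicalize_motif(unit),
                        repeat_count=count,
                    )
                )
            i = j + 1
    loci.sort(key=lambda l: (l.start, l.end, l.motif.unit))
    return loci


def merge_compound(
    loci: Sequence[SsrLocus],
    seq: SequenceRecord,
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[SsrLocus]:
    """Join runs separated by at most ``max_gap`` bases into compound loci.

    Input loci must be sorted by start, non-overlapping and on ``seq``.
    Chains of adjacent runs collapse into a single compound locus whose
    parts record each run and the interruption text (possibly empty, as in
    ``(ATT)2(CA)8``); isolated runs pass through unchanged.
    """
    for locus in loci:
        if locus.sequence_id != seq.id:
            raise ValueError("all loci must come from the given sequence")
    for prev, nxt in zip(loci, loci[1:]):
        if nxt.start < prev.start:
            raise ValueError("loci must be sorted by start")
        if nxt.start < prev.end:
            raise ValueError(
                f"overlapping loci [{prev.start},{prev.end}) and "
                f"[{nxt.start},{nxt.end}) cannot be merged"
            )

    merged: list[SsrLocus] = []
    chain: list[SsrLocus] = []

    def flush() -> None:
        if not chain:
            return
        if len(chain) == 1:
            merged.append(chain[0])
        else:
            parts = []
            for a, b in zip(chain, chain[1:]):
                gap = seq.residues[a.end : b.start]
                for p in a.parts[:-1]:
                    parts.append(p)
                last = a.parts[-1]
                parts.append(SsrPart(last.motif, last.count, gap))
            parts.extend(chain[-1].parts)
            merged.append(
                SsrLocus(
                    sequence_id=seq.id,
                    start=chain[0].start,
                    end=chain[-1].end,
                    motif=chain[0].motif,
                    repeat_count=sum(l.repeat_count for l in chain),
                    kind="compound",
                    parts=tuple(parts),
                )
            )
        chain.clear()

    for locus in loci:
        if chain and locus.start - chain[-1].end <= max_gap:
            chain.append(locus)
        else:
            flush()
            chain.append(locus)
    flush()
    return merged


# ---------------------------------------------------------------------------
# Primer screening


@dataclass(frozen=True)
class PrimerCriteria:
    """Acceptance windows for primer screening.

    Defaults are the marker-development criteria: primer length 18-22 bp,
    Tm 50-60 degC, product 100-300 bp, GC fraction 0.40-0.60.
    """

    size_range: tuple[int, int] = (18, 22)
    tm_range: tuple[float, float] = (50.0, 60.0)
    product_range: tuple[int, int] = (100, 300)
    gc_range: tuple[float, float] = (0.40, 0.60)

    def __post_init__(self) -> None:
        for name in ("size_range", "tm_range", "product_range", "gc_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered min <= max")


@dataclass(frozen=True)
class PrimerPair:
    forward: str
    reverse: str
    product_size: int

    def __post_init__(self) -> None:
        for primer in (self.forward, self.reverse):
            if not primer or set(primer.upper()) - DNA_ALPHABET:
                raise InvalidSequenceError(f"primer {primer!r} is not plain DNA")
        if self.product_size <= max(len(self.forward), len(self.reverse)):
            raise ValueError("product_size must exceed both primer lengths")


@dataclass(frozen=True)
class CriterionCheck:
    criterion: str
    value: float
    low: float
    high: float

    @property
    def passed(self) -> bool:
        return self.low <= self.value <= self.high


@dataclass(frozen=True)
class PrimerScreenReport:
    checks: tuple[CriterionCheck, ...]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def failed_criteria(self) -> list[str]:
        return [c.criterion for c in self.checks if not c.passed]


def melting_temperature(primer: str, method: str = "nearest_neighbor") -> float:
    """Primer Tm in degC.

    ``wallace`` is the 2(A+T)+4(G+C) rule; ``nearest_neighbor`` uses the
    thermodynamic nearest-neighbor model (Biopython's Tm_NN with its default
    Allawi & SantaLucia parameter table), closer to what thermodynamic
    primer-design software reports. Exact parity with any particular design
    tool is not promised.
    """
    if method == "wallace":
        return float(MeltingTemp.Tm_Wallace(primer))
    if method == "nearest_neighbor":
        return float(MeltingTemp.Tm_NN(primer))
    raise ValueError(f"unknown tm_method {method!r}")


def screen_primer_pair(
    pair: PrimerPair,
    criteria: PrimerCriteria | None = None,
    tm_method: str = "nearest_neighbor",
) -> PrimerScreenReport:
    """Evaluate a primer pair against the design criteria.

    Returns a per-criterion report (length, GC, Tm for each primer, product
    size); the pair passes overall iff every criterion passes.  Widening any
    window can only turn failures into passes.
    """
    if criteria is None:
        criteria = PrimerCriteria()
    checks: list[CriterionCheck] = []
    for label, primer in (("forward", pair.forward), ("reverse", pair.reverse)):
        primer = primer.upper()
        checks.append(
            CriterionCheck(f"{label}_length", len(primer), *criteria.size_range)
        )
        checks.append(
            CriterionCheck(
                f"{label}_gc", float(gc_fraction(primer)), *criteria.gc_range
            )
        )
        checks.append(
            CriterionCheck(
                f"{label}_tm",
                melting_temperature(primer, tm_method),
                *criteria.tm_range,
            )
        )
    checks.append(
        CriterionCheck("product_size", pair.product_size, *criteria.product_range)
    )
    return PrimerScreenReport(checks=tuple(checks))


def brute_force_ssrs(
    seq: SequenceRecord,
    min_repeats: Mapping[int, int] | None = None,
) -> list[SsrLocus]:
    """Exhaustive reference enumeration of perfect SSRs (for verification).

    Tests every (start, unit-length) pair independently: takes the unit at
    that position, extends the tandem run greedily to the right character by
    character, and keeps the run only if it cannot be periodically extended
    to the left (i.e. this start is the leftmost anchor of its maximal run).
    Quadratic; intended for short sequences.
    """
    if min_repeats is None:
        min_repeats = DEFAULT_MIN_REPEATS
    s = seq.residues
    n = len(s)
    found: dict[tuple[int, int, str], SsrLocus] = {}
    for length, threshold in min_repeats.items():
        if threshold is None:
            continue
        for start in range(n - length):
            unit = s[start : start + length]
            if set(unit) - DNA_ALPHABET or not _is_primitive(unit):
                continue
            # leftmost anchor of the periodic interval?
            if start > 0 and _match(s[start - 1], s[start + length - 1]):
                continue
            j = start
            while j + length < n and _match(s[j], s[j + length]):
                j += 1
            count = (j + length - start) // length
            if count >= threshold:
                key = (start, start + count * length, unit)
                found[key] = SsrLocus(
                    sequence_id=seq.id,
                    start=start,
                    end=start + count * length,
                    motif=canonicalize_motif(unit),
                    repeat_count=count,
                )
    return sorted(found.values(), key=lambda l: (l.start, l.end, l.motif.unit))
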