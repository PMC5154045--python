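"""Characterization statistics for dominant SSR markers.

Implements the statistics used to characterize marker panels scored as
dominant band data:

* polymorphism information content,
  ``PIC = 1 - sum_i p_i^2 - sum_{i<j} 2 p_i^2 p_j^2``
  over the band frequencies ``p_i`` of a locus;
* discriminating power over distinct banding patterns,
  ``DP = 1 - sum_k q_k (N q_k - 1) / (N - 1)`` — the probability that two
  randomly drawn distinct genotypes show different patterns;
* private bands (bands observed in exactly one species of a multi-species
  panel), a simple species-diagnostic signal;
* cross-species transferability (amplified / tested percentages);
* a per-locus characterization report with panel means and ranges.

All internal math is done at full precision; report rendering rounds to
2 decimals with half-up rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .bands import AmplificationTable, BandMatrix, normalize_species

ALL_SUBSET = "all"


class UndefinedStatisticError(ValueError):
    """Raised when a statistic is requested on data that cannot define it."""


def round2(x: float) -> float:
    """Round to 2 decimals, half up (the convention used in the reports)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), ROUND_HALF_UP))


@dataclass(frozen=True)
class BandFrequencySet:
    """Per-locus band frequencies for a subset of the panel.

    ``mode='presence'`` keeps raw presence fractions (band carriers /
    genotypes scored); ``mode='normalized'`` rescales them to sum to 1,
    which keeps PIC inside its usual [0, 1) bounds.
    """

    locus: str
    subset: str
    p: tuple[float, ...]
    mode: str
    n_scored: int

    def __post_init__(self) -> None:
        if self.mode not in ("normalized", "presence"):
            raise ValueError(f"unknown frequency mode {self.mode!r}")
        if any(not 0 <= x <= 1 for x in self.p):
            raise ValueError("band frequencies must lie in [0, 1]")
        if self.mode == "normalized" and self.p:
            if abs(sum(self.p) - 1.0) > 1e-9:
                raise ValueError("normalized frequencies must sum to 1")

    @property
    def n_bands(self) -> int:
        return sum(1 for x in self.p if x > 0)


@dataclass(frozen=True)
class PatternFrequencySet:
    """Frequencies of distinct presence/absence banding patterns at a locus."""

    locus: str
    subset: str
    n: int
    q: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.q and abs(sum(self.q) - 1.0) > 1e-9:
            raise ValueError("pattern frequencies must sum to 1")


def _subset_mask(matrix: BandMatrix, subset: str) -> pd.Series:
    if subset == ALL_SUBSET:
        return pd.Series(True, index=matrix.scores.index)
    wanted = normalize_species(subset)
    mask = matrix.species.map(normalize_species) == wanted
    if not mask.any():
        raise KeyError(f"no accessions for species {subset!r}")
    return mask


def band_frequencies(
    matrix: BandMatrix,
    locus: str,
    subset: str = ALL_SUBSET,
    mode: str = "normalized",
) -> BandFrequencySet:
    """Band frequencies p_i at ``locus`` over a species subset (or 'all').

    Genotypes in the failed state are excluded from the denominator.
    """
    mask = _subset_mask(matrix, subset)
    block = matrix.scores[locus].loc[mask]
    scored = block.dropna(how="all")
    if scored.empty:
        raise UndefinedStatisticError(
            f"no scored genotypes at locus {locus!r} for subset {subset!r}"
        )
    presence = scored.sum(axis=0).to_numpy(dtype=float) / len(scored)
    if mode == "presence":
        p = presence
    elif mode == "normalized":
        total = presence.sum()
        if total == 0:
            raise UndefinedStatisticError(
                f"no bands observed at locus {locus!r} for subset {subset!r}"
            )
        p = presence / total
    else:
        raise ValueError(f"unknown frequency mode {mode!r}")
    return BandFrequencySet(
        locus=locus, subset=subset, p=tuple(float(x) for x in p),
        mode=mode, n_scored=len(scored),
    )


def pic(freqs: BandFrequencySet | Sequence[float]) -> float:
    """Polymorphism information content of a locus.

    ``PIC = 1 - sum_i p_i^2 - sum_i sum_{j>i} 2 p_i^2 p_j^2`` over band
    frequencies.  Zero for a monomorphic locus (one band at frequency 1,
    normalized mode); higher for many evenly frequent bands.
    """
    p = np.asarray(freqs.p if isinstance(freqs, BandFrequencySet) else freqs, float)
    if p.size == 0:
        raise UndefinedStatisticError("PIC needs at least one band")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("band frequencies must lie in [0, 1]")
    sq = p**2
    pairs = (np.sum(sq) ** 2 - np.sum(sq**2)) / 2.0  # sum_{i<j} p_i^2 p_j^2
    return float(1.0 - np.sum(sq) - 2.0 * pairs)


def banding_patterns(
    matrix: BandMatrix, locus: str, subset: str = ALL_SUBSET
) -> PatternFrequencySet:
    """Frequencies of distinct presence/absence patterns at ``locus``."""
    mask = _subset_mask(matrix, subset)
    block = matrix.scores[locus].loc[mask].dropna(how="all")
    if block.empty:
        raise UndefinedStatisticError(
            f"no scored genotypes at locus {locus!r} for subset {subset!r}"
        )
    patterns = [tuple(int(v) for v in row) for row in block.to_numpy()]
    n = len(patterns)
    counts = pd.Series(patterns).value_counts()
    return PatternFrequencySet(
        locus=locus, subset=subset, n=n,
        q=tuple(float(c) / n for c in counts),
    )


def dp(patterns: PatternFrequencySet | Sequence[float], n: int | None = None) -> float:
    """Discriminating power of a locus over banding patterns.

    ``DP = 1 - sum_k q_k (N q_k - 1) / (N - 1)``: the probability that two
    genotypes drawn without replacement show different banding patterns.
    1 when all N patterns are distinct, 0 when all are identical.
    """
    if isinstance(patterns, PatternFrequencySet):
        q = np.asarray(patterns.q, float)
        n = patterns.n
    else:
        q = np.asarray(patterns, float)
        if n is None:
            raise ValueError("n (genotypes scored) required with raw frequencies")
    if n < 2:
        raise UndefinedStatisticError("DP needs at least 2 scored genotypes")
    return float(1.0 - np.sum(q * (n * q - 1.0)) / (n - 1.0))


# ---------------------------------------------------------------------------
# Private bands


@dataclass
class PrivateBandReport:
    """Private-band tallies: bands seen in exactly one species.

    ``counts`` is a loci x species frame of private-band counts; summary
    rows give per-species totals, the number of loci with at least one
    private band, and that count as a percentage of all panel loci.
    """

    counts: pd.DataFrame
    private_bands: dict[tuple[str, str], list]  # (locus, species) -> band ids

    @property
    def loci_with_private(self) -> pd.Series:
        return (self.counts > 0).sum(axis=0)

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def percent_loci_with_private(self, n_loci: int | None = None) -> pd.Series:
        """Share of loci carrying >= 1 private band, per species.

        ``n_loci`` defaults to the full panel locus count of this report
        (the denominator used in published private-band tables).
        """
        denom = n_loci if n_loci is not None else self.counts.shape[0]
        return 100.0 * self.loci_with_private / denom


def private_bands(matrix: BandMatrix) -> PrivateBandReport:
    """Find bands observed in genotypes of exactly one species.

    A band is private to species s iff it is present in >= 1 genotype of s
    and in 0 genotypes of every other species; failed genotypes are
    non-observations and cannot veto privacy.
    """
    species_names = matrix.species_names()
    if len(species_names) < 2:
        raise UndefinedStatisticError(
            "private bands are undefined for a single-species panel"
        )
    counts = pd.DataFrame(0, index=matrix.loci, columns=species_names, dtype=int)
    assignments: dict[tuple[str, str], list] = {}
    species = matrix.species
    for locus in matrix.loci:
        block = matrix.scores[locus]
        present = block.fillna(0.0).astype(bool)
        for band in block.columns:
            carriers = species[present[band]]
            observed_in = set(carriers.map(normalize_species))
            if len(observed_in) == 1:
                sp = carriers.iloc[0]
                # credit under the panel's canonical label for that species
                canonical = next(
                    s for s in species_names
                    if normalize_species(s) == normalize_species(sp)
                )
                counts.at[locus, canonical] += 1
                assignments.setdefault((locus, canonical), []).append(band)
    return PrivateBandReport(counts=counts, private_bands=assignments)


# ---------------------------------------------------------------------------
# Transferability


def transferability(
    amp: AmplificationTable,
    locus_subset: Sequence[str] | None = None,
    digits: int | None = 2,
) -> pd.Series:
    """Per-species amplification percentage over a locus subset.

    ``100 * sum(amplified) / sum(tested)`` per species over the chosen loci
    (all loci if ``locus_subset`` is None), rounded half-up to ``digits``
    decimals (None = no rounding).  Marker tables conventionally report the
    full panel; panel summaries often restrict to the retained loci — pass
    the subset to get either convention.
    """
    loci = amp.loci if locus_subset is None else list(locus_subset)
    if not loci:
        raise ValueError("locus subset must be non-empty")
    unknown = set(loci) - set(amp.loci)
    if unknown:
        raise KeyError(f"unknown loci {sorted(unknown)}")
    sub = amp.counts.loc[amp.counts.index.get_level_values(0).isin(set(loci))]
    totals = sub.groupby(level=1, sort=False).sum()
    pct = 100.0 * totals["amplified"] / totals["tested"]
    if digits is not None:
        quantum = Decimal(1).scaleb(-digits)
        pct = pct.map(
            lambda x: float(Decimal(repr(float(x))).quantize(quantum, ROUND_HALF_UP))
        )
    return pct


# ---------------------------------------------------------------------------
# Per-locus characterization report


@dataclass
class CharacterizationReport:
    """Per-locus characterization rows plus panel means and ranges.

    ``per_locus`` columns: n_bands_focal, pic_focal, dp_focal,
    n_bands_all, pic_all — band counts and PIC for the focal species and
    for the whole panel, DP for the focal species.
    """

    per_locus: pd.DataFrame
    focal_species: str

    @property
    def means(self) -> pd.Series:
        return self.per_locus.mean(axis=0)

    @property
    def ranges(self) -> pd.DataFrame:
        return self.per_locus.agg(["min", "max"])

    def rendered(self) -> pd.DataFrame:
        """Report with 2-decimal half-up rounding applied to the statistics."""
        out = self.per_locus.copy()
        for col in ("pic_focal", "dp_focal", "pic_all"):
            out[col] = out[col].map(round2)
        return out


def summarize(
    matrix: BandMatrix,
    focal_species: str,
    retained_loci: Sequence[str] | None = None,
    pic_mode: str = "normalized",
) -> CharacterizationReport:
    """Build the per-locus characterization report.

    For each retained locus: number of bands and PIC within the focal
    species and within the full panel, and DP within the focal species.
    """
    loci = list(retained_loci) if retained_loci is not None else matrix.loci
    if not loci:
        raise ValueError("retained_loci must be non-empty")
    rows = []
    for locus in loci:
        f_focal = band_frequencies(matrix, locus, focal_species, mode=pic_mode)
        f_all = band_frequencies(matrix, locus, ALL_SUBSET, mode=pic_mode)
        patt = banding_patterns(matrix, locus, focal_species)
        rows.append(
            {
                "locus": locus,
                "n_bands_focal": f_focal.n_bands,
                "pic_focal": pic(f_focal),
                "dp_focal": dp(patt),
                "n_bands_all": f_all.n_bands,
                "pic_all": pic(f_all),
            }
        )
    per_locus = pd.DataFrame(rows).set_index("locus")
    return CharacterizationReport(per_locus=per_locus, focal_species=focal_species)


def locus_table_means(
    table: pd.DataFrame,
    retained_loci: Sequence[str],
    columns: Sequence[str] = (
        "n_bands_focal", "pic_focal", "dp_focal", "n_bands_all", "pic_all",
    ),
) -> pd.Series:
    """Column means of a per-locus summary table over the retained loci.

    Works on any per-locus table indexed by locus name (e.g. a published
    marker-description table) and returns 2-decimal half-up rounded means,
    the convention such tables print.
    """
    sub = table.loc[list(retained_loci), list(columns)]
    return sub.mean(axis=0).map(round2)
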