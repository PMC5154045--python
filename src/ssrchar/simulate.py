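"""Synthetic band matrices and SSR sequences with known ground truth.

The generator emulates a multi-species germplasm panel scored with
dominant SSR markers (the study-panel scale is 48 genotypes from 8
species at 25 loci): per-species band presence frequencies, injected
species-private bands, amplification failures, and an adjustable
differentiation scalar that sweeps from panmixia (all species share one
frequency vector) to fixed inter-species differences.  Every dataset
carries the truth that generated it, so detection, statistics and
cluster-recovery code can be tested end to end without external data.

Bands are simulated independently within a locus (no dosage model).  An
optional tetraploid mode derives each presence probability as
``1 - (1 - q)^4`` from a latent allele frequency q, mimicking dominant
band expression in a tetraploid; the default is the plain independent
model since no inheritance model is assumed for band presence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .bands import BandMatrix
from .discovery import (
    DEFAULT_MIN_REPEATS,
    SequenceRecord,
    SsrLocus,
    canonicalize_motif,
    find_perfect_ssrs,
)

#: Species panel sizes of the study-scale default configuration.
DEFAULT_PANEL_SIZES = (26, 3, 4, 6, 3, 1, 3, 2)


@dataclass
class SimulationConfig:
    """Configuration for a synthetic dominant band matrix.

    Defaults emulate the study panel: 8 species with genotype counts
    (26, 3, 4, 6, 3, 1, 3, 2), 25 loci, 2-17 bands per locus, a moderate
    differentiation of 0.6 and a 5% amplification-failure rate.
    """

    n_species: int = 8
    genotypes_per_species: tuple[int, ...] = DEFAULT_PANEL_SIZES
    n_loci: int = 25
    bands_per_locus: int | tuple[int, int] = (2, 17)
    #: Beta(alpha, alpha) hyperparameter for species-specific presence
    #: frequencies; small alpha pushes frequencies toward 0/1 (fixed
    #: differences between species).
    freq_alpha: float = 0.5
    #: 0 = all species share one frequency vector; 1 = fully
    #: species-specific frequencies.
    differentiation: float = 0.6
    #: Per-locus probability of injecting one species-exclusive band.
    private_band_rate: float = 0.3
    #: Within-species presence frequency of injected private bands.
    private_band_freq: float = 0.8
    #: Per (genotype, locus) amplification-failure probability; a mapping
    #: of species index -> rate makes failure species-dependent.
    failure_rate: float | dict[int, float] = 0.05
    tetraploid_mode: bool = False
    explicit_freqs: list[np.ndarray] | None = None  # per locus: species x bands
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.genotypes_per_species) != self.n_species:
            raise ValueError("genotypes_per_species length must equal n_species")
        if self.n_species < 1 or self.n_loci < 1:
            raise ValueError("need at least one species and one locus")
        if any(g < 1 for g in self.genotypes_per_species):
            raise ValueError("every species needs at least one genotype")
        if not 0 <= self.differentiation <= 1:
            raise ValueError("differentiation must lie in [0, 1]")
        if not 0 <= self.private_band_rate <= 1:
            raise ValueError("private_band_rate must lie in [0, 1]")

    def failure_rate_for(self, species_idx: int) -> float:
        if isinstance(self.failure_rate, dict):
            return self.failure_rate.get(species_idx, 0.0)
        return float(self.failure_rate)


@dataclass
class SimulatedDataset:
    """A synthetic BandMatrix plus the ground truth that generated it."""

    matrix: BandMatrix
    species_labels: list[str]  # per accession
    #: per locus: species x bands matrix of true presence probabilities
    true_frequencies: list[np.ndarray]
    #: injected private bands as (locus, species, band_size)
    injected_private: list[tuple[str, str, int]]
    expected_missing_rate: dict[str, float]
    config: SimulationConfig


def _species_label(i: int) -> str:
    return f"species_{i + 1:02d}"


def simulate_band_matrix(config: SimulationConfig) -> SimulatedDataset:
    """Draw a dominant band matrix with known per-species frequencies.

    Each (genotype, locus) first draws amplification failure; surviving
    genotypes draw each band independently with their species' presence
    probability.  Injected private bands are appended as extra bands that
    only the chosen species can show; at least one carrier genotype is
    guaranteed so the injection is always observable under lossless
    conditions.  Fully reproducible given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_species = config.n_species
    sizes = config.genotypes_per_species
    species_labels = [
        _species_label(s) for s, n in enumerate(sizes) for _ in range(n)
    ]
    accession_ids = [f"acc_{i + 1:03d}" for i in range(sum(sizes))]
    species_idx = np.repeat(np.arange(n_species), sizes)

    if isinstance(config.bands_per_locus, int):
        band_counts = np.full(config.n_loci, config.bands_per_locus)
    else:
        lo, hi = config.bands_per_locus
        band_counts = rng.integers(lo, hi + 1, size=config.n_loci)

    columns: list[tuple[str, int]] = []
    truths: list[np.ndarray] = []
    injected: list[tuple[str, str, int]] = []
    locus_names = [f"locus_{j + 1:02d}" for j in range(config.n_loci)]
    cells = np.full((len(accession_ids), 0), np.nan)
    all_cols: list[np.ndarray] = []

    for j, locus in enumerate(locus_names):
        nb = int(band_counts[j])
        if config.explicit_freqs is not None:
            freqs = np.asarray(config.explicit_freqs[j], dtype=float)
            nb = freqs.shape[1]
        else:
            shared = rng.uniform(0.1, 0.9, size=nb)
            specific = rng.beta(config.freq_alpha, config.freq_alpha, size=(n_species, nb))
            d = config.differentiation
            freqs = (1 - d) * shared[None, :] + d * specific
        if config.tetraploid_mode:
            freqs = 1.0 - (1.0 - freqs) ** 4

        band_sizes = list(100 + 10 * np.arange(nb))
        # optional species-private band appended with zero frequency elsewhere
        private_here = (
            config.private_band_rate > 0
            and rng.random() < config.private_band_rate
        )
        if private_here:
            target = int(rng.integers(n_species))
            extra = np.zeros((n_species, 1))
            extra[target, 0] = config.private_band_freq
            freqs = np.hstack([freqs, extra])
            private_size = int(100 + 10 * nb)
            band_sizes.append(private_size)
            injected.append((locus, _species_label(target), private_size))
            nb += 1

        # amplification failure first, then band draws
        fail_p = np.array([config.failure_rate_for(s) for s in species_idx])
        failed = rng.random(len(accession_ids)) < fail_p
        draws = rng.random((len(accession_ids), nb)) < freqs[species_idx]
        block = draws.astype(float)
        if private_here:
            # guarantee at least one observable carrier in the target species
            target_rows = np.flatnonzero((species_idx == target) & ~failed)
            if target_rows.size and not block[target_rows, -1].any():
                block[target_rows[0], -1] = 1.0
        block[failed] = np.nan
        all_cols.append(block)
        columns.extend((locus, int(b)) for b in band_sizes)
        truths.append(freqs)

    scores = pd.DataFrame(
        np.hstack(all_cols),
        index=pd.Index(accession_ids, name="accession_id"),
        columns=pd.MultiIndex.from_tuples(columns, names=["locus", "band_size_bp"]),
    )
    species = pd.Series(species_labels, index=scores.index, name="species")
    matrix = BandMatrix(scores, species)
    expected_missing = {
        locus: float(
            np.average([config.failure_rate_for(s) for s in range(n_species)],
                       weights=sizes)
        )
        for locus in locus_names
    }
    return SimulatedDataset(
        matrix=matrix,
        species_labels=species_labels,
        true_frequencies=truths,
        injected_private=injected,
        expected_missing_rate=expected_missing,
        config=config,
    )


# ---------------------------------------------------------------------------
# SSR sequence fixtures


def _leftmost_anchored(
    residues: str, sequence_id: str, start: int, end: int, period: int
) -> SsrLocus:
    """Canonical coordinates of the maximal run containing a planted run.

    A neighbouring interruption or flank character can continue a run's
    periodicity (e.g. a gap ending in C in front of (AAC)n extends the
    periodic interval one base left, phase-shifting the unit to CAA).
    Reported runs are anchored at the leftmost base of their maximal
    periodic interval, so the planted coordinates are adjusted to that
    convention here.
    """
    n = len(residues)

    def match(i: int, j: int) -> bool:
        return residues[i] == residues[j] != "N"

    a, b = start, end
    while a > 0 and match(a - 1, a + period - 1):
        a -= 1
    while b < n and match(b, b - period):
        b += 1
    count = (b - a) // period
    return SsrLocus(
        sequence_id=sequence_id,
        start=a,
        end=a + count * period,
        motif=canonicalize_motif(residues[a : a + period]),
        repeat_count=count,
    )


def simulate_ssr_sequence(
    motifs: Sequence[tuple[str, int]],
    gaps: Sequence[str] = (),
    flank_lengths: tuple[int, int] = (30, 30),
    seed: int = 0,
    min_repeats: dict[int, int] | None = None,
    max_tries: int = 200,
    sequence_id: str = "synthetic",
) -> tuple[SequenceRecord, list[SsrLocus]]:
    """Build flank + repeat runs (+ interruptions) + flank with exact truth.

    Flanks are rejection-sampled until they (and their junctions with the
    repeat region) contain no tandem run meeting the thresholds, so the
    returned truth loci are exactly what a correct detector must report.
    """
    if min_repeats is None:
        min_repeats = DEFAULT_MIN_REPEATS
    if gaps and len(gaps) != len(motifs) - 1:
        raise ValueError("need exactly len(motifs) - 1 interruption texts")
    gaps = list(gaps) or [""] * (len(motifs) - 1)
    rng = np.random.default_rng(seed)

    core_parts = []
    for i, (unit, count) in enumerate(motifs):
        canonicalize_motif(unit)  # validates the unit
        core_parts.append(unit.upper() * count)
        if i < len(gaps):
            core_parts.append(gaps[i].upper())
    core = "".join(core_parts)

    alphabet = np.array(list("ACGT"))
    for _ in range(max_tries):
        left = "".join(rng.choice(alphabet, size=flank_lengths[0]))
        right = "".join(rng.choice(alphabet, size=flank_lengths[1]))
        residues = left + core + right
        seq = SequenceRecord(sequence_id, residues)
        detected = find_perfect_ssrs(seq, min_repeats)
        # accept iff every detected run lies inside the core region: the
        # flanks added no run and did not extend a core run
        offset = len(left)
        if all(offset <= l.start and l.end <= offset + len(core) for l in detected):
            truth = []
            pos = offset
            for i, (unit, count) in enumerate(motifs):
                unit = unit.upper()
                truth.append(
                    _leftmost_anchored(
                        residues, sequence_id, pos, pos + len(unit) * count,
                        len(unit),
                    )
                )
                pos += len(unit) * count
                if i < len(gaps):
                    pos += len(gaps[i])
            return seq, truth
    raise RuntimeError(
        f"could not sample SSR-free flanks in {max_tries} tries; "
        "shorten the flanks or relax the thresholds"
    )
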