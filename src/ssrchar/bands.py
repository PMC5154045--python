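"""Dominant band-score matrices: ingestion, validation, quality filtering.

Polyploid genotypes scored on silver-stained gels yield dominant data: for
each genotype and each locus band (a fragment size in bp) only presence (1)
or absence (0) is known, with no allele dosage.  A genotype can also fail
to amplify at a locus entirely, which is a distinct state from "amplified
but showing none of the scored bands": transferability counts amplification
while band statistics count bands, and conflating the two breaks both.
The file format therefore distinguishes 0 (absent) from NA (failed).

Internally scores live in a pandas DataFrame (accessions x (locus, band))
with values 1.0 / 0.0 / NaN, NaN meaning amplification failure; the failed
state is enforced to be consistent across all bands of a locus.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SCORE_TOKENS = {"1": 1.0, "0": 0.0, "NA": np.nan}

#: Default missing-data threshold above which a locus is dropped from
#: statistical analysis.
DEFAULT_MISSING_THRESHOLD = 0.25


class BandMatrixError(ValueError):
    """Malformed or inconsistent band-score data."""


def normalize_species(label: str) -> str:
    """Case-insensitive comparison form after whitespace normalization."""
    return " ".join(str(label).split()).casefold()


@dataclass(frozen=True)
class AccessionRecord:
    """Panel metadata for one genotype (germplasm-bank style)."""

    local_code: str
    species: str
    collector_code: str | None = None
    latitude: float | None = None
    longitude: float | None = None

    def __post_init__(self) -> None:
        if self.latitude is not None and not -90 <= self.latitude <= 90:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if self.longitude is not None and not -180 <= self.longitude <= 180:
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")


@dataclass(frozen=True)
class LocusDef:
    """A marker locus: name plus optional assay annotations."""

    name: str
    annealing_temp: float | None = None
    size_range: tuple[int, int] | None = None
    motif_string: str | None = None

    def __post_init__(self) -> None:
        if self.size_range is not None and self.size_range[0] > self.size_range[1]:
            raise ValueError("size_range must be ordered min <= max")


class BandMatrix:
    """Genotypes x per-locus bands with present/absent/failed states.

    Parameters
    ----------
    scores
        DataFrame indexed by accession id with a 2-level column MultiIndex
        (locus, band_size_bp) and values in {1.0, 0.0, NaN}.
    species
        Series mapping accession id -> species label (free text).
    """

    def __init__(self, scores: pd.DataFrame, species: pd.Series):
        if not isinstance(scores.columns, pd.MultiIndex) or scores.columns.nlevels != 2:
            raise BandMatrixError("scores must have (locus, band) column MultiIndex")
        if scores.columns.duplicated().any():
            dupes = scores.columns[scores.columns.duplicated()].tolist()
            raise BandMatrixError(f"duplicate (locus, band) columns: {dupes}")
        if scores.index.duplicated().any():
            raise BandMatrixError("duplicate accession ids")
        missing = set(scores.index) - set(species.index)
        if missing:
            raise BandMatrixError(f"accessions without species label: {sorted(missing)}")
        values = scores.to_numpy(dtype=float)
        ok = np.isnan(values) | (values == 0.0) | (values == 1.0)
        if not ok.all():
            raise BandMatrixError("scores must be 1, 0 or NA")
        self.scores = scores.astype(float)
        self.species = species.reindex(scores.index).astype(str)
        self._validate_failed_consistency()

    def _validate_failed_consistency(self) -> None:
        # within one (accession, locus) either every band is NA or none is
        for locus in self.loci:
            block = self.scores[locus]
            n_na = block.isna().sum(axis=1)
            bad = (n_na > 0) & (n_na < block.shape[1])
            if bad.any():
                acc = self.scores.index[bad][0]
                raise BandMatrixError(
                    f"inconsistent failed state for accession {acc!r} at locus "
                    f"{locus!r}: a failure must blank every band of the locus"
                )

    # -- basic structure ----------------------------------------------------

    @property
    def accessions(self) -> list[str]:
        return list(self.scores.index)

    @property
    def loci(self) -> list[str]:
        return list(dict.fromkeys(self.scores.columns.get_level_values(0)))

    def bands(self, locus: str) -> list:
        if locus not in set(self.scores.columns.get_level_values(0)):
            raise KeyError(f"unknown locus {locus!r}")
        return list(self.scores[locus].columns)

    @property
    def species_of(self) -> pd.Series:
        return self.species

    def species_names(self) -> list[str]:
        """Distinct species labels in panel order."""
        return list(dict.fromkeys(self.species))

    def n_accessions(self) -> int:
        return self.scores.shape[0]

    def failed_mask(self) -> pd.DataFrame:
        """Accessions x loci boolean frame: True where amplification failed."""
        frames = {locus: self.scores[locus].isna().all(axis=1) for locus in self.loci}
        return pd.DataFrame(frames, index=self.scores.index)

    def select_loci(self, loci: Sequence[str]) -> "BandMatrix":
        known = set(self.loci)
        unknown = [l for l in loci if l not in known]
        if unknown:
            raise KeyError(f"unknown loci {unknown}")
        cols = [c for c in self.scores.columns if c[0] in set(loci)]
        return BandMatrix(self.scores[cols], self.species)

    def subset_accessions(self, accessions: Sequence[str]) -> "BandMatrix":
        return BandMatrix(self.scores.loc[list(accessions)], self.species)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BandMatrix):
            return NotImplemented
        return self.scores.equals(other.scores) and self.species.equals(other.species)


# ---------------------------------------------------------------------------
# Quality statistics


def missing_rate(matrix: BandMatrix, locus: str) -> float:
    """Fraction of panel accessions that failed to amplify at ``locus``."""
    if locus not in set(matrix.loci):
        raise KeyError(f"unknown locus {locus!r}")
    failed = matrix.scores[locus].isna().all(axis=1)
    return float(failed.mean())


def exclude_high_missing(
    matrix: BandMatrix, threshold: float = DEFAULT_MISSING_THRESHOLD
) -> tuple[BandMatrix, list[str]]:
    """Drop loci whose missing rate exceeds ``threshold``.

    Returns (retained matrix, names of excluded loci); retained loci keep
    their original order.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    excluded = [l for l in matrix.loci if missing_rate(matrix, l) > threshold]
    retained = [l for l in matrix.loci if l not in set(excluded)]
    return matrix.select_loci(retained), excluded


@dataclass
class AmplificationTable:
    """Locus x species counts of amplified vs tested genotypes."""

    counts: pd.DataFrame  # MultiIndex rows (locus, species), columns amplified/tested

    def __post_init__(self) -> None:
        bad = self.counts["amplified"] > self.counts["tested"]
        if bad.any():
            raise ValueError("amplified cannot exceed tested")

    @property
    def loci(self) -> list[str]:
        return list(dict.fromkeys(self.counts.index.get_level_values(0)))

    @property
    def species(self) -> list[str]:
        return list(dict.fromkeys(self.counts.index.get_level_values(1)))

    def cell(self, locus: str, species: str) -> tuple[int, int]:
        row = self.counts.loc[(locus, species)]
        return int(row["amplified"]), int(row["tested"])

    def totals(self) -> pd.DataFrame:
        """Per-species column sums (the table footer)."""
        return self.counts.groupby(level=1, sort=False).sum()


def amplification_counts(matrix: BandMatrix) -> AmplificationTable:
    """Tally amplified/tested genotypes per (locus, species).

    A genotype counts as amplified at a locus iff its state there is not
    failed; tested is the species' panel size.
    """
    failed = matrix.failed_mask()
    species = matrix.species
    rows = []
    for locus in matrix.loci:
        for sp in matrix.species_names():
            members = species == sp
            tested = int(members.sum())
            amplified = int((members & ~failed[locus]).sum())
            rows.append((locus, sp, amplified, tested))
    frame = pd.DataFrame(rows, columns=["locus", "species", "amplified", "tested"])
    return AmplificationTable(frame.set_index(["locus", "species"]))


# ---------------------------------------------------------------------------
# Long-format TSV I/O
#
# One row per score: accession_id, species, locus, band_size_bp, score with
# score in {1, 0, NA}; header row required; UTF-8.


def read_band_matrix(path_or_buffer) -> BandMatrix:
    """Read a long-format band-score TSV into a validated BandMatrix."""
    df = pd.read_csv(
        path_or_buffer,
        sep="\t",
        dtype=str,
        keep_default_na=False,
        encoding="utf-8",
    )
    required = ["accession_id", "species", "locus", "band_size_bp", "score"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise BandMatrixError(f"missing required columns {missing_cols}")
    bad = ~df["score"].isin(SCORE_TOKENS)
    if bad.any():
        line = int(df.index[bad][0]) + 2  # 1-based, after header
        raise BandMatrixError(
            f"malformed score token {df.loc[df.index[bad][0], 'score']!r} "
            f"on line {line}: expected 1, 0 or NA"
        )
    dup = df.duplicated(subset=["accession_id", "locus", "band_size_bp"])
    if dup.any():
        line = int(df.index[dup][0]) + 2
        raise BandMatrixError(f"duplicate (accession, locus, band) row on line {line}")
    df["value"] = df["score"].map(SCORE_TOKENS)
    df["band_size_bp"] = pd.to_numeric(df["band_size_bp"])
    wide = df.pivot(index="accession_id", columns=["locus", "band_size_bp"], values="value")
    # preserve first-appearance order of accessions, loci and bands
    acc_order = list(dict.fromkeys(df["accession_id"]))
    col_order = list(dict.fromkeys(zip(df["locus"], df["band_size_bp"])))
    wide = wide.loc[acc_order, col_order]
    # NaN in the wide frame can come from NA scores (fine) or from an
    # unbalanced long format (not fine): every accession must carry a row
    # for every (locus, band) combination seen in the file.
    per_accession = df.groupby("accession_id", sort=False).size()
    short = per_accession[per_accession != len(col_order)]
    if not short.empty:
        raise BandMatrixError(
            f"unbalanced long format: accession {short.index[0]!r} has "
            f"{int(short.iloc[0])} rows, expected {len(col_order)}"
        )
    species = (
        df.drop_duplicates("accession_id").set_index("accession_id")["species"]
    )
    conflicting = df.groupby("accession_id")["species"].nunique()
    if (conflicting > 1).any():
        acc = conflicting[conflicting > 1].index[0]
        raise BandMatrixError(f"accession {acc!r} has conflicting species labels")
    return BandMatrix(wide, species.loc[acc_order])


def write_band_matrix(matrix: BandMatrix, path_or_buffer) -> None:
    """Write a BandMatrix to the long-format TSV (inverse of read)."""
    rows = []
    for acc in matrix.accessions:
        sp = matrix.species[acc]
        for locus, band in matrix.scores.columns:
            v = matrix.scores.at[acc, (locus, band)]
            token = "NA" if pd.isna(v) else str(int(v))
            rows.append((acc, sp, locus, band, token))
    out = pd.DataFrame(
        rows, columns=["accession_id", "species", "locus", "band_size_bp", "score"]
    )
    out.to_csv(path_or_buffer, sep="\t", index=False, encoding="utf-8")


def read_panel_metadata(path_or_buffer) -> list[AccessionRecord]:
    """Read panel metadata TSV (local_code, species, collector_code, lat, lon)."""
    df = pd.read_csv(path_or_buffer, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        records.append(
            AccessionRecord(
                local_code=row["local_code"],
                species=row["species"],
                collector_code=row.get("collector_code") or None,
                latitude=float(row["latitude"]) if row.get("latitude") else None,
                longitude=float(row["longitude"]) if row.get("longitude") else None,
            )
        )
    codes = [r.local_code for r in records]
    if len(set(codes)) != len(codes):
        raise BandMatrixError("duplicate local_code in panel metadata")
    return records
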