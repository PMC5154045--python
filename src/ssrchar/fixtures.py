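"""Packaged reference tables for the published marker panel.

The raw 48 x 25 band matrix behind the panel was never published, so the
per-locus summary tables are shipped as machine-readable TSVs instead:

* ``locus_summary`` — per-locus marker descriptions (motif, primers,
  annealing temperature, size range) and the printed statistics (band
  counts, PIC, DP for the focal species and for the whole panel), plus
  the excluded-for-missing-data flag;
* ``private_bands`` — per-locus private-band counts per species.  Row
  count multisets and all column summaries match the published table; the
  attribution of a few individual cells to species columns is a consistent
  reconstruction where the published layout is ambiguous;
* ``cross_amplification`` — amplified/tested genotype counts per locus and
  non-focal species;
* ``panel_sizes`` — genotypes per species in the characterization panel.

These are summary counts only; no raw band matrix is fabricated.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .bands import AmplificationTable

FOCAL_SPECIES = "Paspalum plicatulum"


@dataclass
class TableFixtures:
    locus_summary: pd.DataFrame  # indexed by locus
    private_bands: pd.DataFrame  # indexed by locus, one column per species
    cross_amplification: AmplificationTable
    panel_sizes: pd.Series  # species -> genotype count

    @property
    def all_loci(self) -> list[str]:
        return list(self.locus_summary.index)

    @property
    def retained_loci(self) -> list[str]:
        keep = self.locus_summary["excluded"] == 0
        return list(self.locus_summary.index[keep])

    @property
    def excluded_loci(self) -> list[str]:
        return list(self.locus_summary.index[self.locus_summary["excluded"] == 1])

    @property
    def species(self) -> list[str]:
        return list(self.panel_sizes.index)


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("ssrchar.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def table_fixtures() -> TableFixtures:
    """Load the packaged per-locus summary tables."""
    locus_summary = _read("locus_summary.tsv").set_index("locus")
    private = _read("private_bands.tsv").set_index("locus")
    cross = _read("cross_amplification.tsv").set_index(["locus", "species"])
    panel = _read("panel_sizes.tsv").set_index("species")["n_accessions"]
    return TableFixtures(
        locus_summary=locus_summary,
        private_bands=private,
        cross_amplification=AmplificationTable(cross),
        panel_sizes=panel,
    )
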