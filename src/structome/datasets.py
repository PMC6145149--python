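"""Bundled reference datasets.

Two small read-only tables ship with the package:

* the per-cell structome profiles of the seven serial-sectioned
  *M. smegmatis* cells (lengths, diameters, surface areas, compartment
  volumes, ribosome totals and densities, as printed in the source
  report); and
* species-level summaries (n, mean, SD) for the six microorganisms whose
  serial-section structome profiles have been published, used for
  cross-species significance tests.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .io import read_profile_table, read_summary_table
from .stats import MetricSummary
from .stereology import CellProfile

__all__ = [
    "load_msmegmatis_profiles",
    "load_species_summaries",
    "species_summary_map",
]


def _data_path(name: str) -> Path:
    return Path(str(resources.files("structome").joinpath("data", name)))


def load_msmegmatis_profiles() -> list[CellProfile]:
    """The seven measured *M. smegmatis* cell profiles."""
    return read_profile_table(_data_path("msmegmatis_cells.tsv"), fmt="tsv")


def load_species_summaries() -> list[MetricSummary]:
    """Published per-species metric summaries (flat list)."""
    return read_summary_table(_data_path("species_summaries.tsv"), fmt="tsv")


def species_summary_map(group_label: str) -> dict[str, MetricSummary]:
    """Summaries of one species keyed by metric name.

    Group labels: ``M_smegmatis``, ``M_tuberculosis``, ``E_coli``,
    ``Myojin_spiral``, ``Myojin_amorphous``, ``E_dermatitidis``,
    ``S_cerevisiae``.
    """
    rows = {s.metric: s for s in load_species_summaries()
            if s.group_label == group_label}
    if not rows:
        raise KeyError(f"unknown species group {group_label!r}")
    return rows
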