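"""Catalogue of known abiotic CH4 sources and their global flux estimates.

Each record carries a minimum/maximum global flux in Tmol/y (either bound
may be absent), a category (magmatic outgassing, low-temperature water-rock
and metamorphic reactions, impacts), an era (modern Earth vs the
Hadean/Archean), and a provenance string naming the study behind the
number. Laboratory yields that imply fluxes exceeding the crustal iron
supply, and whose organic contamination was never quantified, are flagged
``contamination_suspect`` and excluded from queries by default.

The headline comparison: no catalogued abiotic source approaches the modern
biogenic CH4 flux of ~30 Tmol/y; known abiotic processes top out around
~1.5 Tmol/y (Hadean hydrothermal systems and cometary impacts).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .constants import ABIOTIC_FLUX_CEILING, BIOGENIC_FLUX_MODERN

__all__ = [
    "AbioticSourceRecord",
    "Benchmark",
    "load_compendium",
    "max_abiotic_flux",
]

CATEGORIES = frozenset({"magmatic", "water_rock_metamorphic", "impact"})
ERAS = frozenset({"modern", "hadean_archean"})
QUALITIES = frozenset({"ok", "contamination_suspect"})


@dataclass(frozen=True)
class AbioticSourceRecord:
    """One abiotic CH4 source with its global flux estimate, Tmol/y."""

    source_id: str
    category: str
    era: str
    flux_min: float | None
    flux_max: float | None
    quality: str
    provenance: str


@dataclass(frozen=True)
class Benchmark:
    """Framework reference fluxes, Tmol/y."""

    biogenic_flux_modern: float = BIOGENIC_FLUX_MODERN
    abiotic_plausibility_ceiling: float = ABIOTIC_FLUX_CEILING

    def __post_init__(self) -> None:
        if self.biogenic_flux_modern <= 0 or self.abiotic_plausibility_ceiling <= 0:
            raise ValueError("benchmark fluxes must be positive")


def _packaged_path() -> Path:
    return Path(str(resources.files("ch4context") / "data" / "abiotic_ch4_sources.csv"))


def load_compendium(path: str | Path | None = None) -> list[AbioticSourceRecord]:
    """Load and validate the abiotic-source catalogue.

    Reads the packaged CSV by default. Every row is validated against the
    record schema; a violation raises ``ValueError`` naming the offending
    row index. An empty file is an error, never an empty list.
    """
    path = Path(path) if path is not None else _packaged_path()
    df = pd.read_csv(path, dtype={"source_id": str, "provenance": str})
    if df.empty:
        raise ValueError(f"compendium file {path} contains no records")

    expected = {
        "source_id", "category", "era",
        "flux_min_tmol_y", "flux_max_tmol_y", "quality", "provenance",
    }
    missing = expected - set(df.columns)
    if missing:
        raise ValueError(f"compendium file {path} missing columns {sorted(missing)}")

    records: list[AbioticSourceRecord] = []
    for idx, row in df.iterrows():
        fmin = None if pd.isna(row.flux_min_tmol_y) else float(row.flux_min_tmol_y)
        fmax = None if pd.isna(row.flux_max_tmol_y) else float(row.flux_max_tmol_y)
        if row.category not in CATEGORIES:
            raise ValueError(f"record {idx}: unknown category {row.category!r}")
        if row.era not in ERAS:
            raise ValueError(f"record {idx}: unknown era {row.era!r}")
        if row.quality not in QUALITIES:
            raise ValueError(f"record {idx}: unknown quality {row.quality!r}")
        for bound, name in ((fmin, "flux_min"), (fmax, "flux_max")):
            if bound is not None and bound < 0:
                raise ValueError(f"record {idx}: {name} is negative")
        if fmin is not None and fmax is not None and fmin > fmax:
            raise ValueError(f"record {idx}: flux_min > flux_max")
        records.append(
            AbioticSourceRecord(
                source_id=str(row.source_id),
                category=str(row.category),
                era=str(row.era),
                flux_min=fmin,
                flux_max=fmax,
                quality=str(row.quality),
                provenance=str(row.provenance),
            )
        )
    return records


def max_abiotic_flux(
    records: list[AbioticSourceRecord],
    era: str | None = None,
    include_suspect: bool = False,
) -> float:
    """Largest flux_max (Tmol/y) over records matching the era filter.

    Contamination-suspect records are excluded unless ``include_suspect``;
    records with no upper bound cannot contribute. Raises ``ValueError``
    when nothing matches.
    """
    if not records:
        raise ValueError("empty record list")
    if era is not None and era not in ERAS:
        raise ValueError(f"unknown era {era!r}")
    candidates = [
        r.flux_max
        for r in records
        if r.flux_max is not None
        and (era is None or r.era == era)
        and (include_suspect or r.quality != "contamination_suspect")
    ]
    if not candidates:
        raise ValueError("no records match the filter")
    return max(candidates)


def get_record(records: list[AbioticSourceRecord], source_id: str) -> AbioticSourceRecord:
    """Look up a record by its source_id; raises ``KeyError`` if absent."""
    for r in records:
        if r.source_id == source_id:
            return r
    raise KeyError(source_id)
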