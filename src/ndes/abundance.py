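"""Turn raw plot survey tables into paired simplex-valued observations.

Permanent inventory plots are remeasured on a fixed 5-year cycle.  Each
tree species is assigned to one of three management groups — pine, fir,
broadleaf — and the plot's *abundance* triple is the biomass share of each
group.  Plots measured at both endpoints of a reexamination period, and
forested at its start, form the paired observations that the estimation
module consumes.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import validate_simplex

__all__ = [
    "GROUPS",
    "SpeciesGroupMap",
    "PlotSurvey",
    "PairedObservation",
    "PairingReport",
    "DominanceTally",
    "classify_species_group",
    "compute_plot_abundance",
    "pair_surveys",
    "tally_dominant_groups",
    "read_plot_table",
    "write_plot_table",
]

GROUPS = ("pine", "fir", "broadleaf")

# Genus/species lists of the three management groups as used in subtropical
# Chinese inventory practice.  Editable: users load their own map from config.
DEFAULT_SPECIES_GROUPS: dict[str, tuple[str, ...]] = {
    "pine": (
        "Pinus massoniana",
        "Pinus thunbergii",
        "Pinus taiwanensis",
        "Pinus elliottii",
    ),
    "fir": (
        "Cunninghamia lanceolata",
        "Cryptomeria fortunei",
        "Metasequoia glyptostroboides",
        "Taxodium ascendens",
        "Taxus wallichiana var. chinensis",
    ),
    "broadleaf": (
        "Quercus",
        "Castanopsis",
        "Liquidambar",
        "Schima superba",
        "Cinnamomum camphora",
        "Lauraceae",
    ),
}


def _norm(name: str) -> str:
    return re.sub(r"\s+", " ", name.strip()).lower()


@dataclass(frozen=True)
class SpeciesGroupMap:
    """Mapping from species name to group label; lookup is case-insensitive
    after whitespace normalization."""

    entries: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("species map must be nonempty")
        normalized = {}
        for species, group in self.entries.items():
            if group not in GROUPS:
                raise ValueError(
                    f"species {species!r} maps to unknown group {group!r}; "
                    f"expected one of {GROUPS}"
                )
            key = _norm(species)
            if key in normalized and normalized[key] != group:
                raise ValueError(f"species {species!r} mapped to two groups")
            normalized[key] = group
        object.__setattr__(self, "_normalized", normalized)

    @classmethod
    def default(cls) -> "SpeciesGroupMap":
        entries = {
            sp: grp for grp, names in DEFAULT_SPECIES_GROUPS.items() for sp in names
        }
        return cls(entries)

    @classmethod
    def from_group_lists(cls, groups: Mapping[str, Sequence[str]]) -> "SpeciesGroupMap":
        """Build from a config-style ``{group: [species, ...]}`` mapping."""
        return cls({sp: grp for grp, names in groups.items() for sp in names})

    def lookup(self, species_name: str) -> str:
        key = _norm(species_name)
        try:
            return self._normalized[key]  # type: ignore[attr-defined]
        except KeyError:
            raise KeyError(
                f"species {species_name!r} is not in the species-group map; "
                f"add it to the map config rather than relying on a default"
            ) from None


def classify_species_group(species_name: str, species_map: SpeciesGroupMap) -> str:
    """Return the group label ('pine' | 'fir' | 'broadleaf') for a species.

    Unknown species raise ``KeyError`` naming the species — never a silent
    drop or a default group.
    """
    return species_map.lookup(species_name)


def compute_plot_abundance(biomass) -> np.ndarray:
    """Biomass shares (pine, fir, broadleaf) of a plot; the abundance triple.

    Raises ``ValueError`` on negative biomass or on a zero-total
    (non-forested) plot, for which abundance is undefined.
    """
    b = np.asarray(biomass, dtype=float)
    if b.shape != (3,):
        raise ValueError(f"biomass must be a triple, got shape {b.shape}")
    if np.any(b < 0):
        raise ValueError(f"biomass components must be nonnegative: {b}")
    total = b.sum()
    if total == 0:
        raise ValueError("plot has zero total biomass (non-forested); abundance undefined")
    return b / total


@dataclass(frozen=True)
class PlotSurvey:
    """One plot measured at one survey year.

    Carries biomass per group and/or the abundance triple.  When both are
    present they must agree within 1e-6 (biomass is authoritative, since
    real-world abundance is derived from it); synthetic data is
    abundance-native and carries no biomass.
    """

    plot_id: str
    year: int
    biomass: tuple[float, float, float] | None = None
    abundance: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.biomass is None and self.abundance is None:
            raise ValueError(f"plot {self.plot_id}@{self.year}: need biomass or abundance")
        if self.biomass is not None and sum(self.biomass) > 0 and self.abundance is not None:
            derived = compute_plot_abundance(self.biomass)
            if np.max(np.abs(derived - np.asarray(self.abundance))) > 1e-6:
                raise ValueError(
                    f"plot {self.plot_id}@{self.year}: stored abundance "
                    f"{self.abundance} disagrees with biomass-derived {tuple(derived)}"
                )

    @property
    def forested(self) -> bool:
        if self.biomass is not None:
            return sum(self.biomass) > 0
        return True

    def abundance_triple(self) -> np.ndarray:
        if self.biomass is not None and sum(self.biomass) > 0:
            return compute_plot_abundance(self.biomass)
        if self.abundance is not None:
            return validate_simplex(self.abundance)
        raise ValueError(
            f"plot {self.plot_id}@{self.year}: zero biomass, abundance undefined"
        )


@dataclass(frozen=True)
class PairedObservation:
    """One plot across one reexamination period: former and latter triples."""

    plot_id: str
    period: tuple[int, int]
    y0: np.ndarray
    y1: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "y0", validate_simplex(self.y0))
        object.__setattr__(self, "y1", validate_simplex(self.y1))


@dataclass
class PairingReport:
    """Bookkeeping from pair_surveys; excluded counts by reason."""

    n_paired: int = 0
    n_missing_latter: int = 0
    n_nonforested_start: int = 0
    n_invalid: int = 0

    @property
    def n_excluded(self) -> int:
        return self.n_missing_latter + self.n_nonforested_start + self.n_invalid


def pair_surveys(
    surveys: Iterable[PlotSurvey],
    period: tuple[int, int],
    interval: int = 5,
) -> tuple[list[PairedObservation], PairingReport]:
    """Pair plots present at both endpoint years of a reexamination period.

    Plots must be forested at the period start; plots missing either
    endpoint, or non-forested at the start, are excluded and counted.
    Duplicate (plot_id, year) rows are an error.
    """
    y_start, y_end = period
    if y_end - y_start != interval:
        raise ValueError(
            f"period {period} does not span the survey interval ({interval} years)"
        )
    by_key: dict[tuple[str, int], PlotSurvey] = {}
    for s in surveys:
        key = (s.plot_id, s.year)
        if key in by_key:
            raise ValueError(f"duplicate survey row for plot {s.plot_id} year {s.year}")
        by_key[key] = s

    former_ids = sorted({pid for pid, yr in by_key if yr == y_start})
    pairs: list[PairedObservation] = []
    report = PairingReport()
    for pid in former_ids:
        former = by_key[(pid, y_start)]
        latter = by_key.get((pid, y_end))
        if not former.forested:
            report.n_nonforested_start += 1
            continue
        if latter is None:
            report.n_missing_latter += 1
            continue
        try:
            pair = PairedObservation(
                plot_id=pid,
                period=(y_start, y_end),
                y0=former.abundance_triple(),
                y1=latter.abundance_triple(),
            )
        except ValueError:
            report.n_invalid += 1
            continue
        pairs.append(pair)
    report.n_paired = len(pairs)
    return pairs, report


@dataclass(frozen=True)
class DominanceTally:
    """Plot counts by dominant group, Table-1 style."""

    counts: dict[str, int]
    total: int
    n_ties: int


def tally_dominant_groups(
    pairs: Sequence[PairedObservation],
    stage: str = "former",
) -> DominanceTally:
    """Count plots by dominant (largest-share) group at one survey stage.

    Exact ties are resolved by the fixed priority pine > fir > broadleaf
    (argmax order) and counted in ``n_ties`` so they can be reported.
    """
    if not pairs:
        raise ValueError("cannot tally an empty set of pairs")
    if stage not in ("former", "latter"):
        raise ValueError(f"stage must be 'former' or 'latter', got {stage!r}")
    counts = dict.fromkeys(GROUPS, 0)
    n_ties = 0
    for p in pairs:
        y = p.y0 if stage == "former" else p.y1
        top = int(np.argmax(y))  # first max wins: pine > fir > broadleaf
        if np.sum(y == y[top]) > 1:
            n_ties += 1
        counts[GROUPS[top]] += 1
    return DominanceTally(counts=counts, total=len(pairs), n_ties=n_ties)


# ---------------------------------------------------------------------------
# Plot-table I/O.  Delimited text, comma or tab auto-detected from the header
# row; columns either biomass per group or abundance proportions per group.

_BIOMASS_COLS = ["pine_biomass", "fir_biomass", "broadleaf_biomass"]
_ABUNDANCE_COLS = list(GROUPS)


def read_plot_table(path_or_buffer) -> list[PlotSurvey]:
    """Read surveys from a delimited plot table (UTF-8, header required)."""
    if isinstance(path_or_buffer, (str,)) :
        with open(path_or_buffer, encoding="utf-8") as fh:
            header = fh.readline()
    else:
        header = path_or_buffer.readline()
        path_or_buffer.seek(0)
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path_or_buffer, sep=sep)
    required = {"plot_id", "year"}
    if not required.issubset(df.columns):
        raise ValueError(f"plot table must have columns {sorted(required)}; got {list(df.columns)}")
    has_biomass = set(_BIOMASS_COLS).issubset(df.columns)
    has_abund = set(_ABUNDANCE_COLS).issubset(df.columns)
    if not (has_biomass or has_abund):
        raise ValueError(
            f"plot table needs either biomass columns {_BIOMASS_COLS} "
            f"or abundance columns {_ABUNDANCE_COLS}"
        )
    surveys = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        surveys.append(PlotSurvey(
            plot_id=str(d["plot_id"]),
            year=int(d["year"]),
            biomass=tuple(float(d[c]) for c in _BIOMASS_COLS) if has_biomass else None,
            abundance=tuple(float(d[c]) for c in _ABUNDANCE_COLS) if has_abund else None,
        ))
    return surveys


def write_plot_table(surveys: Sequence[PlotSurvey], path, sep: str = ",") -> None:
    """Write surveys in the same delimited format read_plot_table reads."""
    rows = []
    any_biomass = any(s.biomass is not None for s in surveys)
    for s in surveys:
        row: dict[str, object] = {"plot_id": s.plot_id, "year": s.year}
        if any_biomass:
            b = s.biomass if s.biomass is not None else (np.nan,) * 3
            row.update(zip(_BIOMASS_COLS, b))
        else:
            row.update(zip(_ABUNDANCE_COLS, s.abundance_triple()))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
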