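"""Domain types, validation and CSV I/O for assemblage null-model analysis.

The central object is the :class:`IncidenceMatrix`, a binary species x site
(here: stratigraphic formation) presence/absence table.  Alongside it live
per-species fossil-record counts (:class:`AbundanceVector`) used by richness
estimation, and per-species body lengths (:class:`BodySizeTable`) used by the
size-overlap analysis.  A packaged fixture — the occurrence matrix of 23
South American titanosaur species across 14 Late Cretaceous formations,
together with the two published body-length extremes — is exposed through
:func:`titanosaur_fixtures`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "IncidenceParseError",
    "IncidenceMatrix",
    "AbundanceVector",
    "BodySizeTable",
    "MarginProfile",
    "read_incidence_csv",
    "write_incidence_csv",
    "read_abundance_csv",
    "read_body_size_csv",
    "margins",
    "titanosaur_fixtures",
]


class ValidationError(ValueError):
    """A domain object violates one of its invariants."""


class IncidenceParseError(ValueError):
    """A presence/absence file contains a cell that is not 0 or 1."""


def _check_unique(labels: Sequence[str], what: str) -> list[str]:
    labels = [str(x) for x in labels]
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValidationError(f"duplicate {what} label: {lab!r}")
        seen.add(lab)
    return labels


@dataclass(frozen=True)
class MarginProfile:
    """Row totals (occurrences per species) and column totals (richness per site)."""

    row_totals: np.ndarray
    column_totals: np.ndarray

    def __post_init__(self) -> None:
        rt = np.asarray(self.row_totals, dtype=int)
        ct = np.asarray(self.column_totals, dtype=int)
        object.__setattr__(self, "row_totals", rt)
        object.__setattr__(self, "column_totals", ct)
        if rt.sum() != ct.sum():
            raise ValidationError(
                f"margin sums disagree: rows {rt.sum()} vs columns {ct.sum()}"
            )

    @property
    def fill(self) -> int:
        """Total number of 1-cells."""
        return int(self.row_totals.sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MarginProfile):
            return NotImplemented
        return np.array_equal(self.row_totals, other.row_totals) and np.array_equal(
            self.column_totals, other.column_totals
        )


class IncidenceMatrix:
    """Binary species x site occurrence table with named rows and columns.

    Parameters
    ----------
    species_names, site_names
        Unique row/column labels, order preserved.
    cells
        2-D array-like of 0/1 indicators, shape ``(len(species_names),
        len(site_names))``.
    """

    def __init__(
        self,
        species_names: Sequence[str],
        site_names: Sequence[str],
        cells: Iterable,
    ) -> None:
        self.species_names = _check_unique(species_names, "species")
        self.site_names = _check_unique(site_names, "site")
        cells = np.asarray(cells)
        if cells.ndim != 2 or cells.shape != (len(self.species_names), len(self.site_names)):
            raise ValidationError(
                f"cell block shape {cells.shape} does not match "
                f"{len(self.species_names)} species x {len(self.site_names)} sites"
            )
        if not np.isin(cells, (0, 1)).all():
            bad = np.argwhere(~np.isin(cells, (0, 1)))[0]
            raise ValidationError(
                f"non-binary cell at species {self.species_names[bad[0]]!r}, "
                f"site {self.site_names[bad[1]]!r}"
            )
        self.cells = cells.astype(np.int8)
        if (self.cells.sum(axis=1) == 0).any() or (self.cells.sum(axis=0) == 0).any():
            warnings.warn(
                "incidence matrix contains all-zero rows and/or columns; "
                "co-occurrence analyses drop them by default",
                stacklevel=2,
            )

    # -- basic protocol ---------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species_names)

    @property
    def n_sites(self) -> int:
        return len(self.site_names)

    @property
    def shape(self) -> tuple[int, int]:
        return self.cells.shape

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IncidenceMatrix):
            return NotImplemented
        return (
            self.species_names == other.species_names
            and self.site_names == other.site_names
            and np.array_equal(self.cells, other.cells)
        )

    def __repr__(self) -> str:
        return (
            f"IncidenceMatrix({self.n_species} species x {self.n_sites} sites, "
            f"{int(self.cells.sum())} occurrences)"
        )

    def copy(self) -> "IncidenceMatrix":
        out = IncidenceMatrix.__new__(IncidenceMatrix)
        out.species_names = list(self.species_names)
        out.site_names = list(self.site_names)
        out.cells = self.cells.copy()
        return out

    # -- conversions -------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.cells.astype(int),
            index=pd.Index(self.species_names, name="species"),
            columns=self.site_names,
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "IncidenceMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    # -- derived views -----------------------------------------------------
    def margins(self) -> MarginProfile:
        return MarginProfile(self.cells.sum(axis=1), self.cells.sum(axis=0))

    def drop_empty(self) -> "IncidenceMatrix":
        """Drop all-zero rows and columns (degenerate for co-occurrence tests)."""
        keep_r = self.cells.sum(axis=1) > 0
        keep_c = self.cells.sum(axis=0) > 0
        if keep_r.all() and keep_c.all():
            return self
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return IncidenceMatrix(
                [s for s, k in zip(self.species_names, keep_r) if k],
                [s for s, k in zip(self.site_names, keep_c) if k],
                self.cells[np.ix_(keep_r, keep_c)],
            )


@dataclass(frozen=True)
class AbundanceVector:
    """Per-species fossil-record counts.

    A species with zero records is by definition absent from the assemblage,
    so every count must be a positive integer.
    """

    species_names: Sequence[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        names = _check_unique(self.species_names, "species")
        counts = np.asarray(self.counts)
        if counts.size == 0:
            raise ValidationError("abundance vector is empty")
        if counts.shape != (len(names),):
            raise ValidationError("species_names and counts have different lengths")
        if not np.issubdtype(counts.dtype, np.integer):
            as_int = counts.astype(int)
            if not np.array_equal(as_int, counts):
                raise ValidationError("abundance counts must be integers")
            counts = as_int
        if (counts < 1).any():
            raise ValidationError("abundance counts must be >= 1 for recorded species")
        object.__setattr__(self, "species_names", names)
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    @property
    def total_records(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class BodySizeTable:
    """Per-species estimated total body length, in meters.

    Missing estimates are stored as NaN and flagged, never invented; the
    size-overlap analysis operates on the known subset (and requires at
    least three species with known lengths).
    """

    species_names: Sequence[str]
    lengths_m: np.ndarray

    def __post_init__(self) -> None:
        names = _check_unique(self.species_names, "species")
        lengths = np.asarray(self.lengths_m, dtype=float)
        if lengths.shape != (len(names),):
            raise ValidationError("species_names and lengths_m have different lengths")
        known = lengths[~np.isnan(lengths)]
        if (known <= 0).any():
            raise ValidationError("body lengths must be strictly positive")
        object.__setattr__(self, "species_names", names)
        object.__setattr__(self, "lengths_m", lengths)

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    @property
    def n_known(self) -> int:
        return int((~np.isnan(self.lengths_m)).sum())

    def known(self) -> "BodySizeTable":
        """Subset of species with a known length (missing entries dropped)."""
        mask = ~np.isnan(self.lengths_m)
        if mask.all():
            return self
        warnings.warn(
            f"{int((~mask).sum())} species without body-size estimates "
            "excluded from size analysis",
            stacklevel=2,
        )
        return BodySizeTable(
            [s for s, k in zip(self.species_names, mask) if k],
            self.lengths_m[mask],
        )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_incidence_csv(path: str | Path) -> IncidenceMatrix:
    """Read a presence/absence matrix: header row of site names, first column species.

    Cells must be exactly ``0`` or ``1`` (surrounding whitespace ignored);
    anything else raises :class:`IncidenceParseError` naming the offending
    row and column — coercion would mask transcription errors.
    """
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    values = np.empty(df.shape, dtype=np.int8)
    for i, (sp, row) in enumerate(df.iterrows()):
        for j, (site, raw) in enumerate(row.items()):
            cell = str(raw).strip()
            if cell == "0":
                values[i, j] = 0
            elif cell == "1":
                values[i, j] = 1
            else:
                raise IncidenceParseError(
                    f"cell for species {sp!r}, site {site!r} is {raw!r}; expected 0 or 1"
                )
    return IncidenceMatrix(list(df.index), list(df.columns), values)


def write_incidence_csv(m: IncidenceMatrix, path: str | Path) -> None:
    m.to_dataframe().to_csv(path)


def read_abundance_csv(path: str | Path) -> AbundanceVector:
    """Read a two-column species,count file."""
    df = pd.read_csv(path)
    return AbundanceVector(list(df.iloc[:, 0]), df.iloc[:, 1].to_numpy())


def read_body_size_csv(path: str | Path) -> BodySizeTable:
    """Read a two-column species,length_m file; empty cells mean unknown."""
    df = pd.read_csv(path)
    return BodySizeTable(list(df.iloc[:, 0]), df.iloc[:, 1].to_numpy(dtype=float))


def margins(m: IncidenceMatrix) -> MarginProfile:
    """Row totals (sites per species) and column totals (species per site)."""
    return m.margins()


# ---------------------------------------------------------------------------
# Packaged titanosaur fixture
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("paleonull").joinpath("data", name)


def titanosaur_fixtures() -> tuple[IncidenceMatrix, BodySizeTable]:
    """The packaged Late Cretaceous titanosaur assemblage data.

    Returns the 23-species x 14-formation occurrence matrix and the
    body-length table.  Only the two published extremes are filled in the
    size table (*Rocasaurus muniozi* 8 m, *Puertasaurus reuili* 30 m); the
    remaining species are flagged as missing.  A cross-fixture consistency
    check verifies that both tables list the same species.
    """
    with resources.as_file(_data_path("titanosaur_occurrences.csv")) as p:
        matrix = read_incidence_csv(p)
    with resources.as_file(_data_path("titanosaur_body_sizes.csv")) as p:
        sizes = read_body_size_csv(p)
    if set(matrix.species_names) != set(sizes.species_names):
        raise ValidationError("occurrence and body-size fixtures list different species")
    return matrix, sizes
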