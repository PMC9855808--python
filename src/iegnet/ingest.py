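"""Reading, validating and deriving region-by-animal activity density tables.

The universal input to the pipeline is a :class:`RegionTable`: a matrix of
non-negative immediate-early-gene (IEG) expression densities with brain
regions as rows and animals as columns.  Densities may be supplied directly,
or derived from raw label counts together with Cavalieri grid-point counts
(:func:`cavalieri_density`), where the area of a region is estimated as the
number of evenly spaced grid points falling inside it times the squared grid
spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UndefinedAreaError, ValidationError

#: Default Cavalieri grid spacing in micrometres.
DEFAULT_GRID_SPACING_UM = 22.0

MIN_ANIMALS = 3
MIN_REGIONS = 2


@dataclass(frozen=True)
class DensityRecord:
    """Raw quantification for one region: an IEG+ object count plus the
    number of Cavalieri grid points that fell inside the region.

    Parameters
    ----------
    count : int
        Number of labelled objects counted in the region. Non-negative.
    grid_points : int
        Number of grid points (spacing ``spacing`` µm) falling in the region.
    spacing : float
        Grid spacing in µm; the implied area is ``grid_points * spacing**2``.
    """

    count: int
    grid_points: int
    spacing: float = DEFAULT_GRID_SPACING_UM

    def __post_init__(self) -> None:
        if self.count < 0 or int(self.count) != self.count:
            raise ValidationError(f"count must be a non-negative integer, got {self.count!r}")
        if self.grid_points < 0 or int(self.grid_points) != self.grid_points:
            raise ValidationError(
                f"grid_points must be a non-negative integer, got {self.grid_points!r}"
            )
        if not self.spacing > 0:
            raise ValidationError(f"spacing must be > 0 µm, got {self.spacing!r}")


def cavalieri_density(rec: DensityRecord) -> float:
    """Labels per µm² from a count and a Cavalieri area estimate.

    The region area is estimated by point counting as
    ``grid_points * spacing**2`` and the density is ``count / area``.

    Raises
    ------
    UndefinedAreaError
        If ``grid_points`` is 0: the region was absent from the sampled
        sections, so its density is undefined (never silently 0 or inf).
    """
    if rec.grid_points == 0:
        raise UndefinedAreaError(
            "region has 0 grid points: area is undefined (region absent from sampled sections)"
        )
    area_um2 = rec.grid_points * rec.spacing**2
    return rec.count / area_um2


@dataclass
class RegionTable:
    """Region × animal matrix of non-negative activity densities.

    Attributes
    ----------
    regions : list of str
        Ordered, unique region labels (e.g. Allen-atlas-style abbreviations
        such as BLA, BMA, PALv).
    animals : list of str
        Ordered, unique animal identifiers.
    values : ndarray, shape (n_regions, n_animals)
        Densities in labels/µm²; finite and >= 0, no missing entries.
    """

    regions: list[str]
    animals: list[str]
    values: np.ndarray = field(repr=False)
    #: Permit negative values (latent-scale synthetic tables only).
    allow_negative: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.regions = [str(r) for r in self.regions]
        self.animals = [str(a) for a in self.animals]
        self.values = np.asarray(self.values, dtype=float)
        _validate_table(self.regions, self.animals, self.values,
                        allow_negative=self.allow_negative)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "RegionTable":
        """Build from a DataFrame with regions as the index and animals as
        columns (the orientation written by :meth:`to_csv`)."""
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float, na_value=np.nan))

    @classmethod
    def from_csv(cls, path) -> "RegionTable":
        """Read a density CSV: first column ``region``, one column per animal."""
        # round_trip parsing keeps load->write->load bit-identical
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
        if df.shape[1] == 0:
            raise ValidationError(f"{path}: no animal columns found")
        for row, col in zip(*np.nonzero(~np.isfinite(df.to_numpy(dtype=float, na_value=np.nan)))):
            raise ValidationError(
                f"{path}: missing or non-numeric value at region {df.index[row]!r}, "
                f"animal {df.columns[col]!r}"
            )
        return cls.from_dataframe(df)

    # -- views and export ---------------------------------------------------

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_animals(self) -> int:
        return len(self.animals)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.regions, name="region"),
                            columns=self.animals)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    def select_animals(self, idx) -> "RegionTable":
        """Column subset by integer positions (used by subsampling)."""
        idx = list(idx)
        return RegionTable(self.regions, [self.animals[i] for i in idx], self.values[:, idx],
                           allow_negative=self.allow_negative)


def _validate_table(regions, animals, values, allow_negative: bool = False) -> None:
    if values.ndim != 2 or values.shape != (len(regions), len(animals)):
        raise ValidationError(
            f"values shape {values.shape} does not match {len(regions)} regions × "
            f"{len(animals)} animals"
        )
    if len(regions) < MIN_REGIONS:
        raise ValidationError(f"need at least {MIN_REGIONS} regions, got {len(regions)}")
    if len(animals) < MIN_ANIMALS:
        raise ValidationError(
            f"need at least {MIN_ANIMALS} animals for cross-animal correlation, got {len(animals)}"
        )
    dup_r = _duplicates(regions)
    if dup_r:
        raise ValidationError(f"duplicate region labels: {sorted(dup_r)}")
    dup_a = _duplicates(animals)
    if dup_a:
        raise ValidationError(f"duplicate animal IDs: {sorted(dup_a)}")
    bad = ~np.isfinite(values)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"missing/non-finite value at region {regions[i]!r}, animal {animals[j]!r}"
        )
    neg = values < 0 if not allow_negative else np.zeros_like(values, dtype=bool)
    if neg.any():
        i, j = np.argwhere(neg)[0]
        raise ValidationError(
            f"negative density {values[i, j]!r} at region {regions[i]!r}, animal {animals[j]!r}"
        )


def _duplicates(labels) -> set:
    seen: set = set()
    dups: set = set()
    for x in labels:
        (dups if x in seen else seen).add(x)
    return dups


def load_region_table(path) -> RegionTable:
    """Load and validate a region × animal density CSV.

    The expected dialect: UTF-8, decimal point, no thousands separators;
    first column holds region labels, the header row holds animal IDs.
    Row and column order are preserved exactly as on disk.
    """
    return RegionTable.from_csv(path)


def restrict_regions(table: RegionTable, keep: list[str]) -> RegionTable:
    """Restrict a table to the node set ``keep``, in ``keep``'s order.

    Raises
    ------
    ValidationError
        Listing every label in ``keep`` that is absent from the table.
    """
    pos = {r: i for i, r in enumerate(table.regions)}
    missing = [r for r in keep if r not in pos]
    if missing:
        raise ValidationError(f"unknown region labels: {missing}")
    idx = [pos[r] for r in keep]
    return RegionTable([table.regions[i] for i in idx], list(table.animals),
                       table.values[idx, :], allow_negative=table.allow_negative)


def densities_from_counts(counts: RegionTable, grid_points: RegionTable,
                          spacing: float = DEFAULT_GRID_SPACING_UM) -> RegionTable:
    """Element-wise Cavalieri density from paired count and grid-point tables.

    Both tables must have identical regions and animals.  Cells with zero
    grid points raise :class:`UndefinedAreaError` naming the cell.
    """
    if counts.regions != grid_points.regions or counts.animals != grid_points.animals:
        raise ValidationError("counts and grid-point tables must share regions and animals")
    if not spacing > 0:
        raise ValidationError(f"spacing must be > 0 µm, got {spacing!r}")
    gp = grid_points.values
    zero = gp == 0
    if zero.any():
        i, j = np.argwhere(zero)[0]
        raise UndefinedAreaError(
            f"0 grid points at region {counts.regions[i]!r}, animal {counts.animals[j]!r}: "
            "area undefined"
        )
    dens = counts.values / (gp * spacing**2)
    return RegionTable(list(counts.regions), list(counts.animals), dens)
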