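"""Reading, validating, scaling and writing genus abundance tables and study designs.

The canonical on-disk format is a tab-delimited UTF-8 table whose first
cell is literally ``taxon``: rows are genera, columns are samples. The
sample-design table is a TSV with columns ``sample``, ``site``,
``host_role``, ``group``, ``replicate``. Internally every abundance
table carries a unit tag (``counts``, ``fraction`` or ``percent``);
``percent`` is the canonical analysis unit, matching how relative
abundances are quoted in the amplicon literature (e.g. 0.1147%).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import (
    DegenerateSampleError,
    DesignError,
    DuplicateIdentifierError,
    ValidationError,
)

logger = logging.getLogger(__name__)

UNITS = ("counts", "fraction", "percent")

HOST_ROLES = ("target", "companion")

#: Relative tolerance on per-sample column sums for closed units.
_SUM_RTOL = {"percent": 1e-6, "fraction": 1e-9}
_SUM_TARGET = {"percent": 100.0, "fraction": 1.0}


@dataclass(frozen=True)
class AbundanceTable:
    """A taxa x samples matrix of non-negative abundances with a unit tag.

    Parameters
    ----------
    data
        DataFrame indexed by genus, columns are sample identifiers.
    unit
        One of ``counts``, ``fraction``, ``percent``. Closed units
        (``fraction``, ``percent``) are validated to sum to 1 / 100 per
        sample within a tight relative tolerance.
    """

    data: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValidationError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise DuplicateIdentifierError(f"duplicate taxa: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise DuplicateIdentifierError(f"duplicate samples: {dups}")
        values = df.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite abundance at taxon {df.index[r]!r}, sample {df.columns[c]!r}"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative abundance at taxon {df.index[r]!r}, sample {df.columns[c]!r}"
            )
        if self.unit in _SUM_TARGET and df.shape[0] > 0:
            target = _SUM_TARGET[self.unit]
            sums = values.sum(axis=0)
            bad = ~np.isclose(sums, target, rtol=_SUM_RTOL[self.unit], atol=0)
            if bad.any():
                j = int(np.argmax(bad))
                raise ValidationError(
                    f"sample {df.columns[j]!r} sums to {sums[j]!r}, expected {target} "
                    f"for unit {self.unit!r}"
                )

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def subset_samples(self, samples: Iterable[str]) -> "AbundanceTable":
        samples = list(samples)
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise ValidationError(f"samples not in table: {missing}")
        return AbundanceTable(self.data.loc[:, samples], self.unit)


def _read_rectangular_tsv(path: str | Path) -> list[list[str]]:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [row for row in csv.reader(fh, delimiter="\t") if row]
    if not rows:
        raise ValidationError(f"empty table: {path}")
    width = len(rows[0])
    for i, row in enumerate(rows):
        if len(row) != width:
            raise ValidationError(
                f"{path}: ragged row {i + 1} has {len(row)} fields, expected {width}"
            )
    return rows


def read_abundance_table(path: str | Path, unit: str) -> AbundanceTable:
    """Read a taxa x samples TSV into a validated :class:`AbundanceTable`.

    The header row holds sample names (first cell is the taxon-column
    label and is ignored); the first column holds genus names. Duplicate
    genus rows are an error, never silently merged.
    """
    rows = _read_rectangular_tsv(path)
    header, body = rows[0], rows[1:]
    if len(header) < 2 or not body:
        raise ValidationError(f"{path}: need at least one sample column and one taxon row")
    samples = header[1:]
    taxa = [row[0] for row in body]
    values = np.empty((len(body), len(samples)), dtype=float)
    for i, row in enumerate(body):
        for j, cell in enumerate(row[1:]):
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValidationError(
                    f"{path}: non-numeric cell {cell!r} at taxon {taxa[i]!r}, "
                    f"sample {samples[j]!r}"
                ) from None
    df = pd.DataFrame(values, index=pd.Index(taxa, name="taxon"), columns=samples)
    return AbundanceTable(df, unit)


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    """Write the canonical TSV dialect (first cell ``taxon``, repr floats).

    Uses ``repr``-faithful float formatting so read -> write -> read
    round-trips bit-identically.
    """
    df = table.data.copy()
    df.index.name = "taxon"
    df.to_csv(path, sep="\t", lineterminator="\n")


def total_sum_scale(table: AbundanceTable) -> AbundanceTable:
    """Rescale every sample column to sum to 100 (relative abundance in %).

    Idempotent on tables already in percent. An all-zero sample column is
    a :class:`DegenerateSampleError` because it admits no composition.
    """
    values = table.data.to_numpy(dtype=float)
    sums = values.sum(axis=0)
    zero = sums == 0
    if zero.any():
        j = int(np.argmax(zero))
        raise DegenerateSampleError(
            f"sample {table.data.columns[j]!r} is all-zero and cannot be scaled"
        )
    scaled = values / sums * 100.0
    return AbundanceTable(
        pd.DataFrame(scaled, index=table.data.index, columns=table.data.columns),
        "percent",
    )


@dataclass(frozen=True)
class StudyDesign:
    """Per-sample metadata: site, host role (target | companion), group, replicate."""

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = ["sample", "site", "host_role", "group", "replicate"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise DesignError(f"design missing columns: {missing}")
        if len(self.frame) == 0:
            raise DesignError("design table is empty")
        if self.frame["sample"].duplicated().any():
            dups = self.frame.loc[self.frame["sample"].duplicated(), "sample"].tolist()
            raise DesignError(f"duplicate sample ids in design: {dups}")
        bad = set(self.frame["host_role"]) - set(HOST_ROLES)
        if bad:
            raise DesignError(f"unknown host_role values: {sorted(bad)}; expected {HOST_ROLES}")
        reps = pd.to_numeric(self.frame["replicate"], errors="coerce")
        if reps.isna().any() or (reps < 1).any():
            raise DesignError("replicate indices must be positive integers")
        for group, n in self.frame.groupby("group").size().items():
            if n < 3:
                logger.warning("group %r has only %d sample(s); tests need >= 2, prefer >= 3", group, n)

    @property
    def samples(self) -> list[str]:
        return self.frame["sample"].tolist()

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.frame["group"]))

    @property
    def sites(self) -> list[str]:
        return list(dict.fromkeys(self.frame["site"]))

    def samples_in_group(self, group: str) -> list[str]:
        sub = self.frame.loc[self.frame["group"] == group, "sample"]
        if sub.empty:
            raise DesignError(f"group {group!r} not present in design (or has no samples)")
        return sub.tolist()

    def groups_at_site(self, site: str, host_role: str) -> list[str]:
        mask = (self.frame["site"] == site) & (self.frame["host_role"] == host_role)
        return list(dict.fromkeys(self.frame.loc[mask, "group"]))

    def group_of_sample(self) -> dict[str, str]:
        return dict(zip(self.frame["sample"], self.frame["group"]))

    def check_covers(self, table: AbundanceTable) -> None:
        """Every table sample must appear exactly once in the design."""
        missing = set(table.samples) - set(self.samples)
        if missing:
            raise DesignError(f"samples missing from design: {sorted(missing)}")


def read_design(path: str | Path) -> StudyDesign:
    """Read and validate the sample-design TSV."""
    rows = _read_rectangular_tsv(path)
    header, body = rows[0], rows[1:]
    if not body:
        raise DesignError(f"{path}: design table has no rows")
    frame = pd.DataFrame(body, columns=header)
    return StudyDesign(frame)


def write_design(design: StudyDesign, path: str | Path) -> None:
    design.frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
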