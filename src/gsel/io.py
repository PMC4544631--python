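"""Domain types and tabular readers/writers for genotypes, maps and phenotypes.

Genotypes are dominant presence/absence calls (0/1) on fully inbred lines
(doubled haploids or advanced-generation RILs), so no heterozygote code
exists.  Missing calls are carried as NaN internally.  All on-disk formats
are delimited text:

* genotype: header row of marker ids, first column line ids, cells 0/1/NA;
* map: columns ``marker``, ``chromosome``, ``position_cM``;
* phenotype: columns ``line``, ``location``, ``sub_block``, ``is_control``,
  ``trait``, ``value``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = np.nan


@dataclass
class MarkerMatrix:
    """Lines x markers genotype matrix with 0/1 (dominant) coding.

    Parameters
    ----------
    line_ids : list of str
        Unique line identifiers (rows).
    marker_ids : list of str
        Unique marker identifiers (columns).
    genotypes : ndarray of float, shape (n_lines, n_markers)
        Values in {0, 1, NaN}; NaN marks a missing call.
    population_id : str
        Label of the breeding population the lines belong to.
    """

    line_ids: list
    marker_ids: list
    genotypes: np.ndarray
    population_id: str = ""
    imputed: bool = False

    def __post_init__(self):
        self.line_ids = list(self.line_ids)
        self.marker_ids = list(self.marker_ids)
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("duplicate line ids")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("duplicate marker ids")
        if self.genotypes.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError(
                f"genotype shape {self.genotypes.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        if self.imputed:
            # mean imputation produces fractional calls inside [0, 1]
            ok = (self.genotypes >= 0) & (self.genotypes <= 1)
        else:
            ok = np.isnan(self.genotypes) | (self.genotypes == 0) | (self.genotypes == 1)
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise ValueError(
                f"genotype value {self.genotypes[i, j]!r} at line "
                f"{self.line_ids[i]!r}, marker {self.marker_ids[j]!r} is not 0/1/missing"
            )

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def has_missing(self) -> bool:
        return bool(np.isnan(self.genotypes).any())

    def subset_markers(self, marker_ids) -> "MarkerMatrix":
        """Restrict to the given markers, in the given order."""
        idx = {m: i for i, m in enumerate(self.marker_ids)}
        cols = [idx[m] for m in marker_ids]
        return replace(
            self, marker_ids=list(marker_ids), genotypes=self.genotypes[:, cols]
        )

    def subset_lines(self, line_ids) -> "MarkerMatrix":
        idx = {l: i for i, l in enumerate(self.line_ids)}
        rows = [idx[l] for l in line_ids]
        return replace(self, line_ids=list(line_ids), genotypes=self.genotypes[rows])

    def polymorphic_mask(self) -> np.ndarray:
        """Boolean mask of markers segregating (both alleles seen) among the lines."""
        with np.errstate(invalid="ignore"):
            mn = np.nanmin(self.genotypes, axis=0)
            mx = np.nanmax(self.genotypes, axis=0)
        return mn != mx


@dataclass
class GeneticMap:
    """Marker positions in centimorgans, chromosome-local from the start.

    ``entries`` maps marker id -> (chromosome, position_cM).
    """

    entries: dict

    def __post_init__(self):
        for m, (_, pos) in self.entries.items():
            if pos < 0:
                raise ValueError(f"negative map position for marker {m!r}")

    @property
    def marker_ids(self) -> list:
        return list(self.entries)

    def chromosomes(self) -> list:
        seen = {}
        for chrom, _ in self.entries.values():
            seen[chrom] = None
        return list(seen)

    def chromosome_of(self, marker) -> str:
        return self.entries[marker][0]

    def position_of(self, marker) -> float:
        return self.entries[marker][1]

    def ordered_markers(self, chromosome) -> list:
        """Markers on a chromosome sorted by position (ties keep input order)."""
        on = [(pos, m) for m, (c, pos) in self.entries.items() if c == chromosome]
        on.sort(key=lambda t: t[0])
        return [m for _, m in on]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(m, c, p) for m, (c, p) in self.entries.items()],
            columns=["marker", "chromosome", "position_cM"],
        )


@dataclass
class PhenotypeTable:
    """Long-format field records: one row per plot observation.

    Columns: line, location, sub_block, is_control, trait, value.  Trait
    values are in trait units (e.g. grain yield t/ha, test weight kg/hL,
    heading date days).
    """

    records: pd.DataFrame

    COLUMNS = ["line", "location", "sub_block", "is_control", "trait", "value"]

    def __post_init__(self):
        df = pd.DataFrame(self.records)
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns {missing}")
        df = df[self.COLUMNS].copy()
        df["is_control"] = df["is_control"].astype(bool)
        df["value"] = df["value"].astype(float)
        dup = df.duplicated(["line", "location", "trait", "sub_block"])
        if dup.any():
            r = df[dup].iloc[0]
            raise ValueError(
                f"duplicate record for line {r['line']!r} at {r['location']!r}, "
                f"trait {r['trait']!r}, sub-block {r['sub_block']!r}"
            )
        self.records = df

    def subset(self, location=None, trait=None) -> pd.DataFrame:
        df = self.records
        if location is not None:
            df = df[df["location"] == location]
        if trait is not None:
            df = df[df["trait"] == trait]
        return df


def _sniff_sep(path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_genotype_matrix(path, missing_token: str = "NA", population_id: str = "") -> MarkerMatrix:
    """Read a delimited genotype table (rows = lines, columns = markers).

    The first row holds marker ids and the first column line ids.  Cells must
    be 0, 1 or ``missing_token``; anything else is an error naming the cell.
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    values = df.to_numpy()
    out = np.empty(values.shape, dtype=float)
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            v = values[i, j].strip()
            if v == missing_token:
                out[i, j] = MISSING
            elif v in ("0", "1"):
                out[i, j] = float(v)
            else:
                raise ValueError(
                    f"invalid genotype {v!r} at line {df.index[i]!r}, "
                    f"marker {df.columns[j]!r} (expected 0, 1 or {missing_token!r})"
                )
    return MarkerMatrix(
        line_ids=list(df.index),
        marker_ids=list(df.columns),
        genotypes=out,
        population_id=population_id,
    )


def write_genotype_matrix(m: MarkerMatrix, path, missing_token: str = "NA", sep: str = "\t"):
    df = pd.DataFrame(m.genotypes, index=m.line_ids, columns=m.marker_ids)
    df = df.map(lambda v: missing_token if np.isnan(v) else str(int(v)))
    df.to_csv(path, sep=sep, index_label="line")


def read_genetic_map(path) -> GeneticMap:
    df = pd.read_csv(path, sep=_sniff_sep(path))
    need = {"marker", "chromosome", "position_cM"}
    if not need.issubset(df.columns):
        raise ValueError(f"map file must have columns {sorted(need)}")
    if df["marker"].duplicated().any():
        raise ValueError("duplicate marker ids in map")
    entries = {
        r.marker: (str(r.chromosome), float(r.position_cM)) for r in df.itertuples()
    }
    return GeneticMap(entries)


def write_genetic_map(gmap: GeneticMap, path, sep: str = "\t"):
    gmap.to_frame().to_csv(path, sep=sep, index=False)


def read_phenotype_table(path) -> PhenotypeTable:
    df = pd.read_csv(path, sep=_sniff_sep(path))
    return PhenotypeTable(df)


def write_phenotype_table(t: PhenotypeTable, path, sep: str = "\t"):
    t.records.to_csv(path, sep=sep, index=False)


def impute_missing(m: MarkerMatrix) -> MarkerMatrix:
    """Replace each missing call by its marker's mean over non-missing lines.

    Markers with no observed call at all cannot be imputed; they are dropped
    (and logged).  Non-missing entries are never altered, so per-marker means
    are unchanged.
    """
    G = m.genotypes
    if not np.isnan(G).any():
        return m
    obs = ~np.isnan(G)
    n_obs = obs.sum(axis=0)
    keep = n_obs > 0
    if not keep.all():
        dropped = [mid for mid, k in zip(m.marker_ids, keep) if not k]
        logger.warning("dropping %d all-missing markers: %s", len(dropped), dropped[:10])
    G = G[:, keep]
    obs = obs[:, keep]
    with np.errstate(invalid="ignore"):
        col_mean = np.nansum(G, axis=0) / obs.sum(axis=0)
    out = np.where(np.isnan(G), col_mean[None, :], G)
    return MarkerMatrix(
        line_ids=list(m.line_ids),
        marker_ids=[mid for mid, k in zip(m.marker_ids, keep) if k],
        genotypes=out,
        population_id=m.population_id,
        imputed=True,
    )


def intersect_markers(matrices) -> list:
    """Restrict each matrix to the markers shared by all, in one common order.

    The common order is the marker order of the first matrix.  Raises if the
    intersection is empty or fewer than two matrices are given.
    """
    matrices = list(matrices)
    if len(matrices) < 2:
        raise ValueError("need at least two matrices to intersect")
    common = set(matrices[0].marker_ids)
    for m in matrices[1:]:
        common &= set(m.marker_ids)
    if not common:
        raise ValueError("marker intersection is empty")
    order = [mid for mid in matrices[0].marker_ids if mid in common]
    return [m.subset_markers(order) for m in matrices]
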