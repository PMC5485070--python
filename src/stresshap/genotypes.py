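"""Genotype and geography containers and I/O.

Genotypes are haploid-coded 0/1 allele dosages for fully inbred accessions
(each accession is effectively a homozygous line, so a single bit per marker
suffices).  Heterozygous or missing calls are rejected rather than imputed:
the intended input is a post-QC, imputed SNP matrix.

Two on-disk dialects are supported:

* a genotype TSV (header row = marker ids, first column = accession id)
  with a sidecar marker map TSV (``marker_id``, ``chromosome``,
  ``position_bp_1based``);
* PLINK ``.bed/.bim/.fam`` triples (SNP-major), with homozygous codes
  mapped to {0, 1} and heterozygous/missing codes rejected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "GeoRecord",
    "read_genotypes",
    "write_genotypes",
    "write_plink",
    "read_geo_table",
    "write_geo_table",
    "geographic_subset",
    "minor_allele_frequency",
]


class GenotypeValidationError(ValueError):
    """Raised when an input violates the 0/1 inbred-line genotype contract."""


@dataclass(frozen=True)
class GeoRecord:
    """Collection-site coordinates of one accession."""

    accession_id: str
    latitude: float
    longitude: float
    elevation: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")


@dataclass
class GenotypeMatrix:
    """0/1 call matrix (accessions x markers) with a marker map.

    Parameters
    ----------
    accession_ids
        Unique accession identifiers, one per row of ``calls``.
    markers
        DataFrame with columns ``marker_id``, ``chromosome``, ``position``
        (1-based bp).  Rows correspond to columns of ``calls``.
    calls
        Integer matrix with entries in {0, 1}.
    """

    accession_ids: list[str]
    markers: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.accession_ids = [str(a) for a in self.accession_ids]
        self.calls = np.asarray(self.calls)
        if self.calls.ndim != 2:
            raise GenotypeValidationError("calls must be a 2-D matrix")
        n, m = self.calls.shape
        if len(self.accession_ids) != n:
            raise GenotypeValidationError(
                f"{len(self.accession_ids)} accession ids for {n} call rows"
            )
        if len(set(self.accession_ids)) != n:
            raise GenotypeValidationError("duplicate accession ids")
        required = {"marker_id", "chromosome", "position"}
        if not required.issubset(self.markers.columns):
            raise GenotypeValidationError(
                f"marker table must have columns {sorted(required)}"
            )
        if len(self.markers) != m:
            raise GenotypeValidationError(
                f"{len(self.markers)} marker records for {m} call columns"
            )
        bad = ~np.isin(self.calls, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeValidationError(
                f"call {self.calls[i, j]!r} at accession {self.accession_ids[i]!r}, "
                f"marker {self.markers['marker_id'].iloc[j]!r} is not in {{0, 1}}"
            )
        self.calls = self.calls.astype(np.int8)
        self.markers = self.markers.reset_index(drop=True)
        self.markers["marker_id"] = self.markers["marker_id"].astype(str)
        self.markers["chromosome"] = self.markers["chromosome"].astype(str)
        self.markers["position"] = self.markers["position"].astype(np.int64)
        self._sort_markers()

    def _sort_markers(self) -> None:
        order = self.markers.sort_values(
            ["chromosome", "position"], kind="mergesort"
        ).index.to_numpy()
        if not np.array_equal(order, np.arange(len(order))):
            self.markers = self.markers.iloc[order].reset_index(drop=True)
            self.calls = self.calls[:, order]
        for _, grp in self.markers.groupby("chromosome", sort=False):
            pos = grp["position"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise GenotypeValidationError(
                    f"positions not strictly increasing on chromosome "
                    f"{grp['chromosome'].iloc[0]!r}"
                )

    @property
    def n_accessions(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def subset_accessions(self, ids: Sequence[str]) -> "GenotypeMatrix":
        index = {a: i for i, a in enumerate(self.accession_ids)}
        missing = [a for a in ids if a not in index]
        if missing:
            raise KeyError(f"unknown accession ids: {missing[:5]}")
        rows = [index[a] for a in ids]
        return GenotypeMatrix(
            accession_ids=list(ids),
            markers=self.markers.copy(),
            calls=self.calls[rows, :].copy(),
        )

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            accession_ids=list(self.accession_ids),
            markers=self.markers.iloc[keep].reset_index(drop=True),
            calls=self.calls[:, keep].copy(),
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".markers.tsv")


def read_genotypes(
    path: str | Path,
    format: str = "tsv",
    markers_path: str | Path | None = None,
) -> GenotypeMatrix:
    """Read a genotype matrix from ``tsv`` or ``plink`` files.

    For ``tsv``, ``path`` is the call matrix and the marker map is read from
    ``markers_path`` (default: ``<path>.markers.tsv``).  For ``plink``,
    ``path`` is the file prefix of a ``.bed/.bim/.fam`` triple.
    """
    path = Path(path)
    if format == "tsv":
        return _read_tsv(path, Path(markers_path) if markers_path else _sidecar_path(path))
    if format == "plink":
        return _read_plink(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_tsv(path: Path, markers_path: Path) -> GenotypeMatrix:
    if not path.exists():
        raise FileNotFoundError(path)
    if not markers_path.exists():
        raise FileNotFoundError(f"marker sidecar not found: {markers_path}")
    try:
        calls_df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise GenotypeValidationError(f"cannot parse {path}: {exc}") from exc
    values = np.empty(calls_df.shape, dtype=np.int8)
    for j, col in enumerate(calls_df.columns):
        raw = calls_df[col].to_numpy()
        for i, v in enumerate(raw):
            if v == "0":
                values[i, j] = 0
            elif v == "1":
                values[i, j] = 1
            else:
                raise GenotypeValidationError(
                    f"{path} line {i + 2}: call {v!r} for marker {col!r} is not 0/1 "
                    "(heterozygous/missing calls are not supported)"
                )
    markers = pd.read_csv(markers_path, sep="\t", dtype={"marker_id": str})
    markers = markers.rename(columns={"position_bp_1based": "position"})
    markers = markers[["marker_id", "chromosome", "position"]]
    order = {m: k for k, m in enumerate(markers["marker_id"])}
    missing = [c for c in calls_df.columns if c not in order]
    if missing:
        raise GenotypeValidationError(
            f"markers {missing[:5]} present in {path} but absent from {markers_path}"
        )
    markers = markers.set_index("marker_id").loc[list(calls_df.columns)].reset_index()
    return GenotypeMatrix(
        accession_ids=list(calls_df.index.astype(str)),
        markers=markers,
        calls=values,
    )


def write_genotypes(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write the TSV dialect (matrix plus marker sidecar)."""
    path = Path(path)
    df = pd.DataFrame(
        geno.calls,
        index=pd.Index(geno.accession_ids, name="accession_id"),
        columns=geno.markers["marker_id"],
    )
    df.to_csv(path, sep="\t")
    side = geno.markers.rename(columns={"position": "position_bp_1based"})
    side.to_csv(_sidecar_path(path), sep="\t", index=False)


# -- PLINK .bed/.bim/.fam ----------------------------------------------------
# Minimal SNP-major .bed codec.  Two-bit codes per individual:
#   0b00 hom A1 -> 1, 0b11 hom A2 -> 0, 0b10 het -> rejected,
#   0b01 missing -> rejected.

_BED_MAGIC = bytes((0x6C, 0x1B, 0x01))


def _read_plink(prefix: Path) -> GenotypeMatrix:
    bed, bim, fam = (prefix.with_suffix(s) for s in (".bed", ".bim", ".fam"))
    for f in (bed, bim, fam):
        if not f.exists():
            raise FileNotFoundError(f)
    fam_df = pd.read_csv(fam, sep=r"\s+", header=None, dtype=str)
    accession_ids = list(fam_df[1])
    bim_df = pd.read_csv(bim, sep=r"\s+", header=None, dtype=str)
    markers = pd.DataFrame(
        {
            "marker_id": bim_df[1],
            "chromosome": bim_df[0],
            "position": bim_df[3].astype(int),
        }
    )
    n, m = len(accession_ids), len(markers)
    raw = bed.read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise GenotypeValidationError(f"{bed} lacks the SNP-major .bed magic bytes")
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    stride = (n + 3) // 4
    if len(body) != stride * m:
        raise GenotypeValidationError(
            f"{bed}: expected {stride * m} data bytes for {n} x {m}, got {len(body)}"
        )
    body = body.reshape(m, stride)
    # unpack 2-bit codes, individual-fastest within byte
    codes = np.empty((m, stride * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (body >> (2 * k)) & 0b11
    codes = codes[:, :n]
    if np.any(codes == 0b01):
        snp, ind = np.argwhere(codes == 0b01)[0]
        raise GenotypeValidationError(
            f"missing genotype at accession {accession_ids[ind]!r}, "
            f"marker {markers['marker_id'].iloc[snp]!r}"
        )
    if np.any(codes == 0b10):
        snp, ind = np.argwhere(codes == 0b10)[0]
        raise GenotypeValidationError(
            f"heterozygous genotype at accession {accession_ids[ind]!r}, "
            f"marker {markers['marker_id'].iloc[snp]!r}"
        )
    calls = (codes == 0b00).astype(np.int8).T  # hom A1 -> 1, hom A2 -> 0
    return GenotypeMatrix(accession_ids=accession_ids, markers=markers, calls=calls)


def write_plink(geno: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a SNP-major ``.bed/.bim/.fam`` triple (A1 = the '1' allele)."""
    prefix = Path(prefix)
    fam = pd.DataFrame(
        {
            0: geno.accession_ids,
            1: geno.accession_ids,
            2: 0, 3: 0, 4: 0, 5: -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep=" ", header=False, index=False)
    bim = pd.DataFrame(
        {
            0: geno.markers["chromosome"],
            1: geno.markers["marker_id"],
            2: 0,
            3: geno.markers["position"],
            4: "A",
            5: "T",
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    n, m = geno.calls.shape
    stride = (n + 3) // 4
    codes = np.full((m, stride * 4), 0b11, dtype=np.uint8)  # hom A2 (call 0)
    codes[:, :n] = np.where(geno.calls.T == 1, 0b00, 0b11)
    packed = np.zeros((m, stride), dtype=np.uint8)
    for k in range(4):
        packed |= codes[:, k::4] << (2 * k)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def read_geo_table(path: str | Path) -> list[GeoRecord]:
    """Read a CSV with columns accession_id, latitude, longitude, elevation."""
    df = pd.read_csv(path, dtype={"accession_id": str})
    return [
        GeoRecord(r.accession_id, float(r.latitude), float(r.longitude), float(r.elevation))
        for r in df.itertuples()
    ]


def write_geo_table(geo: Sequence[GeoRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "accession_id": [g.accession_id for g in geo],
            "latitude": [g.latitude for g in geo],
            "longitude": [g.longitude for g in geo],
            "elevation": [g.elevation for g in geo],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Filters and summaries
# ---------------------------------------------------------------------------

def geographic_subset(
    geno: GenotypeMatrix,
    geo: Sequence[GeoRecord],
    lat_min: float = 30.0,
    lon_min: float = -50.0,
    lon_max: float = 50.0,
    elev_max: float = 2000.0,
    strict: bool = False,
) -> GenotypeMatrix:
    """Keep accessions inside the geographic box (all bounds inclusive).

    The default box (latitude >= 30, longitude in [-50, 50], elevation
    <= 2000 m) restricts a world-wide panel to its European accessions.
    Accessions without a geographic record are dropped with a warning, or
    rejected when ``strict`` is set.
    """
    by_id = {g.accession_id: g for g in geo}
    keep: list[str] = []
    missing: list[str] = []
    for acc in geno.accession_ids:
        rec = by_id.get(acc)
        if rec is None:
            missing.append(acc)
            continue
        if (
            rec.latitude >= lat_min
            and lon_min <= rec.longitude <= lon_max
            and rec.elevation <= elev_max
        ):
            keep.append(acc)
    if missing:
        if strict:
            raise KeyError(
                f"{len(missing)} accessions lack geographic records "
                f"(first: {missing[:5]})"
            )
        warnings.warn(
            f"dropping {len(missing)} accessions without geographic records",
            stacklevel=2,
        )
        logger.warning("geographic_subset: %d accessions without GeoRecord", len(missing))
    return geno.subset_accessions(keep)


def minor_allele_frequency(geno: GenotypeMatrix) -> np.ndarray:
    """Per-marker minor allele frequency, min(p, 1 - p) of the 0/1 column."""
    p = geno.calls.mean(axis=0)
    return np.minimum(p, 1.0 - p)
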