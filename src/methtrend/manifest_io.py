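"""Readers/writers for CpG manifests, intensity/β matrices and sample sheets.

All on-disk formats are tab-delimited UTF-8 text with a header row.
Coordinates are 1-based inclusive; BED conversion happens only in
:mod:`methtrend.dmr_scanner`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

ISLAND_RELATIONS = ("Island", "Shore", "Shelf", "OpenSea")
GENE_REGIONS = ("TSS200", "TSS1500", "Exon1", "UTR5", "Body", "UTR3", "IGR")

#: canonical chromosome order; unknown names sort after these, alphabetically
CANONICAL_CHROMS = tuple(str(i) for i in range(1, 23)) + ("X", "Y")
_CHROM_RANK = {c: i for i, c in enumerate(CANONICAL_CHROMS)}

MANIFEST_COLUMNS = (
    "cpg_id",
    "chrom",
    "pos",
    "island_relation",
    "gene_region",
    "gene_symbol",
)


def chrom_sort_key(chrom: str) -> tuple:
    """Sort key placing 1..22, X, Y first and unknown contigs last."""
    rank = _CHROM_RANK.get(chrom)
    if rank is None:
        return (1, chrom, 0)
    return (0, "", rank)


class ManifestError(ValueError):
    """Raised for malformed or invariant-violating manifest input."""


class MatrixError(ValueError):
    """Raised for malformed matrix / sample sheet input."""


@dataclass(frozen=True)
class CpGSite:
    """One assayed CpG with its genomic annotation."""

    cpg_id: str
    chrom: str
    pos: int
    island_relation: str
    gene_region: str
    gene_symbol: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ManifestError(f"{self.cpg_id}: pos must be >= 1, got {self.pos}")
        if self.island_relation not in ISLAND_RELATIONS:
            raise ManifestError(
                f"{self.cpg_id}: unknown island_relation {self.island_relation!r}"
            )
        if self.gene_region not in GENE_REGIONS:
            raise ManifestError(
                f"{self.cpg_id}: unknown gene_region {self.gene_region!r}"
            )


class Manifest:
    """Ordered collection of :class:`CpGSite`, sorted by (chrom, pos).

    The manifest defines the genomic scan order used by the DMR scanner:
    "consecutive" downstream always means adjacent rows here.
    """

    def __init__(self, sites: Iterable[CpGSite]):
        sites = sorted(sites, key=lambda s: (chrom_sort_key(s.chrom), s.pos))
        ids = [s.cpg_id for s in sites]
        if len(set(ids)) != len(ids):
            seen: set = set()
            dup = next(i for i in ids if i in seen or seen.add(i))
            raise ManifestError(f"duplicate cpg_id {dup!r}")
        coords = [(s.chrom, s.pos) for s in sites]
        if len(set(coords)) != len(coords):
            seen = set()
            dup = next(c for c in coords if c in seen or seen.add(c))
            raise ManifestError(f"duplicate (chrom, pos) {dup!r}")
        self._sites = tuple(sites)

    @property
    def sites(self) -> tuple:
        return self._sites

    @property
    def cpg_ids(self) -> list:
        return [s.cpg_id for s in self._sites]

    def __len__(self) -> int:
        return len(self._sites)

    def __iter__(self):
        return iter(self._sites)

    def __eq__(self, other) -> bool:
        return isinstance(other, Manifest) and self._sites == other._sites

    def to_frame(self) -> pd.DataFrame:
        """Manifest as a DataFrame indexed by cpg_id, in scan order."""
        df = pd.DataFrame(
            {
                "cpg_id": [s.cpg_id for s in self._sites],
                "chrom": [s.chrom for s in self._sites],
                "pos": [s.pos for s in self._sites],
                "island_relation": [s.island_relation for s in self._sites],
                "gene_region": [s.gene_region for s in self._sites],
                "gene_symbol": [s.gene_symbol for s in self._sites],
            }
        )
        return df.set_index("cpg_id", drop=False)


def read_manifest(path) -> Manifest:
    """Read a manifest TSV, validating every row.

    Errors name the offending 1-based line number (header is line 1).
    """
    sites = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        rows = [r for r in reader if r and not r[0].startswith("#")]
    if not rows:
        raise ManifestError(f"{path}: empty manifest file")
    header = rows[0]
    missing = [c for c in MANIFEST_COLUMNS if c not in header]
    if missing:
        raise ManifestError(f"{path}: missing column(s) {missing}")
    idx = {c: header.index(c) for c in MANIFEST_COLUMNS}
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) < len(header):
            raise ManifestError(f"{path}:{lineno}: ragged row")
        try:
            pos = int(row[idx["pos"]])
        except ValueError:
            raise ManifestError(
                f"{path}:{lineno}: unparseable position {row[idx['pos']]!r}"
            ) from None
        symbol = row[idx["gene_symbol"]] or None
        try:
            sites.append(
                CpGSite(
                    cpg_id=row[idx["cpg_id"]],
                    chrom=row[idx["chrom"]],
                    pos=pos,
                    island_relation=row[idx["island_relation"]],
                    gene_region=row[idx["gene_region"]],
                    gene_symbol=symbol,
                )
            )
        except ManifestError as exc:
            raise ManifestError(f"{path}:{lineno}: {exc}") from None
    return Manifest(sites)


def write_manifest(manifest: Manifest, path, header_comment: Optional[str] = None) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(MANIFEST_COLUMNS)
        for s in manifest:
            writer.writerow(
                [s.cpg_id, s.chrom, s.pos, s.island_relation, s.gene_region, s.gene_symbol or ""]
            )


def compute_beta(m: pd.DataFrame, u: pd.DataFrame, offset: float = 100.0) -> pd.DataFrame:
    """β = M / (M + U + offset), elementwise.

    The offset regularises low-intensity probes (Illumina convention 100).
    Cells with M = U = 0 and offset 0 are defined as β = 0.
    """
    if offset < 0:
        raise MatrixError(f"offset must be >= 0, got {offset}")
    if m.shape != u.shape:
        raise MatrixError(f"shape mismatch: M {m.shape} vs U {u.shape}")
    if not (m.index.equals(u.index) and m.columns.equals(u.columns)):
        raise MatrixError("M and U row/column ids differ")
    for name, mat in (("M", m), ("U", u)):
        vals = mat.to_numpy(dtype=float)
        if np.any(vals < 0):
            r, c = np.argwhere(vals < 0)[0]
            raise MatrixError(
                f"negative {name} intensity at ({mat.index[r]}, {mat.columns[c]}): "
                f"{vals[r, c]}"
            )
    mv = m.to_numpy(dtype=float)
    uv = u.to_numpy(dtype=float)
    denom = mv + uv + offset
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(denom > 0, mv / np.where(denom > 0, denom, 1.0), 0.0)
    return pd.DataFrame(beta, index=m.index, columns=m.columns)


def _read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.isna().any().any():
        bad = df.columns[df.isna().any()][0]
        raise MatrixError(f"{path}: missing/ragged value in column {bad!r}")
    return df


def read_intensity_matrix(path) -> pd.DataFrame:
    """Read a nonnegative intensity matrix (CpG rows × sample columns)."""
    df = _read_table(path)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise MatrixError(f"{path}: non-numeric cell ({exc})") from None
    if (df.to_numpy() < 0).any():
        raise MatrixError(f"{path}: negative intensity value")
    return df


def read_beta_matrix(path) -> pd.DataFrame:
    """Read a β matrix and validate the [0, 1] range."""
    df = _read_table(path)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise MatrixError(f"{path}: non-numeric cell ({exc})") from None
    vals = df.to_numpy()
    if (vals < 0).any() or (vals > 1).any():
        r, c = np.argwhere((vals < 0) | (vals > 1))[0]
        raise MatrixError(
            f"{path}: beta outside [0,1] at ({df.index[r]}, {df.columns[c]}): {vals[r, c]}"
        )
    return df


def write_matrix(df: pd.DataFrame, path, header_comment: Optional[str] = None) -> None:
    """Write a matrix at full float precision so round trips are lossless."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", lineterminator="\n")


SAMPLE_SHEET_REQUIRED = (
    "sample_id",
    "gleason_group",
    "score",
    "age",
    "batch",
    "bcr_time",
    "bcr_event",
)


def read_sample_sheet(path, required: Sequence[str] = SAMPLE_SHEET_REQUIRED) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MatrixError(f"{path}: sample sheet missing column(s) {missing}")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise MatrixError(f"{path}: duplicate sample_id {dup!r}")
    return df.set_index("sample_id", drop=False)


def write_sample_sheet(df: pd.DataFrame, path, header_comment: Optional[str] = None) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")
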