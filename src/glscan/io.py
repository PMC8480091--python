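"""Readers and writers for Beagle genotype-likelihood files, hard-genotype
matrices and scan-result tables.

The Beagle text format is the de-facto interchange format for genotype
likelihoods in the low-coverage sequencing ecosystem (it is what ANGSD's
``-doGlf 2`` emits): a header line ``marker allele1 allele2`` followed by
three whitespace-separated likelihood columns per individual, one row per
diallelic site.  Likelihood triples are scale-free per (individual, site):
only ratios matter, so files are accepted unnormalized and normalized on
output.  A missing observation (no reads) is encoded, by convention, as
three equal likelihoods.
"""

from __future__ import annotations

import gzip
import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -9
"""Sentinel for a missing hard genotype."""

__all__ = [
    "MISSING",
    "MarkerInfo",
    "GLMatrix",
    "GenotypeMatrix",
    "read_beagle",
    "write_beagle",
    "read_genotype_matrix",
    "genotypes_to_gl",
    "write_scan",
    "read_scan",
]


class BeagleFormatError(ValueError):
    """Raised when a genotype-likelihood file violates the Beagle dialect."""


@dataclass(frozen=True)
class MarkerInfo:
    """A diallelic marker with its alleles and genomic coordinate.

    Marker names of the form ``chrom_pos`` (underscore-separated integer
    suffix) are split into chromosome and 1-based position; any other name
    is kept whole as the chromosome and assigned a sequential position,
    since the scan itself is position-agnostic.
    """

    id: str
    allele1: str
    allele2: str
    chrom: str
    pos: int

    @classmethod
    def from_id(cls, marker_id: str, allele1: str, allele2: str,
                fallback_pos: int) -> "MarkerInfo":
        chrom, _, suffix = marker_id.rpartition("_")
        if chrom and suffix.isdigit():
            return cls(marker_id, allele1, allele2, chrom, int(suffix))
        return cls(marker_id, allele1, allele2, marker_id, fallback_pos)


@dataclass
class GLMatrix:
    """Genotype likelihoods for N individuals at M diallelic sites.

    ``likelihoods`` has shape (N, M, 3) holding P(X_ij | G_ij = g) for
    minor-allele counts g = 0, 1, 2, scale-free per entry pair (i, j).
    """

    likelihoods: np.ndarray
    markers: list[MarkerInfo]
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.likelihoods = np.asarray(self.likelihoods, dtype=float)
        if self.likelihoods.ndim != 3 or self.likelihoods.shape[2] != 3:
            raise ValueError(
                f"likelihoods must have shape (N, M, 3), got {self.likelihoods.shape}"
            )
        if np.any(self.likelihoods < 0):
            raise ValueError("genotype likelihoods must be nonnegative")
        if np.any(self.likelihoods.sum(axis=2) <= 0):
            raise ValueError("all-zero likelihood triple encountered")
        if len(self.markers) != self.likelihoods.shape[1]:
            raise ValueError("marker list length does not match likelihood matrix")
        if not self.sample_ids:
            self.sample_ids = [f"ind{i}" for i in range(self.likelihoods.shape[0])]

    @property
    def n_individuals(self) -> int:
        return self.likelihoods.shape[0]

    @property
    def n_sites(self) -> int:
        return self.likelihoods.shape[1]

    def missing_mask(self) -> np.ndarray:
        """Boolean (N, M) mask of observations whose three likelihoods are
        equal — the Beagle convention for 'no reads'."""
        gl = self.likelihoods
        return (
            np.isclose(gl[:, :, 0], gl[:, :, 1])
            & np.isclose(gl[:, :, 1], gl[:, :, 2])
        )

    def subset_sites(self, keep: np.ndarray) -> "GLMatrix":
        keep = np.asarray(keep)
        markers = [m for m, k in zip(self.markers, keep) if k]
        return GLMatrix(self.likelihoods[:, keep, :], markers, list(self.sample_ids))


@dataclass
class GenotypeMatrix:
    """Hard genotypes (minor-allele dosages 0/1/2, ``MISSING`` = -9) for N
    individuals at M sites; the high-quality-genotype comparison mode."""

    dosages: np.ndarray
    markers: list[MarkerInfo] | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int64)
        valid = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not valid.all():
            bad = self.dosages[~valid].ravel()[0]
            raise ValueError(f"genotype value {bad} outside {{0, 1, 2, {MISSING}}}")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]


def _open_text(path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_beagle(path) -> GLMatrix:
    """Read a (possibly gzipped) Beagle genotype-likelihood file.

    Likelihood triples are stored as read; no renormalization is applied on
    input because every downstream quantity is invariant to per-observation
    scaling.

    Raises
    ------
    BeagleFormatError
        On an empty file, a row whose field count disagrees with the header,
        or an all-zero likelihood triple.
    """
    with _open_text(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise BeagleFormatError(f"{path}: empty input file")
        header_fields = header.split()
        if len(header_fields) < 6 or (len(header_fields) - 3) % 3 != 0:
            raise BeagleFormatError(
                f"{path}: header has {len(header_fields)} fields; expected 3 + 3N"
            )
        n_ind = (len(header_fields) - 3) // 3
        # every individual contributes three columns; name from the first
        sample_ids = [header_fields[3 + 3 * i] for i in range(n_ind)]

        markers: list[MarkerInfo] = []
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 3 + 3 * n_ind:
                raise BeagleFormatError(
                    f"{path}, line {lineno}: {len(fields)} fields, "
                    f"expected {3 + 3 * n_ind}"
                )
            markers.append(
                MarkerInfo.from_id(fields[0], fields[1], fields[2],
                                   fallback_pos=len(markers) + 1)
            )
            try:
                triple = np.array(fields[3:], dtype=float)
            except ValueError as exc:
                raise BeagleFormatError(f"{path}, line {lineno}: {exc}") from exc
            if np.any(triple.reshape(n_ind, 3).sum(axis=1) <= 0):
                raise BeagleFormatError(
                    f"{path}, line {lineno}: all-zero likelihood triple"
                )
            rows.append(triple)

    if not rows:
        raise BeagleFormatError(f"{path}: no data rows")
    gl = np.asarray(rows).reshape(len(rows), n_ind, 3).transpose(1, 0, 2)
    return GLMatrix(gl, markers, sample_ids)


def write_beagle(gl: GLMatrix, path) -> None:
    """Write a GLMatrix in the Beagle dialect accepted by :func:`read_beagle`.

    Triples are normalized to sum to one and printed with six significant
    digits; the file is gzip-compressed when ``path`` ends in ``.gz``.
    """
    if gl.n_sites == 0:
        raise ValueError("refusing to write a Beagle file with no markers")
    norm = gl.likelihoods / gl.likelihoods.sum(axis=2, keepdims=True)
    with _open_text(path, "wt") as fh:
        cols = "\t".join(f"{s}\t{s}\t{s}" for s in gl.sample_ids)
        fh.write(f"marker\tallele1\tallele2\t{cols}\n")
        for j, m in enumerate(gl.markers):
            vals = "\t".join(f"{v:.6g}" for v in norm[:, j, :].ravel())
            fh.write(f"{m.id}\t{m.allele1}\t{m.allele2}\t{vals}\n")


def read_genotype_matrix(path) -> GenotypeMatrix:
    """Read a TSV of hard genotypes: rows are sites, columns individuals,
    entries 0/1/2 with ``-9`` or ``NA`` marking missing."""
    df = pd.read_csv(path, sep=r"\s+", header=None, na_values=["NA"])
    vals = df.to_numpy(dtype=float)
    vals = np.where(np.isnan(vals), MISSING, vals)
    if not np.all(vals == vals.astype(np.int64)):
        raise ValueError(f"{path}: non-integer genotype value")
    # stored sites-by-individuals on disk; internal layout is N x M
    return GenotypeMatrix(vals.astype(np.int64).T)


def genotypes_to_gl(geno: GenotypeMatrix,
                    markers: list[MarkerInfo] | None = None) -> GLMatrix:
    """Encode hard genotypes as certain likelihood triples.

    Dosage g becomes the indicator triple with 1 at position g; a missing
    genotype becomes the uninformative equal triple, so the likelihood
    pipeline run on the result reproduces the genotype pipeline exactly.
    """
    n, m = geno.dosages.shape
    gl = np.full((n, m, 3), 1.0 / 3.0)
    for g in (0, 1, 2):
        mask = geno.dosages == g
        gl[mask] = 0.0
        gl[mask, g] = 1.0
    if markers is None:
        markers = geno.markers or [
            MarkerInfo(f"site{j + 1}", "0", "1", f"site{j + 1}", j + 1)
            for j in range(m)
        ]
    return GLMatrix(gl, list(markers))


_SCAN_BASE_COLS = ["chrom", "pos", "marker", "maf"]


def write_scan(result, path) -> None:
    """Write a ScanResult as a TSV table, one row per retained site.

    Columns: chrom, pos, marker, maf, then per-PC S1 statistics and
    p-values when present, then the S2 Mahalanobis statistic (inflation
    corrected), its p-value and flags.  P-values use scientific notation
    with at least four significant digits.
    """
    df = result.to_frame()
    float_fmt = {}
    for c in df.columns:
        if c.endswith("pval"):
            float_fmt[c] = "{:.4e}"
        elif df[c].dtype.kind == "f":
            float_fmt[c] = "{:.6g}"
    out = df.copy()
    for c, fmt in float_fmt.items():
        out[c] = df[c].map(fmt.format)
    with _open_text(path, "wt") as fh:
        out.to_csv(fh, sep="\t", index=False)


def read_scan(path) -> pd.DataFrame:
    """Read back a scan table written by :func:`write_scan`."""
    return pd.read_csv(path, sep="\t")
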