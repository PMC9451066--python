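"""Genotype input/output and variant-level filtering.

Genotypes are held as *dosages*: the average number of alternate alleles
per haplotype of a diploid genotype, so a hard call is 0, 1/2 or 1 and a
mean-imputed value lies anywhere in [0, 1].  The in-memory convention is
samples-as-rows: an N x M matrix for N individuals and M biallelic SNPs.
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "read_vcf",
    "read_dosage_matrix",
    "read_labels",
    "compute_maf",
    "filter_rare_variants",
    "impute_missing",
    "write_fractions",
    "read_fractions",
    "write_matrix",
]

_BASES = frozenset("ACGT")


@dataclass
class GenotypeMatrix:
    """N x M dosage matrix with sample/variant metadata.

    Attributes
    ----------
    dosages
        Real matrix with entries in [0, 1]; hard genotype calls are in
        {0, 0.5, 1}; imputed entries may lie anywhere in between.
    sample_ids, variant_ids
        Unique identifiers for rows and columns.
    populations
        Optional per-sample population labels (length N).
    missing_mask
        True where the genotype was missing in the source; missing
        entries hold a provisional 0 until :func:`impute_missing`.
    """

    dosages: np.ndarray
    sample_ids: list[str]
    variant_ids: list[str]
    populations: list[str] | None = None
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D array")
        n, m = self.dosages.shape
        if n < 2 or m < 1:
            raise ValueError(f"need at least 2 samples and 1 variant, got N={n}, M={m}")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match row count")
        if len(self.variant_ids) != m:
            raise ValueError("variant_ids length does not match column count")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample IDs")
        if len(set(self.variant_ids)) != m:
            raise ValueError("duplicate variant IDs")
        if self.populations is not None and len(self.populations) != n:
            raise ValueError("populations length does not match sample count")
        if self.missing_mask is None:
            self.missing_mask = np.zeros((n, m), dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != (n, m):
                raise ValueError("missing_mask shape mismatch")
        observed = self.dosages[~self.missing_mask]
        if observed.size and (np.nanmin(observed) < -1e-12 or np.nanmax(observed) > 1 + 1e-12):
            raise ValueError("dosages must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def select_variants(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Return a copy restricted to the variant columns in ``keep``."""
        keep = np.asarray(keep)
        return GenotypeMatrix(
            dosages=self.dosages[:, keep].copy(),
            sample_ids=list(self.sample_ids),
            variant_ids=[self.variant_ids[j] for j in np.atleast_1d(np.arange(self.n_variants)[keep])],
            populations=list(self.populations) if self.populations is not None else None,
            missing_mask=self.missing_mask[:, keep].copy(),
        )


class VCFParseError(ValueError):
    pass


def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Read diploid biallelic SNPs from a VCF (plain or gzipped) into dosages.

    Entry (i, j) is the alternate-allele count of sample i at site j divided
    by two, so 0/0 -> 0, 0/1 -> 0.5 and 1/1 -> 1; phasing is ignored.
    Multi-allelic sites, indels and non-SNP records are skipped (counted in
    the log).  Missing genotypes get a provisional dosage of 0 and are
    flagged in ``missing_mask``.

    Raises
    ------
    VCFParseError
        On malformed records, haploid/mixed-ploidy calls, duplicate sample
        IDs, or when no biallelic SNP survives.
    """
    from cyvcf2 import VCF

    try:
        reader = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise VCFParseError(f"cannot open VCF {path!r}: {exc}") from exc

    samples = list(reader.samples)
    if len(samples) != len(set(samples)):
        raise VCFParseError(f"duplicate sample IDs in {path!r}")
    if len(samples) < 2:
        raise VCFParseError("need at least 2 samples")

    cols: list[np.ndarray] = []
    miss_cols: list[np.ndarray] = []
    variant_ids: list[str] = []
    n_skipped = 0
    for rec_no, var in enumerate(reader, start=1):
        alts = var.ALT
        if len(alts) != 1 or var.REF not in _BASES or alts[0] not in _BASES:
            n_skipped += 1
            continue
        gts = var.genotypes
        if len(gts) != len(samples):
            raise VCFParseError(f"record {rec_no} at {var.CHROM}:{var.POS}: genotype count mismatch")
        dos = np.zeros(len(samples))
        miss = np.zeros(len(samples), dtype=bool)
        for i, gt in enumerate(gts):
            alleles = gt[:-1]  # last element is the phased flag
            if len(alleles) != 2:
                raise VCFParseError(
                    f"record {rec_no} at {var.CHROM}:{var.POS}, sample {samples[i]}: "
                    f"non-diploid genotype (ploidy {len(alleles)})"
                )
            if alleles[0] < 0 or alleles[1] < 0:
                miss[i] = True
            else:
                dos[i] = (alleles[0] + alleles[1]) / 2.0
        cols.append(dos)
        miss_cols.append(miss)
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}:{var.REF}:{alts[0]}"
        variant_ids.append(vid)

    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)
    if not cols:
        raise VCFParseError(f"no biallelic SNP records in {path!r}")
    if len(variant_ids) != len(set(variant_ids)):
        seen: dict[str, int] = {}
        for j, v in enumerate(variant_ids):
            if v in seen:
                seen[v] += 1
                variant_ids[j] = f"{v}_{seen[v]}"
            else:
                seen[v] = 0
    dosages = np.column_stack(cols)
    missing = np.column_stack(miss_cols)
    logger.info("read_vcf: %d samples x %d biallelic SNPs", dosages.shape[0], dosages.shape[1])
    return GenotypeMatrix(dosages, samples, variant_ids, missing_mask=missing)


def read_dosage_matrix(path: str | os.PathLike, delimiter: str | None = None) -> GenotypeMatrix:
    """Read a plain delimited numeric table of dosages (rows = samples).

    A non-numeric first row is treated as a header of variant IDs and a
    non-numeric first column as sample IDs; both are auto-detected.  NaN
    cells are flagged missing; any value outside [0, 1] is an error that
    names the offending cell.
    """
    with open(path) as fh:
        raw = [line.rstrip("\n") for line in fh if line.strip()]
    if not raw:
        raise ValueError(f"empty file {path!r}")
    rows = [line.split(delimiter) if delimiter else line.split() for line in raw]

    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    has_header = any(not _numeric(t) for t in rows[0][1:]) or (len(rows[0]) > 0 and not _numeric(rows[0][-1]))
    body = rows[1:] if has_header else rows
    if not body:
        raise ValueError("table has a header but no data rows")
    has_ids = not _numeric(body[0][0])
    width = len(body[0])
    for i, r in enumerate(body):
        if len(r) != width:
            raise ValueError(f"ragged table: row {i} has {len(r)} fields, expected {width}")

    variant_ids = None
    if has_header:
        m_expected = width - 1 if has_ids else width
        variant_ids = rows[0][-m_expected:]
        if len(rows[0]) not in (m_expected, m_expected + 1):
            raise ValueError("header width does not match data width")
    sample_ids = [r[0] for r in body] if has_ids else None
    data_rows = [r[1:] for r in body] if has_ids else body

    n, m = len(data_rows), len(data_rows[0])
    dosages = np.zeros((n, m))
    missing = np.zeros((n, m), dtype=bool)
    for i, r in enumerate(data_rows):
        for j, tok in enumerate(r):
            try:
                v = float(tok)
            except ValueError:
                raise ValueError(f"non-numeric cell at row {i}, column {j}: {tok!r}") from None
            if np.isnan(v):
                missing[i, j] = True
            elif v < 0 or v > 1:
                raise ValueError(f"dosage out of [0, 1] at row {i}, column {j}: {v}")
            else:
                dosages[i, j] = v
    if sample_ids is None:
        sample_ids = [f"sample{i}" for i in range(n)]
    if variant_ids is None:
        variant_ids = [f"var{j}" for j in range(m)]
    return GenotypeMatrix(dosages, sample_ids, list(variant_ids), missing_mask=missing)


def read_labels(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column sample-to-population label file (TSV or whitespace)."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"label file line {line_no}: expected two columns")
            labels[parts[0]] = parts[1]
    return labels


def compute_maf(g: GenotypeMatrix) -> np.ndarray:
    """Per-variant minor allele frequency, min(p, 1-p) of the ALT frequency.

    Dosages are already per-haplotype averages, so the column mean over
    non-missing entries is the alternate-allele frequency directly.
    Columns with every entry missing get NaN.
    """
    d = np.where(g.missing_mask, np.nan, g.dosages)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", "Mean of empty slice")  # all-missing column -> NaN by design
        p = np.nanmean(d, axis=0)
    return np.minimum(p, 1.0 - p)


def filter_rare_variants(g: GenotypeMatrix, threshold: float = 0.1) -> GenotypeMatrix:
    """Drop variants with MAF strictly below ``threshold``.

    The removal rule is strict: a site at exactly the threshold is kept.
    Fully-missing columns (NaN MAF) are also dropped.  The default 0.1
    is the customary rare-variant cut for ancestry analyses.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError(f"threshold must be in [0, 0.5], got {threshold}")
    maf = compute_maf(g)
    keep = ~np.isnan(maf) & (maf >= threshold)
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("filter_rare_variants: removed %d of %d variants (MAF < %g)", n_removed, g.n_variants, threshold)
    if not keep.any():
        raise ValueError(f"all {g.n_variants} variants removed at MAF threshold {threshold}")
    if n_removed == 0:
        return g
    return g.select_variants(keep)


def impute_missing(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing entry by its column's non-missing mean.

    Columns with no observed genotype at all are dropped with a warning.
    The missing mask is preserved so provenance survives imputation.
    Mean imputation keeps each centered column mean at zero, which is what
    the downstream SVD assumes.
    """
    if not g.missing_mask.any():
        return g
    d = np.where(g.missing_mask, np.nan, g.dosages)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", "Mean of empty slice")
        col_mean = np.nanmean(d, axis=0)
    dead = np.isnan(col_mean)
    if dead.any():
        logger.warning("impute_missing: dropping %d fully-missing variant columns", int(dead.sum()))
    filled = np.where(np.isnan(d), col_mean, d)
    out = GenotypeMatrix(
        dosages=filled[:, ~dead],
        sample_ids=list(g.sample_ids),
        variant_ids=[v for v, k in zip(g.variant_ids, ~dead) if k],
        populations=list(g.populations) if g.populations is not None else None,
        missing_mask=g.missing_mask[:, ~dead].copy(),
    )
    return out


def write_fractions(alpha: np.ndarray, path: str | os.PathLike, sample_ids: list[str] | None = None) -> None:
    """Write an N x K ancestry-fraction matrix as whitespace text (.Q style).

    One row per sample, six decimal places.  Rows must sum to 1 within
    1e-6.  Sample IDs, when given, go to a sibling ``<path>.samples`` file
    so the matrix itself stays ADMIXTURE-compatible.
    """
    alpha = np.asarray(alpha, dtype=float)
    if alpha.ndim != 2:
        raise ValueError("alpha must be 2-D")
    sums = alpha.sum(axis=1)
    bad = np.flatnonzero(np.abs(sums - 1.0) > 1e-6)
    if bad.size:
        raise ValueError(f"alpha row {bad[0]} sums to {sums[bad[0]]:.8f}, not 1")
    with open(path, "w") as fh:
        for row in alpha:
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
    if sample_ids is not None:
        if len(sample_ids) != alpha.shape[0]:
            raise ValueError("sample_ids length mismatch")
        with open(f"{path}.samples", "w") as fh:
            fh.write("\n".join(sample_ids) + "\n")


def read_fractions(path: str | os.PathLike) -> np.ndarray:
    """Read a whitespace .Q-style fraction matrix written by :func:`write_fractions`."""
    return np.loadtxt(path, ndmin=2)


def write_matrix(m: np.ndarray, path: str | os.PathLike, fmt: str = "%.6f") -> None:
    """Write a plain whitespace-delimited numeric matrix (beta, archetype tables)."""
    np.savetxt(path, np.asarray(m, dtype=float), fmt=fmt)
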