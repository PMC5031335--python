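"""Readers, writers and in-memory containers for genotype, SNP-set and phenotype data.

Supported external representations:

* PLINK binary filesets (``.bed``/``.bim``/``.fam``, bed v1.00, SNP-major);
  dosages are counts of the A1 allele, which PLINK conventionally assigns to
  the minor allele.
* Plain numeric dosage matrices (individuals x variants, whitespace- or
  comma-delimited, values 0/1/2 with ``NA`` for missing).
* Two-column SNP-set files (``SetID VariantID``), the SKAT SetID convention.
* Phenotype tables (``SampleID value [covariate ...]``) or the sixth column
  of a ``.fam`` file.

All containers are thin dataclasses over numpy arrays; missing dosages are
stored as NaN and only mean-imputed immediately before a statistic is
computed, so I/O round-trips are lossless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DimensionError, FormatError, ParseError

logger = logging.getLogger("apskat")

_BED_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01

# 2-bit PLINK codes -> A1 dosage: 00=hom A1 (2), 01=missing, 10=het (1), 11=hom A2 (0)
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])
_DOSAGE_TO_CODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}


def compute_maf(dosages: np.ndarray) -> np.ndarray:
    """Folded minor-allele frequency per variant from non-missing dosages.

    ``maf_j = min(f_j, 1 - f_j)`` with ``f_j`` the counted-allele frequency
    ``sum(dosages_j) / (2 * n_called_j)``.  A variant with no called genotypes
    gets NaN (flagged downstream, excluded by :func:`filter_rare`).
    """
    d = np.asarray(dosages, dtype=float)
    called = ~np.isnan(d)
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.nansum(d, axis=0) / (2.0 * n_called)
    f = np.where(n_called == 0, np.nan, f)
    if np.any(n_called == 0):
        logger.warning("%d variant(s) have no called genotypes; MAF set to NaN",
                       int((n_called == 0).sum()))
    return np.minimum(f, 1.0 - f)


@dataclass
class GenotypeMatrix:
    """An n x m dosage matrix with sample/variant metadata and per-variant MAF.

    Parameters
    ----------
    dosages
        Float array of minor-allele counts, shape (n, m); NaN marks missing.
    sample_ids, variant_ids
        Row and column identifiers.
    positions
        Optional base-pair coordinates, length m.
    maf
        Folded allele frequencies; computed from ``dosages`` when omitted.
    """

    dosages: np.ndarray
    sample_ids: list[str]
    variant_ids: list[str]
    positions: np.ndarray | None = None
    maf: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise DimensionError("dosages must be a 2-D (samples x variants) array")
        n, m = self.dosages.shape
        if len(self.sample_ids) != n or len(self.variant_ids) != m:
            raise DimensionError(
                f"id lengths ({len(self.sample_ids)}, {len(self.variant_ids)}) "
                f"do not match dosage shape {self.dosages.shape}")
        observed = self.dosages[~np.isnan(self.dosages)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            bad = observed[~np.isin(observed, (0.0, 1.0, 2.0))][0]
            raise ParseError(f"dosage value {bad!r} outside {{0,1,2,missing}}")
        if self.positions is not None:
            self.positions = np.asarray(self.positions)
            if self.positions.shape != (m,):
                raise DimensionError("positions length does not match variant count")
        if self.maf is None:
            self.maf = compute_maf(self.dosages)
        else:
            self.maf = np.asarray(self.maf, dtype=float)

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    def imputed(self) -> np.ndarray:
        """Dosages with missing calls replaced by the observed column mean (2*MAF
        for minor-allele-counted columns).  Returns a new array; stored data are
        never modified."""
        d = self.dosages.copy()
        if np.isnan(d).any():
            col_mean = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            idx = np.where(np.isnan(d))
            d[idx] = col_mean[idx[1]]
        return d

    def subset_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            dosages=self.dosages[:, index],
            sample_ids=list(self.sample_ids),
            variant_ids=[self.variant_ids[i] for i in np.atleast_1d(index)],
            positions=None if self.positions is None else self.positions[index],
            maf=self.maf[index],
        )

    def subset_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            dosages=self.dosages[index, :],
            sample_ids=[self.sample_ids[i] for i in index],
            variant_ids=list(self.variant_ids),
            positions=self.positions,
        )


def filter_rare(g: GenotypeMatrix, threshold: float = 0.05) -> GenotypeMatrix:
    """Keep exactly the polymorphic variants with ``0 < maf < threshold``.

    The comparison is strict on both sides: monomorphic variants (maf 0 or
    undefined) are removed, and a variant at exactly the threshold is removed.
    Column order is preserved.  An empty result is returned as an empty matrix;
    the caller decides whether to skip the set.
    """
    if not (0.0 < threshold <= 0.5):
        raise ValueError(f"threshold must lie in (0, 0.5], got {threshold}")
    with np.errstate(invalid="ignore"):
        keep = np.flatnonzero((g.maf > 0.0) & (g.maf < threshold))
    return g.subset_variants(keep)


@dataclass
class SnpSetCollection:
    """Ordered mapping from set identifier to its variant identifiers."""

    sets: dict[str, list[str]]

    @property
    def m_sets(self) -> int:
        return len(self.sets)

    def resolve(self, g: GenotypeMatrix) -> dict[str, np.ndarray]:
        """Column indices into ``g`` per set.  Unresolvable variant ids are
        reported via the logger (never silently dropped) and omitted from the
        returned indices."""
        lookup = {v: i for i, v in enumerate(g.variant_ids)}
        resolved: dict[str, np.ndarray] = {}
        for set_id, variants in self.sets.items():
            missing = [v for v in variants if v not in lookup]
            if missing:
                logger.warning("set %s: %d variant id(s) not in genotype data: %s",
                               set_id, len(missing), ", ".join(missing[:5]))
            resolved[set_id] = np.array([lookup[v] for v in variants if v in lookup],
                                        dtype=int)
        return resolved


@dataclass
class PhenotypeData:
    """Trait values with optional covariates.

    ``trait_type`` is ``"quantitative"`` (continuous y) or ``"binary"``
    (case/control coded 0/1).
    """

    values: np.ndarray
    sample_ids: list[str]
    covariates: np.ndarray | None = None
    covariate_names: list[str] | None = None
    trait_type: str = "quantitative"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise DimensionError("phenotype values must be 1-D")
        if len(self.sample_ids) != self.values.size:
            raise DimensionError("sample id count does not match phenotype length")
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == "binary" and not np.isin(self.values, (0.0, 1.0)).all():
            raise ParseError("binary trait must contain only 0/1 values")
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if self.covariates.shape[0] != self.values.size:
                raise DimensionError("covariate rows do not match phenotype length")
            if self.covariate_names is None:
                self.covariate_names = [f"x{j + 1}" for j in range(self.covariates.shape[1])]

    @property
    def n(self) -> int:
        return self.values.size


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam
# ---------------------------------------------------------------------------

def _byte_lut() -> np.ndarray:
    """256 x 4 lookup table: byte value -> dosages of the 4 packed samples."""
    lut = np.empty((256, 4))
    for byte in range(256):
        for i in range(4):
            lut[byte, i] = _CODE_TO_DOSAGE[(byte >> (2 * i)) & 0b11]
    return lut


_LUT = _byte_lut()


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK v1 binary fileset (``prefix.bed/.bim/.fam``).

    Only SNP-major bed files (mode byte 0x01) are supported; sample-major
    files are rejected with an explicit message.  Dosages count the A1 allele
    (PLINK's minor allele by convention); missing calls stay missing.
    """
    prefix = Path(prefix)
    bed_path = Path(str(prefix) + ".bed")
    bim_path = Path(str(prefix) + ".bim")
    fam_path = Path(str(prefix) + ".fam")
    for p in (bed_path, bim_path, fam_path):
        if not p.exists():
            raise FileNotFoundError(f"missing PLINK component: {p}")

    bim = pd.read_csv(bim_path, sep=r"\s+", header=None,
                      names=["chrom", "variant_id", "cm", "pos", "a1", "a2"],
                      dtype={"variant_id": str})
    fam = pd.read_csv(fam_path, sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "phenotype"],
                      dtype={"iid": str})
    n, m = len(fam), len(bim)

    raw = bed_path.read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise FormatError(f"{bed_path}: bad magic bytes {raw[:2]!r}; not a PLINK v1 bed file")
    if raw[2] != _SNP_MAJOR:
        raise FormatError(f"{bed_path}: sample-major bed files are not supported "
                          "(mode byte 0x00); re-export in SNP-major order")
    bytes_per_variant = (n + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != m * bytes_per_variant:
        raise DimensionError(
            f"{bed_path}: payload of {payload.size} bytes does not match "
            f"{m} variants x {bytes_per_variant} bytes ({n} samples)")
    decoded = _LUT[payload.reshape(m, bytes_per_variant)]  # m x bpv x 4
    dosages = decoded.reshape(m, -1)[:, :n].T.copy()

    return GenotypeMatrix(dosages=dosages,
                          sample_ids=fam["iid"].tolist(),
                          variant_ids=bim["variant_id"].tolist(),
                          positions=bim["pos"].to_numpy())


def write_plink(g: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a GenotypeMatrix as a SNP-major PLINK v1 fileset (A1 = counted allele)."""
    prefix = Path(prefix)
    bed_path = Path(str(prefix) + ".bed")
    bim_path = Path(str(prefix) + ".bim")
    fam_path = Path(str(prefix) + ".fam")
    n, m = g.n, g.m
    bytes_per_variant = (n + 3) // 4
    codes = np.full((m, bytes_per_variant * 4), 0b01, dtype=np.uint8)  # pad = missing code
    d = g.dosages.T  # m x n
    for value, code in _DOSAGE_TO_CODE.items():
        codes[:, :n][d == value] = code
    codes[:, :n][np.isnan(d)] = 0b01
    shifts = np.arange(4, dtype=np.uint8) * 2
    packed = (codes.reshape(m, bytes_per_variant, 4) << shifts).sum(axis=2).astype(np.uint8)
    bed_path.write_bytes(_BED_MAGIC + bytes([_SNP_MAJOR]) + packed.tobytes())

    pos = g.positions if g.positions is not None else np.arange(1, m + 1)
    with bim_path.open("w") as fh:
        for vid, p in zip(g.variant_ids, pos):
            fh.write(f"1\t{vid}\t0\t{int(p)}\tA\tG\n")
    with fam_path.open("w") as fh:
        for sid in g.sample_ids:
            fh.write(f"{sid}\t{sid}\t0\t0\t0\t-9\n")


# ---------------------------------------------------------------------------
# Numeric dosage matrices
# ---------------------------------------------------------------------------

_MISSING_TOKENS = {"na", "nan", "-9", "."}


def read_numeric_matrix(path: str | Path) -> GenotypeMatrix:
    """Read an individuals x variants dosage table.

    Whitespace- or comma-delimited.  An optional header row carries variant
    ids; a header whose first token is ``sample_id`` additionally marks the
    first column as sample identifiers.  Cells must be 0, 1, 2 or a missing
    token (NA/nan/-9/.).
    """
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise ParseError(f"{path}: empty file")
    lines = text.splitlines()
    delim = "," if "," in lines[0] else None

    def tokens(line: str) -> list[str]:
        return [t for t in (line.split(delim) if delim else line.split()) if t]

    first = tokens(lines[0])

    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return tok.lower() in _MISSING_TOKENS

    has_sample_col = first[0].lower() in ("sample_id", "sampleid", "iid")
    has_header = has_sample_col or not all(_numeric(t) for t in first)
    variant_ids = None
    body = lines
    if has_header:
        variant_ids = first[1:] if has_sample_col else first
        body = lines[1:]
    if not body:
        raise ParseError(f"{path}: no data rows")

    sample_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(body, start=2 if has_header else 1):
        toks = tokens(line)
        if has_sample_col:
            sample_ids.append(toks[0])
            toks = toks[1:]
        row = []
        for colno, tok in enumerate(toks, start=1):
            if tok.lower() in _MISSING_TOKENS:
                row.append(np.nan)
                continue
            try:
                val = float(tok)
            except ValueError:
                raise ParseError(f"{path}: non-numeric value {tok!r} at line {lineno}, "
                                 f"column {colno}") from None
            if val not in (0.0, 1.0, 2.0):
                raise ParseError(f"{path}: dosage {tok!r} outside {{0,1,2}} at line "
                                 f"{lineno}, column {colno}")
            row.append(val)
        rows.append(row)
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ParseError(f"{path}: ragged rows (widths {sorted(widths)})")
    dosages = np.array(rows, dtype=float)
    n, m = dosages.shape
    if variant_ids is not None and len(variant_ids) != m:
        raise DimensionError(f"{path}: header has {len(variant_ids)} variant ids "
                             f"for {m} columns")
    if variant_ids is None:
        variant_ids = [f"v{j + 1}" for j in range(m)]
    if not sample_ids:
        sample_ids = [f"s{i + 1}" for i in range(n)]
    return GenotypeMatrix(dosages=dosages, sample_ids=sample_ids, variant_ids=variant_ids)


def write_numeric_matrix(g: GenotypeMatrix, path: str | Path) -> None:
    """Write the tab-delimited numeric-matrix format (round-trips exactly)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("sample_id\t" + "\t".join(g.variant_ids) + "\n")
        for sid, row in zip(g.sample_ids, g.dosages):
            cells = ["NA" if np.isnan(v) else str(int(v)) for v in row]
            fh.write(sid + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# SNP-set and phenotype tables
# ---------------------------------------------------------------------------

def read_set_file(path: str | Path) -> SnpSetCollection:
    """Read a two-column ``SetID VariantID`` file into an ordered collection.

    Duplicate (set, variant) pairs are collapsed with a warning; a line with
    a token count other than two is a parse error naming the line.
    """
    path = Path(path)
    sets: dict[str, dict[str, None]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        toks = line.split()
        if len(toks) != 2:
            raise ParseError(f"{path}: expected 2 tokens at line {lineno}, got {len(toks)}")
        set_id, variant_id = toks
        bucket = sets.setdefault(set_id, {})
        if variant_id in bucket:
            logger.warning("%s: duplicate pair (%s, %s) at line %d collapsed",
                           path, set_id, variant_id, lineno)
        bucket[variant_id] = None
    return SnpSetCollection(sets={k: list(v) for k, v in sets.items()})


def write_set_file(sets: SnpSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for set_id, variants in sets.sets.items():
            for v in variants:
                fh.write(f"{set_id}\t{v}\n")


def read_phenotype(path: str | Path, trait_type: str = "quantitative") -> PhenotypeData:
    """Read ``SampleID value [covariate ...]`` (whitespace-separated, optional header)."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty phenotype file")
    first = lines[0].split()
    try:
        float(first[1])
        header = None
    except (ValueError, IndexError):
        header, lines = first, lines[1:]
    sample_ids, values, covs = [], [], []
    for lineno, line in enumerate(lines, start=1 + (header is not None)):
        toks = line.split()
        if len(toks) < 2:
            raise ParseError(f"{path}: expected at least 2 tokens at line {lineno}")
        sample_ids.append(toks[0])
        try:
            values.append(float(toks[1]))
            covs.append([float(t) for t in toks[2:]])
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric value at line {lineno}: {exc}") from None
    k = len(covs[0]) if covs else 0
    if any(len(c) != k for c in covs):
        raise ParseError(f"{path}: inconsistent covariate column count")
    names = header[2:] if header is not None and len(header) > 2 else None
    return PhenotypeData(values=np.array(values), sample_ids=sample_ids,
                         covariates=np.array(covs) if k else None,
                         covariate_names=names, trait_type=trait_type)


def phenotype_from_fam(fam_path: str | Path, trait_type: str = "quantitative") -> PhenotypeData:
    """Phenotype from the sixth column of a ``.fam`` file (-9/0 = missing, dropped)."""
    fam = pd.read_csv(Path(fam_path), sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "phenotype"],
                      dtype={"iid": str})
    values = fam["phenotype"].to_numpy(dtype=float)
    keep = ~np.isin(values, (-9.0, 0.0)) if trait_type == "quantitative" else ~np.isin(values, (-9.0,))
    if trait_type == "binary":
        # PLINK codes case/control as 2/1; recode to 1/0
        values = values - 1.0
        keep &= np.isin(values, (0.0, 1.0))
    dropped = int((~keep).sum())
    if dropped:
        logger.info("%s: dropped %d sample(s) with missing phenotype", fam_path, dropped)
    return PhenotypeData(values=values[keep],
                         sample_ids=fam["iid"].to_numpy()[keep].tolist(),
                         trait_type=trait_type)


def align_samples(g: GenotypeMatrix, pheno: PhenotypeData) -> tuple[GenotypeMatrix, PhenotypeData]:
    """Intersect genotype and phenotype samples by identifier.

    Order follows the genotype file; the number of dropped samples on each
    side is logged.
    """
    pheno_index = {s: i for i, s in enumerate(pheno.sample_ids)}
    g_keep, p_keep = [], []
    for i, sid in enumerate(g.sample_ids):
        if sid in pheno_index:
            g_keep.append(i)
            p_keep.append(pheno_index[sid])
    dropped_g = g.n - len(g_keep)
    dropped_p = pheno.n - len(p_keep)
    if dropped_g or dropped_p:
        logger.info("sample alignment dropped %d genotype and %d phenotype sample(s)",
                    dropped_g, dropped_p)
    if not g_keep:
        raise DimensionError("no samples shared between genotype and phenotype data")
    p_idx = np.array(p_keep)
    aligned = PhenotypeData(
        values=pheno.values[p_idx],
        sample_ids=[pheno.sample_ids[i] for i in p_keep],
        covariates=None if pheno.covariates is None else pheno.covariates[p_idx],
        covariate_names=pheno.covariate_names,
        trait_type=pheno.trait_type,
    )
    return g.subset_samples(np.array(g_keep)), aligned
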