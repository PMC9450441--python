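"""Readers and writers for the standard formats the pipeline touches.

In-memory containers are deliberately thin: a :class:`GenotypeMatrix` wraps an
``animals x variants`` dosage array (0/1/2, ``-1`` = missing) together with a
pandas variant table; genomic relationship matrices live in :class:`GRM`.
On disk we speak PLINK bed/bim/fam (v1.00, SNP-major), the GRM-binary triplet
convention (float32 lower triangle + id file + N file), and delimited
phenotype text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1

_PLINK_MAGIC = bytes([0x6C, 0x1B, 0x01])

#: bed 2-bit codes (SNP-major): 00 = hom A1, 01 = missing, 10 = het, 11 = hom A2.
#: Dosages count the A1 allele, so 00 -> 2, 10 -> 1, 11 -> 0, 01 -> MISSING.
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


def _path(prefix: Path, ext: str) -> Path:
    return prefix.parent / (prefix.name + ext)


class FormatError(ValueError):
    """A file on disk does not match its declared format."""


class SchemaError(ValueError):
    """A phenotype file is missing required columns."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Dosage matrix (animals x variants) plus variant metadata.

    ``variants`` is a DataFrame with at least columns ``id, chrom, pos, a1, a2``
    (1-based bim-convention positions); simulation adds ``maf``, panel
    membership flags (``panel_array``, ``panel_sequence``), per-dataset
    imputation-quality columns (``impute_r2_<label>``) and a hidden-truth
    ``qtl`` flag.
    """

    animal_ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (animals x variants)")
        if self.dosages.shape[0] != len(self.animal_ids):
            raise ValueError(
                f"{self.dosages.shape[0]} dosage rows for {len(self.animal_ids)} animals"
            )
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError(
                f"{self.dosages.shape[1]} dosage columns for {len(self.variants)} variants"
            )
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be in {0,1,2} or the missing code")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Per-variant A1 allele frequency from non-missing dosages."""
        d = np.ma.masked_equal(self.dosages, MISSING)
        p = d.mean(axis=0).filled(np.nan) / 2.0
        return np.asarray(p, dtype=float)

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def subset(self, animals: Sequence[str] | np.ndarray | None = None,
               variant_mask: np.ndarray | None = None) -> "GenotypeMatrix":
        """Row/column subset view (copies the dosage block)."""
        rows = np.arange(self.n_animals)
        ids = self.animal_ids
        if animals is not None:
            index = {a: i for i, a in enumerate(self.animal_ids)}
            missing_ids = [a for a in animals if a not in index]
            if missing_ids:
                raise KeyError(f"animals not in genotype matrix: {missing_ids[:5]}")
            rows = np.array([index[a] for a in animals])
            ids = list(animals)
        cols = np.arange(self.n_variants)
        var = self.variants
        if variant_mask is not None:
            variant_mask = np.asarray(variant_mask)
            cols = np.flatnonzero(variant_mask) if variant_mask.dtype == bool else variant_mask
            var = self.variants.iloc[cols]
        return GenotypeMatrix(ids, var, self.dosages[np.ix_(rows, cols)])


@dataclass
class GRM:
    """Symmetric genomic relationship matrix with its provenance."""

    matrix: np.ndarray
    animal_ids: list[str]
    n_variants_used: int
    maf_threshold: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        n = len(self.animal_ids)
        if self.matrix.shape != (n, n):
            raise ValueError(f"GRM shape {self.matrix.shape} != ({n},{n})")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise ValueError("GRM must be symmetric")
        self.matrix = (self.matrix + self.matrix.T) / 2.0
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("GRM contains non-finite entries")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    def align(self, animal_ids: Sequence[str]) -> np.ndarray:
        """Indices of ``animal_ids`` within this GRM (KeyError if absent)."""
        index = {a: i for i, a in enumerate(self.animal_ids)}
        try:
            return np.array([index[a] for a in animal_ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"animal {exc} not present in GRM") from exc


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam
# ---------------------------------------------------------------------------

def write_plink(gm: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a bed/bim/fam triplet (SNP-major bed v1.00)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n = gm.n_animals
    with open(_path(prefix, ".fam"), "w") as fh:
        for a in gm.animal_ids:
            fh.write(f"{a} {a} 0 0 0 -9\n")
    var = gm.variants
    with open(_path(prefix, ".bim"), "w") as fh:
        for row in var.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.id}\t0\t{row.pos}\t{row.a1}\t{row.a2}\n")
    # pack 4 samples per byte, little-end bits first within each byte
    codes = np.empty(gm.dosages.shape, dtype=np.uint8)
    for dosage, code in _DOSAGE_TO_CODE.items():
        codes[gm.dosages == dosage] = code
    n_bytes = (n + 3) // 4
    with open(_path(prefix, ".bed"), "wb") as fh:
        fh.write(_PLINK_MAGIC)
        padded = np.zeros((gm.n_variants, n_bytes * 4), dtype=np.uint8)
        padded[:, :n] = codes.T
        packed = (
            padded[:, 0::4]
            | (padded[:, 1::4] << 2)
            | (padded[:, 2::4] << 4)
            | (padded[:, 3::4] << 6)
        )
        fh.write(packed.astype(np.uint8).tobytes())


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a bed/bim/fam triplet; dosages count the A1 allele as read."""
    prefix = Path(prefix)
    fam = pd.read_csv(_path(prefix, ".fam"), sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "pheno"],
                      dtype={"iid": str})
    bim = pd.read_csv(_path(prefix, ".bim"), sep=r"\s+", header=None,
                      names=["chrom", "id", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str, "id": str, "a1": str, "a2": str})
    n, m = len(fam), len(bim)
    raw = np.fromfile(_path(prefix, ".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _PLINK_MAGIC:
        raise FormatError(f"{prefix.with_suffix('.bed')}: bad magic, not a bed v1.00 file")
    body = raw[3:]
    n_bytes = (n + 3) // 4
    if body.size != m * n_bytes:
        raise FormatError(
            f"{prefix.with_suffix('.bed')}: {body.size} data bytes, expected "
            f"{m * n_bytes} for {n} animals x {m} variants"
        )
    body = body.reshape(m, n_bytes)
    codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
    codes[:, 0::4] = body & 0b11
    codes[:, 1::4] = (body >> 2) & 0b11
    codes[:, 2::4] = (body >> 4) & 0b11
    codes[:, 3::4] = (body >> 6) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T
    variants = bim[["id", "chrom", "pos", "a1", "a2"]].copy()
    return GenotypeMatrix(list(fam["iid"]), variants, dosages)


# ---------------------------------------------------------------------------
# GRM binary triplet
# ---------------------------------------------------------------------------

def write_grm_binary(grm: GRM, prefix: str | Path) -> None:
    """Write <prefix>.grm.bin / .grm.id / .grm.N.bin (float32 lower triangle)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n = grm.n_animals
    tri = grm.matrix[np.tril_indices(n)]
    tri.astype("<f4").tofile(f"{prefix}.grm.bin")
    counts = np.full(n * (n + 1) // 2, grm.n_variants_used, dtype="<f4")
    counts.tofile(f"{prefix}.grm.N.bin")
    with open(f"{prefix}.grm.id", "w") as fh:
        for a in grm.animal_ids:
            fh.write(f"{a}\t{a}\n")


def read_grm_binary(prefix: str | Path) -> GRM:
    prefix = Path(prefix)
    ids = [line.split()[1] for line in open(f"{prefix}.grm.id") if line.strip()]
    n = len(ids)
    tri = np.fromfile(f"{prefix}.grm.bin", dtype="<f4")
    if tri.size != n * (n + 1) // 2:
        raise FormatError(
            f"{prefix}.grm.bin holds {tri.size} entries but {prefix}.grm.id lists "
            f"{n} animals (need n(n+1)/2 = {n * (n + 1) // 2})"
        )
    mat = np.zeros((n, n))
    mat[np.tril_indices(n)] = tri
    mat = mat + np.tril(mat, -1).T
    counts = np.fromfile(f"{prefix}.grm.N.bin", dtype="<f4")
    n_variants = int(round(float(counts[0]))) if counts.size else 0
    return GRM(mat, ids, n_variants)


# ---------------------------------------------------------------------------
# phenotype text
# ---------------------------------------------------------------------------

#: columns that are categorical identifiers, never parsed as numbers
_ID_COLUMNS = {"animal_id", "sire_id", "dataset", "country", "herd", "cg", "hys",
               "parity_stage", "trial"}

UNKNOWN_SIRE = "<unknown>"


def read_phenotypes(path: str | Path, schema: dict[str, type] | None = None,
                    sep: str | None = None) -> pd.DataFrame:
    """Read a delimited phenotype table with header.

    ``schema`` maps required column names to types (e.g. ``{"DMI": float}``);
    missing columns raise :class:`SchemaError`, unparseable numeric cells raise
    :class:`FormatError` with the offending row number.  ``NA``/empty sire ids
    become the distinct :data:`UNKNOWN_SIRE` marker.
    """
    path = Path(path)
    if sep is None:
        head = open(path).readline()
        sep = "\t" if head.count("\t") >= head.count(",") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if schema:
        missing = [c for c in schema if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing required column(s) {missing}")
    for col in df.columns:
        if col in _ID_COLUMNS:
            continue
        want = schema.get(col) if schema else None
        if want is str:
            continue
        cleaned = df[col].replace({"NA": np.nan, "": np.nan, "nan": np.nan})
        converted = pd.to_numeric(cleaned, errors="coerce")
        bad = converted.isna() & cleaned.notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise FormatError(f"{path}: non-numeric value {df.loc[bad.idxmax(), col]!r} "
                              f"in column {col!r} at line {row}")
        if want is not None or converted.notna().any():
            df[col] = converted
    if "sire_id" in df.columns:
        df["sire_id"] = df["sire_id"].replace({"NA": UNKNOWN_SIRE, "": UNKNOWN_SIRE,
                                               "0": UNKNOWN_SIRE})
    return df


def write_phenotypes(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False)
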