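"""Reading, encoding, filtering and writing genotype/phenotype tables.

Conventions: genotype calls arrive either as allele-pair strings (``AA``,
``AT``, ...) or already numeric (``{-1,0,1}`` or the ``{0,1,2}`` dosage
dialect) and are encoded to ``{-1, 0, 1}`` = ``{aa, Aa, AA}`` where ``A`` is
the reference allele when known, otherwise the most common allele (ties
broken lexicographically).  Phenotypes are min-max normalized to [0, 1].
Missing genotype calls are a hard error — upstream imputation is expected —
while lines with missing phenotype values for any required trait are removed
from both tables.

The canonical on-disk format is tab-delimited text: first column the line
id, header row the marker/trait ids.  VCF ingestion (biallelic records only)
is available when ``cyvcf2`` is installed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    AlignmentError,
    DegenerateTraitError,
    EmptyDatasetError,
    GenotypeFormatError,
    GenotypeMatrix,
    PhenotypeTable,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RawGenotypeTable",
    "DatasetManifest",
    "encode_genotype_calls",
    "normalize_phenotypes",
    "filter_missing_lines",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "read_phenotype_tsv",
    "write_phenotype_tsv",
    "read_vcf",
]

_MISSING_TOKENS = {"", "NA", "NN", "N", "./.", ".|.", "--", "nan"}


@dataclass
class RawGenotypeTable:
    """Unencoded genotype calls: allele-pair strings or numeric dosages."""

    line_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray  # (n, p), dtype object (strings) or numeric
    ref_alleles: list[str] | None = None  # per-marker reference allele, if known


@dataclass
class DatasetManifest:
    """Paths and options describing one genotype+phenotype dataset."""

    genotype_path: str
    phenotype_path: str
    trait_names: list[str]
    encoding: str = "auto"  # auto | signed | dosage | alleles
    normalize: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DatasetManifest":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        manifest = cls(**raw)
        for p in (manifest.genotype_path, manifest.phenotype_path):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        return manifest

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "genotype_path": self.genotype_path,
                    "phenotype_path": self.phenotype_path,
                    "trait_names": list(self.trait_names),
                    "encoding": self.encoding,
                    "normalize": self.normalize,
                },
                fh,
            )


def _encode_string_column(
    col: np.ndarray, marker: str, ref_allele: str | None
) -> np.ndarray:
    """Encode one marker column of allele-pair strings."""
    alleles: dict[str, int] = {}
    for call in col:
        call = str(call).strip()
        if call in _MISSING_TOKENS:
            raise GenotypeFormatError(
                f"marker {marker!r} has a missing call; impute upstream "
                "(this pipeline expects pre-imputed genotypes)"
            )
        if len(call) != 2:
            raise GenotypeFormatError(
                f"marker {marker!r}: call {call!r} is not an allele pair"
            )
        for a in call:
            alleles[a] = alleles.get(a, 0) + 1
    if len(alleles) > 2:
        raise GenotypeFormatError(
            f"marker {marker!r} has {len(alleles)} alleles; only biallelic "
            "markers are supported"
        )
    if ref_allele is not None:
        major = ref_allele
        if major not in alleles and len(alleles) == 2:
            raise GenotypeFormatError(
                f"marker {marker!r}: reference allele {major!r} not observed"
            )
    else:
        # most common allele; ties broken lexicographically (smallest wins)
        major = min(alleles, key=lambda a: (-alleles[a], a))
    out = np.empty(len(col), dtype=np.int8)
    for i, call in enumerate(col):
        n_major = sum(1 for a in str(call).strip() if a == major)
        out[i] = n_major - 1  # 0,1,2 copies of A -> -1,0,1
    return out


def encode_genotype_calls(raw: RawGenotypeTable) -> GenotypeMatrix:
    """Encode raw calls to the signed convention {-1, 0, 1} = {aa, Aa, AA}.

    ``A`` is the reference allele when ``raw.ref_alleles`` is given, otherwise
    the most common allele at the marker.  Numeric inputs are accepted in the
    signed dialect (returned unchanged, so encoding is idempotent) or the
    {0, 1, 2} dosage dialect (shifted to signed).  Markers with more than two
    alleles, and missing calls, raise :class:`GenotypeFormatError`.
    """
    calls = np.asarray(raw.calls)
    if calls.dtype.kind in "ifu":
        vals = np.unique(calls)
        if np.isin(vals, (-1, 0, 1)).all():
            encoded = calls.astype(np.int8)
        elif np.isin(vals, (0, 1, 2)).all():
            encoded = (calls - 1).astype(np.int8)
        else:
            raise GenotypeFormatError(
                "numeric genotype values must be in {-1,0,1} or {0,1,2}"
            )
        if np.asarray(raw.calls, dtype=float).size and np.isnan(
            np.asarray(raw.calls, dtype=float)
        ).any():
            raise GenotypeFormatError("missing genotype calls; impute upstream")
    else:
        encoded = np.empty(calls.shape, dtype=np.int8)
        for j, marker in enumerate(raw.marker_ids):
            ref = raw.ref_alleles[j] if raw.ref_alleles is not None else None
            encoded[:, j] = _encode_string_column(calls[:, j], marker, ref)
    return GenotypeMatrix(
        line_ids=list(raw.line_ids),
        marker_ids=list(raw.marker_ids),
        calls=encoded,
    )


def normalize_phenotypes(
    values: np.ndarray, reference: np.ndarray | None = None
) -> np.ndarray:
    """Min-max normalize one trait vector: (v - min)/(max - min).

    By default min and max come from ``values`` itself (the full-data
    convention, applied before splitting).  Passing ``reference`` — e.g. the
    training-line values — gives the strict no-leakage variant: the range is
    taken from the reference only, so test lines may fall slightly outside
    [0, 1].
    """
    values = np.asarray(values, dtype=float)
    ref = values if reference is None else np.asarray(reference, dtype=float)
    vmin, vmax = np.nanmin(ref), np.nanmax(ref)
    if vmax == vmin:
        raise DegenerateTraitError("trait is constant; cannot normalize")
    return (values - vmin) / (vmax - vmin)


def filter_missing_lines(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    required_traits: list[str] | None = None,
) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Keep only lines with complete records for all required traits.

    Lines present in one table but not the other are dropped with a logged
    warning.  Output tables are row-aligned on the retained line ids, in
    genotype order.  Raises :class:`EmptyDatasetError` if nothing survives.
    """
    if required_traits is None:
        required_traits = list(phenotypes.trait_names)
    for t in required_traits:
        if t not in phenotypes.trait_names:
            raise AlignmentError(f"trait {t!r} not in phenotype table")

    geno_ids = set(genotypes.line_ids)
    pheno_ids = set(phenotypes.line_ids)
    only_pheno = pheno_ids - geno_ids
    only_geno = geno_ids - pheno_ids
    if only_pheno:
        logger.warning(
            "%d line(s) in phenotypes absent from genotypes; dropped: %s",
            len(only_pheno),
            sorted(only_pheno)[:5],
        )
    if only_geno:
        logger.warning(
            "%d line(s) in genotypes absent from phenotypes; dropped",
            len(only_geno),
        )

    cols = [phenotypes.trait_names.index(t) for t in required_traits]
    pheno_pos = {lid: i for i, lid in enumerate(phenotypes.line_ids)}
    keep_geno, keep_pheno = [], []
    for gi, lid in enumerate(genotypes.line_ids):
        pi = pheno_pos.get(lid)
        if pi is None:
            continue
        if np.isnan(phenotypes.values[pi, cols]).any():
            continue
        keep_geno.append(gi)
        keep_pheno.append(pi)
    if len(keep_geno) < 2:
        raise EmptyDatasetError(
            "fewer than two lines have complete genotype and phenotype records"
        )
    return (
        genotypes.subset_lines(np.asarray(keep_geno)),
        phenotypes.subset_lines(np.asarray(keep_pheno)),
    )


# ---------------------------------------------------------------------------
# tab-delimited readers/writers (first column = line id, header = marker ids)

def write_genotype_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        genotypes.calls, index=genotypes.line_ids, columns=genotypes.marker_ids
    )
    df.to_csv(path, sep="\t", index_label="line_id")


def read_genotype_tsv(path: str | Path, encoding: str = "auto") -> GenotypeMatrix:
    """Read a genotype table; non-signed dialects are encoded on the fly."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    raw = RawGenotypeTable(
        line_ids=[str(i) for i in df.index],
        marker_ids=[str(c) for c in df.columns],
        calls=df.to_numpy(),
    )
    return encode_genotype_calls(raw)


def write_phenotype_tsv(phenotypes: PhenotypeTable, path: str | Path) -> None:
    df = pd.DataFrame(
        phenotypes.values, index=phenotypes.line_ids, columns=phenotypes.trait_names
    )
    # %.17g guarantees float64 round-trips bit-exactly through text
    df.to_csv(path, sep="\t", index_label="line_id", float_format="%.17g")


def read_phenotype_tsv(path: str | Path, normalize: bool = False) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    values = df.to_numpy(dtype=float)
    if normalize:
        values = np.column_stack(
            [normalize_phenotypes(values[:, j]) for j in range(values.shape[1])]
        )
    return PhenotypeTable(
        line_ids=[str(i) for i in df.index],
        trait_names=[str(c) for c in df.columns],
        values=values,
    )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into the signed encoding.

    GT ``0/0`` (hom ref) -> 1, ``0/1`` -> 0, ``1/1`` -> -1, taking the
    reference allele as ``A``.  Multi-allelic records and missing genotypes
    raise :class:`GenotypeFormatError`.  Requires the optional ``cyvcf2``
    dependency.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    marker_ids: list[str] = []
    columns: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise GenotypeFormatError(
                f"multi-allelic record at {var.CHROM}:{var.POS}; not supported"
            )
        gts = var.gt_types  # 0=hom ref, 1=het, 2=unknown, 3=hom alt
        if (gts == 2).any():
            raise GenotypeFormatError(
                f"missing genotype at {var.CHROM}:{var.POS}; impute upstream"
            )
        col = np.where(gts == 0, 1, np.where(gts == 1, 0, -1)).astype(np.int8)
        marker_ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        columns.append(col)
    if not columns:
        raise EmptyDatasetError("VCF contains no usable records")
    return GenotypeMatrix(
        line_ids=samples, marker_ids=marker_ids, calls=np.column_stack(columns)
    )


def load_dataset(manifest: DatasetManifest) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Load, encode, filter and (optionally) normalize a dataset."""
    genotypes = read_genotype_tsv(manifest.genotype_path, manifest.encoding)
    phenotypes = read_phenotype_tsv(manifest.phenotype_path)
    genotypes, phenotypes = filter_missing_lines(
        genotypes, phenotypes, manifest.trait_names
    )
    cols = [phenotypes.trait_names.index(t) for t in manifest.trait_names]
    values = phenotypes.values[:, cols]
    if manifest.normalize:
        values = np.column_stack(
            [normalize_phenotypes(values[:, j]) for j in range(values.shape[1])]
        )
    phenotypes = PhenotypeTable(
        line_ids=list(phenotypes.line_ids),
        trait_names=list(manifest.trait_names),
        values=values,
    )
    return genotypes, phenotypes
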