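"""File formats: dataset TSV serialization, variant lists (VCF/TSV), annotation.

The dataset dialect is a wide TSV with columns ``chrom, pos, id, ref, alt``
followed by one count column per sample x nucleotide x strand named
``<sample>.<nt>.<plus|minus|both>`` and, when genotypes are attached, one
``<sample>.GT`` column.  Strandedness is recorded in a ``#strandedness=`` header
line so the file round-trips losslessly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .dataset import (
    ASEDataset,
    NUCLEOTIDES,
    SNPVariant,
    STRANDS,
    normalize_genotype,
)
from .errors import ValidationError

# --------------------------------------------------------------------- dataset


def write_dataset_tsv(ds: ASEDataset, path: str | Path) -> None:
    """Serialize an :class:`ASEDataset` to the wide TSV dialect."""
    cols: dict[str, object] = {
        "chrom": [v.chrom for v in ds.variants],
        "pos": [v.pos for v in ds.variants],
        "id": [v.id for v in ds.variants],
        "ref": [v.ref_allele if v.ref_allele else "." for v in ds.variants],
        "alt": [v.alt_allele if v.alt_allele else "." for v in ds.variants],
    }
    for i, sample in enumerate(ds.samples):
        for k, nt in enumerate(NUCLEOTIDES):
            for m, strand in enumerate(STRANDS):
                cols[f"{sample}.{nt}.{strand}"] = ds.counts[i, :, k, m]
        if ds.genotypes is not None:
            cols[f"{sample}.GT"] = [g if g is not None else "." for g in ds.genotypes[i]]
    frame = pd.DataFrame(cols)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#strandedness={ds.strandedness}\n")
        fh.write(f"#samples={','.join(ds.samples)}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_dataset_tsv(path: str | Path) -> ASEDataset:
    """Read the wide TSV dialect back into an :class:`ASEDataset`."""
    path = Path(path)
    strandedness = "unstranded"
    samples: list[str] | None = None
    with open(path) as fh:
        offset = 0
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            if key == "strandedness":
                strandedness = value
            elif key == "samples":
                samples = value.split(",") if value else []
            offset += 1
    frame = pd.read_csv(path, sep="\t", skiprows=offset, dtype={"chrom": str, "id": str})
    if samples is None:
        # Recover sample order from count column names.
        samples = []
        for col in frame.columns:
            parts = col.split(".")
            if len(parts) == 3 and parts[1] in NUCLEOTIDES and parts[0] not in samples:
                samples.append(parts[0])
    variants = [
        SNPVariant(
            chrom=str(row.chrom),
            pos=int(row.pos),
            id=str(row.id),
            ref_allele=None if row.ref == "." else row.ref,
            alt_allele=None if row.alt == "." else row.alt,
        )
        for row in frame.itertuples()
    ]
    counts = np.zeros((len(samples), len(variants), 4, 3), dtype=np.int64)
    for i, sample in enumerate(samples):
        for k, nt in enumerate(NUCLEOTIDES):
            for m, strand in enumerate(STRANDS):
                counts[i, :, k, m] = frame[f"{sample}.{nt}.{strand}"].to_numpy()
    genotypes = None
    gt_cols = [f"{s}.GT" for s in samples]
    if all(c in frame.columns for c in gt_cols):
        genotypes = np.empty((len(samples), len(variants)), dtype=object)
        for i, col in enumerate(gt_cols):
            genotypes[i] = [None if g == "." else g for g in frame[col].astype(str)]
    return ASEDataset(counts, variants, samples, strandedness, genotypes=genotypes)


# --------------------------------------------------------------------- variants


@dataclass
class VariantReadStats:
    """Bookkeeping from a variant-list parse."""

    n_records: int = 0
    n_snvs: int = 0
    n_skipped_non_snv: int = 0


def read_variants(
    path: str | Path,
    with_genotypes: bool = False,
    stats: VariantReadStats | None = None,
) -> list[SNPVariant] | tuple[list[SNPVariant], list[str], np.ndarray]:
    """Read a variant list from VCF (plain or bgzipped) or 4-column TSV.

    Only single-nucleotide variants are admitted; indels/MNVs are skipped and
    counted in ``stats``.  The TSV dialect has columns chrom, pos, ref, alt
    with an optional leading header and optional 5th id column.

    With ``with_genotypes=True`` (VCF only) also returns the sample list and a
    (n_samples, n_variants) object array of normalised GT calls.
    """
    path = Path(path)
    if stats is None:
        stats = VariantReadStats()
    if _looks_like_vcf(path):
        return _read_vcf(path, with_genotypes, stats)
    if with_genotypes:
        raise ValidationError("genotypes can only be read from VCF input")
    return _read_tsv_variants(path, stats)


def _looks_like_vcf(path: Path) -> bool:
    if path.suffix in (".vcf", ".bcf") or path.name.endswith(".vcf.gz"):
        return True
    opener = open
    if path.suffix == ".gz":
        import gzip

        opener = gzip.open
    try:
        with opener(path, "rt") as fh:
            first = fh.readline()
        return first.startswith("##fileformat=VCF")
    except (OSError, UnicodeDecodeError):
        return False


def _read_vcf(path: Path, with_genotypes: bool, stats: VariantReadStats):
    variants: list[SNPVariant] = []
    gt_rows: list[list[str | None]] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            stats.n_records += 1
            alts = rec.alts or ()
            if (
                len(rec.ref) != 1
                or len(alts) < 1
                or any(len(a) != 1 for a in alts)
                or rec.ref not in NUCLEOTIDES
                or alts[0] not in NUCLEOTIDES
            ):
                stats.n_skipped_non_snv += 1
                continue
            stats.n_snvs += 1
            vid = rec.id if rec.id else f"{rec.chrom}_{rec.pos}"
            variants.append(
                SNPVariant(chrom=rec.chrom, pos=rec.pos, id=vid, ref_allele=rec.ref, alt_allele=alts[0])
            )
            if with_genotypes:
                row = []
                for s in samples:
                    gt = rec.samples[s].get("GT")
                    if gt is None or any(a is None for a in gt):
                        row.append(None)
                    else:
                        row.append(normalize_genotype("/".join(str(min(a, 1)) for a in gt)))
                gt_rows.append(row)
    if with_genotypes:
        genotypes = np.empty((len(samples), len(variants)), dtype=object)
        for j, row in enumerate(gt_rows):
            for i, g in enumerate(row):
                genotypes[i, j] = g
        return variants, samples, genotypes
    return variants


def _read_tsv_variants(path: Path, stats: VariantReadStats) -> list[SNPVariant]:
    variants: list[SNPVariant] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0].lower() in ("chrom", "chr", "chromosome"):
                continue  # header row
            if len(fields) < 4:
                raise ValidationError(
                    f"{path}: expected >= 4 tab-separated columns (chrom, pos, ref, alt)"
                )
            chrom, pos_s, ref, alt = fields[:4]
            stats.n_records += 1
            if len(ref) != 1 or len(alt) != 1 or ref not in NUCLEOTIDES or alt not in NUCLEOTIDES:
                stats.n_skipped_non_snv += 1
                continue
            stats.n_snvs += 1
            vid = fields[4] if len(fields) > 4 else f"{chrom}_{pos_s}"
            variants.append(SNPVariant(chrom=chrom, pos=int(pos_s), id=vid, ref_allele=ref, alt_allele=alt))
    return variants


# ------------------------------------------------------------------ annotation


@dataclass(frozen=True)
class AnnotationFeature:
    """One gene/exon interval for the location-plot track (1-based, closed)."""

    chrom: str
    start: int
    end: int
    name: str
    strand: str
    feature: str  # "gene" or "exon"


def read_annotation(path: str | Path) -> list[AnnotationFeature]:
    """Parse gene/exon features from GTF or 6-column BED.

    GTF: only ``gene`` and ``exon`` features are kept; the gene name is taken
    from ``gene_name`` or ``gene_id``.  BED intervals (0-based half-open) are
    converted to 1-based closed coordinates and typed as genes.
    """
    path = Path(path)
    feats: list[AnnotationFeature] = []
    if path.suffix.lower() in (".gtf", ".gff"):
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2] not in ("gene", "exon"):
                    continue
                attrs = f[8]
                name = _gtf_attr(attrs, "gene_name") or _gtf_attr(attrs, "gene_id") or "?"
                feats.append(
                    AnnotationFeature(f[0], int(f[3]), int(f[4]), name, f[6], f[2])
                )
    else:
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 3:
                    continue
                name = f[3] if len(f) > 3 else "?"
                strand = f[5] if len(f) > 5 else "."
                feats.append(AnnotationFeature(f[0], int(f[1]) + 1, int(f[2]), name, strand, "gene"))
    return feats


def _gtf_attr(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + " ") or part.startswith(key + "="):
            return part.split(None, 1)[1].strip().strip('"')
    return None
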