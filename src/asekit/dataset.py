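"""Strand-aware allele-count container for allele-specific expression analysis.

The central object is :class:`ASEDataset`, a four-axis integer tensor of allele
counts indexed ``[sample][variant][nucleotide][strand]`` together with the
variant coordinates, sample identifiers, optional phenotypes and optional
diploid genotypes.  It is the in-memory unit every other module produces or
consumes: the BAM import step fills one, the imbalance tests read one, and the
plots draw one.

Axes are fixed:

* nucleotide axis is exactly ``(A, C, G, T)`` — reads showing N, insertions,
  deletions or reference skips at the SNP base are never counted;
* strand axis is ``(plus, minus, both)``.  For stranded libraries the ``both``
  slice is the element-wise sum of ``plus`` and ``minus``; for unstranded data
  all counts live in ``both`` and the per-strand slices are zero.

All user-facing coordinates are 1-based and fully closed, matching VCF/GTF.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from .errors import DatasetStateError, DimensionError, ValidationError

NUCLEOTIDES: tuple[str, ...] = ("A", "C", "G", "T")
STRANDS: tuple[str, ...] = ("plus", "minus", "both")
STRANDEDNESS_MODES: tuple[str, ...] = ("unstranded", "fr-firststrand", "fr-secondstrand")

NT_INDEX = {nt: i for i, nt in enumerate(NUCLEOTIDES)}
STRAND_INDEX = {s: i for i, s in enumerate(STRANDS)}

#: Diploid genotype tokens.  Phased separators are normalised to "/" on input;
#: phase information is never used.
GT_HOM_REF = "0/0"
GT_HET = "0/1"
GT_HOM_ALT = "1/1"


def normalize_genotype(token: str | None) -> str | None:
    """Map a VCF-style GT token onto {0/0, 0/1, 1/1} or None (no-call).

    ``0|1`` and ``1/0`` both become ``0/1``; ``./.`` and ``.`` become None.
    Anything referencing an allele index above 1 is rejected (SNV biallelic
    model only).
    """
    if token is None:
        return None
    t = token.replace("|", "/").strip()
    if t in ("", ".", "./.", ".|."):
        return None
    parts = t.split("/")
    if len(parts) != 2 or not all(p in ("0", "1") for p in parts):
        raise ValidationError(f"unsupported genotype token {token!r} (biallelic SNVs only)")
    a, b = sorted(parts)
    return f"{a}/{b}"


@dataclass(frozen=True)
class SNPVariant:
    """A single-nucleotide variant position.

    Parameters
    ----------
    chrom : str
        Sequence (chromosome/contig) name.
    pos : int
        1-based coordinate of the variant base.
    id : str
        Variant identifier (rsID or synthetic).
    ref_allele, alt_allele : str or None
        Reference / alternative nucleotide, when known.  Must differ and be
        one of A, C, G, T.
    """

    chrom: str
    pos: int
    id: str
    ref_allele: str | None = None
    alt_allele: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"variant {self.id}: pos must be >= 1, got {self.pos}")
        for name in ("ref_allele", "alt_allele"):
            allele = getattr(self, name)
            if allele is not None and allele not in NUCLEOTIDES:
                raise ValidationError(
                    f"variant {self.id}: {name} must be one of A/C/G/T, got {allele!r}"
                )
        if (
            self.ref_allele is not None
            and self.alt_allele is not None
            and self.ref_allele == self.alt_allele
        ):
            raise ValidationError(f"variant {self.id}: ref and alt alleles are identical")

    @property
    def has_ref_alt(self) -> bool:
        return self.ref_allele is not None and self.alt_allele is not None


class TopAlleles(NamedTuple):
    """Resolved (ref, alt) pair for one variant."""

    ref: str
    alt: str
    from_metadata: bool
    low_confidence: bool


@dataclass(frozen=True)
class FractionMatrix:
    """Per-sample x per-variant reference-allele fractions.

    ``values[i, j] = ref / (ref + alt)`` on the chosen strand; ``NaN`` marks
    cells whose ref+alt depth is below ``min_depth`` (never coded as 0 or 1).
    """

    values: np.ndarray
    samples: tuple[str, ...]
    variant_ids: tuple[str, ...]
    strand: str
    min_depth: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=list(self.samples), columns=list(self.variant_ids))


class ASEDataset:
    """Allele counts over SNPs for a set of samples, with metadata.

    Use :func:`build_dataset` (or :meth:`ASEDataset.build`) to construct one
    from raw arrays with full validation and strand-sum enforcement, or
    :func:`asekit.counting.count_alleles` to import from BAM files.

    Attributes
    ----------
    counts : ndarray of int, shape (n_samples, n_variants, 4, 3)
        Allele counts; axes are samples, variants, (A,C,G,T), (plus,minus,both).
    samples : tuple of str
    variants : tuple of SNPVariant
    strandedness : {"unstranded", "fr-firststrand", "fr-secondstrand"}
    phenotypes : dict mapping sample -> {key: value}, optional
    genotypes : object ndarray (n_samples, n_variants) of {"0/0","0/1","1/1",None}, optional
        Externally provided genotype calls; always take precedence over calls
        inferred from counts.
    """

    def __init__(
        self,
        counts: np.ndarray,
        variants: Sequence[SNPVariant],
        samples: Sequence[str],
        strandedness: str = "unstranded",
        phenotypes: Mapping[str, Mapping[str, object]] | None = None,
        genotypes: np.ndarray | None = None,
        *,
        validate: bool = True,
    ) -> None:
        self.counts = np.asarray(counts)
        self.variants: tuple[SNPVariant, ...] = tuple(variants)
        self.samples: tuple[str, ...] = tuple(str(s) for s in samples)
        self.strandedness = strandedness
        self.phenotypes = dict(phenotypes) if phenotypes is not None else None
        if genotypes is not None:
            genotypes = np.asarray(genotypes, dtype=object)
        self.genotypes = genotypes
        if validate:
            self._validate()

    # ------------------------------------------------------------------ build

    @classmethod
    def build(
        cls,
        counts: np.ndarray,
        variants: Sequence[SNPVariant],
        samples: Sequence[str],
        strandedness: str = "unstranded",
        phenotypes: Mapping[str, Mapping[str, object]] | None = None,
        genotypes: np.ndarray | None = None,
    ) -> "ASEDataset":
        """Validated construction; recomputes the ``both`` slice when stranded.

        Raises
        ------
        DimensionError
            If the tensor shape disagrees with the sample/variant lists.
        ValidationError
            On negative or non-integer counts, or an unknown strandedness token.
        """
        if strandedness not in STRANDEDNESS_MODES:
            raise ValidationError(
                f"unknown strandedness {strandedness!r}; expected one of {STRANDEDNESS_MODES}"
            )
        arr = np.asarray(counts)
        expected = (len(samples), len(variants), 4, 3)
        if arr.shape != expected:
            raise DimensionError(f"counts shape {arr.shape} does not match {expected}")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.mod(arr, 1) == 0):
                raise ValidationError("counts must be integers")
            arr = arr.astype(np.int64)
        else:
            arr = arr.astype(np.int64, copy=True)
        if np.any(arr < 0):
            raise ValidationError("counts must be non-negative")
        if strandedness != "unstranded":
            both = arr[..., STRAND_INDEX["plus"]] + arr[..., STRAND_INDEX["minus"]]
            arr = arr.copy()
            arr[..., STRAND_INDEX["both"]] = both
        return cls(arr, variants, samples, strandedness, phenotypes, genotypes)

    def _validate(self) -> None:
        expected = (len(self.samples), len(self.variants), 4, 3)
        if self.counts.shape != expected:
            raise DimensionError(f"counts shape {self.counts.shape} does not match {expected}")
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise ValidationError("counts must be an integer array")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")
        if self.strandedness not in STRANDEDNESS_MODES:
            raise ValidationError(f"unknown strandedness {self.strandedness!r}")
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample identifiers")
        plus = self.counts[..., STRAND_INDEX["plus"]]
        minus = self.counts[..., STRAND_INDEX["minus"]]
        both = self.counts[..., STRAND_INDEX["both"]]
        if self.strandedness == "unstranded":
            if np.any(plus) or np.any(minus):
                raise ValidationError(
                    "unstranded dataset must keep all counts in the 'both' slice"
                )
        else:
            if np.any(both != plus + minus):
                raise ValidationError("'both' slice must equal plus + minus for stranded data")
        if self.genotypes is not None and self.genotypes.shape != expected[:2]:
            raise DimensionError(
                f"genotypes shape {self.genotypes.shape} does not match {expected[:2]}"
            )

    # ------------------------------------------------------------- properties

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> tuple[str, ...]:
        return tuple(v.id for v in self.variants)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample id {sample!r}") from None

    def variant_index(self, variant_id: str) -> int:
        for j, v in enumerate(self.variants):
            if v.id == variant_id:
                return j
        raise KeyError(f"unknown variant id {variant_id!r}")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<ASEDataset {self.n_samples} samples x {self.n_variants} variants, "
            f"strandedness={self.strandedness}>"
        )

    # --------------------------------------------------------------- subsetting

    def subset(
        self,
        region: str | None = None,
        samples: Sequence[str] | None = None,
    ) -> "ASEDataset":
        """Restrict to a genomic region and/or a sample subset.

        ``region`` is ``"chrom"`` or ``"chrom:start-end"`` with a 1-based fully
        closed interval; variants with ``start <= pos <= end`` are retained in
        their original order.  An empty result is a valid empty dataset.  An
        unknown sample id raises ``KeyError``.
        """
        v_idx = np.arange(self.n_variants)
        if region is not None:
            chrom, start, end = parse_region(region)
            keep = [
                j
                for j, v in enumerate(self.variants)
                if v.chrom == chrom and (start is None or start <= v.pos <= end)
            ]
            v_idx = np.asarray(keep, dtype=int)
        s_idx = np.arange(self.n_samples)
        if samples is not None:
            s_idx = np.asarray([self.sample_index(s) for s in samples], dtype=int)
        counts = self.counts[np.ix_(s_idx, v_idx)]
        genotypes = self.genotypes[np.ix_(s_idx, v_idx)] if self.genotypes is not None else None
        phenos = None
        if self.phenotypes is not None:
            keep_samples = [self.samples[i] for i in s_idx]
            phenos = {s: self.phenotypes[s] for s in keep_samples if s in self.phenotypes}
        return ASEDataset(
            counts,
            [self.variants[j] for j in v_idx],
            [self.samples[i] for i in s_idx],
            self.strandedness,
            phenos,
            genotypes,
        )

    # ------------------------------------------------------------ ref/alt logic

    def top_alleles(self) -> list[TopAlleles]:
        """Resolve a (ref, alt) pair per variant.

        Variants carrying ref/alt metadata return it unchanged.  Otherwise the
        two nucleotides with the highest total count (summed over samples on
        the ``both`` strand) are returned, ties broken alphabetically; a
        zero-count variant yields ("A", "C") flagged low-confidence.
        """
        totals = self.counts[..., STRAND_INDEX["both"]].sum(axis=0)  # (n_variants, 4)
        out: list[TopAlleles] = []
        for j, v in enumerate(self.variants):
            if v.has_ref_alt:
                out.append(TopAlleles(v.ref_allele, v.alt_allele, True, False))
                continue
            order = sorted(range(4), key=lambda i: (-totals[j, i], NUCLEOTIDES[i]))
            ref, alt = NUCLEOTIDES[order[0]], NUCLEOTIDES[order[1]]
            out.append(TopAlleles(ref, alt, False, bool(totals[j].sum() == 0)))
        return out

    def assign_top_alleles(self) -> "ASEDataset":
        """Return a dataset whose variants all carry resolved ref/alt metadata."""
        tops = self.top_alleles()
        variants = [
            v if v.has_ref_alt else replace(v, ref_allele=t.ref, alt_allele=t.alt)
            for v, t in zip(self.variants, tops)
        ]
        return ASEDataset(
            self.counts, variants, self.samples, self.strandedness, self.phenotypes, self.genotypes
        )

    def _require_ref_alt(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (ref_idx, alt_idx) nucleotide index arrays, or raise."""
        missing = [v.id for v in self.variants if not v.has_ref_alt]
        if missing:
            raise DatasetStateError(
                f"{len(missing)} variant(s) lack ref/alt alleles (e.g. {missing[0]!r}); "
                "call top_alleles()/assign_top_alleles() first or supply ref/alt metadata"
            )
        ref_idx = np.array([NT_INDEX[v.ref_allele] for v in self.variants])
        alt_idx = np.array([NT_INDEX[v.alt_allele] for v in self.variants])
        return ref_idx, alt_idx

    def ref_alt_counts(self, strand: str = "both") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-cell (ref, alt, other) counts on one strand.

        ``other`` is the summed count of the two non-(ref, alt) nucleotides —
        a sequencing/mapping error diagnostic, never part of the test depth.
        """
        if strand not in STRANDS:
            raise ValidationError(f"unknown strand {strand!r}; expected one of {STRANDS}")
        ref_idx, alt_idx = self._require_ref_alt()
        slab = self.counts[..., STRAND_INDEX[strand]]  # (S, V, 4)
        cols = np.arange(self.n_variants)
        ref = slab[:, cols, ref_idx]
        alt = slab[:, cols, alt_idx]
        other = slab.sum(axis=2) - ref - alt
        return ref, alt, other

    def allele_fractions(self, strand: str = "both", min_depth: int = 1) -> FractionMatrix:
        """Reference-allele fraction ``ref/(ref+alt)`` per sample x variant.

        Cells with ref+alt depth below ``min_depth`` are NaN.  Counts of the
        two other nucleotides are ignored.
        """
        if min_depth < 1:
            raise ValidationError("min_depth must be >= 1")
        ref, alt, _ = self.ref_alt_counts(strand)
        depth = ref + alt
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(depth >= min_depth, ref / np.maximum(depth, 1), np.nan)
        return FractionMatrix(values, self.samples, self.variant_ids, strand, min_depth)

    # --------------------------------------------------------------- genotypes

    def infer_genotypes(self, min_depth: int = 10, het_min_minor: float = 0.10) -> np.ndarray:
        """Call genotypes from the counts alone.

        A cell is heterozygous when ref+alt depth >= ``min_depth`` and the
        minor-of-(ref, alt) fraction is at least ``het_min_minor``;
        homozygous for the majority allele when the minor fraction is below
        the band; no-call (None) under the depth gate.
        """
        ref, alt, _ = self.ref_alt_counts("both")
        depth = ref + alt
        calls = np.empty(depth.shape, dtype=object)
        calls[:] = None
        with np.errstate(invalid="ignore", divide="ignore"):
            minor = np.minimum(ref, alt) / np.maximum(depth, 1)
        ok = depth >= min_depth
        het = ok & (minor >= het_min_minor)
        hom_ref = ok & ~het & (ref >= alt)
        hom_alt = ok & ~het & (ref < alt)
        calls[het] = GT_HET
        calls[hom_ref] = GT_HOM_REF
        calls[hom_alt] = GT_HOM_ALT
        return calls

    def effective_genotypes(
        self, min_depth: int = 10, het_min_minor: float = 0.10
    ) -> np.ndarray:
        """Provided genotypes where present, count-inferred calls elsewhere."""
        inferred = self.infer_genotypes(min_depth=min_depth, het_min_minor=het_min_minor)
        if self.genotypes is None:
            return inferred
        provided = self.genotypes
        out = inferred.copy()
        mask = np.vectorize(lambda g: g is not None, otypes=[bool])(provided)
        out[mask] = provided[mask]
        return out

    # --------------------------------------------------------------------- MAF

    def maf(self, min_depth: int = 10, het_min_minor: float = 0.10) -> np.ndarray:
        """Minor-allele frequency per variant across samples.

        With f the ref-allele frequency over diploid calls,
        ``f = (2*hom_ref + het) / (2*called)``, MAF = min(f, 1-f).  No-calls
        drop out of the denominator; a variant with zero called samples gets
        NaN.
        """
        gts = self.effective_genotypes(min_depth=min_depth, het_min_minor=het_min_minor)
        maf = np.full(self.n_variants, np.nan)
        for j in range(self.n_variants):
            col = gts[:, j]
            called = [g for g in col if g is not None]
            if not called:
                continue
            hom_ref = sum(g == GT_HOM_REF for g in called)
            het = sum(g == GT_HET for g in called)
            f = (2 * hom_ref + het) / (2 * len(called))
            maf[j] = min(f, 1.0 - f)
        return maf

    def maf_filter(self, threshold: float = 0.1, **maf_kwargs) -> "ASEDataset":
        """Retain variants with MAF strictly greater than ``threshold``."""
        maf = self.maf(**maf_kwargs)
        keep = np.where(np.nan_to_num(maf, nan=-1.0) > threshold)[0]
        counts = self.counts[:, keep]
        genotypes = self.genotypes[:, keep] if self.genotypes is not None else None
        return ASEDataset(
            counts,
            [self.variants[j] for j in keep],
            self.samples,
            self.strandedness,
            self.phenotypes,
            genotypes,
        )


def build_dataset(
    counts: np.ndarray,
    variants: Sequence[SNPVariant],
    samples: Sequence[str],
    strandedness: str = "unstranded",
    phenotypes: Mapping[str, Mapping[str, object]] | None = None,
    genotypes: np.ndarray | None = None,
) -> ASEDataset:
    """Module-level alias for :meth:`ASEDataset.build`."""
    return ASEDataset.build(counts, variants, samples, strandedness, phenotypes, genotypes)


def parse_region(region: str) -> tuple[str, int | None, int | None]:
    """Parse ``chrom`` or ``chrom:start-end`` (1-based, fully closed)."""
    if ":" not in region:
        return region, None, None
    chrom, _, span = region.rpartition(":")
    try:
        start_s, _, end_s = span.partition("-")
        start, end = int(start_s.replace(",", "")), int(end_s.replace(",", ""))
    except ValueError:
        raise ValidationError(f"cannot parse region {region!r}; expected chrom:start-end") from None
    if start < 1 or end < start:
        raise ValidationError(f"bad interval in region {region!r}")
    return chrom, start, end
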