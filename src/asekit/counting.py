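"""Import allele counts from BAM files into an :class:`ASEDataset`.

For every variant a single-base pileup is taken from each sample's
coordinate-sorted, indexed BAM.  Each admitted read contributes exactly one
count to ``counts[sample][variant][base][strand]``; a read pair whose two mates
both overlap the SNP contributes once (the first-encountered mate by query
name wins — a fragment is one observation of one allele).  Reads whose
alignment places no base on the SNP (deletion, reference skip, soft clip)
contribute nothing, as do bases outside A/C/G/T.

Strand assignment follows the declared library protocol and is never
auto-detected:

* ``unstranded`` — everything lands on the ``both`` slice;
* ``fr-firststrand`` (dUTP) — read2's mapping orientation equals the
  transcript orientation (single-end reads are treated as read1);
* ``fr-secondstrand`` — the inverse.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .dataset import ASEDataset, NT_INDEX, SNPVariant, STRAND_INDEX, STRANDEDNESS_MODES
from .errors import MalformedRecordError, ValidationError

#: Rejection reason tokens, in the order checks are applied.
REJECT_REASONS = ("unmapped", "secondary", "duplicate", "not_proper", "mapq", "baseq")


@dataclass(frozen=True)
class CountFilter:
    """Read/base admission rules for pileup counting.

    Defaults (MAPQ >= 20, base quality >= 10, proper pairs only, drop
    duplicates and secondary/supplementary alignments) follow common
    allele-specific-expression practice; every threshold is inclusive and
    overridable.  ``require_proper_pair`` only applies to paired reads.
    """

    min_mapq: int = 20
    min_baseq: int = 10
    require_proper_pair: bool = True
    drop_duplicates: bool = True
    drop_secondary_supplementary: bool = True

    def __post_init__(self) -> None:
        if self.min_mapq < 0 or self.min_baseq < 0:
            raise ValidationError("quality thresholds must be >= 0")

    @classmethod
    def permissive(cls) -> "CountFilter":
        """Admit everything mapped and primary — used for simulation closure."""
        return cls(min_mapq=0, min_baseq=0, require_proper_pair=False, drop_duplicates=False)


def admit_read(
    read: pysam.AlignedSegment, flt: CountFilter, baseq: int | None = None
) -> tuple[bool, str | None]:
    """Decide whether one alignment record passes the filter.

    Returns ``(admitted, reason)`` where ``reason`` is one token from
    :data:`REJECT_REASONS` (None when admitted).  ``baseq`` is the base
    quality at the SNP position; pass None to skip the base-quality rule
    (e.g. when the record has no quality string).
    """
    if read.is_unmapped:
        return False, "unmapped"
    if flt.drop_secondary_supplementary and (read.is_secondary or read.is_supplementary):
        return False, "secondary"
    if flt.drop_duplicates and read.is_duplicate:
        return False, "duplicate"
    if flt.require_proper_pair and read.is_paired and not read.is_proper_pair:
        return False, "not_proper"
    if read.mapping_quality < flt.min_mapq:
        return False, "mapq"
    if baseq is not None and baseq < flt.min_baseq:
        return False, "baseq"
    return True, None


def fragment_strand(read: pysam.AlignedSegment, strandedness: str) -> str:
    """Transcript strand of the fragment a read belongs to.

    dUTP/fr-firststrand convention: the second-in-pair read maps in the
    transcript's orientation, so read2-forward (or read1-reverse) means a
    plus-strand transcript.  fr-secondstrand is the mirror image.  Single-end
    reads count as read1.  Unstranded data always maps to ``both``.
    """
    if strandedness not in STRANDEDNESS_MODES:
        raise ValidationError(f"unknown strandedness {strandedness!r}")
    if strandedness == "unstranded":
        return "both"
    if read.is_read1 and read.is_read2:
        raise MalformedRecordError(
            f"read {read.query_name!r} is flagged both first and second in pair"
        )
    is_read2 = read.is_read2
    forward = not read.is_reverse
    transcript_forward = forward if is_read2 else not forward
    if strandedness == "fr-secondstrand":
        transcript_forward = not transcript_forward
    return "plus" if transcript_forward else "minus"


@dataclass
class CountingReport:
    """Per-sample read admission tallies from one counting run."""

    admitted: Counter = field(default_factory=Counter)  # sample -> n admitted
    rejected: dict = field(default_factory=dict)  # sample -> Counter(reason -> n)
    mate_deduplicated: Counter = field(default_factory=Counter)
    missing_chromosomes: Counter = field(default_factory=Counter)  # chrom -> n variants

    def tally_reject(self, sample: str, reason: str) -> None:
        self.rejected.setdefault(sample, Counter())[reason] += 1

    def to_frame(self) -> pd.DataFrame:
        samples = sorted(set(self.admitted) | set(self.rejected) | set(self.mate_deduplicated))
        rows = []
        for s in samples:
            row = {"sample": s, "admitted": self.admitted.get(s, 0)}
            rej = self.rejected.get(s, Counter())
            for reason in REJECT_REASONS:
                row[f"rejected_{reason}"] = rej.get(reason, 0)
            row["mate_deduplicated"] = self.mate_deduplicated.get(s, 0)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def count_alleles(
    bam_paths: Mapping[str, str | Path] | Sequence[str | Path],
    variants: Sequence[SNPVariant],
    flt: CountFilter | None = None,
    strandedness: str = "unstranded",
) -> tuple[ASEDataset, CountingReport]:
    """Count alleles over SNPs from one indexed BAM per sample.

    Parameters
    ----------
    bam_paths : mapping sample -> path, or sequence of paths
        One coordinate-sorted, indexed BAM per sample.  For a bare sequence
        the sample names are the file stems.
    variants : sequence of SNPVariant
    flt : CountFilter, optional (defaults apply)
    strandedness : library protocol token

    Returns
    -------
    (ASEDataset, CountingReport)

    A variant on a chromosome absent from a BAM header yields zero counts and
    a warning, not an error; a missing index raises ``FileNotFoundError``
    naming the file.
    """
    if flt is None:
        flt = CountFilter()
    if strandedness not in STRANDEDNESS_MODES:
        raise ValidationError(f"unknown strandedness {strandedness!r}")
    if isinstance(bam_paths, Mapping):
        items = [(str(s), Path(p)) for s, p in bam_paths.items()]
    else:
        items = [(Path(p).stem.removesuffix(".sorted"), Path(p)) for p in bam_paths]

    counts = np.zeros((len(items), len(variants), 4, 3), dtype=np.int64)
    report = CountingReport()
    warned_chroms: set[str] = set()

    for i, (sample, path) in enumerate(items):
        with pysam.AlignmentFile(str(path)) as bam:
            if not bam.has_index():
                raise FileNotFoundError(f"BAM index missing for {path}")
            refs = set(bam.references)
            for j, v in enumerate(variants):
                if v.chrom not in refs:
                    report.missing_chromosomes[v.chrom] += 1
                    if v.chrom not in warned_chroms:
                        warnings.warn(
                            f"chromosome {v.chrom!r} absent from BAM header of {path}; "
                            "zero counts recorded",
                            stacklevel=2,
                        )
                        warned_chroms.add(v.chrom)
                    continue
                _pileup_variant(bam, v, i, j, flt, strandedness, counts, report, sample)

    if strandedness != "unstranded":
        counts[..., STRAND_INDEX["both"]] = (
            counts[..., STRAND_INDEX["plus"]] + counts[..., STRAND_INDEX["minus"]]
        )
    ds = ASEDataset(counts, variants, [s for s, _ in items], strandedness)
    return ds, report


def _pileup_variant(
    bam: pysam.AlignmentFile,
    v: SNPVariant,
    i: int,
    j: int,
    flt: CountFilter,
    strandedness: str,
    counts: np.ndarray,
    report: CountingReport,
    sample: str,
) -> None:
    """Tally one sample x variant cell via the htslib pileup engine."""
    seen: set[str] = set()
    for col in bam.pileup(
        v.chrom,
        v.pos - 1,
        v.pos,
        truncate=True,
        stepper="nofilter",
        max_depth=1_000_000,
        min_base_quality=0,
        ignore_overlaps=False,
        ignore_orphans=False,
    ):
        for pr in col.pileups:
            read = pr.alignment
            if pr.is_del or pr.is_refskip or pr.query_position is None:
                continue  # no base aligned to the SNP
            base = read.query_sequence[pr.query_position]
            if base not in NT_INDEX:
                continue  # N or other ambiguity code
            quals = read.query_qualities
            baseq = int(quals[pr.query_position]) if quals is not None else None
            ok, reason = admit_read(read, flt, baseq)
            if not ok:
                report.tally_reject(sample, reason)
                continue
            if read.query_name in seen:
                report.mate_deduplicated[sample] += 1
                continue
            seen.add(read.query_name)
            report.admitted[sample] += 1
            strand = fragment_strand(read, strandedness)
            counts[i, j, NT_INDEX[base], STRAND_INDEX[strand]] += 1
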