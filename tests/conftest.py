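"""Shared fixtures and the independent brute-force counting oracle.

The oracle deliberately avoids the pileup engine used by the package: it
iterates every alignment record, finds the query base aligned to the SNP
position by walking the aligned pairs, applies the admission filter, and
tallies — so agreement between the two is a genuine dual-route check.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pysam
import pytest

from asekit.counting import CountFilter, admit_read, fragment_strand
from asekit.dataset import NT_INDEX, STRAND_INDEX, SNPVariant
from asekit.simulate import SimConfig, simulate


def oracle_count_tensor(bam_paths, variants, flt, strandedness):
    """Brute-force per-read allele tally; returns the full count tensor."""
    counts = np.zeros((len(bam_paths), len(variants), 4, 3), dtype=np.int64)
    for i, path in enumerate(bam_paths):
        with pysam.AlignmentFile(str(path)) as bam:
            reads = list(bam.fetch(until_eof=True))
        for j, v in enumerate(variants):
            seen: set[str] = set()
            for read in reads:
                if read.is_unmapped or read.reference_name != v.chrom:
                    continue
                qpos = None
                for qp, rp in read.get_aligned_pairs(matches_only=False):
                    if rp == v.pos - 1:
                        qpos = qp
                        break
                if qpos is None:
                    continue  # deletion/refskip over the SNP, or not covered
                base = read.query_sequence[qpos]
                if base not in NT_INDEX:
                    continue
                quals = read.query_qualities
                baseq = int(quals[qpos]) if quals is not None else None
                ok, _ = admit_read(read, flt, baseq)
                if not ok:
                    continue
                if read.query_name in seen:
                    continue
                seen.add(read.query_name)
                strand = fragment_strand(read, strandedness)
                counts[i, j, NT_INDEX[base], STRAND_INDEX[strand]] += 1
    if strandedness != "unstranded":
        counts[..., STRAND_INDEX["both"]] = (
            counts[..., STRAND_INDEX["plus"]] + counts[..., STRAND_INDEX["minus"]]
        )
    return counts


def degrade_bam(path: Path, seed: int) -> None:
    """Randomly perturb MAPQ and flag bits so admission filters have teeth.

    Base identities are never touched, so implementation-vs-oracle equality
    is unaffected by which mate of an overlapping pair wins the dedup.
    """
    rng = np.random.default_rng(seed)
    with pysam.AlignmentFile(str(path)) as bam:
        header = bam.header
        records = list(bam.fetch(until_eof=True))
    for rec in records:
        rec.mapping_quality = int(rng.choice([5, 20, 60], p=[0.15, 0.15, 0.7]))
        if rng.random() < 0.10:
            rec.is_duplicate = True
        if rng.random() < 0.10:
            rec.is_proper_pair = False
        if rng.random() < 0.05:
            rec.is_secondary = True
        if rec.query_qualities is not None and rng.random() < 0.20:
            q = np.asarray(rec.query_qualities)
            q[:] = int(rng.integers(2, 41))
            rec.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(x + 33) for x in q)
            )
    with pysam.AlignmentFile(str(path), "wb", header=header) as out:
        for rec in records:
            out.write(rec)
    pysam.index(str(path))


@pytest.fixture(scope="session")
def sam_header():
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 100000}]}
    )


def make_read(
    header,
    *,
    name="r1",
    pos=100,
    seq="ACGT" * 10,
    mapq=60,
    cigar=None,
    baseq=35,
    flags=None,
    paired=True,
    proper=True,
    read2=False,
    reverse=False,
    duplicate=False,
    secondary=False,
    unmapped=False,
):
    """Hand-build an alignment record (1-based pos)."""
    rec = pysam.AlignedSegment(header)
    rec.query_name = name
    rec.query_sequence = seq
    rec.query_qualities = pysam.qualitystring_to_array(chr(baseq + 33) * len(seq))
    rec.cigarstring = cigar or f"{len(seq)}M"
    rec.reference_name = "chr1"
    rec.reference_start = pos - 1
    rec.mapping_quality = mapq
    rec.is_paired = paired
    rec.is_proper_pair = proper and paired
    rec.is_read1 = paired and not read2
    rec.is_read2 = paired and read2
    rec.is_reverse = reverse
    rec.is_duplicate = duplicate
    rec.is_secondary = secondary
    rec.is_unmapped = unmapped
    if flags is not None:
        rec.flag = flags
    return rec


def write_bam(records, header, path: Path) -> Path:
    records = sorted(records, key=lambda r: (r.reference_id, r.reference_start, r.query_name))
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for rec in records:
            bam.write(rec)
    pysam.index(str(path))
    return path


@pytest.fixture()
def small_sim(tmp_path):
    """One compact simulated experiment (unstranded) plus its config."""
    cfg = SimConfig(n_snps=6, samples=("a", "b"), depth=40, seed=101)
    return simulate(cfg, tmp_path / "sim"), cfg
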