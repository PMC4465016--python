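"""N-mask known SNP positions in a reference genome to reduce mapping bias.

Reads carrying the alternative allele mismatch the reference and map less
often, inflating the apparent reference fraction.  Replacing every known SNP
base with the ambiguity nucleotide N before (re)alignment removes the penalty
from both alleles.  Only single-nucleotide variants are masked; indels and
MNVs are skipped and counted.  Soft-masked (lowercase) input bases become an
uppercase N.  Output preserves sequence order, sequence length and the
input's detected line wrapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .dataset import SNPVariant
from .io import VariantReadStats, read_variants

_DEFAULT_WRAP = 60


@dataclass
class MaskingReport:
    """Outcome of one masking run."""

    masked_per_chrom: dict[str, int] = field(default_factory=dict)
    records_applied: int = 0
    skipped_absent_chrom: int = 0
    skipped_out_of_range: int = 0
    skipped_non_snv: int = 0

    @property
    def total_masked(self) -> int:
        return sum(self.masked_per_chrom.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"chrom": c, "masked_positions": n} for c, n in sorted(self.masked_per_chrom.items())
        ]
        rows.append({"chrom": "__skipped_absent_chrom__", "masked_positions": self.skipped_absent_chrom})
        rows.append({"chrom": "__skipped_out_of_range__", "masked_positions": self.skipped_out_of_range})
        rows.append({"chrom": "__skipped_non_snv__", "masked_positions": self.skipped_non_snv})
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _load_variants(variants) -> tuple[list[SNPVariant], int]:
    """Accept a path (VCF/TSV) or an in-memory variant list."""
    if isinstance(variants, (str, Path)):
        stats = VariantReadStats()
        parsed = read_variants(variants, stats=stats)
        return parsed, stats.n_skipped_non_snv
    return list(variants), 0


def read_fasta(path: str | Path) -> tuple[list[tuple[str, str, str]], int]:
    """Read a FASTA as [(name, description, sequence)], plus detected wrap width.

    The wrap width is the length of the first sequence line of the first
    multi-line record (default 60 when every record fits on one line).
    """
    records: list[tuple[str, str, str]] = []
    wrap: int | None = None
    name = None
    desc = ""
    chunks: list[str] = []
    first_line_len: int | None = None
    multi = False

    def flush():
        nonlocal wrap
        if name is not None:
            records.append((name, desc, "".join(chunks)))
            if wrap is None and multi and first_line_len:
                wrap = first_line_len

    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith(">"):
                flush()
                header = line[1:]
                parts = header.split(None, 1)
                name = parts[0] if parts else ""
                desc = parts[1] if len(parts) > 1 else ""
                chunks = []
                first_line_len = None
                multi = False
            elif line:
                if first_line_len is None:
                    first_line_len = len(line)
                else:
                    multi = True
                chunks.append(line)
        flush()
    if name is None and not records:
        raise OSError(f"unreadable or empty FASTA: {path}")
    return records, wrap or _DEFAULT_WRAP


def write_fasta(records: Iterable[tuple[str, str, str]], path: str | Path, wrap: int) -> None:
    with open(path, "w") as fh:
        for name, desc, seq in records:
            header = f">{name} {desc}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


def mask_reference(
    fasta_in: str | Path,
    variants,
    fasta_out: str | Path,
) -> MaskingReport:
    """Write a copy of ``fasta_in`` with every SNV position replaced by N.

    ``variants`` is a VCF/TSV path or a sequence of :class:`SNPVariant`.
    Multiple records at one position mask it once.  Positions beyond the
    chromosome length, and chromosomes absent from the FASTA, are skipped
    with a warning and counted in the report.
    """
    snvs, n_non_snv = _load_variants(variants)
    records, wrap = read_fasta(fasta_in)
    report = MaskingReport(skipped_non_snv=n_non_snv)

    by_chrom: dict[str, set[int]] = {}
    lengths = {name: len(seq) for name, _, seq in records}
    for v in snvs:
        report.records_applied += 1
        if v.chrom not in lengths:
            report.skipped_absent_chrom += 1
            continue
        if v.pos > lengths[v.chrom]:
            warnings.warn(
                f"variant {v.id} at {v.chrom}:{v.pos} lies beyond the chromosome "
                f"length {lengths[v.chrom]}; skipped",
                stacklevel=2,
            )
            report.skipped_out_of_range += 1
            continue
        by_chrom.setdefault(v.chrom, set()).add(v.pos)

    masked_records = []
    for name, desc, seq in records:
        positions = by_chrom.get(name, set())
        if positions:
            buf = bytearray(seq.encode())
            for pos in positions:
                buf[pos - 1] = ord("N")
            seq = buf.decode()
        report.masked_per_chrom[name] = len(positions)
        masked_records.append((name, desc, seq))

    write_fasta(masked_records, fasta_out, wrap)
    return report


def verify_masking(
    fasta_in: str | Path,
    fasta_out: str | Path,
    variants,
) -> tuple[bool, list[str]]:
    """Check that ``fasta_out`` is ``fasta_in`` with exactly the SNVs N-masked.

    True iff every in-bounds SNV position is N in the output and every other
    position is byte-identical to the input.  Returns the discrepancy list
    (position-level, human readable).
    """
    snvs, _ = _load_variants(variants)
    in_records, _ = read_fasta(fasta_in)
    out_records, _ = read_fasta(fasta_out)
    discrepancies: list[str] = []

    in_map = {name: seq for name, _, seq in in_records}
    out_map = {name: seq for name, _, seq in out_records}
    if list(in_map) != list(out_map):
        discrepancies.append("sequence names or order differ between input and output")
        return False, discrepancies

    expected: dict[str, set[int]] = {}
    for v in snvs:
        if v.chrom in in_map and v.pos <= len(in_map[v.chrom]):
            expected.setdefault(v.chrom, set()).add(v.pos)

    for name, in_seq in in_map.items():
        out_seq = out_map[name]
        if len(out_seq) != len(in_seq):
            discrepancies.append(f"{name}: length changed {len(in_seq)} -> {len(out_seq)}")
            continue
        want = expected.get(name, set())
        for pos in range(1, len(in_seq) + 1):
            a, b = in_seq[pos - 1], out_seq[pos - 1]
            if pos in want:
                if b != "N":
                    discrepancies.append(f"{name}:{pos} should be masked to N, found {b!r}")
            elif a != b:
                discrepancies.append(f"{name}:{pos} changed {a!r} -> {b!r} outside the SNV set")
    return not discrepancies, discrepancies
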