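"""Self-contained synthetic fixtures: toy genome, VCF, aligned reads and truth.

The simulator emits everything the rest of the package consumes — a random
reference FASTA, a VCF of SNVs with per-sample genotypes, one coordinate-
sorted indexed BAM per sample, and a machine-readable truth table of the
realized per-cell allele counts — so counting, testing, masking and plotting
are all exercisable without any external data.

The model: for each heterozygous sample x SNP cell, ``depth`` sequenced
fragments carry the reference allele with the configured true fraction
(ref count ~ Binomial(depth, fraction)); alternative-allele fragments are
then independently dropped with probability ``ref_bias``, an abstraction of
alignment loss of non-reference reads.  Fragments become proper FR read
pairs with an all-match CIGAR, MAPQ 60 and constant base quality 40, placed
so that at least one mate covers the SNP; mate flags follow the declared
strandedness protocol.  A per-base substitution ``error_rate`` can leak
counts onto the two other nucleotides.  Reads are emitted pre-aligned: the
package tests counting and statistics, not alignment.

SNP positions are kept a fragment length away from chromosome ends and two
fragment lengths apart, so every fragment overlaps exactly one SNP and the
truth table is exact by construction at ``error_rate=0``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .counting import CountFilter, count_alleles
from .dataset import (
    ASEDataset,
    GT_HET,
    GT_HOM_ALT,
    GT_HOM_REF,
    NT_INDEX,
    NUCLEOTIDES,
    SNPVariant,
    STRAND_INDEX,
    STRANDEDNESS_MODES,
)
from .errors import SimConfigError

_BASEQ = 40
_MAPQ = 60


@dataclass
class SimConfig:
    """Study conditions for one simulated experiment.

    true_fraction / genotypes may be scalars applied everywhere or full
    (n_samples, n_snps) arrays.  ``transcript_strand`` fixes the strand each
    SNP's gene is transcribed from ("plus", "minus" or "random" per SNP).
    """

    n_chroms: int = 1
    chrom_length: int = 10_000
    n_snps: int = 10
    samples: tuple[str, ...] = ("s1", "s2")
    depth: int = 50
    read_length: int = 75
    fragment_length: int = 120
    strandedness: str = "unstranded"
    true_fraction: float | np.ndarray = 0.5
    genotypes: np.ndarray | None = None  # default: all heterozygous
    ref_bias: float = 0.0
    error_rate: float = 0.0
    transcript_strand: str = "plus"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise SimConfigError("depth must be >= 1")
        if not (0 <= self.ref_bias < 1):
            raise SimConfigError("ref_bias must lie in [0, 1)")
        if not (0 <= self.error_rate < 1):
            raise SimConfigError("error_rate must lie in [0, 1)")
        if not (self.read_length <= self.fragment_length <= self.chrom_length):
            raise SimConfigError("need read_length <= fragment_length <= chrom_length")
        if self.fragment_length > 2 * self.read_length:
            raise SimConfigError(
                "fragment_length must be <= 2*read_length so every fragment base "
                "is covered by a mate"
            )
        if self.strandedness not in STRANDEDNESS_MODES:
            raise SimConfigError(f"unknown strandedness {self.strandedness!r}")
        if self.transcript_strand not in ("plus", "minus", "random"):
            raise SimConfigError("transcript_strand must be plus, minus or random")
        frac = np.asarray(self.true_fraction, dtype=float)
        if np.any(frac < 0) or np.any(frac > 1):
            raise SimConfigError("true fractions must lie in [0, 1]")

    def fraction_matrix(self) -> np.ndarray:
        frac = np.asarray(self.true_fraction, dtype=float)
        shape = (len(self.samples), self.n_snps)
        if frac.ndim == 0:
            return np.full(shape, float(frac))
        if frac.shape != shape:
            raise SimConfigError(f"true_fraction shape {frac.shape} != {shape}")
        return frac

    def genotype_matrix(self) -> np.ndarray:
        shape = (len(self.samples), self.n_snps)
        if self.genotypes is None:
            gts = np.empty(shape, dtype=object)
            gts[:] = GT_HET
            return gts
        gts = np.asarray(self.genotypes, dtype=object)
        if gts.shape != shape:
            raise SimConfigError(f"genotypes shape {gts.shape} != {shape}")
        return gts


@dataclass
class SimResult:
    """Paths of the emitted fixture files."""

    out_dir: Path
    fasta: Path
    vcf: Path
    bams: dict[str, Path]
    truth: Path
    manifest: Path
    variants: list[SNPVariant] = field(default_factory=list)

    def truth_frame(self) -> pd.DataFrame:
        return pd.read_csv(self.truth, sep="\t", dtype={"chrom": str, "id": str})


def _snp_positions(rng: np.random.Generator, cfg: SimConfig) -> list[tuple[str, int]]:
    """Distinct positions, >= fragment_length from ends, 2*fragment_length apart."""
    gap = 2 * cfg.fragment_length
    lo, hi = cfg.fragment_length, cfg.chrom_length - cfg.fragment_length
    per_chrom = [cfg.n_snps // cfg.n_chroms + (c < cfg.n_snps % cfg.n_chroms) for c in range(cfg.n_chroms)]
    out: list[tuple[str, int]] = []
    for c, n in enumerate(per_chrom):
        if n == 0:
            continue
        slack = hi - lo - (n - 1) * gap
        if slack < 0:
            raise SimConfigError(
                f"chromosome length {cfg.chrom_length} too short for {n} SNPs with "
                f"fragment_length {cfg.fragment_length}"
            )
        offsets = np.sort(rng.integers(0, slack + 1, size=n))
        for i, u in enumerate(offsets):
            out.append((f"chr{c + 1}", int(lo + u + i * gap)))
    return out


def _substitute_errors(rng: np.random.Generator, seq: bytearray, rate: float) -> None:
    if rate <= 0:
        return
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        current = chr(seq[i])
        others = [nt for nt in NUCLEOTIDES if nt != current]
        seq[i] = ord(others[rng.integers(0, len(others))])


def simulate(config: SimConfig, out_dir: str | Path) -> SimResult:
    """Emit FASTA + VCF + per-sample sorted/indexed BAM + truth TSV + manifest.

    Deterministic in ``config.seed``: identical config and seed give
    byte-identical FASTA/VCF/truth and an identical post-sort BAM record set.
    """
    cfg = config
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    # --- reference genome
    chrom_names = [f"chr{c + 1}" for c in range(cfg.n_chroms)]
    genome = {
        name: "".join(rng.choice(list(NUCLEOTIDES), size=cfg.chrom_length))
        for name in chrom_names
    }
    fasta_path = out / "reference.fa"
    with open(fasta_path, "w") as fh:
        for name in chrom_names:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")

    # --- variants
    positions = _snp_positions(rng, cfg)
    variants: list[SNPVariant] = []
    for k, (chrom, pos) in enumerate(positions):
        ref = genome[chrom][pos - 1]
        others = [nt for nt in NUCLEOTIDES if nt != ref]
        alt = others[rng.integers(0, 3)]
        variants.append(SNPVariant(chrom=chrom, pos=pos, id=f"snp{k + 1}", ref_allele=ref, alt_allele=alt))

    gts = cfg.genotype_matrix()
    fracs = cfg.fraction_matrix()
    if cfg.transcript_strand == "random":
        strand_v = np.where(rng.random(cfg.n_snps) < 0.5, "plus", "minus")
    else:
        strand_v = np.full(cfg.n_snps, cfg.transcript_strand, dtype=object)

    vcf_path = out / "variants.vcf"
    _write_vcf(vcf_path, chrom_names, cfg.chrom_length, variants, cfg.samples, gts)

    # --- reads + truth
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": name, "LN": cfg.chrom_length} for name in chrom_names],
        }
    )
    truth_rows: list[dict] = []
    bam_paths: dict[str, Path] = {}
    for i, sample in enumerate(cfg.samples):
        records: list[pysam.AlignedSegment] = []
        for j, v in enumerate(variants):
            gt = gts[i, j]
            if gt == GT_HET:
                true_frac = float(fracs[i, j])
                ref_n = int(rng.binomial(cfg.depth, true_frac))
                alt_raw = cfg.depth - ref_n
            elif gt == GT_HOM_REF:
                true_frac, ref_n, alt_raw = 1.0, cfg.depth, 0
            elif gt == GT_HOM_ALT:
                true_frac, ref_n, alt_raw = 0.0, 0, cfg.depth
            else:  # no-call: no coverage simulated
                truth_rows.append(_truth_row(sample, v, gt, np.nan, 0, 0, 0, 0, 0, 0))
                continue
            alt_n = int(rng.binomial(alt_raw, 1.0 - cfg.ref_bias)) if alt_raw else 0

            strand_counts = {("ref", "plus"): 0, ("ref", "minus"): 0, ("alt", "plus"): 0, ("alt", "minus"): 0}
            alleles = [("ref", v.ref_allele)] * ref_n + [("alt", v.alt_allele)] * alt_n
            for frag_idx, (kind, base) in enumerate(alleles):
                strand = str(strand_v[j])
                strand_counts[(kind, strand)] += 1
                qname = f"frag_{sample}_{v.id}_{frag_idx}"
                records.extend(
                    _make_pair(rng, cfg, header, genome[v.chrom], v, base, strand, qname)
                )
            truth_rows.append(
                _truth_row(
                    sample, v, gt, true_frac, ref_n, alt_n,
                    strand_counts[("ref", "plus")], strand_counts[("ref", "minus")],
                    strand_counts[("alt", "plus")], strand_counts[("alt", "minus")],
                )
            )
        records.sort(key=lambda r: (r.reference_id, r.reference_start, r.query_name, r.flag))
        bam_path = out / f"{sample}.bam"
        with pysam.AlignmentFile(str(bam_path), "wb", header=header) as bam:
            for rec in records:
                bam.write(rec)
        pysam.index(str(bam_path))
        bam_paths[sample] = bam_path

    truth_path = out / "truth.tsv"
    pd.DataFrame(truth_rows).to_csv(truth_path, sep="\t", index=False)

    manifest_path = out / "manifest.json"
    manifest = {
        "strandedness": cfg.strandedness,
        "samples": list(cfg.samples),
        "fasta": fasta_path.name,
        "vcf": vcf_path.name,
        "truth": truth_path.name,
        "bams": {s: p.name for s, p in bam_paths.items()},
        "depth": cfg.depth,
        "read_length": cfg.read_length,
        "fragment_length": cfg.fragment_length,
        "ref_bias": cfg.ref_bias,
        "error_rate": cfg.error_rate,
        "seed": cfg.seed,
    }
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return SimResult(out, fasta_path, vcf_path, bam_paths, truth_path, manifest_path, variants)


def _truth_row(sample, v, gt, frac, ref_n, alt_n, rp, rm, ap, am) -> dict:
    return {
        "sample": sample,
        "chrom": v.chrom,
        "pos": v.pos,
        "id": v.id,
        "ref": v.ref_allele,
        "alt": v.alt_allele,
        "genotype": gt if gt is not None else ".",
        "true_fraction": frac,
        "ref_count": ref_n,
        "alt_count": alt_n,
        "ref_plus": rp,
        "ref_minus": rm,
        "alt_plus": ap,
        "alt_minus": am,
    }


def _make_pair(
    rng: np.random.Generator,
    cfg: SimConfig,
    header: pysam.AlignmentHeader,
    chrom_seq: str,
    v: SNPVariant,
    allele: str,
    transcript_strand: str,
    qname: str,
) -> list[pysam.AlignedSegment]:
    """Build one proper FR read pair whose fragment covers the SNP.

    The fragment offset of the SNP is drawn uniformly over offsets at which
    at least one mate covers the base (with fragment_length <= 2*read_length
    that is every offset).  SAM stores sequences in reference orientation, so
    both mates carry plain reference substrings with the allele (and any
    sequencing errors) substituted.
    """
    lr, lf = cfg.read_length, cfg.fragment_length
    d = int(rng.integers(0, lf))  # SNP offset within the fragment
    s = v.pos - d  # 1-based fragment start
    left_start = s
    right_start = s + lf - lr

    def read_seq(start: int) -> bytearray:
        seq = bytearray(chrom_seq[start - 1 : start - 1 + lr].encode())
        off = v.pos - start
        if 0 <= off < lr:
            seq[off] = ord(allele)
        _substitute_errors(rng, seq, cfg.error_rate)
        return seq

    # Which mate is the leftmost/forward read, given the protocol.
    if cfg.strandedness == "fr-firststrand":
        left_is_read2 = transcript_strand == "plus"
    elif cfg.strandedness == "fr-secondstrand":
        left_is_read2 = transcript_strand == "minus"
    else:
        left_is_read2 = bool(rng.integers(0, 2))

    out = []
    for is_left in (True, False):
        rec = pysam.AlignedSegment(header)
        rec.query_name = qname
        rec.reference_name = v.chrom
        rec.reference_start = (left_start if is_left else right_start) - 1
        rec.mapping_quality = _MAPQ
        rec.cigarstring = f"{lr}M"
        rec.query_sequence = read_seq(left_start if is_left else right_start).decode()
        rec.query_qualities = pysam.qualitystring_to_array(chr(_BASEQ + 33) * lr)
        rec.is_paired = True
        rec.is_proper_pair = True
        rec.is_reverse = not is_left
        rec.mate_is_reverse = is_left
        is_read2 = left_is_read2 if is_left else not left_is_read2
        rec.is_read1 = not is_read2
        rec.is_read2 = is_read2
        rec.next_reference_name = v.chrom
        rec.next_reference_start = (right_start if is_left else left_start) - 1
        rec.template_length = lf if is_left else -lf
        out.append(rec)
    return out


def _write_vcf(path, chrom_names, chrom_length, variants, samples, gts) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name in chrom_names:
            fh.write(f"##contig=<ID={name},length={chrom_length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for j, v in enumerate(variants):
            row = [v.chrom, str(v.pos), v.id, v.ref_allele, v.alt_allele, ".", "PASS", ".", "GT"]
            row += [gts[i, j] if gts[i, j] is not None else "./." for i in range(len(samples))]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------- closure check


def recount_equals_truth(out_dir: str | Path) -> bool:
    """Recount the simulated BAMs and compare with the truth table, exactly.

    Runs :func:`asekit.counting.count_alleles` with the permissive filter on
    the emitted BAMs and checks every sample x SNP cell against the realized
    truth counts — per strand for stranded protocols.  Exact equality is the
    expectation at ``error_rate=0``; substitution errors leak counts and
    break exactness by design.
    """
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    from .io import read_variants

    variants = read_variants(out / manifest["vcf"])
    bam_paths = {s: out / name for s, name in manifest["bams"].items()}
    ds, _ = count_alleles(
        bam_paths, variants, CountFilter.permissive(), manifest["strandedness"]
    )
    truth = pd.read_csv(out / manifest["truth"], sep="\t", dtype={"chrom": str, "id": str})
    vid_index = {v.id: j for j, v in enumerate(ds.variants)}
    stranded = manifest["strandedness"] != "unstranded"
    for row in truth.itertuples():
        i = ds.sample_index(row.sample)
        j = vid_index[row.id]
        v = ds.variants[j]
        cell = ds.counts[i, j]
        ref_i, alt_i = NT_INDEX[v.ref_allele], NT_INDEX[v.alt_allele]
        if stranded:
            checks = [
                (cell[ref_i, STRAND_INDEX["plus"]], row.ref_plus),
                (cell[ref_i, STRAND_INDEX["minus"]], row.ref_minus),
                (cell[alt_i, STRAND_INDEX["plus"]], row.alt_plus),
                (cell[alt_i, STRAND_INDEX["minus"]], row.alt_minus),
            ]
        else:
            checks = [
                (cell[ref_i, STRAND_INDEX["both"]], row.ref_count),
                (cell[alt_i, STRAND_INDEX["both"]], row.alt_count),
            ]
        if any(int(got) != int(want) for got, want in checks):
            return False
        # nothing may leak onto the other two nucleotides without errors
        other = cell.sum() - cell[ref_i].sum() - cell[alt_i].sum()
        if manifest["error_rate"] == 0 and other != 0:
            return False
    return True


# ------------------------------------------------------- dataset-level sampler


def simulate_count_dataset(
    n_samples: int,
    n_variants: int,
    depth: int,
    fraction: float | np.ndarray = 0.5,
    ref_bias: float = 0.0,
    seed: int = 0,
) -> ASEDataset:
    """Draw an in-memory heterozygous count dataset, skipping read emission.

    Used for statistical calibration experiments where only the per-cell
    binomial draw matters: ref ~ Binomial(depth, fraction), alt thinned by
    ``ref_bias``.  All cells are heterozygous; ref/alt nucleotides are drawn
    per variant; the dataset is unstranded.
    """
    rng = np.random.default_rng(seed)
    frac = np.broadcast_to(np.asarray(fraction, dtype=float), (n_samples, n_variants))
    variants = []
    ref_idx = np.empty(n_variants, dtype=int)
    alt_idx = np.empty(n_variants, dtype=int)
    for j in range(n_variants):
        ref_i, alt_i = rng.choice(4, size=2, replace=False)
        ref_idx[j], alt_idx[j] = ref_i, alt_i
        variants.append(
            SNPVariant(
                chrom="chr1",
                pos=1000 * (j + 1),
                id=f"snp{j + 1}",
                ref_allele=NUCLEOTIDES[ref_i],
                alt_allele=NUCLEOTIDES[alt_i],
            )
        )
    ref_n = rng.binomial(depth, frac)
    alt_n = rng.binomial(depth - ref_n, 1.0 - ref_bias) if ref_bias > 0 else depth - ref_n
    counts = np.zeros((n_samples, n_variants, 4, 3), dtype=np.int64)
    cols = np.arange(n_variants)
    for i in range(n_samples):
        counts[i, cols, ref_idx, STRAND_INDEX["both"]] = ref_n[i]
        counts[i, cols, alt_idx, STRAND_INDEX["both"]] = alt_n[i]
    gts = np.empty((n_samples, n_variants), dtype=object)
    gts[:] = GT_HET
    samples = [f"s{i + 1}" for i in range(n_samples)]
    return ASEDataset(counts, variants, samples, "unstranded", genotypes=gts)
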