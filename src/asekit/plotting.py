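"""Static allele-count and allele-fraction plots.

Three views:

* :func:`barplot_snp` — one SNP, one bar group per sample, as raw
  per-nucleotide counts or as the reference fraction with a horizontal guide
  line at the expected ratio (0.5 marks balanced 1:1 expression);
* :func:`dual_strand_barplot` — stranded data only: plus-strand counts drawn
  upward, minus-strand downward, per-sample test p-values annotated beneath;
* :func:`locationplot` — a panel of per-SNP mini-barplots laid out along a
  genomic region, each connected to its coordinate on a position axis, with
  an optional gene/exon track parsed from GTF or BED.

Rendering is file-based (PNG/SVG/PDF by extension).  SVG output is
deterministic for identical inputs: fixed hash salt, no embedded date.
Artists carry stable ``gid`` attributes (``snp-panel-*``, ``count-bar-*``)
so structure can be asserted from the vector output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .dataset import ASEDataset, NT_INDEX, NUCLEOTIDES, STRAND_INDEX, parse_region
from .errors import DatasetStateError, ValidationError
from .io import AnnotationFeature

#: Fixed nucleotide palette (colour-blind friendly); override per call.
DEFAULT_PALETTE = {"A": "#1b9e77", "C": "#7570b3", "G": "#d95f02", "T": "#e7298a"}

matplotlib.rcParams["svg.hashsalt"] = "asekit"


def format_pvalue(p: float) -> str:
    """Annotation string for a p-value: "nd" when missing, three decimals down
    to 0.001, scientific notation below."""
    if p is None or not np.isfinite(p):
        return "nd"
    if p >= 0.001:
        return f"{p:.3f}"
    return f"{p:.1e}"


def _save(fig, out: str | Path) -> Path:
    out = Path(out)
    kwargs = {}
    if out.suffix.lower() == ".svg":
        kwargs["metadata"] = {"Date": None}
    fig.savefig(out, **kwargs)
    plt.close(fig)
    return out


def barplot_snp(
    ds: ASEDataset,
    variant_id: str,
    mode: str = "count",
    out: str | Path = "barplot.png",
    strand: str = "both",
    expected: float = 0.5,
    palette: dict[str, str] | None = None,
) -> Path:
    """Per-sample allele counts or reference fraction for one SNP."""
    if mode not in ("count", "fraction"):
        raise ValidationError(f"mode must be 'count' or 'fraction', got {mode!r}")
    j = ds.variant_index(variant_id)
    palette = palette or DEFAULT_PALETTE
    fig, ax = plt.subplots(figsize=(1.0 + 0.9 * ds.n_samples, 3.4))
    _draw_snp_bars(ax, ds, j, mode, strand, expected, palette, gid_prefix=f"{mode}-bar")
    v = ds.variants[j]
    ax.set_title(f"{v.id} ({v.chrom}:{v.pos})", fontsize=10)
    ax.set_ylabel("reads" if mode == "count" else "reference fraction")
    if mode == "count":
        handles = [plt.Rectangle((0, 0), 1, 1, color=palette[nt]) for nt in NUCLEOTIDES]
        ax.legend(handles, NUCLEOTIDES, fontsize=7, ncol=4, frameon=False)
    fig.tight_layout()
    return _save(fig, out)


def _draw_snp_bars(ax, ds, j, mode, strand, expected, palette, gid_prefix) -> None:
    x = np.arange(ds.n_samples)
    if mode == "count":
        slab = ds.counts[:, j, :, STRAND_INDEX[strand]]  # (S, 4)
        bottom = np.zeros(ds.n_samples)
        for k, nt in enumerate(NUCLEOTIDES):
            bars = ax.bar(x, slab[:, k], bottom=bottom, width=0.7, color=palette[nt])
            for i, b in enumerate(bars):
                b.set_gid(f"{gid_prefix}-{ds.samples[i]}-{nt}")
            bottom += slab[:, k]
    else:
        frac = ds.allele_fractions(strand=strand, min_depth=1).values[:, j]
        vals = np.nan_to_num(frac, nan=0.0)
        bars = ax.bar(x, vals, width=0.7, color="#888888")
        for i, b in enumerate(bars):
            b.set_gid(f"{gid_prefix}-{ds.samples[i]}")
        guide = ax.axhline(expected, color="black", linewidth=1.2)
        guide.set_gid("expected-guide")
        ax.set_ylim(0, 1)
    ax.set_xticks(x)
    ax.set_xticklabels(ds.samples, fontsize=8, rotation=45, ha="right")


def dual_strand_barplot(
    ds: ASEDataset,
    variant_id: str,
    tests=None,
    out: str | Path = "dualbar.png",
    palette: dict[str, str] | None = None,
) -> Path:
    """Plus-strand counts upward, minus-strand downward, p-values beneath.

    ``tests`` is a TestResult, or a (plus, minus) pair of TestResults, whose
    per-sample p-values for this SNP are printed under each bar group
    (missing values print as "nd").  Unstranded datasets are refused — use
    :func:`barplot_snp`.
    """
    if ds.strandedness == "unstranded":
        raise DatasetStateError(
            "dual_strand_barplot requires a stranded dataset; use barplot_snp for "
            "unstranded data"
        )
    j = ds.variant_index(variant_id)
    palette = palette or DEFAULT_PALETTE
    fig, ax = plt.subplots(figsize=(1.2 + 0.9 * ds.n_samples, 4.0))
    x = np.arange(ds.n_samples)
    for sign, strand in ((1, "plus"), (-1, "minus")):
        slab = ds.counts[:, j, :, STRAND_INDEX[strand]]
        bottom = np.zeros(ds.n_samples)
        for k, nt in enumerate(NUCLEOTIDES):
            h = sign * slab[:, k]
            bars = ax.bar(x, h, bottom=sign * bottom, width=0.7, color=palette[nt])
            for i, b in enumerate(bars):
                b.set_gid(f"dual-bar-{strand}-{ds.samples[i]}-{nt}")
            bottom += slab[:, k]
    ax.axhline(0, color="black", linewidth=0.8)

    labels = list(ds.samples)
    if tests is not None:
        results = tests if isinstance(tests, (tuple, list)) else (tests,)
        for i, sample in enumerate(ds.samples):
            parts = []
            for res in results:
                jj = [v.id for v in res.variants].index(ds.variants[j].id)
                ii = res.samples.index(sample)
                parts.append(format_pvalue(res.p_values[ii, jj]))
            labels[i] = f"{sample}\n" + "\n".join(parts)
    ax.set_xticks(x)
    ax.set_xticklabels(labels, fontsize=8)
    v = ds.variants[j]
    ax.set_title(f"{v.id} ({v.chrom}:{v.pos})  (+) up / (−) down", fontsize=10)
    ax.set_ylabel("reads")
    fig.tight_layout()
    return _save(fig, out)


@dataclass
class LocationPlotLayout:
    """Structural record of one location plot (for programmatic checks)."""

    path: Path
    panels: list[tuple[str, int, float]]  # (variant id, genomic pos, panel centre in axes x)


def locationplot(
    ds: ASEDataset,
    region: str,
    annotation: Sequence[AnnotationFeature] | None = None,
    mode: str = "fraction",
    out: str | Path = "locationplot.png",
    expected: float = 0.5,
    palette: dict[str, str] | None = None,
) -> LocationPlotLayout:
    """Mini-barplots for every SNP in a region, tied to their coordinates.

    Panels are laid out left to right in genomic order and connected by guide
    lines to their positions on the location axis; an optional gene/exon
    track is drawn beneath.  An empty region raises ``ValueError`` naming the
    nearest variants.
    """
    if mode not in ("count", "fraction"):
        raise ValidationError(f"mode must be 'count' or 'fraction', got {mode!r}")
    chrom, start, end = parse_region(region)
    sub = ds.subset(region=region)
    if sub.n_variants == 0:
        nearest = sorted(
            (v for v in ds.variants if v.chrom == chrom),
            key=lambda v: min(abs(v.pos - (start or v.pos)), abs(v.pos - (end or v.pos))),
        )[:3]
        hint = ", ".join(f"{v.id}@{v.pos}" for v in nearest) or "none on this chromosome"
        raise ValueError(f"no variants in region {region}; nearest: {hint}")
    order = np.argsort([v.pos for v in sub.variants], kind="stable")
    if start is None:
        start = min(v.pos for v in sub.variants)
        end = max(v.pos for v in sub.variants)

    palette = palette or DEFAULT_PALETTE
    n = sub.n_variants
    fig = plt.figure(figsize=(max(6.0, 1.4 * n), 4.6))
    loc_ax = fig.add_axes([0.06, 0.16, 0.90, 0.10])
    loc_ax.set_xlim(start - 0.5, end + 0.5)
    loc_ax.set_ylim(0, 1)
    loc_ax.set_yticks([])
    loc_ax.set_xlabel(f"{chrom} position")

    panels: list[tuple[str, int, float]] = []
    width = 0.90 / n
    for rank, jj in enumerate(order):
        v = sub.variants[jj]
        left = 0.06 + rank * width
        ax = fig.add_axes([left + 0.12 * width, 0.40, 0.76 * width, 0.50])
        _draw_snp_bars(
            ax, sub, jj, mode, "both", expected, palette, gid_prefix=f"snp-panel-{v.id}"
        )
        ax.set_gid(f"snp-panel-{v.id}")
        ax.set_title(v.id, fontsize=7)
        ax.tick_params(labelsize=5)
        if rank > 0:
            ax.set_yticklabels([])
        centre = left + 0.5 * width
        panels.append((v.id, v.pos, centre))
        # guide line from the panel down to the genomic coordinate
        tick = loc_ax.plot([v.pos, v.pos], [0.55, 1.0], color="grey", linewidth=1.0)[0]
        tick.set_gid(f"snp-guide-{v.id}")
        con = matplotlib.patches.ConnectionPatch(
            xyA=(0.5, 0.0),
            coordsA=ax.transAxes,
            xyB=(v.pos, 1.0),
            coordsB=loc_ax.transData,
            color="grey",
            linewidth=0.8,
        )
        fig.add_artist(con)

    if annotation:
        feats = [f for f in annotation if f.chrom == chrom and f.end >= start and f.start <= end]
        for f in feats:
            y, h = (0.25, 0.25) if f.feature == "gene" else (0.20, 0.35)
            rect = matplotlib.patches.Rectangle(
                (f.start, y),
                f.end - f.start + 1,
                h,
                color="#e6c200" if f.feature == "gene" else "#b8860b",
            )
            rect.set_gid(f"annot-{f.feature}-{f.name}")
            loc_ax.add_patch(rect)
            if f.feature == "gene":
                loc_ax.text(
                    (f.start + f.end) / 2, 0.05, f.name, ha="center", fontsize=7
                )
    return LocationPlotLayout(_save(fig, out), panels)
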