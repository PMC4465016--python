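"""Per-cell allelic-imbalance tests against configurable expected allele ratios.

Under balanced expression the reads over a heterozygous SNP are a binomial
sample of the two alleles, so with k reference reads out of n = ref + alt the
null is ``k ~ Binomial(n, p0)`` with p0 = 0.5 — or a mapping-bias-adjusted p0
estimated from material with known 1:1 truth (see
:func:`set_expected_from_counts`).  Two tests are offered per SNP x sample
cell:

* an exact two-sided binomial test, two-sidedness by the minimum-likelihood
  rule: p = sum of P(X = i) over every i whose point probability does not
  exceed P(X = k);
* a 1-df chi-square goodness-of-fit test without continuity correction,
  ``X^2 = (k - n p0)^2 / (n p0) + ((n-k) - n(1-p0))^2 / (n (1-p0))``.

Cells under the depth gate — and, by default, cells that are not heterozygous
— are reported as missing (NaN), never as p = 1.  Counts on the two
non-(ref, alt) nucleotides are excluded from n and carried separately as an
error diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dataset import ASEDataset, GT_HET, SNPVariant
from .errors import ValidationError

ADJUST_METHODS = ("none", "benjamini-hochberg", "bonferroni")

#: Relative slack when comparing point probabilities in the minimum-likelihood
#: two-sided rule; absorbs floating-point fuzz in pmf ties (same convention as
#: the classical exact-test implementations).
_TIE_RELATIVE_SLACK = 1e-7


@dataclass(frozen=True)
class ExpectedRatio:
    """Expected reference-allele fraction under the null.

    ``values`` is a scalar, a per-variant vector, or a per-sample x
    per-variant matrix; every entry must lie strictly inside (0, 1).
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if np.any(~np.isfinite(arr)) or np.any(arr <= 0.0) or np.any(arr >= 1.0):
            raise ValidationError("expected allele ratios must lie strictly in (0, 1)")
        object.__setattr__(self, "values", arr)

    @classmethod
    def balanced(cls) -> "ExpectedRatio":
        return cls(np.asarray(0.5))

    def broadcast(self, n_samples: int, n_variants: int) -> np.ndarray:
        arr = self.values
        if arr.ndim == 0:
            return np.full((n_samples, n_variants), float(arr))
        if arr.ndim == 1:
            if arr.shape[0] != n_variants:
                raise ValidationError(
                    f"per-variant expected ratios length {arr.shape[0]} != {n_variants} variants"
                )
            return np.broadcast_to(arr, (n_samples, n_variants)).copy()
        if arr.shape != (n_samples, n_variants):
            raise ValidationError(
                f"expected-ratio matrix shape {arr.shape} != ({n_samples}, {n_variants})"
            )
        return arr.copy()


def _as_expected(expected) -> ExpectedRatio:
    if isinstance(expected, ExpectedRatio):
        return expected
    return ExpectedRatio(np.asarray(expected, dtype=float))


@dataclass
class TestResult:
    """SNP x sample imbalance-test results.

    ``p_values`` and ``estimates`` are (n_samples, n_variants) float arrays
    with NaN for missing cells (depth gate, non-het when het-gated).
    ``estimates`` is the observed reference fraction k/n.
    """

    p_values: np.ndarray
    estimates: np.ndarray
    method: str
    expected: np.ndarray
    min_depth: int
    strand: str
    samples: tuple[str, ...]
    variants: tuple[SNPVariant, ...]
    ref_counts: np.ndarray
    alt_counts: np.ndarray
    other_counts: np.ndarray
    het_only: bool
    p_adjusted: np.ndarray | None = None
    adjust_method: str = "none"

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per sample x variant cell."""
        rows = []
        for i, s in enumerate(self.samples):
            for j, v in enumerate(self.variants):
                rows.append(
                    {
                        "sample": s,
                        "chrom": v.chrom,
                        "pos": v.pos,
                        "id": v.id,
                        "ref": v.ref_allele,
                        "alt": v.alt_allele,
                        "strand": self.strand,
                        "ref_count": int(self.ref_counts[i, j]),
                        "alt_count": int(self.alt_counts[i, j]),
                        "other_count": int(self.other_counts[i, j]),
                        "fraction": self.estimates[i, j],
                        "expected": self.expected[i, j],
                        "p_value": self.p_values[i, j],
                        "p_adjusted": (
                            self.p_adjusted[i, j] if self.p_adjusted is not None else np.nan
                        ),
                        "method": self.method,
                    }
                )
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")

    def summary(self, alpha: float = 0.05) -> str:
        """Human-readable run summary."""
        p = self.p_values
        tested = int(np.isfinite(p).sum())
        sig = int(np.nansum(p < alpha)) if tested else 0
        padj_line = ""
        if self.p_adjusted is not None:
            sig_adj = int(np.nansum(self.p_adjusted < alpha))
            padj_line = (
                f"significant after {self.adjust_method} adjustment: {sig_adj}\n"
            )
        return (
            f"Allelic imbalance test ({self.method}), strand={self.strand}, "
            f"min_depth={self.min_depth}, het_only={self.het_only}\n"
            f"samples: {len(self.samples)}  variants: {len(self.variants)}\n"
            f"cells tested: {tested} of {len(self.samples) * len(self.variants)}\n"
            f"significant at alpha={alpha}: {sig}\n" + padj_line
        )


def binom_pvalue_two_sided(k: int, n: int, p0: float) -> float:
    """Exact two-sided binomial p-value by the minimum-likelihood rule.

    Sums P(X = i) over all i in 0..n with P(X = i) <= P(X = k) (up to a tiny
    relative slack for floating-point pmf ties), X ~ Binomial(n, p0).
    """
    if n <= 0:
        return float("nan")
    pmf = sps.binom.pmf(np.arange(n + 1), n, p0)
    thresh = pmf[k] * (1.0 + _TIE_RELATIVE_SLACK)
    return float(min(1.0, pmf[pmf <= thresh].sum()))


def chisq_pvalue(k: int, n: int, p0: float) -> tuple[float, float]:
    """1-df goodness-of-fit chi-square statistic and upper-tail p-value."""
    if n <= 0:
        return float("nan"), float("nan")
    e_ref = n * p0
    e_alt = n * (1.0 - p0)
    x2 = (k - e_ref) ** 2 / e_ref + ((n - k) - e_alt) ** 2 / e_alt
    return float(x2), float(sps.chi2.sf(x2, df=1))


def _test_matrix(
    ds: ASEDataset,
    expected,
    strand: str,
    min_depth: int,
    het_only: bool,
    method: str,
) -> TestResult:
    if min_depth < 1:
        raise ValidationError("min_depth must be >= 1")
    exp = _as_expected(expected)
    ref, alt, other = ds.ref_alt_counts(strand)
    n = ref + alt
    p0 = exp.broadcast(ds.n_samples, ds.n_variants)

    testable = n >= min_depth
    if het_only:
        gts = ds.effective_genotypes()
        het = np.vectorize(lambda g: g == GT_HET, otypes=[bool])(gts)
        testable &= het

    with np.errstate(invalid="ignore", divide="ignore"):
        estimates = np.where(n > 0, ref / np.maximum(n, 1), np.nan)
    estimates = np.where(testable, estimates, np.nan)

    p_values = np.full(n.shape, np.nan)
    for i, j in zip(*np.nonzero(testable)):
        if method == "binom":
            p_values[i, j] = binom_pvalue_two_sided(int(ref[i, j]), int(n[i, j]), p0[i, j])
        else:
            p_values[i, j] = chisq_pvalue(int(ref[i, j]), int(n[i, j]), p0[i, j])[1]

    return TestResult(
        p_values=p_values,
        estimates=estimates,
        method=method,
        expected=p0,
        min_depth=min_depth,
        strand=strand,
        samples=ds.samples,
        variants=ds.variants,
        ref_counts=ref,
        alt_counts=alt,
        other_counts=other,
        het_only=het_only,
    )


def binom_test_matrix(
    ds: ASEDataset,
    expected=0.5,
    strand: str = "both",
    min_depth: int = 10,
    het_only: bool = True,
) -> TestResult:
    """Exact binomial imbalance test per SNP x sample cell.

    ``expected`` may be a scalar, per-variant vector, per-cell matrix, or an
    :class:`ExpectedRatio`; entries must lie strictly in (0, 1).
    """
    return _test_matrix(ds, expected, strand, min_depth, het_only, "binom")


def chisq_test_matrix(
    ds: ASEDataset,
    expected=0.5,
    strand: str = "both",
    min_depth: int = 10,
    het_only: bool = True,
) -> TestResult:
    """Chi-square (1 df, no continuity correction) imbalance test per cell."""
    return _test_matrix(ds, expected, strand, min_depth, het_only, "chisq")


def adjust_pvalues(result: TestResult, method: str = "benjamini-hochberg") -> TestResult:
    """Multiple-testing adjustment over all non-missing cells jointly.

    Missing cells stay missing; ``method="none"`` is the identity.
    """
    if method not in ADJUST_METHODS:
        raise ValidationError(f"unknown adjustment method {method!r}; expected one of {ADJUST_METHODS}")
    if method == "none":
        return replace(result, p_adjusted=result.p_values.copy(), adjust_method="none")
    from statsmodels.stats.multitest import multipletests

    mask = np.isfinite(result.p_values)
    adjusted = np.full(result.p_values.shape, np.nan)
    if mask.any():
        sm_method = {"benjamini-hochberg": "fdr_bh", "bonferroni": "bonferroni"}[method]
        _, padj, _, _ = multipletests(result.p_values[mask], method=sm_method)
        adjusted[mask] = padj
    return replace(result, p_adjusted=adjusted, adjust_method=method)


def set_expected_from_counts(
    null_ds: ASEDataset,
    min_depth: int = 10,
    strand: str = "both",
    clamp: tuple[float, float] = (0.05, 0.95),
) -> ExpectedRatio:
    """Estimate per-variant expected ratios from material with 1:1 truth.

    The input should hold counts from reads with a known balanced origin —
    simulated reads distributed equally over both alleles, or genomic DNA —
    so any departure from 0.5 measures mapping bias.  The estimate is the
    pooled ref/(ref+alt) across samples, clamped to ``clamp``; variants whose
    pooled depth falls under ``min_depth`` fall back to 0.5.
    """
    ref, alt, _ = null_ds.ref_alt_counts(strand)
    pooled_ref = ref.sum(axis=0).astype(float)
    pooled_n = (ref + alt).sum(axis=0).astype(float)
    values = np.full(null_ds.n_variants, 0.5)
    ok = pooled_n >= min_depth
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = pooled_ref / np.maximum(pooled_n, 1.0)
    values[ok] = np.clip(frac[ok], clamp[0], clamp[1])
    return ExpectedRatio(values)
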