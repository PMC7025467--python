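"""f3 and f4 statistics with block-jackknife standard errors.

The f-statistics are moments of population allele frequencies:

* admixture f3(X; Y, W) = E[(x - y)(x - w)].  Under any tree relating the
  three populations this is the drift on the branch leading to X and hence
  nonnegative; a significantly negative value implies X is admixed between
  sources related to Y and W.
* outgroup f3(O; T, R) is the same moment with an outgroup as the apex; it
  estimates the shared drift between T and R relative to O and is used only
  for ranking candidate relatives (high = closer).
* f4(X, Y; W, Z) = E[(x - y)(w - z)].  Zero under treeness for concordant
  quartets, even in the presence of incomplete lineage sorting; a
  significantly nonzero value indicates gene flow.

Standard errors come from a weighted delete-one block jackknife over
contiguous SNP blocks (default 20 SNPs, the same genome-contiguous blocks
used by the covariance fit), which is robust to residual LD between nearby
SNPs.  Z = estimate / SE, and p-values use the normal tail.

The admixture f3 subtracts the sampling-noise term x(1-x)/(n_X - 1) per SNP
(n_X = sampled allele count in X), giving the standard unbiased estimator;
the correction is off by default for the outgroup form, where only the
ranking matters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genotype_io import AlleleFreqTable
from .ld_blocks import block_index

__all__ = [
    "FStatResult",
    "ZDiff",
    "block_jackknife",
    "f3_admixture",
    "f3_outgroup",
    "f4",
    "zdiff_outgroup",
    "holm_bonferroni",
]


@dataclass
class FStatResult:
    name: str
    pops: tuple
    estimate: float
    se: float
    z: float
    p: float
    n_blocks: int
    n_snps: int


@dataclass
class ZDiff:
    outgroup: str
    target: str
    ref1: str
    ref2: str
    zdiff: float
    d_estimate: float
    d_se: float


def block_jackknife(per_block_sums, per_block_counts):
    """Weighted delete-one-block jackknife for a ratio-of-sums estimator.

    The estimand is theta = (sum of per-SNP values) / (number of SNPs); the
    blocks may be unequal (the trailing genome block usually is).  Uses the
    weighted-jackknife variance of Busing, Meijer & van der Leeden (1999),
    which reduces to the textbook delete-1 formula for equal blocks.

    Returns ``(estimate, se, loo)`` where ``loo`` is the vector of
    leave-one-block-out estimates.
    """
    sums = np.asarray(per_block_sums, dtype=float)
    counts = np.asarray(per_block_counts, dtype=float)
    keep = counts > 0
    sums, counts = sums[keep], counts[keep]
    B = len(sums)
    if B < 2:
        raise ValueError("SE undefined with fewer than 2 informative blocks")
    n = counts.sum()
    theta = sums.sum() / n
    loo = (sums.sum() - sums) / (n - counts)
    h = n / counts
    theta_dot = B * theta - ((1 - counts / n) * loo).sum()
    pseudo = h * theta - (h - 1) * loo
    var = np.sum((pseudo - theta_dot) ** 2 / (h - 1)) / B
    return float(theta), float(np.sqrt(var)), loo


def _usable(freqs, totals, pop_idx, need_n2=()):
    """SNPs where every argument population has data (and >=2 alleles where
    a bias correction divides by n-1)."""
    ok = np.all(totals[pop_idx] > 0, axis=0)
    for i in need_n2:
        ok &= totals[i] > 1
    return ok


def _blocked_stat(u, blocks):
    ids = np.unique(blocks)
    sums = np.array([u[blocks == b].sum() for b in ids])
    counts = np.array([(blocks == b).sum() for b in ids])
    return sums, counts


def _per_snp_f3(freqs, totals, ix, iy, iw, bias_correct):
    x, y, w = freqs[ix], freqs[iy], freqs[iw]
    u = (x - y) * (x - w)
    if bias_correct:
        u = u - x * (1 - x) / (totals[ix] - 1)
    return u


def _result(name, pops, u, blocks, alternative):
    sums, counts = _blocked_stat(u, blocks)
    est, se, _ = block_jackknife(sums, counts)
    if se > 0:
        z = est / se
    else:  # degenerate inputs (e.g., identical populations)
        z = 0.0 if est == 0 else np.inf * np.sign(est)
    if alternative == "less":       # H1: f3 < 0 (admixture)
        p = float(stats.norm.cdf(z))
    else:                           # two-sided (f4) or ranking (outgroup f3)
        p = float(2 * stats.norm.sf(abs(z)))
    return FStatResult(name, tuple(pops), est, se, float(z), p,
                       int((counts > 0).sum()), int(len(u)))


def _indices(table, names):
    if len(set(names)) != len(names):
        raise ValueError(f"populations must be distinct, got {names}")
    return [table.populations.index(n) for n in names]


def f3_admixture(
    table: AlleleFreqTable, X: str, Y: str, W: str,
    block: int = 20, bias_correct: bool = True,
) -> FStatResult:
    """Admixture test f3(X; Y, W); one-sided p for H1: f3 < 0."""
    ix, iy, iw = _indices(table, (X, Y, W))
    freqs, totals = table.freqs(), table.totals
    ok = _usable(freqs, totals, [ix, iy, iw], need_n2=[ix] if bias_correct else [])
    if not ok.any():
        raise ValueError("no usable SNPs for this f3 configuration")
    u = _per_snp_f3(freqs[:, ok], totals[:, ok], ix, iy, iw, bias_correct)
    blocks = block_index(table.n_snps, block)[ok]
    return _result("f3", (X, Y, W), u, blocks, "less")


def f3_outgroup(
    table: AlleleFreqTable, O: str, target: str, ref: str,
    block: int = 20, bias_correct: bool = False,
) -> FStatResult:
    """Outgroup f3(O; target, ref): shared drift of target and ref given O."""
    io, it, ir = _indices(table, (O, target, ref))
    freqs, totals = table.freqs(), table.totals
    ok = _usable(freqs, totals, [io, it, ir], need_n2=[io] if bias_correct else [])
    if not ok.any():
        raise ValueError("no usable SNPs for this f3 configuration")
    u = _per_snp_f3(freqs[:, ok], totals[:, ok], io, it, ir, bias_correct)
    blocks = block_index(table.n_snps, block)[ok]
    return _result("f3_outgroup", (O, target, ref), u, blocks, "two-sided")


def f4(
    table: AlleleFreqTable, X: str, Y: str, W: str, Z: str, block: int = 20
) -> FStatResult:
    """Treeness test f4(X, Y; W, Z); two-sided p."""
    ix, iy, iw, iz = _indices(table, (X, Y, W, Z))
    freqs, totals = table.freqs(), table.totals
    ok = _usable(freqs, totals, [ix, iy, iw, iz])
    if not ok.any():
        raise ValueError("no usable SNPs for this f4 configuration")
    f = freqs[:, ok]
    u = (f[ix] - f[iy]) * (f[iw] - f[iz])
    blocks = block_index(table.n_snps, block)[ok]
    return _result("f4", (X, Y, W, Z), u, blocks, "two-sided")


def zdiff_outgroup(
    table: AlleleFreqTable, O: str, target: str, r1: str, r2: str,
    block: int = 20, bias_correct: bool = False,
) -> ZDiff:
    """|Z_diff| between f3(O; target, r1) and f3(O; target, r2).

    Computed from the per-block *paired* difference of the two per-SNP
    statistics on their common usable SNPs, so the (typically strong)
    correlation between the two outgroup-f3 values is accounted for.
    """
    io, it, i1, i2 = _indices(table, (O, target, r1, r2))
    freqs, totals = table.freqs(), table.totals
    ok = _usable(freqs, totals, [io, it, i1, i2],
                 need_n2=[io] if bias_correct else [])
    if not ok.any():
        raise ValueError("no usable SNPs common to both f3 configurations")
    f, t = freqs[:, ok], totals[:, ok]
    d = (_per_snp_f3(f, t, io, it, i1, bias_correct)
         - _per_snp_f3(f, t, io, it, i2, bias_correct))
    blocks = block_index(table.n_snps, block)[ok]
    sums, counts = _blocked_stat(d, blocks)
    est, se, _ = block_jackknife(sums, counts)
    if se > 0:
        z = abs(est) / se
    else:  # degenerate: references identical (d == 0 everywhere)
        z = 0.0 if est == 0 else np.inf
    return ZDiff(O, target, r1, r2, float(z), est, se)


def holm_bonferroni(pvalues, alpha: float = 0.05):
    """Holm's step-down familywise-error control.

    Returns ``(reject, adjusted)`` aligned to the input order.
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=alpha, method="holm")
    return reject, adjusted
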