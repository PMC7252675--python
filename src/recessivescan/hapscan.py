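"""Sliding-window haplotype association testing.

A window of 50 contiguous phased SNPs is shifted along each chromosome in
steps of 15 SNPs.  Within a window every haplotype (exact allele-string
match) with population frequency > 1% is tested for association with a
quantitative phenotype by ordinary least squares of the phenotype on an
intercept, the top principal components of the genomic relationship matrix
and a haplotype predictor coded additively (copy count), dominantly
(carrier indicator) or recessively (homozygote indicator).  Recessive tests
require the haplotype to be homozygous in at least 1% of individuals.

Multiple testing is handled with a Bonferroni threshold over the number of
haplotype tests actually performed, and the genomic inflation factor is

    lambda = median(qchisq(1 - p, 1)) / qchisq(0.5, 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .panel import HaplotypePanel, MISSING

MODELS = ("additive", "dominant", "recessive")


# ------------------------------------------------------------------ genotype QC

def hwe_exact_p(obs_het: int, obs_hom1: int, obs_hom2: int) -> float:
    """Two-sided Hardy-Weinberg exact test P (Wigginton-style recurrence, mid-p off)."""
    if min(obs_het, obs_hom1, obs_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = obs_het + obs_hom1 + obs_hom2
    if n == 0:
        return 1.0
    rare = 2 * min(obs_hom1, obs_hom2) + obs_het
    # probabilities over all possible heterozygote counts with fixed allele counts
    het_max = rare if (rare % 2 == obs_het % 2) else rare - 1
    mid = rare * (2 * n - rare) // (2 * n - 1) if (2 * n - 1) > 0 else 0
    if mid % 2 != rare % 2:
        mid += 1
    probs = {mid: 1.0}
    het = mid
    while het > 1:
        hom_r = (rare - het) // 2
        hom_c = n - het - hom_r
        probs[het - 2] = probs[het] * het * (het - 1.0) / (4.0 * (hom_r + 1.0) * (hom_c + 1.0))
        het -= 2
    het = mid
    while het <= het_max - 2:
        hom_r = (rare - het) // 2
        hom_c = n - het - hom_r
        probs[het + 2] = probs[het] * 4.0 * hom_r * hom_c / ((het + 2.0) * (het + 1.0))
        het += 2
    total = sum(probs.values())
    p_obs = probs.get(obs_het, 0.0)
    return min(1.0, sum(v for v in probs.values() if v <= p_obs * (1 + 1e-12)) / total)


def qc_genotypes(
    G: np.ndarray,
    markers: pd.DataFrame,
    max_missing: float = 0.20,
    min_maf: float = 0.005,
    hwe_alpha: float = 1e-5,
):
    """Sample- then SNP-level genotype QC; genotypes coded 0/1/2, missing = -1.

    Returns ``(G_filtered, markers_filtered, kept_samples, report)``.
    """
    G = np.asarray(G)
    n, m = G.shape
    miss = G < 0
    keep_s = np.flatnonzero(miss.mean(axis=1) <= max_missing)
    G = G[keep_s]
    miss = miss[keep_s]

    snp_missing = miss.mean(axis=0)
    called = (~miss).sum(axis=0).astype(float)
    alt = np.where(miss, 0, G).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(called > 0, alt / (2.0 * called), 0.0)
    maf = np.minimum(freq, 1.0 - freq)

    hwe_p = np.ones(m)
    candidate = (snp_missing <= max_missing) & (maf >= min_maf)
    for j in np.flatnonzero(candidate):
        col = G[:, j]
        col = col[col >= 0]
        hwe_p[j] = hwe_exact_p(
            int((col == 1).sum()), int((col == 0).sum()), int((col == 2).sum())
        )
    keep_m = candidate & (hwe_p >= hwe_alpha)
    report = {
        "n_samples_dropped": int(n - len(keep_s)),
        "n_snps_high_missing": int((snp_missing > max_missing).sum()),
        "n_snps_low_maf": int(((snp_missing <= max_missing) & (maf < min_maf)).sum()),
        "n_snps_hwe": int((candidate & (hwe_p < hwe_alpha)).sum()),
        "n_snps_kept": int(keep_m.sum()),
    }
    if not keep_m.any():
        raise ValueError("genotype QC removed every SNP")
    return G[:, keep_m], markers.iloc[keep_m].reset_index(drop=True), keep_s, report


def grm_pcs(G: np.ndarray, k: int = 10):
    """Top-k principal components of the VanRaden-style genomic relationship matrix.

    Genotypes are centred at twice the allele frequency and variance
    standardized; PCs are eigenvectors scaled by the square root of their
    eigenvalues.  Returns ``(pcs (n, k), eigenvalues (k,))``.
    """
    G = np.asarray(G, float)
    miss = G < 0
    called = (~miss).sum(axis=0).astype(float)
    alt = np.where(miss, 0.0, G).sum(axis=0)
    p = np.where(called > 0, alt / (2.0 * called), 0.0)
    poly = (p > 0) & (p < 1)
    G, p, miss = G[:, poly], p[poly], miss[:, poly]
    W = (G - 2.0 * p[None, :]) / np.sqrt(2.0 * p * (1.0 - p))[None, :]
    W[miss] = 0.0
    K = W @ W.T / W.shape[1]
    evals, evecs = np.linalg.eigh(K)
    order = np.argsort(evals)[::-1][:k]
    evals = np.clip(evals[order], 0.0, None)
    return evecs[:, order] * np.sqrt(evals)[None, :], evals


# ------------------------------------------------------------------ windows

@dataclass(frozen=True)
class Window:
    chrom: str
    start: int  # global marker index, inclusive
    end: int
    start_bp: int
    end_bp: int
    index: int  # window number within the chromosome

    @property
    def size(self) -> int:
        return self.end - self.start + 1


def enumerate_windows(markers: pd.DataFrame, window_size: int = 50, step: int = 15):
    """Full sliding windows per chromosome; windows never span chromosomes."""
    windows = []
    for chrom, sub in markers.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        w = 0
        for s in range(0, len(idx) - window_size + 1, step):
            e = s + window_size - 1
            windows.append(
                Window(
                    chrom=str(chrom),
                    start=int(idx[s]),
                    end=int(idx[e]),
                    start_bp=int(pos[s]),
                    end_bp=int(pos[e]),
                    index=w,
                )
            )
            w += 1
    return windows


def window_haplotypes(panel: HaplotypePanel, window: Window, min_freq: float = 0.01):
    """Distinct allele strings in a window with per-sample copy counts.

    Returns a list of ``(hap_string, copies (n,), freq)`` for haplotypes with
    frequency > ``min_freq``, most frequent first.  Copy counts are exact
    string matches on each phased chromosome.
    """
    sub = panel.H[:, window.start : window.end + 1]
    uniq, inverse, counts = np.unique(sub, axis=0, return_inverse=True, return_counts=True)
    n2 = sub.shape[0]
    order = np.argsort(counts)[::-1]
    out = []
    inv2 = inverse.reshape(-1, 2)
    for h in order:
        freq = counts[h] / n2
        if freq <= min_freq:
            continue
        copies = (inv2 == h).sum(axis=1).astype(np.int8)
        hap = "".join(str(int(a)) for a in uniq[h])
        out.append((hap, copies, float(freq)))
    return out


# ------------------------------------------------------------------ tests

def _code_predictor(copies: np.ndarray, model: str, min_hom_frac: float):
    n = len(copies)
    if model == "additive":
        return copies.astype(float)
    if model == "dominant":
        return (copies >= 1).astype(float)
    if model == "recessive":
        n_hom = int((copies == 2).sum())
        if n_hom < math.ceil(min_hom_frac * n):
            return None  # ineligible, not merely constant
        return (copies == 2).astype(float)
    raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")


def test_haplotype(y, pcs, copies, model: str, min_hom_frac: float = 0.01):
    """OLS association test of one haplotype; returns dict or None if skipped.

    Design: intercept + PCs + predictor; two-sided t-test on the predictor
    coefficient.
    """
    y = np.asarray(y, float)
    copies = np.asarray(copies)
    x = _code_predictor(copies, model, min_hom_frac)
    if x is None or np.ptp(x) == 0:
        return None
    C = np.column_stack([np.ones(len(y))] + ([pcs] if pcs is not None and
                                             np.size(pcs) else []))
    Q, _ = np.linalg.qr(C)
    return _fwl_test(y - Q @ (Q.T @ y), x - Q @ (Q.T @ x), len(y) - C.shape[1] - 1)


def _fwl_test(y_res, x_res, df):
    sxx = float(x_res @ x_res)
    if sxx <= 0 or df <= 0:
        return None
    beta = float(x_res @ y_res) / sxx
    rss = float(y_res @ y_res) - beta * beta * sxx
    sigma2 = max(rss, 0.0) / df
    se = math.sqrt(sigma2 / sxx)
    if se == 0:
        p = 0.0
        t = math.inf
    else:
        t = beta / se
        p = 2.0 * stats.t.sf(abs(t), df)
    return {"beta": beta, "se": se, "t": t, "p": max(p, 5e-324)}


def bonferroni_alpha(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise threshold over the number of haplotype tests performed."""
    if n_tests < 1:
        raise ValueError("n_tests must be positive")
    return alpha / n_tests


def genomic_lambda(p_values) -> float:
    """median(qchisq(1-p, 1)) / qchisq(0.5, 1)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise ValueError("no P values")
    return float(np.median(stats.chi2.isf(p, 1)) / stats.chi2.ppf(0.5, 1))


@dataclass
class ScanResult:
    records: pd.DataFrame
    n_tests: int
    n_windows: int
    bonferroni_alpha: float
    lambda_: float
    model: str
    dropped_samples: list = field(default_factory=list)

    def top(self, k: int = 1) -> pd.DataFrame:
        return self.records.nsmallest(k, "p")

    def significant(self) -> pd.DataFrame:
        return self.records[self.records["p"] < self.bonferroni_alpha]

    def summary(self) -> dict:
        top = self.top(1)
        return {
            "model": self.model,
            "n_windows": self.n_windows,
            "n_tests": self.n_tests,
            "bonferroni_alpha": self.bonferroni_alpha,
            "lambda": self.lambda_,
            "n_significant": int(len(self.significant())),
            "top_p": float(top["p"].iloc[0]) if len(top) else None,
            "top_window": (
                {
                    "chrom": str(top["chrom"].iloc[0]),
                    "start_bp": int(top["start_bp"].iloc[0]),
                    "end_bp": int(top["end_bp"].iloc[0]),
                    "haplotype": str(top["haplotype"].iloc[0]),
                }
                if len(top)
                else None
            ),
        }


def scan(
    panel: HaplotypePanel,
    y,
    pcs=None,
    model: str = "recessive",
    window_size: int = 50,
    step: int = 15,
    min_freq: float = 0.01,
    min_hom_frac: float = 0.01,
    condition=None,
    alpha: float = 0.05,
) -> ScanResult:
    """Genome scan: all windows x qualifying haplotypes under one model.

    ``y`` may be a pandas Series indexed by sample id (samples without a
    phenotype are dropped) or an array aligned with ``panel.samples``.
    ``condition`` is an optional per-sample covariate added to every
    regression (used by :func:`conditional_scan`).
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    if isinstance(y, pd.Series):
        y = y.reindex(panel.samples)
        keep = np.flatnonzero(y.notna().to_numpy())
        dropped = [s for i, s in enumerate(panel.samples) if i not in set(keep)]
        y = y.to_numpy(float)[keep]
    else:
        y = np.asarray(y, float)
        keep = np.flatnonzero(~np.isnan(y))
        dropped = [s for i, s in enumerate(panel.samples) if i not in set(keep)]
        y = y[keep]
    hap_rows = np.stack([2 * keep, 2 * keep + 1], axis=1).ravel()
    H = panel.H[hap_rows]
    sub = HaplotypePanel(
        samples=[panel.samples[i] for i in keep], markers=panel.markers, H=H
    )
    n = len(y)

    cols = [np.ones(n)]
    if pcs is not None and np.size(pcs):
        cols.append(np.asarray(pcs, float)[keep])
    if condition is not None:
        cond = np.asarray(condition, float)[keep]
        if np.ptp(cond) > 0:
            cols.append(cond.reshape(-1, 1))
        else:
            warnings.warn("conditioning covariate is constant; ignored", stacklevel=2)
    C = np.column_stack(cols)
    Q, _ = np.linalg.qr(C)
    y_res = y - Q @ (Q.T @ y)
    df = n - C.shape[1] - 1

    windows = enumerate_windows(sub.markers, window_size, step)
    rows = []
    for w in windows:
        for hap, copies, freq in window_haplotypes(sub, w, min_freq):
            if freq >= 1.0:
                continue
            x = _code_predictor(copies, model, min_hom_frac)
            if x is None or np.ptp(x) == 0:
                continue
            res = _fwl_test(y_res, x - Q @ (Q.T @ x), df)
            if res is None:
                continue
            rows.append(
                {
                    "chrom": w.chrom,
                    "window_index": w.index,
                    "start": w.start,
                    "end": w.end,
                    "start_bp": w.start_bp,
                    "end_bp": w.end_bp,
                    "haplotype": hap,
                    "model": model,
                    "freq": freq,
                    "n_hom": int((copies == 2).sum()),
                    "beta": res["beta"],
                    "se": res["se"],
                    "p": res["p"],
                }
            )
    records = pd.DataFrame(
        rows,
        columns=[
            "chrom", "window_index", "start", "end", "start_bp", "end_bp",
            "haplotype", "model", "freq", "n_hom", "beta", "se", "p",
        ],
    )
    n_tests = len(records)
    return ScanResult(
        records=records,
        n_tests=n_tests,
        n_windows=len(windows),
        bonferroni_alpha=bonferroni_alpha(n_tests, alpha) if n_tests else float("nan"),
        lambda_=genomic_lambda(records["p"]) if n_tests else float("nan"),
        model=model,
        dropped_samples=dropped,
    )


def conditional_scan(
    panel: HaplotypePanel,
    y,
    pcs,
    model: str,
    condition_status,
    **kwargs,
) -> ScanResult:
    """Re-scan with the top-haplotype status as an extra covariate.

    ``condition_status`` maps each sample to its copy count (0/1/2) of the
    conditioning haplotype.  The covariate is the homozygosity indicator for
    a recessive scan, the carrier indicator for a dominant scan and the copy
    count for an additive scan.
    """
    if isinstance(condition_status, pd.Series):
        condition_status = condition_status.reindex(panel.samples).to_numpy(float)
    copies = np.asarray(condition_status, float)
    if model == "recessive":
        cov = (copies == 2).astype(float)
    elif model == "dominant":
        cov = (copies >= 1).astype(float)
    else:
        cov = copies
    return scan(panel, y, pcs=pcs, model=model, condition=cov, **kwargs)
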