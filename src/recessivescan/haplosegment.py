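"""Haplotype copy-number assignment and shared-autozygosity fine-mapping.

Starting from the associated seed window, the shared segment is extended
marker-by-marker in both directions for as long as every homozygous carrier
is homozygous AND all carriers share the same homozygous genotype; the
reported boundaries are the outermost conforming markers.  Because imputed
panels are complete, missing genotypes default to "conforming" (skip), but
this is configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import HaplotypePanel, MISSING
from .hapscan import Window


def assign_status(panel: HaplotypePanel, window: Window, hap_string: str) -> pd.Series:
    """Copies (0/1/2) of the allele string per sample; exact string match per chromosome."""
    if len(hap_string) != window.size:
        raise ValueError("haplotype string length does not match the window")
    target = np.frombuffer(hap_string.encode(), dtype=np.uint8) - ord("0")
    sub = panel.H[:, window.start : window.end + 1]
    match = (sub == target[None, :]).all(axis=1)
    copies = match.reshape(-1, 2).sum(axis=1)
    return pd.Series(copies.astype(int), index=panel.samples, name="copies")


@dataclass
class SharedSegment:
    chrom: str
    start_bp: int
    end_bp: int
    start: int  # global marker indices of the outermost conforming markers
    end: int
    n_markers: int
    n_carriers: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp

    def to_bed(self) -> str:
        """BED line (0-based half-open)."""
        return f"{self.chrom}\t{self.start_bp - 1}\t{self.end_bp}"


def shared_segment(
    panel: HaplotypePanel,
    status: pd.Series,
    seed_window: Window,
    on_missing: str = "skip",
    on_nonconforming_seed: str = "error",
) -> SharedSegment:
    """Maximal segment of shared autozygosity among homozygous carriers.

    Parameters
    ----------
    status : per-sample copy count of the seed haplotype; carriers are copies == 2.
    on_missing : 'skip' treats missing genotypes as conforming, 'break' stops there.
    on_nonconforming_seed : 'error' or 'warn' when a carrier is not homozygous
        inside the seed window itself.
    """
    if on_missing not in ("skip", "break"):
        raise ValueError("on_missing must be 'skip' or 'break'")
    carriers = [s for s in panel.samples if status.get(s, 0) == 2]
    if len(carriers) < 2:
        raise ValueError("shared-segment search requires at least 2 homozygous carriers")
    rows = np.array(
        [[2 * panel.sample_index(s), 2 * panel.sample_index(s) + 1] for s in carriers]
    ).ravel()
    H = panel.H[rows]  # (2K, M)
    a, b = H[0::2].astype(np.int16), H[1::2].astype(np.int16)
    miss = (a == MISSING) | (b == MISSING)

    def conforming(j: int) -> bool:
        col_a, col_b, col_m = a[:, j], b[:, j], miss[:, j]
        if col_m.any():
            if on_missing == "break":
                return False
            called = ~col_m
            if not called.any():
                return True  # nothing contradicts sharing
            col_a, col_b = col_a[called], col_b[called]
        if (col_a != col_b).any():
            return False
        return col_a.min() == col_a.max()

    chrom_idx = panel.chrom_indices(seed_window.chrom)
    lo, hi = int(chrom_idx[0]), int(chrom_idx[-1])

    for j in range(seed_window.start, seed_window.end + 1):
        if not conforming(j):
            msg = "a homozygous carrier is heterozygous inside the seed window"
            if on_nonconforming_seed == "error":
                raise ValueError(msg)
            warnings.warn(msg + "; reporting the seed window without extension",
                          stacklevel=2)
            return _make_segment(panel, seed_window, seed_window.start,
                                 seed_window.end, len(carriers))

    left = seed_window.start
    while left - 1 >= lo and conforming(left - 1):
        left -= 1
    right = seed_window.end
    while right + 1 <= hi and conforming(right + 1):
        right += 1
    return _make_segment(panel, seed_window, left, right, len(carriers))


def _make_segment(panel, seed_window, left, right, n_carriers) -> SharedSegment:
    pos = panel.markers["pos"]
    return SharedSegment(
        chrom=seed_window.chrom,
        start_bp=int(pos.iloc[left]),
        end_bp=int(pos.iloc[right]),
        start=int(left),
        end=int(right),
        n_markers=right - left + 1,
        n_carriers=n_carriers,
    )
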