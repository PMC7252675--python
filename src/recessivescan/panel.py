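"""Phased haplotype panel and marker map containers.

A :class:`HaplotypePanel` holds phased biallelic alleles (coded 0/1) for N
individuals over an ordered marker map.  Haplotypes are stored row-wise in a
``(2N, M)`` uint8 array; rows ``2i`` and ``2i+1`` belong to sample ``i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = 255  # sentinel for a missing allele

MARKER_COLUMNS = ["snp_id", "chrom", "pos", "ref", "alt"]


def validate_markers(markers: pd.DataFrame) -> pd.DataFrame:
    """Check marker-map invariants: required columns, strictly increasing pos per chrom."""
    missing = [c for c in ("snp_id", "chrom", "pos") if c not in markers.columns]
    if missing:
        raise ValueError(f"marker map lacks columns: {missing}")
    markers = markers.reset_index(drop=True)
    for chrom, sub in markers.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        if not np.all(np.diff(pos) > 0):
            raise ValueError(f"marker positions not strictly increasing on chrom {chrom}")
    return markers


@dataclass
class HaplotypePanel:
    samples: list[str]
    markers: pd.DataFrame
    H: np.ndarray  # (2N, M) uint8 in {0, 1, MISSING}

    def __post_init__(self) -> None:
        self.markers = validate_markers(self.markers)
        self.H = np.asarray(self.H, dtype=np.uint8)
        if self.H.shape != (2 * len(self.samples), len(self.markers)):
            raise ValueError(
                f"haplotype array shape {self.H.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        ok = (self.H == 0) | (self.H == 1) | (self.H == MISSING)
        if not ok.all():
            raise ValueError("allele values must be 0, 1 or missing")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def chroms(self) -> list:
        return list(dict.fromkeys(self.markers["chrom"]))

    def chrom_indices(self, chrom) -> np.ndarray:
        """Global marker indices belonging to ``chrom`` (contiguous by construction)."""
        return np.flatnonzero((self.markers["chrom"] == chrom).to_numpy())

    def genotypes(self) -> np.ndarray:
        """(N, M) allele-dosage matrix; missing if either haplotype is missing."""
        a, b = self.H[0::2], self.H[1::2]
        g = (a.astype(np.int16) + b.astype(np.int16)).astype(np.int16)
        g[(a == MISSING) | (b == MISSING)] = -1
        return g

    def sample_index(self, sample_id: str) -> int:
        return self.samples.index(sample_id)

    # ------------------------------------------------------------------ I/O

    def write_vcf(self, path: str) -> None:
        """Write the panel as a phased VCF 4.2 text file (bgzipped if *.gz)."""
        lines = ["##fileformat=VCFv4.2"]
        for chrom in self.chroms:
            idx = self.chrom_indices(chrom)
            maxpos = int(self.markers["pos"].iloc[idx[-1]]) + 1000
            lines.append(f"##contig=<ID={chrom},length={maxpos}>")
        lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
        lines.append(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(self.samples)
        )
        ref = self.markers.get("ref", pd.Series(["A"] * self.n_markers))
        alt = self.markers.get("alt", pd.Series(["C"] * self.n_markers))
        a, b = self.H[0::2], self.H[1::2]
        for j in range(self.n_markers):
            row = self.markers.iloc[j]
            gts = [
                "./."
                if a[i, j] == MISSING or b[i, j] == MISSING
                else f"{a[i, j]}|{b[i, j]}"
                for i in range(self.n_samples)
            ]
            lines.append(
                f"{row['chrom']}\t{int(row['pos'])}\t{row['snp_id']}\t{ref.iloc[j]}\t"
                f"{alt.iloc[j]}\t.\tPASS\t.\tGT\t" + "\t".join(gts)
            )
        text = "\n".join(lines) + "\n"
        if str(path).endswith(".gz"):
            import pysam

            with pysam.BGZFile(str(path), "wb") as fh:
                fh.write(text.encode())
        else:
            with open(path, "w") as fh:
                fh.write(text)

    @classmethod
    def from_vcf(cls, path: str) -> "HaplotypePanel":
        """Load a phased biallelic VCF (``|``-separated GT) into a panel."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        rows, haps = [], []
        for var in vcf:
            if len(var.ALT) != 1:
                continue
            gt = np.array(var.genotype.array())  # (N, 3): a, b, phased
            col = np.empty(2 * len(samples), dtype=np.uint8)
            col[0::2] = np.where(gt[:, 0] < 0, MISSING, gt[:, 0])
            col[1::2] = np.where(gt[:, 1] < 0, MISSING, gt[:, 1])
            haps.append(col)
            rows.append(
                {
                    "snp_id": var.ID or f"{var.CHROM}:{var.POS}",
                    "chrom": var.CHROM,
                    "pos": var.POS,
                    "ref": var.REF,
                    "alt": var.ALT[0],
                }
            )
        markers = pd.DataFrame(rows, columns=MARKER_COLUMNS)
        H = np.column_stack(haps) if haps else np.zeros((2 * len(samples), 0), np.uint8)
        return cls(samples=samples, markers=markers, H=H)

    def write_matrix(self, hap_path: str, marker_path: str) -> None:
        """Plain-text alternative to VCF: one haplotype row per line + markers.tsv."""
        self.markers.to_csv(marker_path, sep="\t", index=False)
        with open(hap_path, "w") as fh:
            for i, sid in enumerate(self.samples):
                for k in (0, 1):
                    alleles = "".join(
                        "." if v == MISSING else str(int(v)) for v in self.H[2 * i + k]
                    )
                    fh.write(f"{sid}\t{k}\t{alleles}\n")

    @classmethod
    def from_matrix(cls, hap_path: str, marker_path: str) -> "HaplotypePanel":
        markers = pd.read_csv(marker_path, sep="\t", dtype={"chrom": str})
        samples: list[str] = []
        rows = []
        with open(hap_path) as fh:
            for line in fh:
                sid, _k, alleles = line.rstrip("\n").split("\t")
                if not samples or samples[-1] != sid:
                    samples.append(sid)
                rows.append(
                    np.frombuffer(
                        alleles.replace(".", chr(MISSING)).encode("latin1"), dtype=np.uint8
                    )
                    - ord("0")
                )
        H = np.vstack(rows).astype(np.int16)
        H[H == MISSING - ord("0")] = MISSING
        return cls(samples=samples, markers=markers, H=H.astype(np.uint8))
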