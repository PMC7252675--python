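"""Cryptic splice-donor gain detection and junction-read tallying.

A single-nucleotide variant inside an exon can create or strengthen a GT
splice-donor motif; if the spliceosome uses the new donor, the exon is
truncated by the distance between the cryptic and the natural donor.  A
truncation divisible by three deletes truncation/3 residues in frame; any
other length shifts the reading frame.  Donor strength is scored with a
position weight matrix over the -3..+6 donor context (log2 odds against a
uniform background), built from generic vertebrate donor-site base
frequencies shipped with the package.

Junction usage is quantified from spliced read alignments: a read supports
a junction when two consecutive aligned blocks end exactly at the donor
exon end and start exactly at the acceptor, with a minimum aligned overhang
on both sides.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

PWM_POSITIONS = (-3, -2, -1, 1, 2, 3, 4, 5, 6)


def load_donor_pwm() -> pd.DataFrame:
    """Donor-site base-frequency matrix (rows -3..+6, columns A/C/G/T)."""
    with resources.files("recessivescan.data").joinpath("donor_pwm.tsv").open() as fh:
        pwm = pd.read_csv(fh, sep="\t", comment="#", index_col="pos")
    return pwm


_PWM = None


def donor_pwm_score(ninemer: str) -> float:
    """Log2-odds donor score of a 9-mer spanning -3..+6 of a candidate donor.

    The GT dinucleotide must sit at positions +1/+2 (string indices 3-4).
    """
    global _PWM
    if _PWM is None:
        _PWM = load_donor_pwm()
    ninemer = ninemer.upper()
    if len(ninemer) != 9:
        raise ValueError("donor context must be exactly 9 bases (-3..+6)")
    if ninemer[3:5] != "GT":
        raise ValueError("candidate donor lacks the invariant GT at +1/+2")
    score = 0.0
    for base, pos in zip(ninemer, PWM_POSITIONS):
        if base not in "ACGT":
            raise ValueError(f"unexpected base {base!r} in donor context")
        score += math.log2(_PWM.at[pos, base] / 0.25)
    return score


# ------------------------------------------------------------------ gene model

@dataclass
class GeneModel:
    """Plus-strand internal representation of a protein-coding gene.

    ``exons`` are 1-based inclusive genomic intervals ordered 5'->3';
    ``cds_start``/``cds_end`` are the genomic positions of the first and last
    coding base.  Minus-strand genes are expected to be reverse-complemented
    (with coordinates remapped) before construction.
    """

    gene_id: str
    exons: list
    cds_start: int
    cds_end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        prev_end = -1
        for s, e in self.exons:
            if s > e or s <= prev_end:
                raise ValueError("exons must be ordered, non-overlapping, start <= end")
            prev_end = e
        if not any(s <= self.cds_start <= e for s, e in self.exons):
            raise ValueError("cds_start not inside an exon")

    def exon_of(self, pos: int):
        for i, (s, e) in enumerate(self.exons):
            if s <= pos <= e:
                return i
        return None

    def cds_intervals(self) -> list:
        out = []
        for s, e in self.exons:
            s2, e2 = max(s, self.cds_start), min(e, self.cds_end)
            if s2 <= e2:
                out.append((s2, e2))
        return out

    def cds_pos(self, pos: int) -> int:
        """1-based coding-sequence coordinate of a genomic position."""
        total = 0
        for s, e in self.cds_intervals():
            if s <= pos <= e:
                return total + (pos - s) + 1
            total += e - s + 1
        raise ValueError(f"position {pos} is not coding")

    def exon_phase(self, exon_index: int) -> int:
        """Reading-frame phase at the start of an exon's coding part."""
        s, _e = self.cds_intervals()[0] if exon_index == 0 else (None, None)
        start = max(self.exons[exon_index][0], self.cds_start)
        return (self.cds_pos(start) - 1) % 3

    @classmethod
    def from_tsv(cls, path: str) -> "GeneModel":
        """GFF3-like TSV: columns gene_id, strand, feature, start, end.

        Rows with feature == 'exon' define exons; a single 'CDS' row defines
        the coding span.
        """
        df = pd.read_csv(path, sep="\t")
        exons = [
            (int(r.start), int(r.end))
            for r in df[df["feature"] == "exon"].itertuples()
        ]
        cds = df[df["feature"] == "CDS"].iloc[0]
        return cls(
            gene_id=str(df["gene_id"].iloc[0]),
            exons=sorted(exons),
            cds_start=int(cds["start"]),
            cds_end=int(cds["end"]),
            strand=str(df["strand"].iloc[0]),
        )


# ------------------------------------------------------------------ donor gains

@dataclass
class DonorSiteCall:
    gt_pos: int  # genomic position of the G of the cryptic GT
    ref_score: float
    alt_score: float
    truncation: int  # bases removed from the exon 3' end
    frame: str  # 'in-frame' | 'frameshift'
    exon_index: int
    deleted_residues: tuple | None = None  # 1-based inclusive protein interval

    def __post_init__(self) -> None:
        if self.truncation < 1:
            raise ValueError("truncation must be >= 1")
        expected = "in-frame" if self.truncation % 3 == 0 else "frameshift"
        if self.frame != expected:
            raise ValueError("frame label inconsistent with truncation length")


@dataclass
class SpliceJunctionPair:
    wt_donor_end: int  # 1-based last exonic base of the wild-type exon
    truncation: int
    acceptor_start: int  # 1-based first base of the next exon

    @property
    def mt_donor_end(self) -> int:
        return self.wt_donor_end - self.truncation

    def __post_init__(self) -> None:
        if self.truncation < 1:
            raise ValueError("mutant exon end must precede the wild-type exon end")
        if self.acceptor_start <= self.wt_donor_end:
            raise ValueError("acceptor must lie downstream of the donor")


def find_donor_gain(
    variant,
    gene_model: GeneModel,
    seq: str,
    seq_start: int,
    threshold: float = 0.0,
) -> list:
    """Exonic donor gains created by a variant; list of :class:`DonorSiteCall`.

    ``variant`` is ``(chrom, pos, ref, alt)`` with 1-based ``pos``; ``seq`` is
    the reference sequence window starting at genomic position ``seq_start``
    and must cover the affected exon plus 50 bp of context.  A site is
    reported when its alt-allele context contains the variant, scores at
    least ``threshold`` bits and scores strictly higher than the reference
    context.
    """
    _chrom, pos, ref, alt = variant
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError("only single-nucleotide variants are supported")
    exon_index = gene_model.exon_of(pos)
    if exon_index is None:
        warnings.warn("variant is not exonic; no donor-gain search performed",
                      stacklevel=2)
        return []
    off = pos - seq_start
    if not (0 <= off < len(seq)) or seq[off].upper() != ref.upper():
        raise ValueError("reference allele does not match the sequence window")
    alt_seq = seq[:off] + alt + seq[off + 1 :]

    estart, eend = gene_model.exons[exon_index]
    calls = []
    for g in range(estart + 1, eend):  # cryptic donor strictly inside the exon
        i = g - seq_start
        if i - 3 < 0 or i + 6 > len(seq):
            continue
        if alt_seq[i : i + 2].upper() != "GT":
            continue
        if not (g - 3 <= pos <= g + 5):
            continue  # variant outside the -3..+6 context
        alt_score = donor_pwm_score(alt_seq[i - 3 : i + 6])
        if seq[i : i + 2].upper() == "GT":
            ref_score = donor_pwm_score(seq[i - 3 : i + 6])
        else:
            ref_score = -math.inf
        if alt_score < threshold or not (alt_score > ref_score):
            continue
        truncation = eend - (g - 1)
        call = DonorSiteCall(
            gt_pos=g,
            ref_score=ref_score,
            alt_score=alt_score,
            truncation=truncation,
            frame="in-frame" if truncation % 3 == 0 else "frameshift",
            exon_index=exon_index,
        )
        if call.frame == "in-frame" and gene_model.cds_start <= eend <= gene_model.cds_end:
            call.deleted_residues = protein_deletion(call, gene_model)
        calls.append(call)
    return calls


def protein_deletion(call: DonorSiteCall, gene_model: GeneModel) -> tuple:
    """1-based inclusive residue interval removed by an in-frame truncation."""
    if call.truncation % 3 != 0:
        raise ValueError("protein deletion is only defined for in-frame truncations")
    _s, eend = gene_model.exons[call.exon_index]
    c2 = gene_model.cds_pos(min(eend, gene_model.cds_end))
    c1 = c2 - call.truncation + 1
    first = (c1 + 2) // 3
    return (first, first + call.truncation // 3 - 1)


# ------------------------------------------------------------------ junction tally

@dataclass
class JunctionTally:
    wt_reads: int
    mt_reads: int
    unassigned: int

    def as_tuple(self):
        return (self.wt_reads, self.mt_reads, self.unassigned)


def _blocks(read) -> list:
    """Aligned reference blocks (1-based inclusive), split only at N operations."""
    blocks = []
    ref = read.reference_start  # 0-based
    cur_start = None
    for op, length in read.cigartuples or []:
        if op in (0, 2, 7, 8):  # M, D, =, X consume reference within a block
            if cur_start is None:
                cur_start = ref
            ref += length
        elif op == 3:  # N splits blocks
            if cur_start is not None:
                blocks.append((cur_start + 1, ref))
                cur_start = None
            ref += length
        # I, S, H, P do not consume reference
    if cur_start is not None:
        blocks.append((cur_start + 1, ref))
    return blocks


def _supports(blocks, donor_end: int, acceptor_start: int, min_overhang: int) -> bool:
    for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
        if e1 == donor_end and s2 == acceptor_start:
            if e1 - s1 + 1 >= min_overhang and e2 - s2 + 1 >= min_overhang:
                return True
    return False


def tally_junctions(sam_path: str, pair: SpliceJunctionPair, min_overhang: int = 6
                    ) -> JunctionTally:
    """Count reads supporting the wild-type vs the truncated exon junction.

    A read overlapping the wild-type junction interval that matches neither
    junction exactly (or matches with insufficient overhang) is counted as
    unassigned, so wt + mt + unassigned equals the number of overlapping
    reads.
    """
    import pysam

    wt = mt = unassigned = 0
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for read in sam:
            if read.is_unmapped or read.cigartuples is None:
                continue
            blocks = _blocks(read)
            if not blocks:
                continue
            span_start, span_end = blocks[0][0], blocks[-1][1]
            overlaps = span_start <= pair.wt_donor_end and span_end >= pair.acceptor_start
            if not overlaps:
                continue
            if _supports(blocks, pair.wt_donor_end, pair.acceptor_start, min_overhang):
                wt += 1
            elif _supports(blocks, pair.mt_donor_end, pair.acceptor_start, min_overhang):
                mt += 1
            else:
                unassigned += 1
    return JunctionTally(wt_reads=wt, mt_reads=mt, unassigned=unassigned)
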