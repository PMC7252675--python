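"""Frequency-threshold filtration of variants for recessive compatibility.

Candidate causal variants for a recessive haplotype must have an alternate
allele frequency that is high in homozygous haplotype carriers, intermediate
in heterozygous carriers and near zero in non-carriers.  Frequencies (not
hard genotype requirements) absorb sequencing errors, under-called
heterozygotes at low coverage and occasional haplotype misclassification.
All three thresholds are inclusive; frequencies are computed over called
alleles only, and a variant whose frequency is undefined in any group
(all genotypes missing) fails closed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class StatusGroups:
    homozygous: list
    heterozygous: list
    noncarrier: list

    def __post_init__(self) -> None:
        groups = [set(self.homozygous), set(self.heterozygous), set(self.noncarrier)]
        if sum(len(g) for g in groups) != len(set().union(*groups)):
            raise ValueError("status groups must be disjoint")
        if not self.homozygous:
            raise ValueError("homozygous group must be non-empty")

    @classmethod
    def from_status(cls, status: pd.Series) -> "StatusGroups":
        return cls(
            homozygous=list(status.index[status == 2]),
            heterozygous=list(status.index[status == 1]),
            noncarrier=list(status.index[status == 0]),
        )


@dataclass
class CompatibilityRule:
    min_hom_freq: float = 0.8
    het_freq_range: tuple = (0.4, 0.6)
    max_noncarrier_freq: float = 0.05

    def validate(self) -> None:
        vals = [self.min_hom_freq, *self.het_freq_range, self.max_noncarrier_freq]
        if any(not (0.0 <= v <= 1.0) for v in vals):
            raise ValueError("thresholds must be within [0, 1]")
        if self.het_freq_range[0] > self.het_freq_range[1]:
            raise ValueError("empty heterozygote frequency interval")


@dataclass
class GroupedVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str  # SNP / indel / SV type
    freqs: dict  # group -> alt frequency or None (no called alleles)
    called: dict  # group -> number of called alleles
    consequence: str = ""
    info: dict = field(default_factory=dict)


def _variant_class(ref: str, alt: str, svtype: str | None = None) -> str:
    if alt.startswith("<") or svtype:
        return svtype or alt.strip("<>")
    if len(ref) == 1 and len(alt) == 1:
        return "SNP"
    return "indel"


def _group_freq(alleles: np.ndarray, members: np.ndarray, alt_code: int):
    """Alt frequency over called alleles of a sample subset; None if none called."""
    sub = alleles[members].ravel()
    called = sub[sub >= 0]
    if called.size == 0:
        return None, 0
    return float((called == alt_code).sum() / called.size), int(called.size)


def group_frequencies(variant, groups: StatusGroups, sample_order, alt_index: int = 0
                      ) -> GroupedVariant:
    """Per-group alternate-allele frequencies for one cyvcf2 record.

    ``sample_order`` is the VCF's sample list; both ``|`` and ``/`` genotype
    separators are accepted, and missing genotypes are excluded from the
    denominator.  Multi-allelic records are assessed one alternate allele at
    a time (``alt_index``).
    """
    pos = {s: i for i, s in enumerate(sample_order)}
    gt = np.array(variant.genotype.array())[:, :2]
    members = {
        "homozygous": np.array([pos[s] for s in groups.homozygous], dtype=int),
        "heterozygous": np.array([pos[s] for s in groups.heterozygous], dtype=int),
        "noncarrier": np.array([pos[s] for s in groups.noncarrier], dtype=int),
    }
    freqs, called = {}, {}
    for name, idx in members.items():
        f, c = _group_freq(gt, idx, alt_index + 1)
        freqs[name], called[name] = f, c
    csq = variant.INFO.get("CSQ") or variant.INFO.get("ANN") or ""
    svtype = variant.INFO.get("SVTYPE")
    return GroupedVariant(
        chrom=str(variant.CHROM),
        pos=int(variant.POS),
        ref=variant.REF,
        alt=variant.ALT[alt_index],
        variant_class=_variant_class(variant.REF, variant.ALT[alt_index], svtype),
        freqs=freqs,
        called=called,
        consequence=str(csq),
        info={"VIOL": variant.INFO.get("VIOL")},
    )


def is_compatible(gv: GroupedVariant, rule: CompatibilityRule | None = None):
    """Recessive-compatibility check; returns ``(bool, failure reasons)``."""
    rule = rule or CompatibilityRule()
    rule.validate()
    reasons = []
    f = gv.freqs
    if f["homozygous"] is None:
        reasons.append("homozygous: no called alleles")
    elif f["homozygous"] < rule.min_hom_freq:
        reasons.append(f"homozygous freq {f['homozygous']:.3f} < {rule.min_hom_freq}")
    if f["heterozygous"] is None:
        if len(gv.called) and gv.called.get("heterozygous", 0) == 0:
            reasons.append("heterozygous: no called alleles")
    elif not (rule.het_freq_range[0] <= f["heterozygous"] <= rule.het_freq_range[1]):
        reasons.append(
            f"heterozygous freq {f['heterozygous']:.3f} outside {rule.het_freq_range}"
        )
    if f["noncarrier"] is None:
        reasons.append("noncarrier: no called alleles")
    elif f["noncarrier"] > rule.max_noncarrier_freq:
        reasons.append(f"noncarrier freq {f['noncarrier']:.3f} > {rule.max_noncarrier_freq}")
    return (len(reasons) == 0), reasons


def filter_region(
    vcf_path: str,
    region: str,
    groups: StatusGroups,
    rule: CompatibilityRule | None = None,
    inner_interval: tuple | None = None,
):
    """Stream a region and return compatible variants plus summary counts.

    ``region`` is ``chrom:start-end`` (1-based inclusive).  ``inner_interval``
    optionally counts compatible variants inside a secondary interval such as
    the shared-autozygosity segment.  Returns ``(compatible list, summary)``;
    the summary tallies totals, per-class and per-consequence counts and the
    failure reasons of incompatible variants.
    """
    from cyvcf2 import VCF

    rule = rule or CompatibilityRule()
    chrom, _, span = region.partition(":")
    if not span:
        raise ValueError("region must be chrom:start-end")
    start, end = (int(x) for x in span.split("-"))
    vcf = VCF(str(vcf_path))
    contigs = set(vcf.seqnames)
    if contigs and chrom not in contigs:
        raise ValueError(f"region chromosome {chrom!r} absent from the VCF header")
    samples = list(vcf.samples)
    for s in groups.homozygous + groups.heterozygous + groups.noncarrier:
        if s not in samples:
            raise ValueError(f"sample {s!r} not in the VCF")

    import os

    has_index = any(os.path.exists(f"{vcf_path}{ext}") for ext in (".tbi", ".csi"))
    if has_index:
        iterator = vcf(region)
    else:  # plain-text VCF: stream everything, filter manually
        iterator = (v for v in vcf if v.CHROM == chrom and start <= v.POS <= end)

    compatible = []
    summary = {
        "n_seen": 0,
        "n_skipped_all_missing": 0,
        "n_compatible": 0,
        "by_class": {},
        "by_consequence": {},
        "failure_reasons": {},
        "n_compatible_inner": 0,
    }
    for var in iterator:
        if not (start <= var.POS <= end):
            continue
        for alt_index in range(len(var.ALT)):
            summary["n_seen"] += 1
            gv = group_frequencies(var, groups, samples, alt_index)
            if all(v is None for v in gv.freqs.values()):
                summary["n_skipped_all_missing"] += 1
                continue
            ok, reasons = is_compatible(gv, rule)
            if ok:
                compatible.append(gv)
                summary["n_compatible"] += 1
                summary["by_class"][gv.variant_class] = (
                    summary["by_class"].get(gv.variant_class, 0) + 1
                )
                if gv.consequence:
                    summary["by_consequence"][gv.consequence] = (
                        summary["by_consequence"].get(gv.consequence, 0) + 1
                    )
                if inner_interval and inner_interval[0] <= gv.pos <= inner_interval[1]:
                    summary["n_compatible_inner"] += 1
            else:
                # tally by the offending group of the first violated threshold
                key = reasons[0].split(" ")[0].rstrip(":")
                summary["failure_reasons"][key] = summary["failure_reasons"].get(key, 0) + 1
    return compatible, summary
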