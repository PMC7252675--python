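"""Synthetic-data generator for the recessive semen-quality QTL pipeline.

Everything the pipeline consumes can be generated here under a single seed:
a phased haplotype panel with an implanted recessive QTL haplotype, a
pedigree, repeated ejaculate records with known variance components and
deliberately injected quality-control violations, insemination outcomes, a
candidate-region VCF with a known number of recessive-compatible variants,
and junction-spanning RNA-seq reads in SAM format.

The population model is deliberately simple: each chromosome is a mosaic of
two founder haplotypes (per-SNP switch probability ``switch_prob``), which
creates the local multi-SNP haplotype sharing the sliding-window scan needs
without coalescent machinery.  The QTL haplotype is a fixed 50-SNP allele
string implanted on a Binomial(2N, qtl_hap_freq) subset of chromosomes; it
sits inside a longer identical ancestral segment (``qtl_ibd_markers``) so
that homozygous carriers share a recoverable run of autozygosity.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import HaplotypePanel, MARKER_COLUMNS


@dataclass
class SimConfig:
    """Study conditions for the generator (defaults emulate the mapping cohort)."""

    seed: int = 1
    n_bulls: int = 800
    n_snps_per_chrom: tuple = (1000, 1000)
    qtl_chrom: int = 1  # 1-based position in n_snps_per_chrom
    qtl_window_index: int = 10  # sliding-window number (step 15) on qtl_chrom
    qtl_hap_freq: float = 0.24
    qtl_ibd_markers: int = 120  # identical ancestral segment containing the QTL window
    # non-carrier / heterozygous / homozygous trait means (sperm motility, %)
    trait_means_by_status: tuple = (86.37, 86.37, 82.77)
    trait_sd: float = 2.33
    h2: float = 0.25
    repeatability: float = 0.43
    records_per_bull: tuple = (8, 40)
    marker_spacing_bp: float = 4000.0
    switch_prob: float = 0.02
    noise_rate: float = 0.0  # per-allele chance of drawing afresh from the SNP frequency
    window_size: int = 50
    window_step: int = 15
    n_sires: int = 40
    n_dams: int = 400
    n_collectors: int = 6
    collector_sd: float = 0.3
    season_sd: float = 0.2
    age_slope_per_day: float = 5e-4
    interval_slope_per_day: float = 0.01
    inseminations_per_bull: int = 500
    qc_violations: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not (0 < self.qtl_hap_freq <= 0.5):
            raise ValueError("qtl_hap_freq must be in (0, 0.5]")
        if not (0 <= self.h2 < 1):
            raise ValueError("h2 must be in [0, 1)")
        if self.repeatability < self.h2 or self.repeatability >= 1:
            raise ValueError("repeatability must satisfy h2 <= repeatability < 1")
        for name in ("n_bulls", "qtl_ibd_markers", "window_size", "window_step",
                     "n_sires", "n_dams", "n_collectors", "inseminations_per_bull"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(n <= 0 for n in self.n_snps_per_chrom):
            raise ValueError("n_snps_per_chrom entries must be positive")
        if self.records_per_bull[0] < 1 or self.records_per_bull[1] < self.records_per_bull[0]:
            raise ValueError("records_per_bull bounds invalid")
        if not (1 <= self.qtl_chrom <= len(self.n_snps_per_chrom)):
            raise ValueError("qtl_chrom outside the simulated genome")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream per generator stage."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class PanelTruth:
    """Ground-truth manifest for a simulated panel."""

    qtl_chrom: str
    window_index: int
    window_start: int  # global marker indices, inclusive
    window_end: int
    window_start_bp: int
    window_end_bp: int
    hap_string: str
    block_start: int  # IBD (shared-autozygosity) block, global marker indices
    block_end: int
    block_start_bp: int
    block_end_bp: int
    status: dict  # sample id -> 0/1/2

    def to_json(self) -> dict:
        return dataclasses.asdict(self)


def bull_ids(n: int) -> list:
    return [f"B{i:04d}" for i in range(1, n + 1)]


def simulate_panel(cfg: SimConfig):
    """Simulate a phased panel with an implanted recessive QTL haplotype.

    Returns ``(panel, status, truth)`` where ``status`` maps each bull to its
    copy count (0/1/2) of the implanted haplotype and ``truth`` is the
    ground-truth manifest.
    """
    cfg.validate()
    rng = cfg.rng(0)
    samples = bull_ids(cfg.n_bulls)
    n_hap = 2 * cfg.n_bulls

    marker_rows = []
    hap_blocks = []
    offset = 0
    qtl_span = None
    for c, m in enumerate(cfg.n_snps_per_chrom):
        chrom = str(c + 1)
        spacing = np.maximum(1, rng.exponential(cfg.marker_spacing_bp, m).astype(np.int64))
        pos = 10_000 + np.cumsum(spacing)
        freq = rng.uniform(0.05, 0.95, m)
        founder = rng.random((2, m)) < freq[None, :]  # founder haplotypes A and B

        if c + 1 == cfg.qtl_chrom:
            wstart = cfg.qtl_window_index * cfg.window_step
            wend = wstart + cfg.window_size - 1
            if wend >= m:
                raise ValueError("qtl_window_index places the window outside the marker map")
            extra = max(0, cfg.qtl_ibd_markers - cfg.window_size)
            bstart = max(0, wstart - extra // 2)
            bend = min(m - 1, bstart + max(cfg.qtl_ibd_markers, cfg.window_size) - 1)
            # polymorphic flanking markers pin the shared-autozygosity boundary
            for j in (bstart - 1, bend + 1):
                if 0 <= j < m:
                    founder[1, j] = ~founder[0, j]
            qtl_span = (offset + wstart, offset + wend, offset + bstart, offset + bend, chrom)

        switches = rng.random((n_hap, m)) < cfg.switch_prob
        switches[:, 0] = False
        state = (rng.integers(0, 2, n_hap)[:, None] + np.cumsum(switches, axis=1)) % 2
        alleles = np.where(state == 0, founder[0][None, :], founder[1][None, :])
        if cfg.noise_rate > 0:
            noise = rng.random((n_hap, m)) < cfg.noise_rate
            fresh = rng.random((n_hap, m)) < freq[None, :]
            alleles = np.where(noise, fresh, alleles)
        hap_blocks.append(alleles.astype(np.uint8))
        marker_rows.append(
            pd.DataFrame(
                {
                    "snp_id": [f"snp{chrom}_{j + 1}" for j in range(m)],
                    "chrom": chrom,
                    "pos": pos,
                    "ref": "A",
                    "alt": "C",
                }
            )
        )
        offset += m

    markers = pd.concat(marker_rows, ignore_index=True)[MARKER_COLUMNS]
    H = np.concatenate(hap_blocks, axis=1)

    wstart, wend, bstart, bend, qchrom = qtl_span
    ancestral = rng.integers(0, 2, bend - bstart + 1).astype(np.uint8)
    carrier = rng.random(n_hap) < cfg.qtl_hap_freq
    H[carrier, bstart : bend + 1] = ancestral[None, :]
    status_arr = carrier[0::2].astype(int) + carrier[1::2].astype(int)
    status = pd.Series(status_arr, index=samples, name="copies")

    hap_string = "".join(str(int(a)) for a in ancestral[wstart - bstart : wend - bstart + 1])
    truth = PanelTruth(
        qtl_chrom=qchrom,
        window_index=cfg.qtl_window_index,
        window_start=wstart,
        window_end=wend,
        window_start_bp=int(markers["pos"].iloc[wstart]),
        window_end_bp=int(markers["pos"].iloc[wend]),
        hap_string=hap_string,
        block_start=bstart,
        block_end=bend,
        block_start_bp=int(markers["pos"].iloc[bstart]),
        block_end_bp=int(markers["pos"].iloc[bend]),
        status=status.to_dict(),
    )
    panel = HaplotypePanel(samples=samples, markers=markers, H=H)
    return panel, status, truth


def simulate_pedigree(cfg: SimConfig) -> pd.DataFrame:
    """Founder sires/dams (unknown parents) plus the genotyped bulls."""
    rng = cfg.rng(1)
    sires = [f"S{i:03d}" for i in range(1, cfg.n_sires + 1)]
    dams = [f"D{i:03d}" for i in range(1, cfg.n_dams + 1)]
    rows = [{"animal": a, "sire": "", "dam": ""} for a in sires + dams]
    for b in bull_ids(cfg.n_bulls):
        rows.append(
            {
                "animal": b,
                "sire": sires[rng.integers(0, cfg.n_sires)],
                "dam": dams[rng.integers(0, cfg.n_dams)],
            }
        )
    return pd.DataFrame(rows)


def _breeding_values(cfg: SimConfig, pedigree: pd.DataFrame, rng) -> dict:
    """Polygenic values drawn down the pedigree: g = (g_s + g_d)/2 + Mendelian term."""
    sg = np.sqrt(cfg.h2)
    g: dict = {}
    for row in pedigree.itertuples(index=False):
        s, d = row.sire, row.dam
        if not s and not d:
            g[row.animal] = rng.normal(0.0, sg)
        else:
            mid = (g.get(s, 0.0) + g.get(d, 0.0)) / 2.0
            g[row.animal] = mid + rng.normal(0.0, sg * np.sqrt(0.5))
    return g


# QC-violation labels the generator can inject; each record violates exactly one rule.
INJECTABLE = [
    "interval_missing",
    "age_out_of_range",
    "volume_missing",
    "motility_missing",
    "rejection_cause",
    "low_motility",
    "low_volume",
    "low_concentration",
    "pooled",
    "duplicate_day",
    "collector_missing",
    "bad_score",
    "straw_out_of_range",
]


def simulate_records(cfg: SimConfig, status: pd.Series, pedigree: pd.DataFrame):
    """Repeated ejaculate records with the repeated-records animal-model structure.

    Per record: y = mu(status) + g_bull + pe_bull + collector + season + age and
    interval covariate effects + residual, with Var(g) = h2 and
    Var(g) + Var(pe) = repeatability on the internal unit-variance scale.
    Returns ``(records, manifest)``; the manifest lists injected QC violations.
    """
    cfg.validate()
    rng = cfg.rng(2)
    g = _breeding_values(cfg, pedigree, rng)
    spe = np.sqrt(cfg.repeatability - cfg.h2)
    se = np.sqrt(1.0 - cfg.repeatability)
    m0, m1, m2 = cfg.trait_means_by_status
    shift = {0: 0.0, 1: (m1 - m0) / cfg.trait_sd, 2: (m2 - m0) / cfg.trait_sd}
    collectors = [f"C{i}" for i in range(1, cfg.n_collectors + 1)]
    coll_eff = dict(zip(collectors, rng.normal(0.0, cfg.collector_sd, cfg.n_collectors)))
    season_eff = rng.normal(0.0, cfg.season_sd, 4)
    base = pd.Timestamp("2010-01-01")

    rows = []
    for bull in status.index:
        n_rec = int(rng.integers(cfg.records_per_bull[0], cfg.records_per_bull[1] + 1))
        ages = np.sort(rng.choice(np.arange(400, 1001), size=n_rec, replace=False))
        birth = base + pd.Timedelta(days=int(rng.integers(0, 2000)))
        pe = rng.normal(0.0, spe)
        prev_age = None
        for age in ages:
            date = birth + pd.Timedelta(days=int(age))
            interval = float(age - prev_age) if prev_age is not None else float(rng.integers(3, 11))
            prev_age = age
            coll = collectors[rng.integers(0, cfg.n_collectors)]
            season = (date.quarter - 1) % 4
            y = (
                shift[int(status[bull])]
                + g[bull]
                + pe
                + coll_eff[coll]
                + season_eff[season]
                + cfg.age_slope_per_day * (age - 700)
                + cfg.interval_slope_per_day * (interval - 7)
                + rng.normal(0.0, se)
            )
            motility = float(np.clip(m0 + cfg.trait_sd * y, 70.5, 100.0))
            rows.append(
                {
                    "bull_id": bull,
                    "collection_date": date.date().isoformat(),
                    "ejaculate_no": 1,
                    "age_days": int(age),
                    "interval_days": interval,
                    "volume_ml": float(max(1.05, rng.normal(3.93, 0.94))),
                    "concentration_1e9_per_ml": float(max(0.35, rng.normal(1.32, 0.32))),
                    "motility_pct": motility,
                    "head_score": int(rng.choice(4, p=[0.93, 0.05, 0.015, 0.005])),
                    "tail_score": int(rng.choice(4, p=[0.87, 0.10, 0.02, 0.01])),
                    "sperm_per_straw_mio": float(np.clip(rng.normal(16.45, 1.91), 15.0, 25.0)),
                    "collector_id": coll,
                    "pooled_flag": False,
                    "rejection_cause": "",
                }
            )
    records = pd.DataFrame(rows)

    injected = {}
    n_injected = 0
    n_base = len(records)  # donors come from clean base records only
    for label, count in cfg.qc_violations.items():
        if label not in INJECTABLE:
            raise ValueError(f"unknown QC-violation label: {label}")
        injected[label] = int(count)
        for _ in range(int(count)):
            donor = records.iloc[int(rng.integers(0, n_base))].copy()
            if label == "duplicate_day":
                donor["ejaculate_no"] = 2
            else:
                # fresh globally unique date so the first-per-day rule is untouched
                n_injected += 1
                donor["collection_date"] = (
                    pd.Timestamp("2030-01-01") + pd.Timedelta(days=n_injected)
                ).date().isoformat()
            if label == "interval_missing":
                donor["interval_days"] = np.nan
            elif label == "age_out_of_range":
                donor["age_days"] = 399 if rng.random() < 0.5 else 1001
            elif label == "volume_missing":
                donor["volume_ml"] = np.nan
            elif label == "motility_missing":
                donor["motility_pct"] = np.nan
            elif label == "rejection_cause":
                donor["rejection_cause"] = "impurities"
            elif label == "low_motility":
                donor["motility_pct"] = 65.0
            elif label == "low_volume":
                donor["volume_ml"] = 0.8
            elif label == "low_concentration":
                donor["concentration_1e9_per_ml"] = 0.2
            elif label == "pooled":
                donor["pooled_flag"] = True
            elif label == "collector_missing":
                donor["collector_id"] = ""
            elif label == "bad_score":
                donor["head_score"] = 7
            elif label == "straw_out_of_range":
                donor["sperm_per_straw_mio"] = 27.0
            records = pd.concat([records, donor.to_frame().T], ignore_index=True)

    records = records.sample(frac=1.0, random_state=int(cfg.seed)).reset_index(drop=True)
    for col in ("age_days", "head_score", "tail_score", "ejaculate_no"):
        records[col] = records[col].astype(int)
    for col in ("interval_days", "volume_ml", "concentration_1e9_per_ml", "motility_pct",
                "sperm_per_straw_mio"):
        records[col] = records[col].astype(float)
    records["pooled_flag"] = records["pooled_flag"].astype(bool)

    manifest = {
        "variance_components": {
            "sigma_g2": cfg.h2,
            "sigma_pe2": cfg.repeatability - cfg.h2,
            "sigma_e2": 1.0 - cfg.repeatability,
            "h2": cfg.h2,
            "repeatability": cfg.repeatability,
        },
        "trait_sd": cfg.trait_sd,
        "trait_means_by_status": list(cfg.trait_means_by_status),
        "injected_violations": injected,
        "breeding_values": {k: float(v) for k, v in g.items()},
    }
    return records, manifest


def simulate_inseminations(cfg: SimConfig, fertility_truth: pd.Series) -> pd.DataFrame:
    """Bernoulli non-return outcomes shifted by per-bull truth plus nuisance effects."""
    cfg.validate()
    rng = cfg.rng(3)
    month_eff = rng.normal(0.0, 0.02, 12)
    parity_eff = {"heifer": 0.01, "cow": -0.01}
    price_eff = dict(zip("ABC", rng.normal(0.0, 0.01, 3)))
    breeds = ["BSWxBSW", "BSWxOB", "BSWxHOL"]
    breed_eff = dict(zip(breeds, rng.normal(0.0, 0.01, 3)))
    n_tech, n_herd = 25, 60
    tech_eff = rng.normal(0.0, 0.02, n_tech)
    herd_eff = rng.normal(0.0, 0.02, n_herd)

    rows = []
    for bull, truth in fertility_truth.items():
        month = rng.integers(0, 12, cfg.inseminations_per_bull)
        parity = rng.choice(["heifer", "cow"], cfg.inseminations_per_bull)
        price = rng.choice(list("ABC"), cfg.inseminations_per_bull)
        breed = rng.choice(breeds, cfg.inseminations_per_bull)
        tech = rng.integers(0, n_tech, cfg.inseminations_per_bull)
        herd = rng.integers(0, n_herd, cfg.inseminations_per_bull)
        p = np.clip(
            0.67
            + truth
            + month_eff[month]
            + np.array([parity_eff[x] for x in parity])
            + np.array([price_eff[x] for x in price])
            + np.array([breed_eff[x] for x in breed])
            + tech_eff[tech]
            + herd_eff[herd],
            0.02,
            0.98,
        )
        outcome = (rng.random(cfg.inseminations_per_bull) < p).astype(int)
        for k in range(cfg.inseminations_per_bull):
            rows.append(
                {
                    "bull_id": bull,
                    "month": int(month[k] + 1),
                    "parity": parity[k],
                    "straw_price": price[k],
                    "breed_combination": breed[k],
                    "technician_id": f"T{tech[k]:02d}",
                    "herd_id": f"H{herd[k]:03d}",
                    "outcome": int(outcome[k]),
                }
            )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------- region VCF

_VIOLATIONS = ["hom_low", "het_low", "het_high", "noncarrier_high", "hom_missing"]


def simulate_region_vcf(
    groups,
    n_variants: int,
    n_compatible: int,
    seed: int,
    path: str,
    chrom: str = "6",
    region: tuple = (55_000_000, 65_000_000),
    sv: bool = False,
):
    """Write a VCF where exactly ``n_compatible`` variants pass the recessive rule.

    ``groups`` is a :class:`recessivescan.recfilter.StatusGroups`.  Incompatible
    variants each violate one threshold; the violation label is stored in the
    ``VIOL`` INFO field for test introspection.  With ``sv=True`` symbolic-allele
    records are written and every variant is made incompatible.
    Returns the manifest dict (positions of compatible variants, violations).
    """
    if len(groups.homozygous) == 0:
        raise ValueError("recessive-compatibility rule undefined without homozygous carriers")
    if n_compatible > n_variants:
        raise ValueError("n_compatible exceeds n_variants")
    if sv and n_compatible:
        raise ValueError("symbolic SV records are always written incompatible")
    rng = np.random.default_rng(seed)
    hom, het, non = list(groups.homozygous), list(groups.heterozygous), list(groups.noncarrier)
    samples = hom + het + non
    pos = np.sort(rng.choice(np.arange(region[0], region[1]), size=n_variants, replace=False))
    compat_idx = set(rng.choice(n_variants, size=n_compatible, replace=False).tolist())

    def gts(freq_target, n, missing=False):
        if missing:
            return ["./."] * n
        n_alt = int(round(freq_target * 2 * n))
        g = []
        for i in range(n):
            take = min(2, n_alt)
            n_alt -= take
            g.append(["0/0", "0/1", "1/1"][take])
        return g

    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom},length={region[1] + 10_000}>",
        '##INFO=<ID=VIOL,Number=1,Type=String,Description="Injected rule violation">',
        '##INFO=<ID=COMPAT,Number=0,Type=Flag,Description="Constructed compatible">',
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    manifest = {"compatible_pos": [], "violations": {}}
    svtypes = ["<DEL>", "<DUP>", "<INV>"]
    for i in range(n_variants):
        if sv:
            ref, alt = "N", svtypes[i % len(svtypes)]
            info_extra = f";SVTYPE={alt[1:-1]}"
        elif i % 4 == 3:
            ref, alt, info_extra = "A", "AT", ""  # indel
        else:
            ref, alt, info_extra = "A", "G", ""  # SNP
        if i in compat_idx:
            g_hom = ["0/1"] + ["1/1"] * (len(hom) - 1) if len(hom) >= 3 else ["1/1"] * len(hom)
            g_het = ["0|1" if k % 5 == 0 else "0/1" for k in range(len(het))]
            g_non = ["0/0"] * len(non)
            info = "COMPAT"
            manifest["compatible_pos"].append(int(pos[i]))
        else:
            viol = _VIOLATIONS[i % len(_VIOLATIONS)]
            g_hom, g_het, g_non = (
                gts(1.0, len(hom)),
                gts(0.5, len(het)),
                gts(0.0, len(non)),
            )
            if viol == "hom_low":
                g_hom = gts(0.5, len(hom))
            elif viol == "het_low":
                g_het = gts(0.2, len(het))
            elif viol == "het_high":
                g_het = gts(1.0, len(het))
            elif viol == "noncarrier_high":
                g_non = gts(max(0.1, 1.0 / max(1, 2 * len(non)) + 0.05), len(non))
            elif viol == "hom_missing":
                g_hom = gts(0, len(hom), missing=True)
            info = f"VIOL={viol}"
            manifest["violations"][int(pos[i])] = viol
        lines.append(
            f"{chrom}\t{pos[i]}\tv{i + 1}\t{ref}\t{alt}\t.\tPASS\t{info}{info_extra}\tGT\t"
            + "\t".join(g_hom + g_het + g_non)
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return manifest


def simulate_junction_reads(
    wt_count: int,
    mt_count: int,
    junction,
    read_len: int = 100,
    seed: int = 1,
    path: str = "junctions.sam",
    min_overhang: int = 10,
    contig: str = "6",
):
    """Write a SAM file with exact numbers of wild-type and mutant junction reads.

    ``junction`` is a :class:`recessivescan.splicekit.SpliceJunctionPair`.  Each
    read has one aligned block ending at the junction's donor exon end and one
    starting at the acceptor, with at least ``min_overhang`` bases on each side.
    """
    import pysam

    rng = np.random.default_rng(seed)
    ref_len = junction.acceptor_start + read_len + 1000
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": contig, "LN": int(ref_len)}]}
    reads = []
    for label, count, donor_end in (
        ("wt", wt_count, junction.wt_donor_end),
        ("mt", mt_count, junction.mt_donor_end),
    ):
        for k in range(count):
            left = int(rng.integers(min_overhang, read_len - min_overhang + 1))
            start = donor_end - left + 1  # 1-based
            gap = junction.acceptor_start - donor_end - 1
            reads.append((start, f"{left}M{gap}N{read_len - left}M", f"{label}_{k + 1}"))
    reads.sort()
    with pysam.AlignmentFile(path, "w", header=header) as sam:
        for start, cigar, name in reads:
            a = pysam.AlignedSegment(sam.header)
            a.query_name = name
            a.reference_id = 0
            a.reference_start = start - 1
            a.mapping_quality = 60
            a.cigarstring = cigar
            a.query_sequence = "A" * read_len
            a.query_qualities = pysam.qualitystring_to_array("I" * read_len)
            sam.write(a)
    return path


def simulate_all(cfg: SimConfig, outdir: str) -> dict:
    """Generate every pipeline input under ``outdir`` and write manifest.json."""
    import os

    from .recfilter import StatusGroups
    from .splicekit import SpliceJunctionPair

    os.makedirs(outdir, exist_ok=True)
    panel, status, truth = simulate_panel(cfg)
    pedigree = simulate_pedigree(cfg)
    records, rec_manifest = simulate_records(cfg, status, pedigree)
    rng = cfg.rng(4)
    fert_truth = pd.Series(rng.normal(0.0, 0.05, cfg.n_bulls), index=status.index)
    fert_truth[status == 2] -= 0.05
    insem = simulate_inseminations(cfg, fert_truth)

    panel.write_vcf(os.path.join(outdir, "panel.vcf.gz"))
    panel.markers.to_csv(os.path.join(outdir, "markers.tsv"), sep="\t", index=False)
    pedigree.to_csv(os.path.join(outdir, "pedigree.csv"), index=False)
    records.to_csv(os.path.join(outdir, "ejaculates.csv"), index=False)
    insem.to_csv(os.path.join(outdir, "inseminations.csv"), index=False)

    groups = StatusGroups.from_status(status)
    vcf_manifest = simulate_region_vcf(
        groups, n_variants=500, n_compatible=12, seed=cfg.seed,
        path=os.path.join(outdir, "region.vcf"),
    )
    junction = SpliceJunctionPair(wt_donor_end=58_373_894, truncation=9,
                                  acceptor_start=58_374_929)
    simulate_junction_reads(5, 24, junction, seed=cfg.seed,
                            path=os.path.join(outdir, "junctions.sam"))

    manifest = {
        "config": dataclasses.asdict(cfg),
        "panel": truth.to_json(),
        "records": rec_manifest,
        "fertility_truth": {k: float(v) for k, v in fert_truth.items()},
        "region_vcf": vcf_manifest,
        "junctions": {"wt": 5, "mt": 24, "pair": dataclasses.asdict(junction)},
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
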