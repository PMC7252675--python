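"""Ejaculate-record QC cascade, trait aggregation and bull-fertility estimation.

The filter cascade reproduces the sequential quality control applied to raw
AI-center ejaculate records: every rule is applied in a fixed order and an
attrition log records how many records and bulls survive each step.  Counts
are order-dependent, so the order is only configurable behind an explicit
flag.  The two AI-minimum thresholds that the raw data encode via rejection
causes (volume > 1 ml, concentration > 0.3e9/ml) are applied immediately
after the motility threshold.

Bull fertility is a non-return-rate (NRR56) index: a linear probability
model with insemination-level nuisance effects and a bull effect, the bull
effects standardized to mean 100, SD 12.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRAITS = [
    "volume_ml",
    "concentration_1e9_per_ml",
    "motility_pct",
    "head_score",
    "tail_score",
    "sperm_per_straw_mio",
]


@dataclass
class FilterConfig:
    age_range: tuple = (400, 1000)
    min_motility: float = 70.0
    min_volume: float = 1.0  # strict: volume must exceed this
    min_concentration: float = 0.3  # strict, 1e9/ml
    straw_range: tuple = (15.0, 25.0)
    min_ejaculates: int = 8
    require_collector: bool = True
    require_interval: bool = True
    require_non_pooled: bool = True
    first_per_day: bool = True
    require_no_rejection: bool = True
    plausible_scores: tuple = (0, 1, 2, 3)

    def validate(self) -> None:
        if self.age_range[0] > self.age_range[1] or self.straw_range[0] > self.straw_range[1]:
            raise ValueError("empty filter range")
        if self.min_ejaculates < 1:
            raise ValueError("min_ejaculates must be >= 1")


def _season(dates: pd.Series) -> pd.Series:
    """Season = calendar quarter of the collection date."""
    return pd.to_datetime(dates).dt.quarter


def filter_ejaculates(
    records: pd.DataFrame,
    cfg: FilterConfig | None = None,
    genotyped=None,
    cascade_order: list | None = None,
):
    """Apply the QC cascade; returns ``(filtered records, attrition log)``.

    ``genotyped`` is an optional collection of bull ids with genotypes; when
    given, a final join-to-genotypes step is applied.  ``cascade_order``
    overrides the fixed rule order (explicit opt-in; counts are
    order-dependent).
    """
    cfg = cfg or FilterConfig()
    cfg.validate()
    df = records.copy()

    def plausible(frame):
        bad = ~(
            frame["head_score"].isin(cfg.plausible_scores)
            & frame["tail_score"].isin(cfg.plausible_scores)
        )
        if bad.any():
            warnings.warn(
                f"{int(bad.sum())} records dropped for implausible anomaly scores",
                stacklevel=3,
            )
        return frame[~bad]

    def first_per_day(frame):
        order_col = "ejaculate_no" if "ejaculate_no" in frame.columns else None
        if order_col:
            frame = frame.sort_values(["bull_id", "collection_date", order_col],
                                      kind="stable")
        return frame.drop_duplicates(subset=["bull_id", "collection_date"], keep="first")

    rules = {
        "interval_known": lambda f: f[f["interval_days"].notna()] if cfg.require_interval else f,
        "age_in_range": lambda f: f[
            (f["age_days"] >= cfg.age_range[0]) & (f["age_days"] <= cfg.age_range[1])
        ],
        "volume_recorded": lambda f: f[f["volume_ml"].notna()],
        "motility_recorded": lambda f: f[f["motility_pct"].notna()],
        "no_rejection_cause": lambda f: (
            f[f["rejection_cause"].fillna("") == ""] if cfg.require_no_rejection else f
        ),
        "min_motility": lambda f: f[f["motility_pct"] >= cfg.min_motility],
        "min_volume": lambda f: f[f["volume_ml"] > cfg.min_volume],
        "min_concentration": lambda f: f[
            f["concentration_1e9_per_ml"] > cfg.min_concentration
        ],
        "not_pooled": lambda f: f[~f["pooled_flag"]] if cfg.require_non_pooled else f,
        "first_per_day": first_per_day if cfg.first_per_day else (lambda f: f),
        "collector_recorded": lambda f: (
            f[f["collector_id"].fillna("") != ""] if cfg.require_collector else f
        ),
        "plausible_scores": plausible,
        "straw_in_range": lambda f: f[
            (f["sperm_per_straw_mio"] >= cfg.straw_range[0])
            & (f["sperm_per_straw_mio"] <= cfg.straw_range[1])
        ],
        "min_ejaculates": lambda f: f.groupby("bull_id").filter(
            lambda g: len(g) >= cfg.min_ejaculates
        ),
    }
    order = cascade_order or list(rules)
    unknown = [r for r in order if r not in rules]
    if unknown:
        raise ValueError(f"unknown cascade rules: {unknown}")

    log_rows = [("raw", len(df), df["bull_id"].nunique())]
    for label in order:
        df = rules[label](df)
        log_rows.append((label, len(df), df["bull_id"].nunique()))
    if genotyped is not None:
        df = df[df["bull_id"].isin(set(genotyped))]
        log_rows.append(("genotyped", len(df), df["bull_id"].nunique()))
    log = pd.DataFrame(log_rows, columns=["filter", "n_records", "n_bulls"])
    return df.reset_index(drop=True), log


def aggregate_traits(filtered: pd.DataFrame, traits=None) -> pd.DataFrame:
    """Per-bull arithmetic trait means from the filtered records."""
    traits = traits or [t for t in TRAITS if t in filtered.columns]
    out = filtered.groupby("bull_id")[traits].mean()
    out.insert(0, "n_ejaculates", filtered.groupby("bull_id").size())
    return out


def adjust_traits(filtered: pd.DataFrame, traits=None):
    """Per-bull means of residuals from y = mu + a*age + f*interval + collector + season.

    Returns ``(adjusted bull means, raw-vs-adjusted Pearson r per trait)``.
    Factors with a single level are dropped with a warning (singular design).
    """
    import statsmodels.api as sm

    traits = traits or [t for t in TRAITS if t in filtered.columns]
    df = filtered.copy()
    df["season"] = _season(df["collection_date"])
    parts = [np.ones(len(df)), df["age_days"].to_numpy(float),
             df["interval_days"].to_numpy(float)]
    names = ["intercept", "age", "interval"]
    for factor in ("collector_id", "season"):
        levels = df[factor].astype(str)
        if levels.nunique() < 2:
            warnings.warn(f"factor {factor} has a single level; dropped", stacklevel=2)
            continue
        dummies = pd.get_dummies(levels, prefix=factor, drop_first=True, dtype=float)
        parts.append(dummies.to_numpy())
        names.extend(dummies.columns)
    X = np.column_stack(parts)

    raw = aggregate_traits(filtered, traits)
    adj = pd.DataFrame(index=raw.index)
    adj["n_ejaculates"] = raw["n_ejaculates"]
    cors = {}
    for trait in traits:
        y = df[trait].to_numpy(float)
        resid = sm.OLS(y, X).fit().resid
        per_bull = pd.Series(resid, index=df["bull_id"].values).groupby(level=0).mean()
        adj[trait] = per_bull.reindex(raw.index)
        cors[trait] = float(np.corrcoef(raw[trait], adj[trait])[0, 1])
    return adj, cors


@dataclass
class FertilityResult:
    index: pd.DataFrame  # bull_id-indexed: index, n_inseminations
    excluded_low_n: list = field(default_factory=list)
    outliers_removed: list = field(default_factory=list)


def estimate_fertility(
    inseminations: pd.DataFrame,
    min_inseminations: int = 200,
    outlier_sd: float = 3.0,
    drop_outliers: bool = True,
) -> FertilityResult:
    """NRR56 bull-fertility index from insemination outcomes.

    Linear probability model with month, parity, straw-price, breed-combination,
    technician and herd fixed effects plus a bull effect; bull effects are
    centred and standardized to mean 100, SD 12.  Bulls more than ``outlier_sd``
    standard deviations below the mean are flagged and (by default) dropped.
    """
    counts = inseminations.groupby("bull_id").size()
    keep = counts[counts >= min_inseminations].index
    excluded = sorted(set(counts.index) - set(keep))
    df = inseminations[inseminations["bull_id"].isin(keep)].copy()
    if df.empty:
        raise ValueError("no bull reaches the minimum insemination count")

    y = df["outcome"].to_numpy(float)
    parts = [np.ones(len(df))]
    for factor in ("month", "parity", "straw_price", "breed_combination",
                   "technician_id", "herd_id"):
        if factor not in df.columns:
            continue
        levels = df[factor].astype(str)
        if levels.nunique() < 2:
            continue
        parts.append(
            pd.get_dummies(levels, prefix=factor, drop_first=True, dtype=float).to_numpy()
        )
    bull_d = pd.get_dummies(df["bull_id"].astype(str), drop_first=True, dtype=float)
    X = np.column_stack(parts + [bull_d.to_numpy()])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    n_bull_cols = bull_d.shape[1]
    bull_order = [str(b) for b in sorted(df["bull_id"].astype(str).unique())]
    eff = pd.Series(0.0, index=bull_order)
    eff.iloc[1:] = beta[-n_bull_cols:] if n_bull_cols else []
    eff -= eff.mean()
    sd = float(eff.std(ddof=0))
    # guard: no real spread in bull effects (e.g. constant outcomes) -> flat 100
    if sd < 1e-10 * max(1.0, float(np.abs(y).mean())):
        index = pd.Series(100.0, index=eff.index)
    else:
        index = 100.0 + 12.0 * eff / sd

    out = pd.DataFrame(
        {"index": index, "n_inseminations": counts.reindex(index.index).astype(int)}
    )
    out.index.name = "bull_id"
    outliers = []
    if drop_outliers:
        cut = 100.0 - outlier_sd * 12.0
        outliers = sorted(out.index[out["index"] < cut])
        out = out.drop(index=outliers)
    return FertilityResult(index=out, excluded_low_n=excluded, outliers_removed=outliers)


def trait_correlations(bull_traits: pd.DataFrame, traits=None) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations of per-bull trait means."""
    traits = traits or [t for t in TRAITS if t in bull_traits.columns]
    return bull_traits[traits].corr(method="pearson")
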