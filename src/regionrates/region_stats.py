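"""Per-protein region means, conservation ratios, and robust summaries.

The core statistic is the conservation ratio: for protein *i*, the mean
evolutionary rate of residues in one region divided by the mean rate in
another (canonically disorder over domain).  A region mean is defined only
when the region holds at least ``min_region_residues`` residues with a
defined rate (default 20); otherwise the mean — and any ratio built on it —
is undefined, which is a value, not an error.  Ratio distributions are
summarized by the median and the (unscaled) median absolute deviation.
Medians of even-length samples use the mean-of-the-two-middle convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ConfigurationError
from .region_annotation import AnnotationConfig

logger = logging.getLogger("regionrates.region_stats")

__all__ = [
    "RegionSummary",
    "RatioRecord",
    "RatioSummary",
    "REGIONS",
    "mean_region_rate",
    "region_summaries",
    "conservation_ratio",
    "ratio_records",
    "summarize_ratios",
    "asa_cutoff_sweep",
    "parse_pair",
]

REGIONS = ("disorder", "domain", "surface", "buried", "full")

_REGION_MASK_COLUMN = {
    "disorder": "is_disordered",
    "domain": "is_domain",
    "surface": "is_surface",
    "buried": "is_buried",
}

_PAIR_ALIASES = {"diso": "disorder", "dom": "domain"}


def parse_pair(pair: str) -> tuple[str, str]:
    """Parse 'diso:domain'-style region pair strings."""
    try:
        num, den = pair.split(":")
    except ValueError:
        raise ConfigurationError(f"region pair must be 'num:den', got {pair!r}") from None
    num = _PAIR_ALIASES.get(num.strip(), num.strip())
    den = _PAIR_ALIASES.get(den.strip(), den.strip())
    for region in (num, den):
        if region not in REGIONS:
            raise ConfigurationError(f"unknown region {region!r}")
    return num, den


@dataclass
class RegionSummary:
    protein_id: str
    region: str
    n_residues: int
    mean_rate: float  # NaN when n_residues < min_region_residues


@dataclass
class RatioRecord:
    protein_id: str
    numerator_region: str
    denominator_region: str
    ratio: float  # NaN when undefined
    flag: str = ""


@dataclass
class RatioSummary:
    numerator_region: str
    denominator_region: str
    n_proteins: int
    median_ratio: float
    mad: float


def mean_region_rate(
    rates: np.ndarray | pd.Series,
    mask: np.ndarray | pd.Series,
    protein_id: str,
    region: str,
    min_n: int = 20,
) -> RegionSummary:
    """Arithmetic mean rate over a region; undefined below ``min_n`` residues."""
    rates = np.asarray(rates, dtype=float)
    mask = np.asarray(mask, dtype=bool) & np.isfinite(rates)
    n = int(mask.sum())
    mean = float(rates[mask].mean()) if n >= min_n else math.nan
    return RegionSummary(protein_id=protein_id, region=region, n_residues=n, mean_rate=mean)


def region_summaries(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    regions: tuple[str, ...] = REGIONS,
    min_n: int = 20,
) -> pd.DataFrame:
    """Per-protein mean rate for every requested region.

    ``features`` and ``labels`` must be row-aligned (same protein_id,
    position order).  Returns protein_id, region, n_residues, mean_rate.
    """
    if len(features) != len(labels):
        raise ConfigurationError("features and labels must be row-aligned")
    rates = features["rate"].to_numpy(dtype=float)
    rows = []
    pid_arr = features["protein_id"].to_numpy()
    order = pd.unique(pid_arr)
    indices = pd.Series(np.arange(len(features))).groupby(pid_arr, sort=False).groups
    for pid in order:
        idx = np.asarray(indices[pid])
        for region in regions:
            if region == "full":
                mask = np.ones(len(idx), dtype=bool)
            else:
                mask = labels[_REGION_MASK_COLUMN[region]].to_numpy()[idx]
            summary = mean_region_rate(rates[idx], mask, pid, region, min_n=min_n)
            rows.append(
                (pid, region, summary.n_residues, summary.mean_rate)
            )
    return pd.DataFrame(rows, columns=["protein_id", "region", "n_residues", "mean_rate"])


def conservation_ratio(
    summary_num: RegionSummary, summary_den: RegionSummary
) -> RatioRecord:
    """Ratio of two region means for the same protein; undefined propagates."""
    if summary_num.protein_id != summary_den.protein_id:
        raise ConfigurationError("conservation ratio requires the same protein")
    flag = ""
    if math.isnan(summary_num.mean_rate) or math.isnan(summary_den.mean_rate):
        ratio = math.nan
    elif summary_den.mean_rate == 0:
        ratio = math.nan
        flag = "zero-denominator"
    else:
        ratio = summary_num.mean_rate / summary_den.mean_rate
    return RatioRecord(
        protein_id=summary_num.protein_id,
        numerator_region=summary_num.region,
        denominator_region=summary_den.region,
        ratio=ratio,
        flag=flag,
    )


def ratio_records(
    summaries: pd.DataFrame, pairs: list[str] | list[tuple[str, str]]
) -> pd.DataFrame:
    """Per-protein conservation ratios for a list of region pairs.

    Returns protein_id, numerator_region, denominator_region, ratio
    (NaN when either mean is undefined or the denominator is 0).
    """
    wide_mean = summaries.pivot(index="protein_id", columns="region", values="mean_rate")
    frames = []
    for pair in pairs:
        num, den = parse_pair(pair) if isinstance(pair, str) else pair
        ratio = wide_mean[num] / wide_mean[den]
        ratio = ratio.where(wide_mean[den] != 0)
        frames.append(
            pd.DataFrame(
                {
                    "protein_id": wide_mean.index,
                    "numerator_region": num,
                    "denominator_region": den,
                    "ratio": ratio.to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def summarize_ratios(ratios: pd.Series | np.ndarray,
                     numerator_region: str = "",
                     denominator_region: str = "") -> RatioSummary:
    """Median and unscaled MAD over defined ratios.

    With zero defined ratios, returns n_proteins=0 and NaN statistics.
    """
    vals = np.asarray(ratios, dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        return RatioSummary(numerator_region, denominator_region, 0, math.nan, math.nan)
    med = float(np.median(vals))
    mad = float(np.median(np.abs(vals - med)))
    return RatioSummary(numerator_region, denominator_region, len(vals), med, mad)


def asa_cutoff_sweep(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    config: AnnotationConfig | None = None,
    numerator_region: str = "disorder",
) -> pd.DataFrame:
    """Disorder-vs-surface median ratio across increasingly stringent cutoffs.

    The disorder set stays fixed; surface is redefined per cutoff c as
    non-disordered residues with rASA > c, with the minimum-residue rule
    re-applied.  Returns one row per cutoff: cutoff, n_proteins,
    median_ratio, mad.
    """
    config = config or AnnotationConfig()
    rates = features["rate"].to_numpy(dtype=float)
    rasa = features["rasa"].to_numpy(dtype=float)
    raw_diso = labels["raw_disordered"].to_numpy(dtype=bool)
    num_mask_all = labels[_REGION_MASK_COLUMN[numerator_region]].to_numpy(dtype=bool)
    pid_arr = features["protein_id"].to_numpy()
    indices = pd.Series(np.arange(len(features))).groupby(pid_arr, sort=False).groups
    min_n = config.min_region_residues
    rows = []
    for cutoff in config.rasa_sweep_grid:
        surface = np.isfinite(rasa) & (rasa > cutoff) & ~raw_diso
        ratios = []
        for pid, idx in indices.items():
            idx = np.asarray(idx)
            num = mean_region_rate(rates[idx], num_mask_all[idx], pid, numerator_region, min_n)
            den = mean_region_rate(rates[idx], surface[idx], pid, "surface", min_n)
            rec = conservation_ratio(num, den)
            if np.isfinite(rec.ratio):
                ratios.append(rec.ratio)
        summary = summarize_ratios(np.asarray(ratios), numerator_region, "surface")
        rows.append((float(cutoff), summary.n_proteins, summary.median_ratio, summary.mad))
    return pd.DataFrame(rows, columns=["cutoff", "n_proteins", "median_ratio", "mad"])
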