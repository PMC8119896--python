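"""Residue region classification: disorder, domain, surface, buried.

Disorder is operationalized proteome-wide: the top fraction (default 20%)
of residues by disorder probability, across all proteins pooled, are
flagged disordered.  Domains are the union of intervals passing an E-value
filter (default 1e-3).  Structured residues with a relative solvent
accessibility split at a cutoff (default 0.25) into surface (rASA > cutoff)
and buried (rASA <= cutoff); residues without a rASA are unassigned, and
disordered residues never enter the surface/buried sets.

Residues flagged both disordered and domain are, by default, excluded from
both region sets used for rate averaging, keeping the disorder-vs-domain
contrast between unambiguous residues; "domain-wins" and "disorder-wins"
policies are available for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ConfigurationError, EstimationError, IntegrityError

logger = logging.getLogger("regionrates.annotation")

__all__ = [
    "AnnotationConfig",
    "disorder_threshold",
    "classify_burial",
    "assign_domains",
    "build_region_labels",
]

DEFAULT_SWEEP_GRID = tuple(np.round(np.arange(0.25, 0.801, 0.05), 2))
OVERLAP_POLICIES = ("exclude", "domain-wins", "disorder-wins")


@dataclass
class AnnotationConfig:
    surface_rasa_cutoff: float = 0.25
    disorder_top_fraction: float = 0.20
    domain_evalue_max: float = 1e-3
    min_region_residues: int = 20
    rasa_sweep_grid: tuple[float, ...] = DEFAULT_SWEEP_GRID
    overlap_policy: str = "exclude"

    def __post_init__(self) -> None:
        if not 0.0 < self.surface_rasa_cutoff < 1.0:
            raise ConfigurationError("surface_rasa_cutoff must be in (0, 1)")
        if not 0.0 <= self.disorder_top_fraction <= 1.0:
            raise ConfigurationError("disorder_top_fraction must be in [0, 1]")
        if self.min_region_residues < 1:
            raise ConfigurationError("min_region_residues must be >= 1")
        if self.overlap_policy not in OVERLAP_POLICIES:
            raise ConfigurationError(
                f"overlap_policy must be one of {OVERLAP_POLICIES}"
            )


def disorder_threshold(
    disorder_probs: pd.Series | np.ndarray,
    top_fraction: float = 0.20,
) -> tuple[float, np.ndarray]:
    """Proteome-wide disorder flagging by top-fraction thresholding.

    The threshold is the empirical (1 - top_fraction) quantile of all
    non-missing probabilities, using the "higher" interpolation so it is an
    observed value; residues with probability >= threshold are flagged
    (ties at the threshold are all flagged, so the flagged fraction can
    exceed ``top_fraction``).
    """
    probs = np.asarray(disorder_probs, dtype=float)
    defined = np.isfinite(probs)
    if not defined.any():
        raise EstimationError("all disorder probabilities are missing")
    if top_fraction <= 0.0:
        return float("inf"), np.zeros(len(probs), dtype=bool)
    if top_fraction >= 1.0:
        threshold = float(np.min(probs[defined]))
        return threshold, defined.copy()
    threshold = float(
        np.quantile(probs[defined], 1.0 - top_fraction, method="higher")
    )
    flags = np.zeros(len(probs), dtype=bool)
    flags[defined] = probs[defined] >= threshold
    return threshold, flags


def classify_burial(
    rasa: pd.Series | np.ndarray, cutoff: float = 0.25
) -> np.ndarray:
    """Per-residue burial call: 'surface' (rASA > cutoff), 'buried'
    (rASA <= cutoff), or 'unassigned' (missing rASA)."""
    if not 0.0 < cutoff < 1.0:
        raise ConfigurationError("burial cutoff must be in (0, 1)")
    vals = np.asarray(rasa, dtype=float)
    out = np.full(len(vals), "unassigned", dtype=object)
    defined = np.isfinite(vals)
    out[defined & (vals > cutoff)] = "surface"
    out[defined & (vals <= cutoff)] = "buried"
    return out


def assign_domains(
    features: pd.DataFrame,
    domains: pd.DataFrame,
    evalue_max: float = 1e-3,
) -> np.ndarray:
    """Flag residues covered by >= 1 domain interval with E-value <= evalue_max.

    ``features`` must carry protein_id and position (1-based); ``domains``
    carries protein_id, start, end (1-based inclusive), evalue.  Overlapping
    intervals union.  Intervals outside the protein's residue range raise
    :class:`IntegrityError`.
    """
    lengths = features.groupby("protein_id")["position"].max()
    flags = np.zeros(len(features), dtype=bool)
    kept = domains.loc[pd.to_numeric(domains["evalue"]) <= evalue_max]
    index_by_protein = {
        pid: grp.index.to_numpy() for pid, grp in features.groupby("protein_id")
    }
    position_by_protein = {
        pid: features.loc[idx, "position"].to_numpy()
        for pid, idx in index_by_protein.items()
    }
    for row in kept.itertuples(index=False):
        pid = row.protein_id
        if pid not in index_by_protein:
            continue
        if row.start < 1 or row.end > int(lengths[pid]) or row.start > row.end:
            raise IntegrityError(
                f"domain interval [{row.start}, {row.end}] out of bounds for "
                f"protein {pid} (length {int(lengths[pid])})"
            )
        pos = position_by_protein[pid]
        covered = (pos >= row.start) & (pos <= row.end)
        flags[index_by_protein[pid][covered]] = True
    return flags


def build_region_labels(
    features: pd.DataFrame,
    domains: pd.DataFrame | None = None,
    config: AnnotationConfig | None = None,
) -> pd.DataFrame:
    """Assemble per-residue region labels for rate averaging.

    Returns a frame aligned with ``features`` carrying the raw flags
    (``raw_disordered``, ``raw_domain``) and the averaging-set booleans
    ``is_disordered``, ``is_domain`` (after the overlap policy),
    ``is_surface``, ``is_buried`` (only non-disordered residues with a
    rASA).  If ``domains`` is None the feature table's own ``in_domain``
    column is used as the raw domain flag.
    """
    config = config or AnnotationConfig()
    threshold, raw_diso = disorder_threshold(
        features["disorder_prob"], config.disorder_top_fraction
    )
    if domains is not None:
        raw_dom = assign_domains(features, domains, config.domain_evalue_max)
    else:
        raw_dom = features["in_domain"].to_numpy(dtype=bool)
    if config.overlap_policy == "exclude":
        is_diso = raw_diso & ~raw_dom
        is_dom = raw_dom & ~raw_diso
    elif config.overlap_policy == "domain-wins":
        is_dom = raw_dom
        is_diso = raw_diso & ~raw_dom
    else:  # disorder-wins
        is_diso = raw_diso
        is_dom = raw_dom & ~raw_diso
    burial = classify_burial(features["rasa"], config.surface_rasa_cutoff)
    is_surface = (burial == "surface") & ~raw_diso
    is_buried = (burial == "buried") & ~raw_diso
    labels = pd.DataFrame(
        {
            "protein_id": features["protein_id"].to_numpy(),
            "position": features["position"].to_numpy(),
            "raw_disordered": raw_diso,
            "raw_domain": raw_dom,
            "is_disordered": is_diso,
            "is_domain": is_dom,
            "is_surface": is_surface,
            "is_buried": is_buried,
        }
    )
    labels.attrs["disorder_threshold"] = threshold
    flagged = float(raw_diso.mean())
    logger.info(
        "disorder threshold %.4f flags %.1f%% of residues; %d residues in both "
        "disorder and domain handled by policy %r",
        threshold,
        100 * flagged,
        int((raw_diso & raw_dom).sum()),
        config.overlap_policy,
    )
    return labels
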