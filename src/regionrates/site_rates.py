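"""Per-site evolutionary rate estimation from ortholog alignments.

Empirical-Bayes discrete-gamma rate inference in the Rate4Site tradition:
among-site rate variation is modeled by a mean-one gamma distribution
approximated with K equiprobable categories; the gamma shape alpha is fitted
by maximum likelihood over alignment columns; each column's rate is then the
posterior mean over categories.  Column likelihoods come from Felsenstein's
pruning algorithm on a fixed phylogeny under a reversible amino-acid model
(Poisson model by default: equal exchangeabilities and uniform frequencies,
whose transition probability has the closed form
``P_aa(t) = 1/20 + (19/20) exp(-20 t / 19)``).

Rates are reported on a positive scale and normalized so the grand mean
over all reference-mapped residues of all proteins equals 1, which is the
scale on which per-protein region-mean ratios are taken downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .io_formats import (
    GAP_CHAR,
    GAP_CODE,
    N_STATES,
    ConfigurationError,
    EstimationError,
    FormatError,
    IntegrityError,
    OrthoGroup,
    PhyloTree,
    encode_sequence,
)

logger = logging.getLogger("regionrates.site_rates")

__all__ = [
    "PoissonModel",
    "SUBSTITUTION_MODELS",
    "GammaRateModel",
    "SiteRateResult",
    "AlphaEstimate",
    "discretize_gamma",
    "site_log_likelihood",
    "column_log_likelihoods",
    "estimate_alpha",
    "posterior_mean_rates",
    "normalize_rates",
    "map_to_reference",
    "pairwise_identity_summary",
    "build_nj_tree",
    "estimate_rates",
]

#: floor applied to column log-likelihoods so an impossible column (zero
#: likelihood, e.g. a variable column at rate 0) yields a large negative
#: sentinel instead of -inf propagating through sums.
LOG_ZERO = -1e8

ALPHA_SEARCH_BOUNDS = (math.log(0.01), math.log(100.0))
ALPHA_TOL = 1e-4


# ---------------------------------------------------------------------------
# Substitution model
# ---------------------------------------------------------------------------


class PoissonModel:
    """Poisson (equal-rates) amino-acid model with uniform frequencies."""

    name = "poisson"

    def __init__(self) -> None:
        self.frequencies = np.full(N_STATES, 1.0 / N_STATES)

    def p_stay(self, t: float | np.ndarray) -> float | np.ndarray:
        return 1.0 / 20.0 + (19.0 / 20.0) * np.exp(-20.0 * np.asarray(t) / 19.0)

    def transition_matrix(self, t: float) -> np.ndarray:
        """P[a, b] = P(state b at time t | state a at time 0)."""
        if t < 0:
            raise ValueError("branch length * rate must be >= 0")
        e = math.exp(-20.0 * t / 19.0)
        off = (1.0 - e) / 20.0
        mat = np.full((N_STATES, N_STATES), off)
        np.fill_diagonal(mat, 1.0 / 20.0 + (19.0 / 20.0) * e)
        return mat


SUBSTITUTION_MODELS = {"poisson": PoissonModel()}


def get_model(model: str | PoissonModel) -> PoissonModel:
    if isinstance(model, str):
        try:
            return SUBSTITUTION_MODELS[model]
        except KeyError:
            raise ConfigurationError(f"unknown substitution model {model!r}") from None
    return model


# ---------------------------------------------------------------------------
# Discrete gamma
# ---------------------------------------------------------------------------


def discretize_gamma(alpha: float, K: int) -> tuple[np.ndarray, np.ndarray]:
    """Mean-one discretization of Gamma(alpha) into K equiprobable categories.

    Category boundaries are the i/K quantiles of Gamma(shape=alpha,
    rate=alpha) (which has mean 1); the category rate is the conditional
    mean of the gamma within each quantile slab, so the discretized mean is
    exactly 1.  Priors are all 1/K.
    """
    if alpha <= 0:
        raise ConfigurationError("gamma shape alpha must be > 0")
    if K < 1:
        raise ConfigurationError("number of categories K must be >= 1")
    if K == 1:
        return np.array([1.0]), np.array([1.0])
    probs = np.arange(1, K) / K
    bounds = stats.gamma.ppf(probs, a=alpha, scale=1.0 / alpha)
    # E[X; X in slab] for X ~ Gamma(alpha, rate alpha) uses the CDF of
    # Gamma(alpha + 1, rate alpha) at the same boundaries.
    upper_cdf = np.concatenate(
        [stats.gamma.cdf(bounds, a=alpha + 1.0, scale=1.0 / alpha), [1.0]]
    )
    lower_cdf = np.concatenate([[0.0], upper_cdf[:-1]])
    rates = K * (upper_cdf - lower_cdf)
    priors = np.full(K, 1.0 / K)
    rates /= float(np.sum(rates * priors))  # enforce mean one numerically
    return rates, priors


@dataclass
class GammaRateModel:
    """Discrete-gamma among-site rate model bound to a substitution model."""

    alpha: float
    K: int = 16
    category_rates: np.ndarray = field(default=None)  # type: ignore[assignment]
    category_priors: np.ndarray = field(default=None)  # type: ignore[assignment]
    substitution_model: str = "poisson"

    def __post_init__(self) -> None:
        if self.category_rates is None or self.category_priors is None:
            self.category_rates, self.category_priors = discretize_gamma(self.alpha, self.K)
        self.category_rates = np.asarray(self.category_rates, dtype=float)
        self.category_priors = np.asarray(self.category_priors, dtype=float)
        if abs(self.category_priors.sum() - 1.0) > 1e-9:
            raise ConfigurationError("category priors must sum to 1")
        if abs(float(self.category_priors @ self.category_rates) - 1.0) > 1e-9:
            raise ConfigurationError("discretization must have mean 1")

    @classmethod
    def from_alpha(cls, alpha: float, K: int = 16, substitution_model: str = "poisson"):
        return cls(alpha=alpha, K=K, substitution_model=substitution_model)


# ---------------------------------------------------------------------------
# Pruning likelihood
# ---------------------------------------------------------------------------


def _leaf_rows(group_matrix: np.ndarray, group_taxa: Sequence[str], tree: PhyloTree) -> dict[int, int]:
    """Map tree leaf node index -> row of the alignment matrix."""
    row_of = {taxon: i for i, taxon in enumerate(group_taxa)}
    mapping = {}
    for node, label in tree.leaf_labels.items():
        if label not in row_of:
            raise IntegrityError(f"tree leaf {label!r} has no sequence in the alignment")
        mapping[node] = row_of[label]
    return mapping


def column_log_likelihoods(
    codes: np.ndarray,
    taxa: Sequence[str],
    tree: PhyloTree,
    rate: float,
    model: str | PoissonModel = "poisson",
) -> np.ndarray:
    """Log-likelihood of every alignment column at a common rate multiplier.

    ``codes`` is the (n_sequences, n_columns) uint8 matrix; gap and unknown
    characters are missing data (all-ones partial likelihoods).  Vectorized
    over columns, with per-column rescaling to avoid underflow.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    mod = get_model(model)
    n_cols = codes.shape[1]
    leaf_row = _leaf_rows(codes, taxa, tree)
    partials: dict[int, np.ndarray] = {}
    log_scale = np.zeros(n_cols)
    for node in tree.postorder:
        node = int(node)
        if tree.is_leaf(node):
            col = codes[leaf_row[node]]
            part = np.zeros((n_cols, N_STATES))
            observed = col < N_STATES
            part[observed, col[observed]] = 1.0
            part[~observed, :] = 1.0  # gap/X: missing data
            partials[node] = part
        else:
            part = np.ones((n_cols, N_STATES))
            for child in tree.children[node]:
                p_mat = mod.transition_matrix(float(tree.branch_lengths[child]) * rate)
                part *= partials.pop(child) @ p_mat.T
            mx = part.max(axis=1)
            small = (mx > 0) & (mx < 1e-150)
            if small.any():
                part[small] /= mx[small, None]
                log_scale[small] += np.log(mx[small])
            partials[node] = part
    lik = partials[tree.root] @ mod.frequencies
    with np.errstate(divide="ignore"):
        out = np.log(lik) + log_scale
    return np.maximum(out, LOG_ZERO)


def site_log_likelihood(
    column: str | Sequence[str],
    tree: PhyloTree,
    rate: float,
    model: str | PoissonModel = "poisson",
    taxa: Sequence[str] | None = None,
) -> float:
    """Log-likelihood of one column given the tree, model, and rate.

    ``column`` holds one character per leaf.  If ``taxa`` is omitted the
    characters are matched to ``sorted(tree.taxa)``.
    """
    chars = list(column)
    if taxa is None:
        taxa = tree.taxa
    if len(chars) != len(taxa):
        raise FormatError(
            f"column has {len(chars)} characters for {len(taxa)} taxa"
        )
    if len(taxa) != tree.n_leaves:
        raise FormatError("column must provide one character per tree leaf")
    codes = np.array([[encode_sequence(c)[0]] for c in chars], dtype=np.uint8)
    return float(column_log_likelihoods(codes, list(taxa), tree, rate, model)[0])


# ---------------------------------------------------------------------------
# Alpha estimation
# ---------------------------------------------------------------------------


@dataclass
class AlphaEstimate:
    alpha: float | None
    log_likelihood: float | None
    pinned: bool
    n_sites: int
    note: str = ""


def _informative_mask(codes: np.ndarray) -> np.ndarray:
    """Columns with >= 2 amino-acid (non-gap, non-unknown) characters."""
    return (codes < N_STATES).sum(axis=0) >= 2


def _mixture_log_likelihood(
    codes: np.ndarray,
    taxa: Sequence[str],
    tree: PhyloTree,
    rates: np.ndarray,
    priors: np.ndarray,
    model: str | PoissonModel,
) -> np.ndarray:
    """Per-column log of the prior-weighted mixture over rate categories."""
    per_cat = np.stack(
        [column_log_likelihoods(codes, taxa, tree, r, model) for r in rates]
    )  # (K, n_cols)
    return special.logsumexp(per_cat + np.log(priors)[:, None], axis=0)


def estimate_alpha(
    orthogroups: OrthoGroup | Iterable[OrthoGroup],
    tree: PhyloTree,
    K: int = 16,
    model: str | PoissonModel = "poisson",
) -> AlphaEstimate:
    """Maximum-likelihood gamma shape over the concatenated columns.

    Bounded 1-D search on log-alpha in [log 0.01, log 100] with tolerance
    1e-4 on log-alpha.  An estimate at the upper bound (no detectable rate
    heterogeneity, e.g. all columns invariant) is flagged ``pinned``.
    """
    if isinstance(orthogroups, OrthoGroup):
        orthogroups = [orthogroups]
    groups = list(orthogroups)
    if K == 1:
        return AlphaEstimate(
            alpha=None, log_likelihood=None, pinned=False, n_sites=0,
            note="not estimated (single rate category)",
        )
    mats = []
    for g in groups:
        m = g.matrix()
        mats.append(m[:, _informative_mask(m)])
    codes = np.concatenate(mats, axis=1)
    if codes.shape[1] == 0:
        raise EstimationError(
            "no informative columns (every column has < 2 amino-acid characters)"
        )
    taxa = groups[0].taxa
    for g in groups[1:]:
        if g.taxa != taxa:
            raise IntegrityError("shared-alpha estimation requires identical taxon sets")

    def negative_ll(log_alpha: float) -> float:
        rates, priors = discretize_gamma(math.exp(log_alpha), K)
        return -float(_mixture_log_likelihood(codes, taxa, tree, rates, priors, model).sum())

    res = optimize.minimize_scalar(
        negative_ll,
        bounds=ALPHA_SEARCH_BOUNDS,
        method="bounded",
        options={"xatol": ALPHA_TOL},
    )
    log_alpha = float(res.x)
    # an estimate stuck at either search bound carries no usable shape
    # signal (e.g. an all-invariant alignment drives alpha to the lower
    # bound, concentrating nearly all rate mass at zero) and is flagged
    pinned = (
        log_alpha > ALPHA_SEARCH_BOUNDS[1] - 10 * ALPHA_TOL
        or log_alpha < ALPHA_SEARCH_BOUNDS[0] + 10 * ALPHA_TOL
    )
    if pinned:
        logger.warning(
            "alpha estimate pinned at a search bound (alpha=%.4g over %d columns)",
            math.exp(log_alpha), codes.shape[1],
        )
    return AlphaEstimate(
        alpha=math.exp(log_alpha),
        log_likelihood=-float(res.fun),
        pinned=pinned,
        n_sites=int(codes.shape[1]),
    )


# ---------------------------------------------------------------------------
# Posterior rates
# ---------------------------------------------------------------------------


@dataclass
class SiteRateResult:
    """Posterior site rates for one orthogroup, mapped to the reference."""

    group_id: str
    posterior_mean: np.ndarray  # per column; NaN for all-gap columns
    posterior_sd: np.ndarray
    alpha_hat: float | None
    log_likelihood: float
    reference_map: dict[int, int]  # 1-based column -> 1-based reference position
    reference_taxon: str
    reference_sequence: str  # aligned reference row

    def to_frame(self, protein_id: str | None = None) -> pd.DataFrame:
        """Per-residue table (protein_id, position, amino_acid, rate, posterior_sd)."""
        pid = protein_id if protein_id is not None else self.group_id
        cols = sorted(self.reference_map)
        return pd.DataFrame(
            {
                "protein_id": pid,
                "position": [self.reference_map[c] for c in cols],
                "amino_acid": [self.reference_sequence[c - 1] for c in cols],
                "rate": [self.posterior_mean[c - 1] for c in cols],
                "posterior_sd": [self.posterior_sd[c - 1] for c in cols],
            }
        )


def posterior_mean_rates(
    group: OrthoGroup,
    tree: PhyloTree,
    model: GammaRateModel,
) -> SiteRateResult:
    """Empirical-Bayes posterior mean (and sd) rate for every column.

    posterior_mean = sum_k r_k p_k L_k / sum_k p_k L_k, computed in log
    space.  Columns with no amino-acid character at all get a missing rate.
    """
    codes = group.matrix()
    taxa = group.taxa
    rates = model.category_rates
    priors = model.category_priors
    per_cat = np.stack(
        [
            column_log_likelihoods(codes, taxa, tree, r, model.substitution_model)
            for r in rates
        ]
    )  # (K, n_cols)
    logw = per_cat + np.log(priors)[:, None]
    m = logw.max(axis=0)
    w = np.exp(logw - m)
    wsum = w.sum(axis=0)
    post_mean = (w * rates[:, None]).sum(axis=0) / wsum
    post_sq = (w * (rates**2)[:, None]).sum(axis=0) / wsum
    post_sd = np.sqrt(np.maximum(post_sq - post_mean**2, 0.0))
    has_data = (codes < N_STATES).sum(axis=0) >= 1
    post_mean[~has_data] = np.nan
    post_sd[~has_data] = np.nan
    total_ll = float(special.logsumexp(logw, axis=0).sum())
    return SiteRateResult(
        group_id=group.group_id,
        posterior_mean=post_mean,
        posterior_sd=post_sd,
        alpha_hat=model.alpha,
        log_likelihood=total_ll,
        reference_map=map_to_reference(group),
        reference_taxon=group.reference_taxon,
        reference_sequence=group.reference_sequence,
    )


def normalize_rates(results: Sequence[SiteRateResult]) -> list[SiteRateResult]:
    """Rescale all results so the grand mean rate over mapped residues is 1.

    The mean is taken over reference-mapped, non-missing rates of all
    groups; posterior sds are scaled by the same factor.  Idempotent.
    """
    values = [
        res.posterior_mean[c - 1]
        for res in results
        for c in res.reference_map
        if np.isfinite(res.posterior_mean[c - 1])
    ]
    if not values:
        raise EstimationError("no defined rates to normalize")
    grand_mean = float(np.mean(values))
    out = []
    for res in results:
        out.append(
            SiteRateResult(
                group_id=res.group_id,
                posterior_mean=res.posterior_mean / grand_mean,
                posterior_sd=res.posterior_sd / grand_mean,
                alpha_hat=res.alpha_hat,
                log_likelihood=res.log_likelihood,
                reference_map=dict(res.reference_map),
                reference_taxon=res.reference_taxon,
                reference_sequence=res.reference_sequence,
            )
        )
    return out


def normalize_rate_frame(df: pd.DataFrame, column: str = "rate") -> pd.DataFrame:
    """Divide a rate column by its mean over defined values (grand mean -> 1)."""
    df = df.copy()
    mean = df[column].mean()
    if not np.isfinite(mean) or mean == 0:
        raise EstimationError("no defined rates to normalize")
    df[column] = df[column] / mean
    return df


def map_to_reference(group: OrthoGroup) -> dict[int, int]:
    """1-based alignment column -> 1-based reference position (non-gap only)."""
    ref = group.reference_sequence
    mapping = {}
    pos = 0
    for col, char in enumerate(ref, start=1):
        if char != GAP_CHAR:
            pos += 1
            mapping[col] = pos
    return mapping


def pairwise_identity_summary(group: OrthoGroup) -> tuple[float, float]:
    """(mean % identity over all pairs, over pairs including the reference).

    Pairwise identity counts identical residues over columns where both
    sequences are non-gap, in percent.  Pairs with zero co-aligned columns
    are excluded from the means.
    """
    codes = group.matrix()
    n = codes.shape[0]
    if n < 2:
        raise FormatError("pairwise identity requires >= 2 sequences")
    ref_row = group.taxa.index(group.reference_taxon)
    all_vals, ref_vals = [], []
    non_gap = codes != GAP_CODE
    for i in range(n):
        for j in range(i + 1, n):
            both = non_gap[i] & non_gap[j]
            n_both = int(both.sum())
            if n_both == 0:
                continue
            ident = 100.0 * float((codes[i, both] == codes[j, both]).sum()) / n_both
            all_vals.append(ident)
            if ref_row in (i, j):
                ref_vals.append(ident)
    mean_all = float(np.mean(all_vals)) if all_vals else math.nan
    mean_ref = float(np.mean(ref_vals)) if ref_vals else math.nan
    return mean_all, mean_ref


# ---------------------------------------------------------------------------
# Fallback tree (fixtures only) and high-level driver
# ---------------------------------------------------------------------------


def build_nj_tree(group: OrthoGroup) -> PhyloTree:
    """Neighbor-joining tree from Poisson-corrected pairwise distances.

    FALLBACK for fixtures when no phylogeny is supplied; production runs
    should pass a tree.  Distances are -19/20 * ln(1 - 20 d / 19) with d the
    pairwise amino-acid difference fraction over co-aligned columns;
    saturated pairs are capped.  Negative NJ branch lengths are clipped to 0.
    """
    import io as _io

    import dendropy

    codes = group.matrix()
    n = codes.shape[0]
    non_gap = codes != GAP_CODE
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = non_gap[i] & non_gap[j]
            n_both = int(both.sum())
            d = float((codes[i, both] != codes[j, both]).sum()) / n_both if n_both else 0.0
            d = min(d, 19.0 / 20.0 - 1e-6)
            dist[i, j] = dist[j, i] = -19.0 / 20.0 * math.log(1.0 - 20.0 * d / 19.0)
    buf = _io.StringIO()
    buf.write("," + ",".join(group.taxa) + "\n")
    for i, taxon in enumerate(group.taxa):
        buf.write(taxon + "," + ",".join(f"{x:.10f}" for x in dist[i]) + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(buf, delimiter=",")
    nj = pdm.nj_tree()
    tree = PhyloTree.from_dendropy(nj)
    blen = np.maximum(tree.branch_lengths, 0.0)
    logger.warning("using NJ fallback tree for group %s", group.group_id)
    return PhyloTree(tree.parent, blen, tree.leaf_labels)


def estimate_rates(
    groups: Sequence[OrthoGroup],
    tree: PhyloTree,
    K: int = 16,
    shared_alpha: bool = False,
    model: str = "poisson",
    normalize: str = "proteome",
    protein_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Run the full estimator over many orthogroups.

    Alpha is fitted per group by default, or once on the concatenated
    columns with ``shared_alpha=True``.  ``normalize`` is ``"proteome"``
    (grand mean over all residues -> 1, the default) or ``"per-protein"``.
    Returns one row per reference residue: protein_id, position,
    amino_acid, rate, posterior_sd, alpha_hat.
    """
    if normalize not in ("proteome", "per-protein"):
        raise ConfigurationError(f"unknown normalization {normalize!r}")
    if protein_ids is None:
        protein_ids = [g.group_id for g in groups]
    shared: AlphaEstimate | None = None
    if shared_alpha and K > 1:
        shared = estimate_alpha(groups, tree, K=K, model=model)
    results, ids = [], []
    for pid, group in zip(protein_ids, groups):
        est = shared if shared is not None else (
            estimate_alpha(group, tree, K=K, model=model) if K > 1 else None
        )
        alpha = est.alpha if est is not None and est.alpha is not None else 1.0
        rate_model = GammaRateModel.from_alpha(alpha, K=K, substitution_model=model)
        results.append(posterior_mean_rates(group, tree, rate_model))
        ids.append(pid)
    if normalize == "proteome":
        results = normalize_rates(results)
    frames = []
    for pid, res in zip(ids, results):
        frame = res.to_frame(protein_id=pid)
        if normalize == "per-protein":
            frame["rate"] /= frame["rate"].mean()
        frame["alpha_hat"] = res.alpha_hat
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
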