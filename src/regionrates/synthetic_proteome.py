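"""Synthetic proteomes with region-structured evolutionary rates.

The generator emulates the statistical structure of a fungal proteome as the
downstream analysis assumes it: a few thousand proteins, each laid out as
alternating folded domains and intrinsically disordered segments (disorder at
the termini and as inter-domain linkers), with

* log-normal protein lengths and log-normal cellular abundances (ppm);
* per-residue relative solvent accessibility (rASA) for structured residues,
  drawn from a right-skewed distribution on [0, 1], and missing for
  disordered residues (which have no stable structure);
* disorder probabilities high inside disordered segments, low elsewhere,
  with the proteome-wide disordered fraction near 20%;
* true per-residue evolutionary rates whose expectation depends on region
  (a disorder:domain mean-rate ratio ``rho_diso_domain``, default 2), on
  rASA within structured regions (calibrated so the surface:buried
  mean-rate ratio at the 25% cutoff hits ``surface_buried_ratio``), and on
  abundance through a power-law factor ``(ppm / median ppm) ** g`` with a
  global (or optionally region-specific) exponent g <= 0;
* i.i.d. log-normal per-residue noise plus a small per-protein, per-region
  log-normal effect.

All rates are normalized to a proteome-wide mean of exactly 1, matching the
scale on which conservation ratios are computed.  A companion sequence
simulator evolves gapless alignments along a phylogeny under a Poisson
amino-acid model with per-site rate multipliers, enabling recovery tests of
the site-rate estimator.

Randomness is split per protein from the master seed, so generating a larger
proteome leaves the random draws of earlier proteins untouched.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_formats import (
    AMINO_ACIDS,
    ConfigurationError,
    OrthoGroup,
    PhyloTree,
    RangeError,
    write_abundance_table,
    write_domain_table,
    write_feature_table,
)

logger = logging.getLogger("regionrates.synthetic")

__all__ = [
    "SyntheticConfig",
    "SyntheticProteome",
    "generate_proteome",
    "simulate_msa",
    "make_default_tree",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class SyntheticConfig:
    """Parameters of the generative model.

    Defaults describe the study conditions the analysis is designed for:
    ~3000 proteins, median length ~400 residues, ppm abundances spanning
    roughly 0.1 to > 20,000 with median ~20, a disorder:domain rate ratio of
    2, a surface:buried rate ratio of 2 at the 25% rASA cutoff, ~20%
    disordered residues proteome-wide, and a mild global abundance-rate
    coupling (g = -0.2).
    """

    n_proteins: int = 3000
    seed: int = 0

    # protein length: lognormal, clipped below
    length_log_mean: float = math.log(400.0)
    length_log_sd: float = 0.45
    min_length: int = 80

    # abundance: lognormal ppm
    abundance_log_mean: float = math.log(20.0)
    abundance_log_sd: float = 2.0

    # region rate structure
    rho_diso_domain: float = 2.0
    surface_buried_ratio: float = 2.0
    rasa_alpha: float = 1.2
    rasa_beta: float = 2.0
    surface_cutoff: float = 0.25  # cutoff at which surface_buried_ratio is calibrated

    # abundance coupling: rate *= (ppm_eff / median ppm) ** g
    abundance_coupling: float = -0.2
    region_specific_coupling: dict[str, float] | None = None  # {"disorder": g, "domain": g}
    coupling_floor_ppm: float | None = None  # ppm below this see no coupling

    # noise
    noise_sd: float = 0.3  # per residue, log scale
    region_noise_sd: float = 0.1  # per protein x region, log scale

    # layout
    disorder_fraction: float = 0.20
    disorder_fraction_concentration: float = 60.0  # Beta concentration per protein
    disorder_segment_mean: float = 40.0
    min_segment: int = 20

    # disorder probability emission (Beta parameters)
    disorder_prob_in: tuple[float, float] = (9.0, 2.0)
    disorder_prob_out: tuple[float, float] = (2.0, 9.0)

    # "virtual rASA" mode: disordered residues draw a rASA from the upper
    # tail (> virtual_rasa_min) of the structured-residue distribution and
    # take the rate multiplier of that rASA, placing disorder at the
    # super-accessible end of the surface spectrum.
    virtual_rasa: bool = False
    virtual_rasa_min: float = 0.8

    decoy_domain_prob: float = 0.2  # chance of one above-threshold (filtered) hit
    pdb_structure_prob: float = 0.2

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ConfigurationError("n_proteins must be >= 1")
        if self.rho_diso_domain <= 0:
            raise ConfigurationError("rho_diso_domain must be > 0")
        if self.surface_buried_ratio <= 0:
            raise ConfigurationError("surface_buried_ratio must be > 0")
        if self.noise_sd < 0 or self.region_noise_sd < 0:
            raise ConfigurationError("noise standard deviations must be >= 0")
        if not 0.0 < self.disorder_fraction < 1.0:
            raise ConfigurationError("disorder_fraction must be in (0, 1)")
        if self.abundance_coupling > 0:
            raise ConfigurationError("abundance_coupling must be <= 0")
        if self.min_length < 4 * self.min_segment:
            raise ConfigurationError(
                "min_length must be at least 4 * min_segment so every protein "
                "can hold a disordered and a domain segment with margin"
            )
        if not 0.0 < self.surface_cutoff < 1.0:
            raise ConfigurationError("surface_cutoff must be in (0, 1)")


@dataclass
class SyntheticProteome:
    """A generated proteome: metadata, residues with true rates, domains."""

    proteins: pd.DataFrame  # protein_id, length, abundance_ppm, orthogroup_id, has_pdb_structure
    residues: pd.DataFrame  # canonical feature columns; ``rate`` is the true rate
    domains: pd.DataFrame  # protein_id, start, end, evalue
    config: SyntheticConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write features.tsv, abundance.tsv, domains.tsv; return the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "features": outdir / "features.tsv",
            "abundance": outdir / "abundance.tsv",
            "domains": outdir / "domains.tsv",
        }
        write_feature_table(self.residues, paths["features"])
        abundance = dict(
            zip(self.proteins["protein_id"], self.proteins["abundance_ppm"])
        )
        write_abundance_table(abundance, paths["abundance"])
        write_domain_table(self.domains, paths["domains"])
        return paths


# ---------------------------------------------------------------------------
# rASA -> rate multiplier calibration
# ---------------------------------------------------------------------------


def _rasa_grid(a: float, b: float, n: int = 4001) -> tuple[np.ndarray, np.ndarray]:
    """Midpoint grid and Beta(a, b) weights for numerical expectations."""
    edges = np.linspace(0.0, 1.0, n + 1)
    x = 0.5 * (edges[:-1] + edges[1:])
    w = np.diff(stats.beta.cdf(edges, a, b))
    return x, w


def calibrate_rasa_slope(config: SyntheticConfig) -> float:
    """Exponential-slope b such that E[e^{b r} | r > c] / E[e^{b r} | r <= c]
    equals the configured surface:buried ratio under the rASA Beta law."""
    target = config.surface_buried_ratio
    x, w = _rasa_grid(config.rasa_alpha, config.rasa_beta)
    above = x > config.surface_cutoff

    def ratio_minus_target(slope: float) -> float:
        m = np.exp(slope * x)
        num = (m * w)[above].sum() / w[above].sum()
        den = (m * w)[~above].sum() / w[~above].sum()
        return num / den - target

    if abs(target - 1.0) < 1e-12:
        return 0.0
    return float(optimize.brentq(ratio_minus_target, -60.0, 60.0, xtol=1e-12))


def _rasa_multiplier_fn(config: SyntheticConfig):
    """Return (slope, normalizer) so exp(slope*r)/Z has mean 1 over the Beta law."""
    slope = calibrate_rasa_slope(config)
    x, w = _rasa_grid(config.rasa_alpha, config.rasa_beta)
    z = float((np.exp(slope * x) * w).sum())
    return slope, z


# ---------------------------------------------------------------------------
# Proteome generation
# ---------------------------------------------------------------------------


def _split_lengths(total: int, k: int, min_len: int, rng: np.random.Generator) -> np.ndarray:
    """Random composition of ``total`` into ``k`` parts, each >= ``min_len``."""
    extra = total - k * min_len
    if extra < 0:
        raise ValueError("total too small for requested segments")
    if k == 1:
        return np.array([total])
    weights = rng.dirichlet(np.ones(k))
    parts = np.floor(weights * extra).astype(int)
    parts[rng.integers(0, k)] += extra - parts.sum()
    return parts + min_len


def _protein_layout(
    length: int, config: SyntheticConfig, rng: np.random.Generator
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Segment a protein into alternating domain/disorder stretches.

    Returns a boolean per-residue disorder mask and the list of domain
    intervals (1-based inclusive).
    """
    ms = config.min_segment
    f = rng.beta(
        config.disorder_fraction_concentration * config.disorder_fraction,
        config.disorder_fraction_concentration * (1.0 - config.disorder_fraction),
    )
    n_diso = int(np.clip(round(f * length), ms, length - ms))
    n_dom = length - n_diso
    k = int(np.clip(round(n_diso / config.disorder_segment_mean), 1, n_diso // ms))
    m_max = n_dom // ms  # >= 1 because n_dom >= ms
    k = min(k, m_max + 1)  # alternation requires |k - m| <= 1 with m <= m_max
    m = int(np.clip(k + rng.integers(-1, 2), max(1, k - 1), min(m_max, k + 1)))
    diso_lens = _split_lengths(n_diso, k, ms, rng)
    dom_lens = _split_lengths(n_dom, m, ms, rng)
    segments: list[tuple[str, int]] = []
    if m == k + 1:  # domains at both termini, disorder only as linkers
        for i in range(k):
            segments += [("D", dom_lens[i]), ("I", diso_lens[i])]
        segments.append(("D", dom_lens[k]))
    elif m == k:  # disorder at exactly one terminus
        if rng.random() < 0.5:
            for i in range(k):
                segments += [("I", diso_lens[i]), ("D", dom_lens[i])]
        else:
            for i in range(k):
                segments += [("D", dom_lens[i]), ("I", diso_lens[i])]
    else:  # m == k - 1: disorder at both termini
        segments.append(("I", diso_lens[0]))
        for i in range(m):
            segments += [("D", dom_lens[i]), ("I", diso_lens[i + 1])]
    mask = np.zeros(length, dtype=bool)
    intervals: list[tuple[int, int]] = []
    pos = 0
    for kind, seg_len in segments:
        if kind == "I":
            mask[pos : pos + seg_len] = True
        else:
            intervals.append((pos + 1, pos + seg_len))  # 1-based inclusive
        pos += seg_len
    assert pos == length
    return mask, intervals


def generate_proteome(config: SyntheticConfig) -> SyntheticProteome:
    """Generate a synthetic proteome with true per-residue rates.

    Deterministic given ``config.seed``.  The returned residue table's
    ``rate`` column holds the true rate, globally normalized to mean 1.
    """
    config.validate()
    slope, z = _rasa_multiplier_fn(config)
    master = np.random.SeedSequence(config.seed)
    children = master.spawn(config.n_proteins)
    # abundance first (own substream per protein) so the median is available
    ppm = np.empty(config.n_proteins)
    streams = []
    for i, child in enumerate(children):
        ss_ppm, ss_res = child.spawn(2)
        rng_ppm = np.random.default_rng(ss_ppm)
        ppm[i] = rng_ppm.lognormal(config.abundance_log_mean, config.abundance_log_sd)
        streams.append(ss_res)
    median_ppm = float(np.median(ppm))

    g_global = config.abundance_coupling
    g_by_region = config.region_specific_coupling or {}
    g_diso = float(g_by_region.get("disorder", g_global))
    g_dom = float(g_by_region.get("domain", g_global))
    floor = config.coupling_floor_ppm

    amino = np.array(list(AMINO_ACIDS))
    prot_rows = []
    res_frames = []
    dom_rows = []
    for i in range(config.n_proteins):
        rng = np.random.default_rng(streams[i])
        pid = f"P{i:05d}"
        length = int(
            max(config.min_length, round(rng.lognormal(config.length_log_mean, config.length_log_sd)))
        )
        diso_mask, intervals = _protein_layout(length, config, rng)
        aa = amino[rng.integers(0, 20, size=length)]

        rasa = np.full(length, np.nan)
        n_struct = int((~diso_mask).sum())
        rasa[~diso_mask] = rng.beta(config.rasa_alpha, config.rasa_beta, size=n_struct)

        dprob = np.empty(length)
        a_in, b_in = config.disorder_prob_in
        a_out, b_out = config.disorder_prob_out
        n_diso = int(diso_mask.sum())
        dprob[diso_mask] = rng.beta(a_in, b_in, size=n_diso)
        dprob[~diso_mask] = rng.beta(a_out, b_out, size=n_struct)

        mult = np.empty(length)
        mult[~diso_mask] = np.exp(slope * rasa[~diso_mask]) / z
        if config.virtual_rasa:
            # disorder behaves as super-accessible surface: sample rASA from
            # the structured distribution conditioned on r > virtual_rasa_min
            lo = stats.beta.cdf(config.virtual_rasa_min, config.rasa_alpha, config.rasa_beta)
            u = rng.uniform(lo, 1.0, size=n_diso)
            vr = stats.beta.ppf(u, config.rasa_alpha, config.rasa_beta)
            rasa[diso_mask] = vr
            mult[diso_mask] = np.exp(slope * vr) / z
        else:
            mult[diso_mask] = config.rho_diso_domain

        ppm_eff = max(ppm[i], floor) if floor is not None else ppm[i]
        rel = ppm_eff / median_ppm
        coupling = np.where(diso_mask, rel**g_diso, rel**g_dom)

        region_noise_d, region_noise_s = np.exp(
            rng.normal(0.0, config.region_noise_sd, size=2)
        )
        region_noise = np.where(diso_mask, region_noise_d, region_noise_s)
        noise = np.exp(rng.normal(0.0, config.noise_sd, size=length))
        rate = mult * coupling * region_noise * noise

        evalues = 10.0 ** (-rng.uniform(3.5, 10.0, size=len(intervals)))
        in_domain = np.zeros(length, dtype=bool)
        dom_evalue = np.full(length, np.nan)
        for (start, end), ev in zip(intervals, evalues):
            in_domain[start - 1 : end] = True
            dom_evalue[start - 1 : end] = ev
            dom_rows.append((pid, start, end, ev))
        if rng.random() < config.decoy_domain_prob:
            # an above-threshold hit that the E-value filter must discard
            dlen = int(rng.integers(config.min_segment, 3 * config.min_segment))
            dstart = int(rng.integers(1, max(2, length - dlen)))
            dom_rows.append((pid, dstart, min(length, dstart + dlen - 1),
                             10.0 ** (-rng.uniform(0.0, 2.9))))

        res_frames.append(
            pd.DataFrame(
                {
                    "protein_id": pid,
                    "position": np.arange(1, length + 1),
                    "amino_acid": aa,
                    "rasa": rasa,
                    "disorder_prob": dprob,
                    "in_domain": in_domain,
                    "domain_evalue": dom_evalue,
                    "rate": rate,
                }
            )
        )
        prot_rows.append(
            (
                pid,
                length,
                ppm[i],
                f"OG{i:05d}",
                bool(rng.random() < config.pdb_structure_prob),
            )
        )

    residues = pd.concat(res_frames, ignore_index=True)
    residues["rate"] /= residues["rate"].mean()  # proteome mean exactly 1
    proteins = pd.DataFrame(
        prot_rows,
        columns=["protein_id", "length", "abundance_ppm", "orthogroup_id", "has_pdb_structure"],
    )
    domains = pd.DataFrame(dom_rows, columns=["protein_id", "start", "end", "evalue"])
    logger.info("generated %d proteins, %d residues", len(proteins), len(residues))
    return SyntheticProteome(proteins=proteins, residues=residues, domains=domains, config=config)


# ---------------------------------------------------------------------------
# Sequence simulation
# ---------------------------------------------------------------------------


def simulate_msa(
    tree: PhyloTree,
    site_rates: Sequence[float],
    model: str = "poisson",
    seed: int = 0,
    reference_taxon: str | None = None,
    group_id: str = "sim",
) -> OrthoGroup:
    """Evolve a gapless alignment along ``tree`` with per-site rate multipliers.

    The root sequence is drawn from the model's equilibrium frequencies and
    each branch evolves each site under the reversible amino-acid model with
    effective time ``branch_length * site_rates[i]``.  Under the Poisson
    model this is simulated exactly via its event representation: with
    probability ``exp(-20 t / 19)`` the site keeps its state, otherwise it
    redraws uniformly from the 20 amino acids.
    """
    if model != "poisson":
        raise ConfigurationError(f"unknown substitution model {model!r}")
    rates = np.asarray(site_rates, dtype=float)
    if rates.ndim != 1 or len(rates) == 0:
        raise ConfigurationError("site_rates must be a non-empty 1-D sequence")
    if np.any(~np.isfinite(rates)) or np.any(rates < 0):
        raise RangeError("site_rates must be finite and >= 0")
    if tree.n_leaves < 2:
        raise ConfigurationError("tree must have >= 2 leaves")
    rng = np.random.default_rng(seed)
    n_sites = len(rates)
    states: dict[int, np.ndarray] = {
        tree.root: rng.integers(0, 20, size=n_sites, dtype=np.int64)
    }
    for node in tree.postorder[::-1]:  # preorder: parents before children
        node = int(node)
        if node == tree.root:
            continue
        t = float(tree.branch_lengths[node]) * rates
        p_event = -np.expm1(-(20.0 / 19.0) * t)
        child = states[int(tree.parent[node])].copy()
        hit = rng.random(n_sites) < p_event
        child[hit] = rng.integers(0, 20, size=int(hit.sum()), dtype=np.int64)
        states[node] = child
    amino = np.array(list(AMINO_ACIDS))
    leaf_nodes = sorted(tree.leaf_labels)
    taxa = [tree.leaf_labels[n] for n in leaf_nodes]
    seqs = ["".join(amino[states[n]]) for n in leaf_nodes]
    ref = reference_taxon if reference_taxon is not None else taxa[0]
    return OrthoGroup(group_id=group_id, taxa=taxa, sequences=seqs, reference_taxon=ref)


def make_default_tree(
    n_taxa: int,
    depth: float = 1.0,
    seed: int = 0,
    jitter_sd: float = 0.3,
) -> PhyloTree:
    """Random coalescent-style phylogeny scaled to a given mean root-to-tip path.

    Pairs of lineages merge at exponential waiting times (Kingman rates),
    branch lengths get independent log-normal rate jitter (so the tree is
    not ultrametric), and all branch lengths are then rescaled so the mean
    root-to-tip path length equals ``depth`` exactly.  Leaves are labeled
    t01, t02, ...
    """
    if n_taxa < 2:
        raise ConfigurationError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    n_nodes = 2 * n_taxa - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    height = np.zeros(n_nodes)
    active = list(range(n_taxa))
    t = 0.0
    nxt = n_taxa
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[int(i)], active[int(j)]
        parent[a] = parent[b] = nxt
        height[nxt] = t
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    blen = np.zeros(n_nodes)
    for node in range(n_nodes - 1):
        blen[node] = height[parent[node]] - height[node]
    if jitter_sd > 0:
        blen[:-1] *= rng.lognormal(0.0, jitter_sd, size=n_nodes - 1)
    width = max(2, len(str(n_taxa)))
    labels = {i: f"t{i + 1:0{width}d}" for i in range(n_taxa)}
    tree = PhyloTree(parent, blen, labels)
    mean_depth = float(np.mean(list(tree.root_to_tip_lengths().values())))
    return tree.scaled(depth / mean_depth)
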