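"""End-to-end orchestration: simulate -> rates -> annotate -> ratios -> abundance.

A single plain-text (YAML) config drives every stage; all randomness flows
from one seed.  Each run writes TSV result tables, a ``summary.json`` with
the headline numbers, and a ``manifest.json`` recording the echoed config,
the seed, SHA-256 digests of every input, and protein counts at every
filter step — enough to re-run bit-identically.  Two runs with the same
config and seed produce byte-identical result directories (wall-clock
timings go to the log, never into result files).
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import math
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .abundance_analysis import (
    AbundanceBins,
    bin_by_abundance,
    coupling_by_class,
    fit_sigmoid,
    log10_with_offset,
    ratio_abundance_trend,
)
from .io_formats import (
    ConfigurationError,
    PhyloTree,
    read_abundance_table,
    read_domain_table,
    read_feature_table,
    read_msa_fasta,
    read_newick,
    write_feature_table,
    write_msa_fasta,
    write_newick,
    write_table,
)
from .region_annotation import AnnotationConfig, build_region_labels
from .region_stats import (
    asa_cutoff_sweep,
    parse_pair,
    ratio_records,
    region_summaries,
    summarize_ratios,
)
from .site_rates import estimate_rates
from .synthetic_proteome import SyntheticConfig, generate_proteome, make_default_tree, simulate_msa

logger = logging.getLogger("regionrates.pipeline")

__all__ = ["DEFAULT_CONFIG", "load_config", "run_all", "compare_to_reference"]


DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "simulate": {
        "n_proteins": 300,
        "noise_sd": 0.3,
        "region_noise_sd": 0.1,
        "rho_diso_domain": 2.0,
        "surface_buried_ratio": 2.0,
        "abundance_coupling": -0.2,
        "region_specific_coupling": None,
        "coupling_floor_ppm": None,
        "virtual_rasa": False,
        "write_msas": False,
        "n_msas": 4,
        "msa_n_taxa": 14,
        "tree_depth": 1.0,
    },
    "inputs": {
        "features": None,
        "abundance": None,
        "domains": None,
        "msa_dir": None,
        "tree": None,
        "reference_taxon": None,
    },
    "rates": {"categories": 16, "shared_alpha": False, "normalize": "proteome"},
    "annotate": {
        "surface_rasa_cutoff": 0.25,
        "disorder_top_fraction": 0.20,
        "domain_evalue_max": 1e-3,
        "min_region_residues": 20,
        "overlap_policy": "exclude",
    },
    "ratios": {"pairs": ["disorder:domain", "surface:buried"], "sweep": False},
    "abundance": {
        "bins": [0, 3, 18, 59, 352, 21866],
        "quantile_bins": None,
        "pairs": ["disorder:domain", "surface:buried"],
        "fit_sigmoid": True,
    },
}


def _deep_update(base: dict, overrides: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, val in overrides.items():
        if isinstance(val, Mapping) and isinstance(out.get(key), dict):
            out[key] = _deep_update(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | Path | None = None, overrides: Mapping | None = None) -> dict:
    """Merge the default config with a YAML file and explicit overrides."""
    config = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigurationError(f"config file {path} must hold a mapping")
        config = _deep_update(config, loaded)
    if overrides:
        config = _deep_update(config, overrides)
    return config


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_json(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def _simulate_stage(config: dict, outdir: Path) -> dict[str, Path]:
    sim = config["simulate"]
    syn_config = SyntheticConfig(
        n_proteins=int(sim["n_proteins"]),
        seed=int(config["seed"]),
        noise_sd=float(sim["noise_sd"]),
        region_noise_sd=float(sim["region_noise_sd"]),
        rho_diso_domain=float(sim["rho_diso_domain"]),
        surface_buried_ratio=float(sim["surface_buried_ratio"]),
        abundance_coupling=float(sim["abundance_coupling"]),
        region_specific_coupling=sim["region_specific_coupling"],
        coupling_floor_ppm=sim["coupling_floor_ppm"],
        virtual_rasa=bool(sim["virtual_rasa"]),
    )
    proteome = generate_proteome(syn_config)
    paths = proteome.write(outdir)
    if sim["write_msas"]:
        tree = make_default_tree(
            int(sim["msa_n_taxa"]), depth=float(sim["tree_depth"]), seed=int(config["seed"])
        )
        tree_path = outdir / "tree.nwk"
        write_newick(tree, tree_path)
        msa_dir = outdir / "msa"
        msa_dir.mkdir(exist_ok=True)
        ref = tree.taxa[0]
        for i, (pid, grp) in enumerate(proteome.residues.groupby("protein_id", sort=True)):
            if i >= int(sim["n_msas"]):
                break
            group = simulate_msa(
                tree,
                grp["rate"].to_numpy(),
                seed=int(config["seed"]) * 100003 + i,
                reference_taxon=ref,
                group_id=pid,
            )
            write_msa_fasta(group, msa_dir / f"{pid}.fasta")
        paths["msa_dir"] = msa_dir
        paths["tree"] = tree_path
    return paths


def run_all(
    config: dict,
    outdir: str | Path,
    simulate: bool = False,
) -> dict:
    """Execute every configured stage and return the run manifest.

    With ``simulate=True`` the synthetic generator provides all inputs;
    otherwise the paths under ``config["inputs"]`` are read.  Missing
    required inputs abort with :class:`ConfigurationError` before any
    computation.
    """
    t0 = time.monotonic()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = dict(config["inputs"])
    if simulate:
        sim_paths = _simulate_stage(config, outdir / "inputs")
        inputs["features"] = sim_paths["features"]
        inputs["abundance"] = sim_paths["abundance"]
        inputs["domains"] = sim_paths["domains"]
        if "msa_dir" in sim_paths:
            inputs["msa_dir"] = sim_paths["msa_dir"]
            inputs["tree"] = sim_paths["tree"]
            inputs["reference_taxon"] = read_newick(sim_paths["tree"]).taxa[0]
        logger.info("simulate stage done (%.1fs)", time.monotonic() - t0)
    for required in ("features", "abundance"):
        if inputs.get(required) is None:
            raise ConfigurationError(f"missing required input {required!r}")
        if not Path(inputs[required]).exists():
            raise ConfigurationError(f"input file not found: {inputs[required]}")

    digests = {
        key: _sha256(Path(val))
        for key, val in inputs.items()
        if val is not None and Path(str(val)).is_file()
    }

    features = read_feature_table(inputs["features"])
    abundance = read_abundance_table(inputs["abundance"])
    domains = read_domain_table(inputs["domains"]) if inputs.get("domains") else None
    counts: dict[str, int] = {"proteins_in": int(features["protein_id"].nunique())}

    # ---- rates stage ------------------------------------------------------
    t_stage = time.monotonic()
    if inputs.get("msa_dir"):
        if inputs.get("tree") is None:
            raise ConfigurationError("rates from MSAs require a tree input")
        tree = read_newick(inputs["tree"])
        ref = inputs.get("reference_taxon") or tree.taxa[0]
        msa_paths = sorted(Path(inputs["msa_dir"]).glob("*.fasta"))
        groups = [read_msa_fasta(p, reference_taxon=ref) for p in msa_paths]
        rates_cfg = config["rates"]
        estimated = estimate_rates(
            groups,
            tree,
            K=int(rates_cfg["categories"]),
            shared_alpha=bool(rates_cfg["shared_alpha"]),
            normalize=rates_cfg["normalize"],
        )
        write_table(estimated, outdir / "rates.tsv")
        # estimated rates replace input rates for proteins with an MSA
        est_map = estimated.set_index(["protein_id", "position"])["rate"]
        idx = pd.MultiIndex.from_frame(features[["protein_id", "position"]])
        replacement = est_map.reindex(idx)
        features = features.copy()
        mask = replacement.notna().to_numpy()
        features.loc[mask, "rate"] = replacement.to_numpy()[mask]
        logger.info(
            "rates stage: estimated %d groups (%.1fs)",
            len(groups), time.monotonic() - t_stage,
        )
    features = features[np.isfinite(features["rate"])].reset_index(drop=True)
    features["rate"] /= features["rate"].mean()
    counts["proteins_with_rates"] = int(features["protein_id"].nunique())

    # ---- annotate stage ---------------------------------------------------
    ann_cfg = config["annotate"]
    ann = AnnotationConfig(
        surface_rasa_cutoff=float(ann_cfg["surface_rasa_cutoff"]),
        disorder_top_fraction=float(ann_cfg["disorder_top_fraction"]),
        domain_evalue_max=float(ann_cfg["domain_evalue_max"]),
        min_region_residues=int(ann_cfg["min_region_residues"]),
        overlap_policy=ann_cfg["overlap_policy"],
    )
    labels = build_region_labels(features, domains, ann)
    write_table(labels, outdir / "labels.tsv")

    # ---- ratios stage -----------------------------------------------------
    summaries = region_summaries(features, labels, min_n=ann.min_region_residues)
    write_table(summaries, outdir / "region_means.tsv")
    pairs = [parse_pair(p) for p in config["ratios"]["pairs"]]
    ratios = ratio_records(summaries, pairs)
    write_table(ratios, outdir / "ratios.tsv")
    summary_rows = []
    ratio_summary_stats: dict[str, Any] = {}
    for num, den in pairs:
        sub = ratios[(ratios["numerator_region"] == num) & (ratios["denominator_region"] == den)]
        rs = summarize_ratios(sub["ratio"], num, den)
        summary_rows.append((num, den, rs.n_proteins, rs.median_ratio, rs.mad))
        ratio_summary_stats[f"{num}:{den}"] = {
            "n": rs.n_proteins, "median": rs.median_ratio, "mad": rs.mad,
        }
        counts[f"proteins_with_ratio_{num}:{den}"] = rs.n_proteins
    write_table(
        pd.DataFrame(
            summary_rows,
            columns=["numerator_region", "denominator_region", "n_proteins",
                     "median_ratio", "mad"],
        ),
        outdir / "ratio_summaries.tsv",
    )
    if config["ratios"]["sweep"]:
        sweep = asa_cutoff_sweep(features, labels, ann)
        write_table(sweep, outdir / "sweep.tsv")

    # ---- abundance stage --------------------------------------------------
    ab_cfg = config["abundance"]
    ppm = pd.Series(abundance, name="ppm")
    protein_ids = summaries["protein_id"].unique()
    ppm = ppm.reindex(protein_ids)
    counts["proteins_with_abundance"] = int(ppm.notna().sum())
    if ab_cfg.get("quantile_bins"):
        k = int(ab_cfg["quantile_bins"])
        qs = np.quantile(ppm.dropna(), np.linspace(0, 1, k + 1))
        qs[0] = 0.0
        edges = tuple(np.unique(qs))
        bins = AbundanceBins(edges)
    else:
        bins = AbundanceBins(tuple(ab_cfg["bins"]))
    classes = bin_by_abundance(ppm, bins)
    region_means = summaries.pivot(index="protein_id", columns="region", values="mean_rate")

    coupling_rows = []
    abundance_stats: dict[str, Any] = {"bins": list(bins.edges)}
    for pair_name in ab_cfg["pairs"]:
        pair = parse_pair(pair_name)
        for res in coupling_by_class(region_means, classes, pair, bins):
            coupling_rows.append(
                (res.class_label, res.numerator_region, res.denominator_region,
                 res.n_proteins, res.spearman_rho, res.p_value)
            )
            abundance_stats.setdefault("coupling", {}).setdefault(
                f"{pair[0]}:{pair[1]}", {}
            )[res.class_label] = {
                "n": res.n_proteins, "rho": res.spearman_rho, "p": res.p_value,
            }
    write_table(
        pd.DataFrame(
            coupling_rows,
            columns=["class", "numerator_region", "denominator_region",
                     "n_proteins", "spearman_rho", "p_value"],
        ),
        outdir / "coupling.tsv",
    )

    trend_frames = []
    for pair_name in ab_cfg["pairs"]:
        num, den = parse_pair(pair_name)
        sub = ratios[(ratios["numerator_region"] == num) & (ratios["denominator_region"] == den)]
        ratio_series = sub.set_index("protein_id")["ratio"].reindex(protein_ids)
        rho, p, per_class = ratio_abundance_trend(ratio_series, ppm, bins)
        per_class.insert(0, "pair", f"{num}:{den}")
        trend_frames.append(per_class)
        abundance_stats.setdefault("ratio_trend", {})[f"{num}:{den}"] = {
            "rho": rho, "p": p,
        }
    write_table(pd.concat(trend_frames, ignore_index=True), outdir / "trend.tsv")

    sigmoid_stats: dict[str, Any] = {}
    if ab_cfg["fit_sigmoid"]:
        x_all = log10_with_offset(ppm.to_numpy())
        for region in ("full", "disorder", "domain"):
            if region not in region_means.columns:
                continue
            er = region_means[region].reindex(protein_ids).to_numpy()
            ok = np.isfinite(er) & np.isfinite(x_all)
            if ok.sum() >= 8 and (x_all[ok].max() - x_all[ok].min()) >= 1.0:
                fit = fit_sigmoid(x_all[ok], er[ok])
                sigmoid_stats[region] = asdict(fit)
        _write_json(sigmoid_stats, outdir / "sigmoid.json")

    summary = {
        "ratio_summaries": ratio_summary_stats,
        "abundance": abundance_stats,
        "disorder_threshold": labels.attrs.get("disorder_threshold"),
        "counts": counts,
    }
    _write_json(summary, outdir / "summary.json")

    manifest = {
        "package_version": __version__,
        "seed": int(config["seed"]),
        "config": config,
        "input_digests": digests,
        "stages": ["simulate" if simulate else "load", "rates", "annotate",
                    "ratios", "abundance"],
        "counts": counts,
    }
    _write_json(manifest, outdir / "manifest.json")
    logger.info("pipeline finished in %.1fs", time.monotonic() - t0)
    return manifest


# ---------------------------------------------------------------------------
# Comparison harness
# ---------------------------------------------------------------------------


def flatten(obj: Mapping, prefix: str = "") -> dict[str, Any]:
    """Flatten nested mappings into dot-separated keys."""
    out: dict[str, Any] = {}
    for key, val in obj.items():
        full = f"{prefix}.{key}" if prefix else str(key)
        if isinstance(val, Mapping):
            out.update(flatten(val, full))
        else:
            out[full] = val
    return out


def compare_to_reference(
    observed: Mapping[str, Any],
    reference: pd.DataFrame | str | Path,
) -> pd.DataFrame:
    """Check observed values against a reference table of expectations.

    ``reference`` has columns id, value, cmp (eq|ge|le), tolerance (used by
    eq).  ``observed`` is a (possibly nested) mapping; nested keys address
    via dots.  Returns a report frame with a boolean ``passed`` column; an
    id absent from ``observed`` raises :class:`ConfigurationError`.
    """
    if not isinstance(reference, pd.DataFrame):
        reference = pd.read_csv(reference, sep="\t", comment="#")
    flat = flatten(dict(observed))
    rows = []
    for row in reference.itertuples(index=False):
        key = str(row.id)
        if key not in flat:
            raise ConfigurationError(f"unknown target id {key!r} (not in observed results)")
        obs = float(flat[key])
        target = float(row.value)
        cmp_op = str(row.cmp)
        tol = float(getattr(row, "tolerance", 0.0) or 0.0)
        if cmp_op == "eq":
            passed = abs(obs - target) <= tol
        elif cmp_op == "ge":
            passed = obs >= target
        elif cmp_op == "le":
            passed = obs <= target
        else:
            raise ConfigurationError(f"unknown comparator {cmp_op!r}")
        rows.append((key, obs, target, cmp_op, tol, bool(passed)))
    return pd.DataFrame(
        rows, columns=["id", "observed", "value", "cmp", "tolerance", "passed"]
    )
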