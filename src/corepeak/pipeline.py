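"""End-to-end pipeline: simulate/load -> concordance -> superset -> widths ->
annotate -> profile -> pause -> enrich, driven by a YAML config.

Every output table is tab-separated and carries a provenance header
(``#``-prefixed lines naming the package version, the inputs and the
parameters that produced it), so results remain traceable. When only peak
tables are provided ("tables-only" mode) the track-dependent stages
(profiles, pausing) are skipped.
"""

from __future__ import annotations

import os

import pandas as pd
import yaml

from . import __version__
from .annotation import annotate_peaks, category_composition, tss_distance_histogram
from .concordance import consensus_peaks, default_rank_grid, max_overlap_cutoff, superset
from .enrichment import class_composition, venn_overlap
from .genome_model import (
    read_binned_track,
    read_peaks,
    read_segmentation,
    read_transcripts,
    write_peaks,
)
from .peak_metrics import proximity_counts, width_histogram, width_stats
from .pausing import pause_deciles, pause_ratios, peak_pause_enrichment
from .signal import meta_profile, upper_quantile_normalize

__all__ = ["ConfigError", "load_config", "run_pipeline"]

_DEFAULT_PARAMS = {
    "rank_grid_points": 50,
    "width_threshold": 2000,
    "hist_bin": 100,
    "cluster_window": 5000,
    "tss_hist_bin": 25,
    "tss_hist_range": 1000,
    "flank": 2000,
    "upper_quantile": 0.95,
    "tss_window": 250,
    "summit_window": 100,
    "deciles": 10,
}


class ConfigError(ValueError):
    """Raised when the pipeline config violates its schema."""


def load_config(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigError("config must be a YAML mapping")
    return validate_config(config)


def validate_config(config: dict) -> dict:
    inputs = config.get("inputs")
    if not isinstance(inputs, dict):
        raise ConfigError("missing or invalid key: inputs (mapping required)")
    missing = [k for k in ("rep_a", "rep_b") if k not in inputs]
    if missing:
        raise ConfigError(f"missing required input keys: {missing}")
    unknown = set(config) - {"inputs", "parameters", "outdir"}
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    params = dict(_DEFAULT_PARAMS)
    user_params = config.get("parameters") or {}
    bad = set(user_params) - set(params)
    if bad:
        raise ConfigError(f"unknown parameter keys: {sorted(bad)}")
    params.update(user_params)
    config = dict(config)
    config["parameters"] = params
    file_keys = ["rep_a", "rep_b"] + list(inputs.get("others", []))
    for key in ("genes", "segmentation", "chrom_sizes"):
        if inputs.get(key):
            file_keys.append(key)
    for key in file_keys:
        path = inputs[key] if key in inputs else key
        if not os.path.exists(path):
            raise ConfigError(f"input file does not exist: {path}")
    for name, path in (inputs.get("tracks") or {}).items():
        if not os.path.exists(path):
            raise ConfigError(f"track file does not exist: {path} ({name})")
    return config


def _provenance(config: dict, stage: str) -> str:
    lines = [f"# corepeak {__version__} :: {stage}"]
    for key, value in sorted(config.get("inputs", {}).items()):
        lines.append(f"# input {key} = {value}")
    for key, value in sorted(config["parameters"].items()):
        lines.append(f"# param {key} = {value}")
    return "\n".join(lines) + "\n"


def _write_table(df: pd.DataFrame, path: str, config: dict, stage: str, **kwargs) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(config, stage))
        df.to_csv(fh, sep="\t", **kwargs)


def _read_chrom_sizes(path: str) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chrom, size = line.split()[:2]
                sizes[chrom] = int(size)
    return sizes


def run_pipeline(config: dict | str | os.PathLike, outdir: str | None = None) -> dict:
    """Run the full workflow described by ``config``; returns a result bundle.

    ``config`` is a validated mapping or the path of a YAML file. Outputs are
    written under ``outdir`` (or ``config["outdir"]``). Deterministic given
    the same inputs and parameters; the bundle maps stage names to in-memory
    results and output paths.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        config = validate_config(config)
    outdir = outdir or config.get("outdir") or "corepeak_results"
    os.makedirs(outdir, exist_ok=True)
    inputs = config["inputs"]
    params = config["parameters"]
    results: dict = {"outdir": outdir, "outputs": []}

    def emit(name: str, df: pd.DataFrame, stage: str, **kwargs) -> None:
        path = os.path.join(outdir, name)
        _write_table(df, path, config, stage, **kwargs)
        results["outputs"].append(path)

    # --- concordance ------------------------------------------------------
    rep_a = read_peaks(inputs["rep_a"], format=inputs.get("format", "narrowPeak"))
    rep_b = read_peaks(inputs["rep_b"], format=inputs.get("format", "narrowPeak"))
    grid = default_rank_grid(len(rep_a), len(rep_b), params["rank_grid_points"])
    curve = max_overlap_cutoff(rep_a, rep_b, grid)
    consensus = consensus_peaks(rep_a, rep_b, curve)
    results["curve"] = curve
    results["consensus"] = consensus
    emit(
        "overlap_curve.tsv",
        pd.DataFrame({"rank": curve.ranks, "percent_overlap": curve.percent}),
        "concordance",
        index=False,
    )
    consensus_path = os.path.join(outdir, "consensus.narrowPeak")
    write_peaks(consensus, consensus_path)
    results["outputs"].append(consensus_path)

    # --- superset ---------------------------------------------------------
    final_peaks = consensus
    others = inputs.get("others") or []
    if others:
        other_lists = [read_peaks(p, format=inputs.get("format", "narrowPeak")) for p in others]
        final_peaks = superset(consensus, other_lists)
        superset_path = os.path.join(outdir, "superset.narrowPeak")
        write_peaks(final_peaks, superset_path)
        results["outputs"].append(superset_path)
    results["final_peaks"] = final_peaks

    # --- widths & clustering ---------------------------------------------
    stats = width_stats(final_peaks, params["width_threshold"])
    results["width_stats"] = stats
    emit(
        "width_stats.tsv",
        pd.DataFrame([stats]),
        "widths",
        index=False,
    )
    hist = width_histogram(final_peaks, params["hist_bin"])
    emit(
        "width_histogram.tsv",
        pd.DataFrame(
            {"width_bin_start": [k * params["hist_bin"] for k in hist], "count": list(hist.values())}
        ),
        "widths",
        index=False,
    )
    prox = proximity_counts(final_peaks, params["cluster_window"])
    emit(
        "proximity_counts.tsv",
        pd.DataFrame({"peak": [p.name for p in final_peaks], "neighbors": prox}),
        "clustering",
        index=False,
    )

    # --- annotation -------------------------------------------------------
    genes = None
    if inputs.get("genes"):
        genes = read_transcripts(inputs["genes"], format=inputs.get("genes_format", "gtf"))
        records = annotate_peaks(final_peaks, genes)
        results["annotation"] = records
        emit(
            "annotation.tsv",
            pd.DataFrame([r.__dict__ for r in records]),
            "annotation",
            index=False,
        )
        composition = category_composition(records)
        results["category_composition"] = composition
        emit(
            "category_composition.tsv",
            pd.DataFrame(
                {"category": list(composition), "percent": list(composition.values())}
            ),
            "annotation",
            index=False,
        )
        tss_hist = tss_distance_histogram(
            final_peaks, genes, params["tss_hist_bin"], params["tss_hist_range"]
        )
        results["tss_histogram"] = tss_hist

    # --- track-dependent stages (skipped in tables-only mode) -------------
    track_paths = inputs.get("tracks") or {}
    if track_paths:
        if not inputs.get("chrom_sizes"):
            raise ConfigError("tracks given but no chrom_sizes file")
        sizes = _read_chrom_sizes(inputs["chrom_sizes"])
        bin_size = int(inputs.get("bin_size", 100))
        tracks = {
            name: read_binned_track(path, bin_size, sizes)
            for name, path in track_paths.items()
        }
        normalized, factors = upper_quantile_normalize(tracks, params["upper_quantile"])
        results["scale_factors"] = factors
        emit(
            "scale_factors.tsv",
            pd.DataFrame({"track": list(factors), "factor": list(factors.values())}),
            "normalization",
            index=False,
        )
        profiles = {}
        for name, track in normalized.items():
            prof = meta_profile(track, final_peaks, params["flank"], strand_source=genes)
            profiles[name] = prof
        results["profiles"] = profiles
        emit(
            "meta_profiles.tsv",
            pd.DataFrame(
                {"offset": next(iter(profiles.values()))["offsets"]}
                | {name: prof["mean"] for name, prof in profiles.items()}
            ),
            "profiles",
            index=False,
        )
        if genes is not None and "rnap2" in normalized:
            records = pause_ratios(
                normalized["rnap2"], genes, tss_window=params["tss_window"]
            )
            deciles = pause_deciles(records, params["deciles"])
            annot = results.get("annotation") or annotate_peaks(final_peaks, genes)
            enrich = peak_pause_enrichment(annot, deciles, params["deciles"])
            results["pause_records"] = records
            results["pause_deciles"] = deciles
            results["pause_enrichment"] = enrich
            emit(
                "pause_ratios.tsv",
                pd.DataFrame(
                    [
                        {
                            "transcript_id": r.transcript_id,
                            "tss_count": r.tss_count,
                            "body_count": r.body_count,
                            "pause_ratio": r.pause_ratio,
                            "usable": r.usable,
                            "decile": deciles.get(r.transcript_id),
                        }
                        for r in records
                    ]
                ),
                "pausing",
                index=False,
            )
            emit(
                "pause_enrichment.tsv",
                pd.DataFrame(
                    {"decile": list(enrich), "percent_of_bound": list(enrich.values())}
                ),
                "pausing",
                index=False,
            )

    # --- chromatin-class enrichment ---------------------------------------
    if inputs.get("segmentation"):
        seg = read_segmentation(inputs["segmentation"])
        composition = class_composition(final_peaks, seg, params["summit_window"])
        results["class_composition"] = composition
        emit("class_composition.tsv", composition, "enrichment")

    # --- replicate venn ----------------------------------------------------
    venn = venn_overlap(rep_a, rep_b)
    results["venn"] = venn
    emit(
        "venn.tsv",
        pd.DataFrame([venn]),
        "venn",
        index=False,
    )
    return results
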