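"""End-to-end pipeline: simulate -> DE -> off-target correction -> CRF ->
group assignment -> BIN enrichment -> external comparison.

A single flat configuration (every threshold a named key, overridable from
the command line) drives all stages; every output table carries a header
comment with the package version, a hash of the configuration and the seed,
and rerunning with the same configuration reproduces all tables
byte-identically.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .background import correct_itps, fit_offtarget_model, flag_shared_degs
from .bins import build_heatmap, zero_filtered_fc
from .compare import per_group_comparison
from .crf import assign_group, compute_crf, flag_context_dependent_panel, group_summary
from .de import run_contrast
from .io import ContrastResult, Thresholds, write_table
from .simulate import simulate_all

__all__ = ["DEFAULT_CONFIG", "load_config", "config_hash", "run_pipeline"]

#: every paper-visible threshold is a named key with its published default
DEFAULT_CONFIG: dict = {
    # simulation
    "n_genes": 2000,
    "seed": 7,
    "effect_scale": 1.0,
    "k_contrasts": 9,
    "timepoints": "4h,6h",
    "n_replicates": 4,
    "depth": 20_000_000,
    "theta": 2.5e-7,
    "panel_noise_sd": 0.15,
    "panel_missing_rate": 0.1,
    "external_mode": "reciprocal",
    "external_noise_sd": 0.1,
    # DEG calling
    "fdr": 0.05,
    "fc": 2.0,          # linear-scale strict fold change (log2 threshold 1)
    "fc_relaxed": 1.1487,  # 2**0.2, i.e. log2 threshold 0.2
    # correction
    "correction_mode": "flag",  # or "residualize"
    # CRF assignment
    "crf_threshold": 0.1,
    "min_obs": 3,
    "responsiveness": "relaxed",
    "assign_timepoint": "4h",
    # enrichment
    "enrich_filter": "strict",
    "compare_filter": "relaxed",
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults, updated from a flat key-value YAML file, then overrides."""
    import yaml

    config = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config file {path} is not a flat key-value mapping")
        unknown = set(user) - set(config)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        config.update(user)
    if overrides:
        config.update({k: v for k, v in overrides.items() if v is not None})
    return config


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _thresholds(config: dict) -> Thresholds:
    import math

    return Thresholds(
        fdr=float(config["fdr"]),
        log2_fc_strict=math.log2(float(config["fc"])),
        log2_fc_relaxed=math.log2(float(config["fc_relaxed"])),
    )


def _timepoints(config: dict) -> tuple[str, ...]:
    tps = config["timepoints"]
    if isinstance(tps, str):
        return tuple(t.strip() for t in tps.split(",") if t.strip())
    return tuple(tps)


def run_pipeline(config: dict, outdir) -> dict:
    """Run every stage on a freshly simulated dataset; write all tables.

    Returns a dict of in-memory results (dataset, contrasts, shared-DEG
    reports, CRF records, heatmap, comparison) for programmatic use.
    Raises before any stage runs if the configuration is incomplete.
    """
    missing = set(DEFAULT_CONFIG) - set(config)
    if missing:
        raise ValueError(f"config missing key(s): {sorted(missing)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = [
        f"crfdecon {__version__}",
        f"config_hash {config_hash(config)}",
        f"seed {config['seed']}",
    ]
    log: list[str] = [f"crfdecon {__version__} config_hash={config_hash(config)}"]
    thresholds = _thresholds(config)
    timepoints = _timepoints(config)

    # --- simulate -----------------------------------------------------------
    data = simulate_all(
        n_genes=int(config["n_genes"]),
        seed=int(config["seed"]),
        effect_scale=float(config["effect_scale"]),
        k_contrasts=int(config["k_contrasts"]),
        timepoints=timepoints,
        n_replicates=int(config["n_replicates"]),
        depth=float(config["depth"]),
        theta=float(config["theta"]),
        panel_noise_sd=float(config["panel_noise_sd"]),
        panel_missing_rate=float(config["panel_missing_rate"]),
        external_mode=str(config["external_mode"]),
        external_noise_sd=float(config["external_noise_sd"]),
    )
    write_table(data.counts.counts, outdir / "counts.tsv", header)
    sheet = data.counts.samples.copy()
    sheet["library_size"] = data.counts.library_sizes
    write_table(sheet, outdir / "samples.tsv", header)
    write_table(data.lengths, outdir / "lengths.tsv", header)
    write_table(data.panel, outdir / "panel.tsv", header)
    write_table(data.binmap, outdir / "binmap.tsv", header)
    write_table(data.external, outdir / "external.tsv", header)
    write_table(data.truth.table, outdir / "truth.tsv", header)
    log.append(f"simulate: {len(data.truth.gene_ids)} genes, "
               f"{data.counts.counts.shape[1]} samples")

    # --- differential expression, per genotype and timepoint ---------------
    contrasts: dict[tuple[str, str], ContrastResult] = {}
    for genotype in ("iTPS", "alcR"):
        for tp in timepoints:
            cr = run_contrast(
                data.counts,
                data.lengths,
                {"genotype": genotype, "treatment": "ethanol", "timepoint": tp},
                {"genotype": genotype, "treatment": "water", "timepoint": tp},
                thresholds=thresholds,
            )
            contrasts[(genotype, tp)] = cr
            write_table(cr, outdir / f"contrast_{genotype}_{tp}.tsv", header)
            log.append(
                f"de {genotype} {tp}: testable={int(cr.table['testable'].sum())} "
                f"strict={len(cr.passing('strict'))} relaxed={len(cr.passing('relaxed'))}"
            )

    # --- off-target correction ---------------------------------------------
    excluded: set[str] = set()
    for tp in timepoints:
        itps_cr, alcr_cr = contrasts[("iTPS", tp)], contrasts[("alcR", tp)]
        report = flag_shared_degs(itps_cr, alcr_cr)
        write_table(report.table, outdir / f"shared_degs_{tp}.tsv", header)
        log.append(
            f"correct {tp}: shared={report.n_shared} "
            f"same_direction={report.n_same_direction} excluded={len(report.excluded)}"
        )
        excluded |= set(report.excluded)
        if config["correction_mode"] == "residualize":
            model = fit_offtarget_model(itps_cr.log2_fc, alcr_cr.log2_fc)
            corrected = correct_itps(itps_cr.log2_fc, alcr_cr.log2_fc, model)
            write_table(corrected, outdir / f"corrected_{tp}.tsv", header)
            log.append(f"residualize {tp}: beta={model.beta:.4g} r2={model.r_squared:.4g}")

    def drop_excluded(cr: ContrastResult) -> ContrastResult:
        keep = ~cr.table.index.isin(sorted(excluded))
        return ContrastResult(table=cr.table.loc[keep].copy(), thresholds=cr.thresholds)

    # --- CRF and group assignment ------------------------------------------
    crf_table = compute_crf(data.panel, min_obs=int(config["min_obs"]))
    crf_table["context_dependent"] = flag_context_dependent_panel(
        data.panel, thr=float(config["effect_scale"]) / 2.0
    )
    write_table(crf_table, outdir / "crf.tsv", header)

    assign_tp = str(config["assign_timepoint"])
    if assign_tp not in timepoints:
        raise ValueError(f"assign_timepoint {assign_tp!r} not among timepoints {timepoints}")
    itps_main = drop_excluded(contrasts[("iTPS", assign_tp)])
    records = assign_group(
        itps_main,
        crf_table,
        responsiveness=str(config["responsiveness"]),
        crf_threshold=float(config["crf_threshold"]),
    )
    records["context_dependent"] = crf_table["context_dependent"].reindex(
        records.index, fill_value=False
    )
    write_table(records, outdir / "groups.tsv", header)
    summary = group_summary(records)
    write_table(summary, outdir / "group_summary.tsv", header)
    log.append(
        "assign: " + " ".join(f"{g}={int(summary.loc[g, 'count'])}" for g in summary.index)
    )

    # --- BIN enrichment heatmap --------------------------------------------
    display = [
        (tp, zero_filtered_fc(drop_excluded(contrasts[("iTPS", tp)]),
                              filter=str(config["enrich_filter"])))
        for tp in timepoints
    ]
    heatmap = build_heatmap(display, records, data.binmap)
    flat = heatmap.copy()
    flat.columns = [f"{g}:{c}" for g, c in heatmap.columns]
    write_table(flat, outdir / "bin_heatmap.tsv", header)
    log.append(f"enrich: {heatmap.shape[0]} BINs x {heatmap.shape[1]} columns")

    # --- external comparison ------------------------------------------------
    comparison = per_group_comparison(
        itps_main, data.external, records, filter=str(config["compare_filter"])
    )
    write_table(comparison, outdir / "comparison.tsv", header)
    log.append("compare: " + " ".join(
        f"{s}(n={int(comparison.loc[s, 'n_genes'])})" for s in comparison.index
    ))

    (outdir / "pipeline.log").write_text("\n".join(log) + "\n", encoding="utf-8")
    return {
        "data": data,
        "contrasts": contrasts,
        "excluded": excluded,
        "crf": crf_table,
        "records": records,
        "summary": summary,
        "heatmap": heatmap,
        "comparison": comparison,
    }
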