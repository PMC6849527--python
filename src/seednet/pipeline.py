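"""Orchestration of the full analysis: classify -> prune -> metrics ->
null models -> coextinction -> paired comparisons.

Every stage derives its random seeds deterministically from the master
seed, so a rerun with the same configuration is bit-identical.  Outputs
are tidy CSV tables plus a JSON run log recording every seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import coextinction as coext
from . import compare
from . import network_metrics as nm
from . import null_models as nulls
from . import species_metrics as sm
from .network import LabeledNetwork, normalize_prune_mode, prune, read_edge_list
from .synthetic import SyntheticConfig, generate_ensemble, write_manifest

STATE_OF_MODE = {"all_nonmutualistic": "pruned_all", "predation_only": "pruned_predation"}


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    input_path: str | None = None
    synthetic: SyntheticConfig | None = None
    prune_modes: tuple[str, ...] = ("all_nonmutualistic",)
    null_models: tuple[str, ...] = ("patefield", "quasiswap_count")
    n_null: int = 1000
    threshold: float = 0.75
    lpa_repeats: int = 1
    seed: int | None = None
    out_dir: str = "seednet_out"

    def validate(self) -> None:
        if (self.input_path is None) == (self.synthetic is None):
            raise ValueError("provide exactly one of input_path or synthetic config")
        if not self.prune_modes:
            raise ValueError("at least one prune mode is required")
        if self.n_null < 1:
            raise ValueError("null ensemble size must be >= 1")


def _network_metric_row(net, state: str, seed, lpa_repeats: int) -> dict:
    _, q = nm.lpawb_plus(net, seed=seed, repeats=lpa_repeats)
    return {
        "network_id": net.network_id,
        "state": state,
        "size": nm.network_size(net),
        "weighted_connectance": nm.weighted_connectance(net),
        "wnodf": nm.weighted_nodf(net),
        "h2_prime": nm.h2_prime(net),
        "modularity_q": q,
        "seed": seed,
    }


def network_metric_report(net: LabeledNetwork, state: str, seed=None,
                          lpa_repeats: int = 1,
                          threshold: float = 0.75) -> dict:
    """All network-level metrics (including robustness) for one state."""
    row = _network_metric_row(net, state, seed, lpa_repeats)
    result = coext.simulate_coextinction(net, threshold=threshold)
    row["robustness"] = coext.robustness(result)
    return row


def _delta_rows(net, state, model, n_null, seed, lpa_repeats, threshold):
    ss = np.random.SeedSequence(seed)
    ens_seed, lpa_master = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2)]
    ensemble = nulls.generate_null_ensemble(net, model=model, n_samples=n_null,
                                           seed=ens_seed)
    lpa_seeds = iter(np.random.SeedSequence(lpa_master).spawn(n_null + 1))

    def modularity_metric(x):
        child = next(lpa_seeds)
        _, q = nm.lpawb_plus(x, seed=int(child.generate_state(1)[0] % (2**31)),
                             repeats=lpa_repeats)
        return q

    def robustness_metric(x):
        return coext.robustness(coext.simulate_coextinction(x, threshold=threshold))

    metrics = [
        (nm.weighted_connectance, "weighted_connectance"),
        (nm.weighted_nodf, "wnodf"),
        (nm.h2_prime, "h2_prime"),
        (modularity_metric, "modularity_q"),
        (robustness_metric, "robustness"),
    ]
    rows = []
    for fn, name in metrics:
        dm = nulls.delta_transform(fn, net, ensemble, name=name)
        rows.append(
            {
                "network_id": net.network_id,
                "state": state,
                "model": model,
                "metric": name,
                "observed": dm.observed,
                "null_mean": dm.null_mean,
                "delta": dm.delta,
                "n_samples": dm.n_samples,
                "n_skipped": dm.n_skipped,
                "seed": ens_seed,
            }
        )
    return rows


def _curve_rows(net, state, threshold):
    result = coext.simulate_coextinction(net, threshold=threshold)
    rows = [
        {
            "network_id": net.network_id,
            "state": state,
            "step": k,
            "birds_removed_fraction": x,
            "plants_surviving_fraction": y,
        }
        for k, (x, y) in enumerate(result.curve)
    ]
    return rows, result


def run_analysis(config: RunConfig) -> Path:
    """Run the complete pipeline and write all tables under ``out_dir``."""
    config.validate()
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": config.seed, "stages": {}}

    if config.synthetic is not None:
        syn = config.synthetic
        if syn.seed is None:
            syn = SyntheticConfig(**{**syn.__dict__, "seed": config.seed})
        nets, manifest = generate_ensemble(syn)
        write_manifest(manifest, out / "synthetic_manifest.json")
    else:
        nets = read_edge_list(config.input_path)
    log["networks"] = list(nets)

    modes = [normalize_prune_mode(m) for m in config.prune_modes]
    states: dict[str, dict[str, LabeledNetwork]] = {"original": dict(nets)}
    prune_info = []
    for mode in modes:
        state = STATE_OF_MODE[mode]
        states[state] = {}
        for nid, net in nets.items():
            res = prune(net, mode)
            states[state][nid] = res.pruned
            prune_info.append(
                {
                    "network_id": nid,
                    "mode": mode,
                    "removed_links": res.removed_links,
                    "removed_frequency": res.removed_frequency,
                    "dropped_plants": len(res.dropped_plants),
                    "dropped_birds": len(res.dropped_birds),
                }
            )
    pd.DataFrame(prune_info).to_csv(out / "prune_summary.csv", index=False)

    # deterministic per-(network, state) seed stream (stable across runs)
    def derived_seed(*parts) -> int:
        key = "|".join(str(p) for p in ("seednet", config.seed) + parts)
        digest = hashlib.sha256(key.encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)

    # network metrics -----------------------------------------------------
    t = time.time()
    net_rows = []
    curve_rows = []
    for state, group in states.items():
        for nid, net in group.items():
            seed = derived_seed("lpa", state, nid)
            row = _network_metric_row(net, state, seed, config.lpa_repeats)
            curves, result = _curve_rows(net, state, config.threshold)
            row["robustness"] = coext.robustness(result)
            net_rows.append(row)
            curve_rows.extend(curves)
    wide = pd.DataFrame(net_rows)
    tidy = wide.melt(
        id_vars=["network_id", "state", "seed"],
        value_vars=["size", "weighted_connectance", "wnodf", "h2_prime",
                    "modularity_q", "robustness"],
        var_name="metric",
        value_name="value",
    )
    tidy.to_csv(out / "network_metrics.csv", index=False)
    pd.DataFrame(curve_rows).to_csv(out / "coextinction_curves.csv", index=False)
    log["stages"]["network_metrics_s"] = round(time.time() - t, 3)

    # species metrics ------------------------------------------------------
    t = time.time()
    sp_frames = []
    for state, group in states.items():
        for nid, net in group.items():
            rep = sm.species_report(net, state=state)
            result = coext.simulate_coextinction(net, threshold=config.threshold)
            res_tab = coext.resilience_table(result)
            rep["resilience_75"] = [
                res_tab.get(s, float("nan")) if g == "plant" else float("nan")
                for s, g in zip(rep["species"], rep["guild"])
            ]
            sp_frames.append(rep)
    species_wide = pd.concat(sp_frames, ignore_index=True)
    species_tidy = species_wide.melt(
        id_vars=["network_id", "state", "guild", "species"],
        value_vars=["degree", "frequency", "d_prime", "strength", "resilience_75"],
        var_name="metric",
        value_name="value",
    )
    species_tidy.to_csv(out / "species_metrics.csv", index=False)
    log["stages"]["species_metrics_s"] = round(time.time() - t, 3)

    # null models ----------------------------------------------------------
    t = time.time()
    delta_rows = []
    for model in config.null_models:
        for state, group in states.items():
            for nid, net in group.items():
                delta_rows.extend(
                    _delta_rows(net, state, model, config.n_null,
                                derived_seed("null", model, state, nid),
                                config.lpa_repeats, config.threshold)
                )
    pd.DataFrame(delta_rows).to_csv(out / "delta_metrics.csv", index=False)
    log["stages"]["null_models_s"] = round(time.time() - t, 3)

    # comparisons ----------------------------------------------------------
    t = time.time()
    for mode in modes:
        after_state = STATE_OF_MODE[mode]
        if len(nets) >= 3:
            tables = compare.build_comparison_tables(
                tidy, species_tidy, before_state="original", after_state=after_state
            )
            suffix = "" if after_state == "pruned_all" else "_predation"
            tables["network_level"].to_csv(
                out / f"network_level_changes{suffix}.csv", index=False)
            tables["species_level"].to_csv(
                out / f"species_level_changes{suffix}.csv", index=False)
            tables["per_network"].to_csv(
                out / f"per_network_significance{suffix}.csv", index=False)
            tables["moran"].to_csv(out / f"moran_summary{suffix}.csv", index=False)
    log["stages"]["comparisons_s"] = round(time.time() - t, 3)

    log["total_s"] = round(time.time() - t0, 3)
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True, default=str)
    return out
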