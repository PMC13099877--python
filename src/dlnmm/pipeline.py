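"""End-to-end orchestration: simulate -> screen -> fit -> score -> effects.

One invocation handles one climatic region (a set of subregions sharing
exposure dynamics).  The run directory it produces contains, as CSV/JSON:

* the exposure and count panels used,
* the per-exposure lag-screen table and selected maximum lags,
* each candidate family's fit summary (convergence, llf, AIC/BIC),
* the metric + composite-score table over all candidates,
* percentile-contrast IRR tables from the top-ranked model,
* a manifest tying every artifact to the configuration hash.

Candidate models default to the eight-family roster: plain GLMs (no
lagged/nonlinear terms) with Poisson/NegBin kernels and random
intercepts, and DLNM variants with ZIP/ZINB kernels without random
intercepts plus all four kernels with random intercepts.  A family that
fails to fit is recorded in the manifest and the run continues.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import selection
from .basis import CrossBasisSpec
from .model import DLNMCountModel
from .screening import select_max_lag
from .simulate import (
    EXPOSURE_NAMES,
    SimConfig,
    default_crossbasis_specs,
    default_truth,
    simulate_counts,
    simulate_exposures,
)

log = logging.getLogger("dlnmm.pipeline")

#: the candidate model roster; name -> (family, random intercept, DLNM terms)
MODEL_ROSTER = {
    "GLM-Poisson_rf": ("poisson", True, False),
    "GLM-NegBin_rf": ("negbin", True, False),
    "DLNM-ZIP": ("zip", False, True),
    "DLNM-ZINBI": ("zinb", False, True),
    "DLNM-Poisson_rf": ("poisson", True, True),
    "DLNM-NegBin_rf": ("negbin", True, True),
    "DLNM-ZIP_rf": ("zip", True, True),
    "DLNM-ZINBI_rf": ("zinb", True, True),
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run (one region)."""

    output_dir: str = "dlnmm_run"
    seed: int = 0
    # inputs: either paths to CSV panels or a simulation config
    counts_path: str | None = None
    exposures_path: str | None = None
    sim: SimConfig | dict | None = None
    # analysis settings
    candidates: tuple = tuple(MODEL_ROSTER)
    alpha: float = 0.05
    scan_bound: int = 14
    n_perm: int = 199
    exposure_df: int = 3
    lag_df: int = 3
    n_quad: int = 15
    exposures: tuple = EXPOSURE_NAMES

    def __post_init__(self):
        if not self.candidates:
            raise ValueError("candidate list must be non-empty")
        unknown = [c for c in self.candidates if c not in MODEL_ROSTER]
        if unknown:
            raise ValueError(f"unknown candidate models: {unknown}")
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        if self.sim is None and (self.counts_path is None or self.exposures_path is None):
            self.sim = SimConfig(seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest (also written to disk)."""
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "artifacts": {},
        "failures": {},
    }

    def save(df: pd.DataFrame, name: str):
        path = out / name
        df.to_csv(path, index=False)
        manifest["artifacts"][name] = str(path)

    # -- stage 1: inputs ------------------------------------------------
    if config.counts_path and config.exposures_path:
        log.info("loading panels from %s / %s", config.counts_path, config.exposures_path)
        counts = pd.read_csv(config.counts_path)
        exposures = pd.read_csv(config.exposures_path)
    else:
        log.info("simulating panels (seed=%d)", config.sim.seed)
        exposures = simulate_exposures(config.sim)
        specs0 = default_crossbasis_specs(
            exposures,
            max_lags={n: config.scan_bound for n in config.exposures},
            exposure_df=config.exposure_df,
            lag_df=config.lag_df,
            names=config.exposures,
        )
        truth = default_truth(specs0, exposures,
                              n_subregions=config.sim.n_subregions,
                              seed=config.sim.seed)
        counts = simulate_counts(exposures, truth, specs0, seed=config.sim.seed + 1)
        (out / "truth.json").write_text(json.dumps(truth.to_dict(), indent=1))
        manifest["artifacts"]["truth.json"] = str(out / "truth.json")
    save(exposures, "exposures.csv")
    save(counts, "counts.csv")

    # -- stage 2: lag screening (region-aggregated series) ---------------
    agg_y = counts.groupby("week")["count"].sum()
    agg_x = exposures.groupby("week")[list(config.exposures)].mean()
    common = agg_y.index.intersection(agg_x.index)
    selected: dict[str, int] = {}
    for name in config.exposures:
        L = select_max_lag(
            agg_x.loc[common, name].to_numpy(),
            agg_y.loc[common].to_numpy(),
            scan_bound=config.scan_bound,
            alpha=config.alpha,
            n_perm=config.n_perm,
            seed=config.seed,
        )
        selected[name] = L
        log.info("selected max lag for %s: L=%d", name, L)
    (out / "selected_lags.json").write_text(json.dumps(selected, indent=1))
    manifest["artifacts"]["selected_lags.json"] = str(out / "selected_lags.json")

    # -- stage 3: cross-basis specs --------------------------------------
    specs = default_crossbasis_specs(
        exposures, max_lags=selected,
        exposure_df=config.exposure_df, lag_df=config.lag_df,
        names=config.exposures,
    )
    (out / "crossbasis_specs.json").write_text(
        json.dumps({s.name: s.to_dict() for s in specs}, indent=1)
    )
    manifest["artifacts"]["crossbasis_specs.json"] = str(out / "crossbasis_specs.json")

    # Burn-in must match the largest selected lag: drop early count weeks.
    max_lag = max((s.max_lag for s in specs), default=0)
    exp_first = exposures.groupby("subregion")["week"].min()
    need = counts["subregion"].map(exp_first) + max_lag
    counts_fit = counts[counts["week"] >= need].copy()

    # -- stage 4: fit candidates -----------------------------------------
    rows = []
    fits = {}
    for name in config.candidates:
        family, rand_int, dlnm = MODEL_ROSTER[name]
        log.info("fitting %s", name)
        try:
            model = DLNMCountModel.from_panels(
                counts_fit,
                exposures,
                specs=specs if dlnm else None,
                exposure_columns=None if dlnm else list(config.exposures),
                family=family,
                random_intercept=rand_int,
                n_quad=config.n_quad,
            )
            res = model.fit()
            fits[name] = res
            acc = selection.accuracy_metrics(model.y, res.fittedvalues)
            rows.append(
                {
                    "model": name,
                    "mae": acc["mae"],
                    "rmse": acc["rmse"],
                    "aic": res.aic,
                    "bic": res.bic,
                    "llf": res.llf,
                    "converged": res.converged,
                }
            )
            (out / f"fit_{name}.json").write_text(json.dumps(res.to_dict()))
            manifest["artifacts"][f"fit_{name}.json"] = str(out / f"fit_{name}.json")
        except Exception as exc:  # record and continue
            log.warning("fit failed for %s: %s", name, exc)
            manifest["failures"][name] = str(exc)

    if not rows:
        raise RuntimeError("every candidate model failed to fit")
    metric_table = pd.DataFrame(rows)

    # -- stage 5: composite scoring ---------------------------------------
    scored = selection.composite_scores(metric_table)
    if len(scored) >= 3:
        manifest["score_sensitivity_r"] = selection.score_sensitivity(scored)
    save(scored, "score_table.csv")

    # -- stage 6: effect summaries from the top-ranked model ---------------
    best_name = scored.loc[scored["minmax_score"].idxmax(), "model"]
    manifest["best_model"] = str(best_name)
    best = fits[best_name]
    if MODEL_ROSTER[best_name][2]:  # effects need cross-basis terms
        contrasts = []
        for s in specs:
            contrasts.append(best.percentile_contrasts(s.name))
            surf = best.rr_surface(s.name)
            save(surf.to_frame(), f"rr_surface_{s.name}.csv")
        save(pd.concat(contrasts, ignore_index=True), "cumulative_irr.csv")

    manifest["runtime_s"] = round(time.time() - t0, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
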