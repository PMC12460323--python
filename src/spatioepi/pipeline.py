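"""End-to-end orchestration of the four-stage analysis workflow.

Stage order mirrors the analytical framework of state-level incidence
studies: (1) global clustering (Moran's I per year and per multi-year
window), (2) local hot/cold spots (Gi* per window with a persistence
summary), (3) GeoDetector factor, interaction, and sensitivity analysis,
(4) GTNNWR spatiotemporal regression metrics and coefficient summaries.
Each stage writes delimited tables and a JSON summary into the output
directory; a manifest records every artifact.  Identical seeds reproduce
byte-identical numeric tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import autocorr, geodetector
from .gtnnwr import GTNNWRConfig, GTNNWRModel
from .panel import PanelDataset, bin_years, read_panel
from .weights import SpatialWeights, read_weights

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "moran_series"]


@dataclass
class PipelineConfig:
    panel: str = ""
    weights: str = ""
    output_dir: str = "spatioepi_output"
    columns: dict = field(default_factory=dict)  # role -> column name mapping
    exclude_units: list = field(default_factory=list)
    bin_width: int = 5
    moran: dict = field(default_factory=dict)  # significance_z, variance, permutations
    gistar: dict = field(default_factory=dict)  # row_standardized
    geodetector: dict = field(default_factory=dict)  # factors, alpha, class_range,
    #   methods, sensitivity: {perturb_fraction, n_replicates}, interactions: bool
    gtnnwr: dict = field(default_factory=dict)  # enabled, epochs, swnn_hidden, ...
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def moran_series(panel: PanelDataset, W: SpatialWeights, per: str = "bin",
                 bin_width: int = 5, **moran_opts) -> pd.DataFrame:
    """Moran's I per year or per multi-year window, with the peak flagged."""
    if per == "year":
        sections = [panel.outcome_section(int(y)) for y in panel.years]
    elif per == "bin":
        sections = bin_years(panel, bin_width)
    else:
        raise ValueError("per must be 'year' or 'bin'")
    if len(sections) < 2:
        raise ValueError("need at least 2 time points")
    rows = []
    for sec in sections:
        r = autocorr.global_morans_i(sec, W, **moran_opts)
        rows.append(
            {"window": sec.label, "I": r.I, "z": r.z, "p": r.p_analytic,
             "significant": r.significant}
        )
    out = pd.DataFrame(rows)
    out["peak"] = out["I"] == out["I"].max()
    return out


def _write(df: pd.DataFrame, path: Path, manifest: list) -> None:
    df.to_csv(path, index=False, float_format="%.10g")
    manifest.append(path.name)


def run_pipeline(config: PipelineConfig, panel: PanelDataset | None = None,
                 W: SpatialWeights | None = None) -> dict:
    """Run all enabled stages; returns a dict of in-memory stage results.

    ``panel``/``W`` may be passed directly (e.g., fresh synthetic data);
    otherwise they are read from the configured paths.  A stage failure
    aborts with a stage-named diagnostic, leaving earlier outputs on disk.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("spatioepi")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    manifest: list[str] = ["run.log"]
    results: dict = {}
    try:
        if panel is None:
            cfg_cols = dict(config.columns)
            if config.exclude_units:
                cfg_cols["exclude_units"] = config.exclude_units
            panel = read_panel(config.panel, cfg_cols)
        if W is None:
            W = read_weights(config.weights)
        W = W.subset(panel.unit_ids)
        logger.info("panel: %d records, %d units", panel.n_records, len(panel.unit_ids))

        # -- stage 1: global clustering ---------------------------------
        try:
            mo = dict(config.moran)
            n_perm = mo.pop("permutations", 0)
            yearly = moran_series(panel, W, per="year", **mo)
            binned = moran_series(panel, W, per="bin", bin_width=config.bin_width, **mo)
            if n_perm:
                pp = []
                for sec in bin_years(panel, config.bin_width):
                    pp.append(autocorr.morans_permutation(sec, W, n_perm, config.seed))
                binned["p_perm"] = pp
            _write(yearly, out / "moran_yearly.csv", manifest)
            _write(binned, out / "moran_windows.csv", manifest)
            results["moran"] = {"yearly": yearly, "windows": binned}
            logger.info("moran stage done; peak window %s",
                        yearly.loc[yearly["peak"], "window"].iloc[0])
        except Exception as e:
            raise RuntimeError(f"stage 'moran' failed: {e}") from e

        # -- stage 2: hot spots ------------------------------------------
        try:
            gs_opts = dict(config.gistar)
            sections = bin_years(panel, config.bin_width)
            gi = [autocorr.getis_ord_gistar(sec, W, **gs_opts) for sec in sections]
            per_window = pd.concat(
                [g.as_frame().assign(window=g.label) for g in gi], ignore_index=True
            )
            persistence = autocorr.hotspot_persistence(gi).reset_index()
            _write(per_window, out / "gistar_windows.csv", manifest)
            _write(persistence, out / "gistar_persistence.csv", manifest)
            results["gistar"] = {"windows": per_window, "persistence": persistence}
            logger.info("gistar stage done")
        except Exception as e:
            raise RuntimeError(f"stage 'gistar' failed: {e}") from e

        # -- stage 3: geodetector ----------------------------------------
        try:
            gd = dict(config.geodetector)
            factors = gd.get("factors") or panel.covariate_names
            alpha = gd.get("alpha", 0.05)
            class_range = tuple(gd.get("class_range", (3, 8)))
            screen = geodetector.factor_screen(
                panel, factors, alpha, bin_width=config.bin_width,
                class_range=class_range,
            )
            _write(screen, out / "geodetector_factors.csv", manifest)
            results["geodetector"] = {"factors": screen}
            if gd.get("interactions", True):
                qmat, cats = geodetector.interaction_matrix(
                    panel, factors, class_range=class_range
                )
                qmat.to_csv(out / "geodetector_interaction_matrix.csv",
                            float_format="%.10g")
                manifest.append("geodetector_interaction_matrix.csv")
                _write(cats, out / "geodetector_interactions.csv", manifest)
                results["geodetector"]["interactions"] = cats
            sens_cfg = gd.get("sensitivity", {})
            sens = geodetector.sensitivity_analysis(
                panel, factors,
                perturb_fraction=sens_cfg.get("perturb_fraction", 0.10),
                n_replicates=sens_cfg.get("n_replicates", 20),
                seed=config.seed, class_range=class_range,
            )
            sens_df = pd.DataFrame(
                {"factor": list(sens.per_factor), "dq_over_q": list(sens.per_factor.values())}
            )
            _write(sens_df, out / "geodetector_sensitivity.csv", manifest)
            results["geodetector"]["sensitivity"] = sens
            logger.info(
                "geodetector stage done; mean dq/q %.4f (%s the 10%% threshold)",
                sens.mean_rel_change, "below" if sens.stable else "ABOVE",
            )
        except Exception as e:
            raise RuntimeError(f"stage 'geodetector' failed: {e}") from e

        # -- stage 4: gtnnwr ---------------------------------------------
        gt = dict(config.gtnnwr)
        if gt.pop("enabled", True):
            try:
                known = {f.name for f in dataclasses.fields(GTNNWRConfig)}
                desk = gt.pop("desk_scale", True)
                opts = {k: v for k, v in gt.items() if k in known}
                bad = set(gt) - known
                if bad:
                    raise ValueError(f"unknown gtnnwr options: {sorted(bad)}")
                cfg = (GTNNWRConfig.desk_scale(**opts) if desk else GTNNWRConfig(**opts))
                model = GTNNWRModel(cfg).fit(panel)
                metrics = model.metrics_report()
                with open(out / "gtnnwr_metrics.json", "w") as fh:
                    json.dump(metrics, fh, indent=2)
                manifest.append("gtnnwr_metrics.json")
                surf = model.extract_coefficients()
                _write(surf.as_frame(), out / "gtnnwr_coefficients.csv", manifest)
                imp = surf.yearly_importance().reset_index()
                _write(imp, out / "gtnnwr_yearly_importance.csv", manifest)
                results["gtnnwr"] = {"model": model, "metrics": metrics, "surface": surf}
                logger.info("gtnnwr stage done; test R2 %.4f",
                            metrics.get("test", {}).get("r2", float("nan")))
            except Exception as e:
                raise RuntimeError(f"stage 'gtnnwr' failed: {e}") from e

        with open(out / "manifest.json", "w") as fh:
            json.dump({"artifacts": sorted(manifest), "seed": config.seed}, fh, indent=2)
        results["manifest"] = sorted(manifest)
        return results
    finally:
        root.removeHandler(handler)
        handler.close()
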