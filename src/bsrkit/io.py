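"""Readers/writers for the observation CSV schema, run configuration and reports.

Observation files are long-format CSV with the documented header
``reactor_id,hrt_h,position_L,species,conc_mg_per_L`` (UTF-8, "." decimal);
one row per species per sample point. Concentrations are mg/L at the I/O
boundary, times in hours (HRTs may be supplied in days in the config, with
an explicit unit). The run configuration is YAML validated against a strict
schema: unknown keys are rejected with their location.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Literal

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .kinetics import FitOptions, KineticFit, ReactorGeometry, SteadyStateObservation
from .predictions import PredictionResult

__all__ = [
    "OBSERVATION_COLUMNS",
    "SALT_TO_ANION",
    "RunConfig",
    "SchemaError",
    "load_config",
    "read_observations",
    "write_observations",
    "report",
]

logger = logging.getLogger("bsrkit")

OBSERVATION_COLUMNS = ("reactor_id", "hrt_h", "position_L", "species", "conc_mg_per_L")

#: Feed salts → (anion id, salt molar mass g/mol, anion molar mass g/mol).
#: Salt dosing (g/L) is converted to anion concentration (mg/L) at load time.
SALT_TO_ANION = {
    "sodium_acetate": ("acetate", 82.03, 59.04),
    "sodium_lactate": ("lactate", 112.06, 89.07),
    "sodium_citrate": ("citrate", 258.07, 189.10),
    "sodium_sulfate": ("sulfate", 142.04, 96.06),
}


class SchemaError(ValueError):
    """A file failed schema validation (wrong columns, bad config keys)."""


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_StrictModel):
    id: str
    kind: Literal["plug_flow", "cstr", "channel"]
    total_volume_L: float = Field(gt=0)
    zone_boundaries_L: list[float]

    def build(self) -> ReactorGeometry:
        return ReactorGeometry(
            reactor_id=self.id,
            kind=self.kind,
            total_volume=self.total_volume_L,
            zone_boundaries=tuple(self.zone_boundaries_L),
        )


class FeedConfig(_StrictModel):
    salts_g_per_L: dict[str, float] = Field(default_factory=dict)
    species_mg_per_L: dict[str, float] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _known_salts(self) -> "FeedConfig":
        unknown = set(self.salts_g_per_L) - set(SALT_TO_ANION)
        if unknown:
            raise ValueError(
                f"feed.salts_g_per_L: unknown salts {sorted(unknown)}; "
                f"known: {sorted(SALT_TO_ANION)}"
            )
        return self

    def anion_mg_per_L(self) -> dict[str, float]:
        """Feed composition as anion mg/L (salt doses converted, then overrides)."""
        feed: dict[str, float] = {}
        for salt, grams in self.salts_g_per_L.items():
            anion, salt_mw, anion_mw = SALT_TO_ANION[salt]
            feed[anion] = feed.get(anion, 0.0) + grams / salt_mw * anion_mw * 1000.0
        feed.update(self.species_mg_per_L)
        return feed


class FitConfig(_StrictModel):
    objective: Literal["conc", "rate"] = "conc"
    n_bounds: tuple[float, float] = (0.1, 5.0)
    extra_k_starts: int = 0

    def build(self) -> FitOptions:
        return FitOptions(
            objective=self.objective,
            n_bounds=self.n_bounds,
            extra_k_starts=self.extra_k_starts,
        )


class RunConfig(_StrictModel):
    """Validated run configuration (geometry, feed, regime, fit options)."""

    reactor: GeometryConfig
    feed: FeedConfig = Field(default_factory=FeedConfig)
    regime: Literal["acetate", "lactate"] = "lactate"
    ye_acetate_mg_per_L: float = Field(default=0.0, ge=0)
    hrt_unit: Literal["h", "d"] = "h"
    fit: FitConfig = Field(default_factory=FitConfig)
    seed: int = 0
    log_level: str = "INFO"


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        locs = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        )
        raise SchemaError(f"{path}: invalid configuration — {locs}") from exc


def read_observations(
    path: str | Path,
    geometry: ReactorGeometry | None = None,
    feed: dict[str, float] | None = None,
    hrt_unit: str = "h",
) -> list[SteadyStateObservation]:
    """Parse a long-format observation CSV into typed records.

    Rows are grouped by (reactor, HRT, position) into one observation each.
    Malformed rows are reported with their line numbers; when a geometry is
    supplied, flow rates are derived from HRT and the F × HRT = V invariant
    is checked at load.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(OBSERVATION_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required columns {sorted(missing)}")
    errors = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            conc = float(row["conc_mg_per_L"])
        except (TypeError, ValueError):
            errors.append(f"line {line}: conc_mg_per_L {row['conc_mg_per_L']!r} is not a number")
            continue
        if conc < 0:
            errors.append(f"line {line}: negative concentration {conc}")
        if float(row["hrt_h"]) <= 0 or float(row["position_L"]) <= 0:
            errors.append(f"line {line}: hrt_h and position_L must be positive")
    if errors:
        raise SchemaError(f"{path}: " + "; ".join(errors))

    hrt_factor = 24.0 if hrt_unit == "d" else 1.0
    observations = []
    for (reactor_id, hrt, position), group in df.groupby(
        ["reactor_id", "hrt_h", "position_L"], sort=True
    ):
        hrt_h = float(hrt) * hrt_factor
        total_volume = geometry.total_volume if geometry else float(position)
        flow = total_volume / hrt_h
        obs = SteadyStateObservation(
            reactor_id=str(reactor_id),
            hrt=hrt_h,
            flow_rate=flow,
            position=float(position),
            concentrations=dict(zip(group["species"], group["conc_mg_per_L"].astype(float))),
            feed=dict(feed or {}),
        )
        if geometry is not None:
            obs.check_flow_consistency(geometry.total_volume)
        observations.append(obs)
    logger.info("read %d observations from %s", len(observations), path)
    return observations


def write_observations(observations: list[SteadyStateObservation], path: str | Path) -> None:
    """Write observations in the long CSV schema (deterministic ordering)."""
    rows = [
        {
            "reactor_id": o.reactor_id,
            "hrt_h": o.hrt,
            "position_L": o.position,
            "species": sp,
            "conc_mg_per_L": conc,
        }
        for o in observations
        for sp, conc in sorted(o.concentrations.items())
    ]
    df = pd.DataFrame(rows, columns=list(OBSERVATION_COLUMNS))
    df = df.sort_values(["reactor_id", "hrt_h", "position_L", "species"], kind="mergesort")
    df.to_csv(path, index=False, float_format="%.6f")


def _fit_to_dict(fit: KineticFit) -> dict:
    d = dataclasses.asdict(fit)
    d["residuals"] = [float(r) for r in fit.residuals]
    d["clipped_observations"] = list(fit.clipped_observations)
    return d


def report(
    fit: KineticFit | None,
    predictions: list[PredictionResult],
    out_dir: str | Path,
    plots: bool = False,
) -> list[Path]:
    """Write deterministic fit/prediction tables (and optional plots).

    Produces ``fit.json`` + ``fit_residuals.csv`` when a fit is given and
    ``predictions.csv`` when predictions are given; returns the paths
    written. Plots are clearly derived artifacts, off by default.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if fit is not None:
        fit_path = out_dir / "fit.json"
        fit_path.write_text(json.dumps(_fit_to_dict(fit), indent=2, sort_keys=True) + "\n")
        written.append(fit_path)
        res_path = out_dir / "fit_residuals.csv"
        pd.DataFrame({"residual_mg_per_L": fit.residuals}).to_csv(
            res_path, index_label="observation", float_format="%.6g"
        )
        written.append(res_path)
    if predictions:
        pred_path = out_dir / "predictions.csv"
        rows = [
            {
                "species": p.species,
                "observed_mg_per_L": p.observed,
                "predicted_mg_per_L": p.predicted,
                "percent_difference": p.percent_diff,
                "basis": p.basis,
                "model_violation": p.model_violation,
                "components": json.dumps(p.components, sort_keys=True),
            }
            for p in predictions
        ]
        pd.DataFrame(rows).to_csv(pred_path, index=False, float_format="%.6f")
        written.append(pred_path)
    if plots and fit is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        ax.plot(fit.residuals, "o")
        ax.axhline(0.0, color="k", lw=0.8)
        ax.set_xlabel("observation")
        ax.set_ylabel("residual (mg/L)")
        ax.set_title(f"n = {fit.n:.3g}, k = {fit.k:.3g} (derived plot)")
        plot_path = out_dir / "fit_residuals.png"
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
        written.append(plot_path)
    return written
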