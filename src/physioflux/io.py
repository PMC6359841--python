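"""File I/O, run configuration and the end-to-end pipeline.

CSV schemas (all tidy/long form, units as a column, never in headers):

* time-series: columns ``time_h, channel, value, unit, replicate, strain``
  with a first comment line ``# physioflux-timeseries mode=... key=val``
  carrying scalar metadata (mode, aeration, volume, dilution rate, feed,
  pH, temperature).  Gas channels are ``y_co2``/``y_o2`` (mol_fraction);
  unknown units fail loudly.
* metabolite panel: columns ``strain, replicate, metabolite, value``.

:func:`run_pipeline` wires the stages rates → flux map → balance →
energetics → metabolites, writing one tidy CSV per stage, a summary
table, an edge list for diagram rendering, a machine-readable warnings
file and a log that records the config hash and seed.  Every number in
the report is read back from a stage output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from .bioreactor import CHANNEL_UNITS, BioreactorSeries
from .exceptions import PhysiofluxError, SchemaError
from .flux_accounting import FluxMap, carbon_balance, normalize_fluxes
from .metabolites import FoldChangeModel, MetabolitePanel
from .energetics import MixingModel, acid_speciation, ledger_table, solve_mixing
from .rate_estimation import (
    BatchPhysiologyModel,
    ChemostatPhysiologyModel,
    PhysiologyResults,
    pool_replicates,
)
from .synthetic import (
    BatchScenario,
    ChemostatScenario,
    PanelScenario,
    simulate_batch,
    simulate_chemostat,
    simulate_panel,
)

logger = logging.getLogger(__name__)

_META_PREFIX = "# physioflux-timeseries"
_REQUIRED_COLUMNS = ["time_h", "channel", "value", "unit", "replicate", "strain"]


def write_timeseries(series: BioreactorSeries, path: str | Path) -> Path:
    """Serialize a series to the long-format CSV schema."""
    path = Path(path)
    meta = {"mode": series.mode, "aeration": series.aeration,
            "volume": series.volume, "temperature": series.temperature}
    if series.ph is not None:
        meta["ph"] = series.ph
    if series.dilution_rate is not None:
        meta["dilution_rate"] = series.dilution_rate
    for compound, conc in series.feed.items():
        meta[f"feed_{compound}"] = conc
    rows = []

    def emit(channel: str, values: np.ndarray) -> None:
        unit = CHANNEL_UNITS[channel]
        for t, v in zip(series.time, values):
            rows.append({"time_h": t, "channel": channel, "value": v,
                         "unit": unit, "replicate": series.replicate_id or "r1",
                         "strain": series.strain or "unknown"})

    emit("biomass", series.biomass)
    for compound in sorted(series.concentrations):
        emit(compound, series.concentrations[compound])
    if series.y_co2 is not None:
        emit("y_co2", series.y_co2)
    if series.y_o2 is not None:
        emit("y_o2", series.y_o2)
    header = _META_PREFIX + "".join(f" {k}={v}" for k, v in meta.items())
    body = pd.DataFrame(rows).to_csv(index=False)
    path.write_text(header + "\n" + body)
    return path


def read_timeseries(path: str | Path) -> BioreactorSeries:
    """Parse and validate a long-format time-series CSV.

    Strictly validates the schema: required columns, known channels,
    exact unit match per channel, strictly increasing time.  Violations
    raise :class:`SchemaError` naming the offending channel or rows.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    if not first.startswith(_META_PREFIX):
        raise SchemaError(f"{path}: missing metadata header line "
                          f"('{_META_PREFIX} mode=...')")
    meta: dict[str, str] = {}
    for token in first[len(_META_PREFIX):].split():
        key, _, value = token.partition("=")
        meta[key] = value
    if meta.get("mode") not in ("batch", "chemostat"):
        raise SchemaError(f"{path}: metadata mode must be batch or chemostat")

    frame = pd.read_csv(path, comment="#")
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    unknown = set(frame["channel"]) - set(CHANNEL_UNITS)
    if unknown:
        raise SchemaError(f"{path}: unknown channels {sorted(unknown)}")
    for channel, group in frame.groupby("channel"):
        expected = CHANNEL_UNITS[channel]
        bad = set(group["unit"]) - {expected}
        if bad:
            raise SchemaError(
                f"{path}: channel {channel!r} has unit(s) {sorted(bad)}, "
                f"expected {expected!r}")

    def channel_values(channel: str) -> tuple[np.ndarray, np.ndarray]:
        sub = frame[frame["channel"] == channel].sort_values("time_h")
        return sub["time_h"].to_numpy(), sub["value"].to_numpy()

    t, biomass = channel_values("biomass")
    if len(t) == 0:
        raise SchemaError(f"{path}: no biomass channel")
    if np.any(np.diff(t) <= 0):
        raise SchemaError(f"{path}: time not strictly increasing in biomass channel")
    conc = {}
    for channel in frame["channel"].unique():
        if channel in ("biomass", "y_co2", "y_o2"):
            continue
        tc, vals = channel_values(channel)
        if len(tc) != len(t) or np.any(tc != t):
            raise SchemaError(f"{path}: channel {channel!r} time grid differs "
                              "from biomass channel")
        conc[channel] = vals
    gas = {}
    for channel in ("y_co2", "y_o2"):
        if channel in set(frame["channel"]):
            _, gas[channel] = channel_values(channel)

    feed = {k[len("feed_"):]: float(v) for k, v in meta.items()
            if k.startswith("feed_")}
    return BioreactorSeries(
        mode=meta["mode"], time=t, biomass=biomass, concentrations=conc,
        y_co2=gas.get("y_co2"), y_o2=gas.get("y_o2"),
        aeration=float(meta.get("aeration", 36.0)),
        volume=float(meta.get("volume", 0.6)),
        temperature=float(meta.get("temperature", 30.0)),
        ph=float(meta["ph"]) if "ph" in meta else None,
        dilution_rate=float(meta["dilution_rate"]) if "dilution_rate" in meta else None,
        feed=feed,
        replicate_id=str(frame["replicate"].iloc[0]),
        strain=str(frame["strain"].iloc[0]))


def write_panel(panels: list[MetabolitePanel], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for panel in panels:
        for rep, (_, series) in enumerate(panel.values.iterrows(), start=1):
            for met, value in series.items():
                rows.append({"strain": panel.strain, "replicate": f"r{rep}",
                             "metabolite": met, "value": value})
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_panel(path: str | Path) -> dict[str, MetabolitePanel]:
    """Read panel CSV -> {strain: MetabolitePanel}."""
    frame = pd.read_csv(path)
    required = ["strain", "replicate", "metabolite", "value"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    panels = {}
    for strain, group in frame.groupby("strain"):
        wide = group.pivot(index="replicate", columns="metabolite",
                           values="value")
        panels[str(strain)] = MetabolitePanel(str(strain), wide)
    return panels


class RunConfig(BaseModel):
    """Validated configuration of one pipeline run (YAML-serializable)."""

    mode: str = "batch"
    timeseries: dict[str, list[str]] = Field(default_factory=dict)  # strain -> paths
    panel_path: str | None = None
    control_strain: str = "control"
    test_strain: str = "xfpk"
    simulate_if_missing: bool = True
    n_replicates: int = Field(default=4, ge=1)
    noise_cv: float = Field(default=0.0, ge=0.0, le=0.5)
    balance_mode: str = "as-printed"
    drift_threshold: float = Field(default=0.05, gt=0.0, lt=1.0)
    balance_warn_band: tuple[float, float] = (90.0, 110.0)
    ph: float = Field(default=5.0, ge=0.0, le=14.0)
    pka: float = 4.76
    mixing: tuple[float, float, float] | None = None  # (q_ref_glc, q_ref_ace, q_obs)
    seed: int = 0
    outdir: str = "physioflux_out"

    @field_validator("mode", "balance_mode")
    @classmethod
    def _known_choice(cls, v: str, info) -> str:
        allowed = {"mode": ("batch", "chemostat"),
                   "balance_mode": ("as-printed", "closed")}[info.field_name]
        if v not in allowed:
            raise ValueError(f"{info.field_name} must be one of {allowed}")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.model_dump(mode="json")))
        return path

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _strain_series(config: RunConfig, strain: str,
                   default_scenario) -> list[BioreactorSeries]:
    paths = config.timeseries.get(strain, [])
    if paths:
        return [read_timeseries(p) for p in paths]
    if not config.simulate_if_missing:
        raise PhysiofluxError(f"no time-series configured for strain {strain!r}")
    out = []
    for rep in range(config.n_replicates):
        scenario = default_scenario(
            noise_cv=config.noise_cv, balance=config.balance_mode,
            seed=config.seed * 10_000 + rep)
        sim = simulate_batch(scenario) if config.mode == "batch" \
            else simulate_chemostat(scenario)
        sim.replicate_id = f"r{rep + 1}"
        out.append(sim)
    return out


def _fit_strain(config: RunConfig,
                series_list: list[BioreactorSeries]) -> PhysiologyResults:
    fits = []
    for series in series_list:
        if config.mode == "batch":
            fits.append(BatchPhysiologyModel(series).fit())
        else:
            fits.append(ChemostatPhysiologyModel(
                series, drift_threshold=config.drift_threshold).fit())
    return fits[0] if len(fits) == 1 else pool_replicates(fits)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the configured pipeline; returns {artifact name: path}.

    Stages: specific rates per strain (replicates pooled) → normalized
    C-mol flux map and carbon balance → energetics ledger (acid
    speciation at the run pH, route ATP costs, optional mixing model) →
    metabolite fold-changes (if a panel is configured or simulated).
    Deterministic for a fixed (config, seed).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("physioflux")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    warnings_list: list[dict] = []
    artifacts: dict[str, Path] = {"log": log_path}
    try:
        logger.info("run config hash=%s seed=%d", config.config_hash(),
                    config.seed)
        scenario_types = {
            "batch": {"control": BatchScenario.control, "xfpk": BatchScenario.xfpk},
            "chemostat": {"control": ChemostatScenario.control,
                          "xfpk": ChemostatScenario.xfpk},
        }[config.mode]

        results: dict[str, PhysiologyResults] = {}
        maps: dict[str, FluxMap] = {}
        phys_frames, flux_frames, edges = [], [], []
        for strain in (config.control_strain, config.test_strain):
            factory = scenario_types.get(strain, scenario_types["control"])
            series_list = _strain_series(config, strain, factory)
            result = _fit_strain(config, series_list)
            result.strain = strain
            results[strain] = result
            frame = result.to_frame()
            frame.insert(0, "strain", strain)
            phys_frames.append(frame)

            fmap = normalize_fluxes(result)
            maps[strain] = fmap
            fframe = fmap.to_frame()
            fframe.insert(0, "strain", strain)
            fframe["balance_closure_pct"] = fmap.balance_closure
            fframe["respiration_fraction_pct"] = fmap.respiration_fraction
            flux_frames.append(fframe)
            lo, hi = config.balance_warn_band
            if not lo <= fmap.balance_closure <= hi:
                warnings_list.append(
                    {"stage": "balance", "strain": strain,
                     "message": f"closure {fmap.balance_closure:.1f}% outside "
                                f"[{lo}, {hi}]"})
            for src, sink, pct in fmap.to_edge_list():
                edges.append(f"{strain}\t{src}\t{sink}\t{pct}")

        artifacts["physiology"] = outdir / "physiology.csv"
        pd.concat(phys_frames).to_csv(artifacts["physiology"], index=False)
        artifacts["fluxmap"] = outdir / "fluxmap.csv"
        pd.concat(flux_frames).to_csv(artifacts["fluxmap"], index=False)
        artifacts["edges"] = outdir / "fluxmap_edges.tsv"
        artifacts["edges"].write_text(
            "strain\tsource\tsink\tpercent\n" + "\n".join(edges) + "\n")

        energetics_lines = [ledger_table(), "",
                            f"HA fraction at pH {config.ph} "
                            f"(pKa {config.pka}): "
                            f"{acid_speciation(config.ph, config.pka):.4f}"]
        if config.mixing is not None:
            sol = solve_mixing(MixingModel(*config.mixing))
            energetics_lines.append(
                f"mixing model {config.mixing}: acetate-derived fraction "
                f"{sol.fraction_acetate:.4f}"
                + (" (extrapolated)" if sol.extrapolated else ""))
            if sol.extrapolated:
                warnings_list.append({"stage": "energetics",
                                      "message": "mixing fraction outside [0,1]"})
        artifacts["energetics"] = outdir / "energetics.txt"
        artifacts["energetics"].write_text("\n".join(energetics_lines) + "\n")

        panels = None
        if config.panel_path:
            panels = read_panel(config.panel_path)
        elif config.simulate_if_missing and config.mode == "chemostat":
            control, test = simulate_panel(PanelScenario(seed=config.seed))
            panels = {control.strain: control, test.strain: test}
        if panels and config.control_strain in panels \
                and config.test_strain in panels:
            fc = FoldChangeModel(panels[config.test_strain],
                                 panels[config.control_strain]).fit()
            artifacts["metabolites"] = outdir / "metabolites.csv"
            fc.to_frame().to_csv(artifacts["metabolites"], index=False)
        else:
            logger.info("no metabolite panel for both strains; stage skipped")

        summary = _assemble_summary(artifacts)
        artifacts["summary"] = outdir / "summary.txt"
        artifacts["summary"].write_text(summary)
        artifacts["warnings"] = outdir / "warnings.json"
        artifacts["warnings"].write_text(json.dumps(warnings_list, indent=2))
        return artifacts
    except PhysiofluxError as exc:
        raise PhysiofluxError(f"pipeline failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()


def _assemble_summary(artifacts: dict[str, Path]) -> str:
    """Summary table assembled from stage output files only."""
    phys = pd.read_csv(artifacts["physiology"])
    flux = pd.read_csv(artifacts["fluxmap"])
    lines = ["Physiological parameters", "=" * 60]
    for strain, group in phys.groupby("strain", sort=False):
        lines.append(f"\n[{strain}]")
        for _, row in group.iterrows():
            sd = "" if pd.isna(row["sd"]) else f" ± {row['sd']:.3g}"
            lines.append(f"  {row['parameter']:<34s}{row['value']: .4g}{sd}")
        sub = flux[flux["strain"] == strain]
        lines.append(f"  {'Carbon balance (%)':<34s} "
                     f"{sub['balance_closure_pct'].iloc[0]:.4g}")
    return "\n".join(lines) + "\n"
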