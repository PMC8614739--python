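"""Reading and writing the package's plain-text interchange formats.

One cultivation is stored as a long-format CSV (columns ``time_h, signal,
value, replicate_id, units``; feed balances appear as ``weight_<feed>``
signals) plus a YAML configuration holding the per-signal uncertainty specs,
feed metadata (concentration, density), sampling events (withdrawn volumes
in mL, converted to litres at ingestion) and all evaluation settings.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data_model import (
    FeedSpec,
    MeasurementSeries,
    ProcessDataset,
    SigmaKind,
    UncertaintySpec,
)
from .pipeline import PipelineSettings

__all__ = [
    "load_config",
    "load_dataset",
    "settings_from_config",
    "write_dataset",
    "scenario_config",
]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _spec_from_dict(d: dict) -> UncertaintySpec:
    return UncertaintySpec(
        kind=SigmaKind(d["kind"]),
        value=float(d.get("value", 0.0)),
        floor=float(d.get("floor", 0.0)),
    )


def load_dataset(csv_path: str | Path, config: dict) -> ProcessDataset:
    """Assemble a :class:`ProcessDataset` from the long CSV and its config."""
    df = pd.read_csv(csv_path)
    required = {"time_h", "signal", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"data CSV needs columns {sorted(required)}")
    has_rep = "replicate_id" in df.columns

    signals_cfg = config.get("signals", {})
    feed_cfgs = {f["name"]: f for f in config.get("feeds", [])}

    offline: list[MeasurementSeries] = []
    feeds: list[FeedSpec] = []
    for name, g in df.groupby("signal", sort=False):
        g = g.sort_values("time_h")
        units = str(g["units"].iloc[0]) if "units" in g.columns else ""
        if name.startswith("weight_"):
            feed_name = name[len("weight_"):]
            cfg = feed_cfgs.get(feed_name)
            if cfg is None:
                raise ValueError(f"no feed config for balance signal {name!r}")
            sig_cfg = signals_cfg.get(name, {"kind": "absolute", "value": 0.1})
            spec = _spec_from_dict(sig_cfg)
            series = MeasurementSeries(
                name=name,
                times=g["time_h"].to_numpy(),
                values=g["value"].to_numpy(),
                sigma=np.full(len(g), spec.value),
                units=units or "g",
            )
            feeds.append(
                FeedSpec(
                    name=feed_name,
                    concentration=float(cfg["concentration_g_per_L"]),
                    density=float(cfg["density_g_per_mL"]),
                    balance_series=series,
                )
            )
            continue
        if has_rep and g["replicate_id"].notna().any():
            reps, times, values = [], [], []
            for t, gt in g.groupby("time_h"):
                r = gt["value"].to_numpy(dtype=float)
                times.append(float(t))
                values.append(r.mean())
                reps.append(r)
            series = MeasurementSeries(
                name=name, times=np.array(times), values=np.array(values),
                replicates=reps, units=units,
            )
        else:
            series = MeasurementSeries(
                name=name,
                times=g["time_h"].to_numpy(dtype=float),
                values=g["value"].to_numpy(dtype=float),
                units=units,
            )
        offline.append(series)

    uncertainty = {
        name: _spec_from_dict(d)
        for name, d in signals_cfg.items()
        if not name.startswith("weight_") and name != "sampling"
    }
    events = [
        (float(t), float(v_ml) / 1000.0)
        for t, v_ml in config.get("sample_events_mL", [])
    ]
    return ProcessDataset(
        organism_label=str(config.get("organism", "")),
        initial_volume=float(config["initial_volume_L"]),
        feeds=feeds,
        sample_events=events,
        offline=offline,
        uncertainty=uncertainty,
    )


def settings_from_config(config: dict) -> PipelineSettings:
    ev = config.get("evaluation", {})
    balances = {}
    for comp, d in ev.get("balances", {}).items():
        balances[comp] = (d["kind"], d.get("feed"))
    sampling = config.get("signals", {}).get("sampling", {})
    reg = config.get("regression", {})
    lim = config.get("limits", {})
    har = config.get("harvest", {})
    sg = ev.get("savgol", {})
    mc = ev.get("mc", {})
    return PipelineSettings(
        biomass_signal=ev.get("biomass_signal", "biomass"),
        balances=balances,
        strict_dilution=bool(ev.get("strict_dilution", True)),
        savgol_window=int(sg.get("window", 51)),
        savgol_order=int(sg.get("order", 2)),
        n_mc=int(mc.get("n", 500)),
        seed=int(mc.get("seed", 1)),
        mc_mode=str(mc.get("mode", "chained")),
        sampling_sigma=float(sampling.get("value", 3.0)) / 1000.0,
        regression_x=reg.get("x"),
        regression_y=reg.get("y"),
        regression_method=str(reg.get("method", "york")),
        magnitude_x=bool(reg.get("magnitude_x", True)),
        setpoint=lim.get("setpoint"),
        k_sigma=float(lim.get("k_sigma", 3.0)),
        harvest_signal=har.get("signal"),
        harvest_threshold=float(har.get("threshold", 90.0)),
        harvest_certainty=float(har.get("certainty", 0.9)),
        harvest_direction=str(har.get("direction", "above")),
    )


def write_dataset(ds: ProcessDataset, csv_path: str | Path) -> None:
    """Write a dataset to the long CSV format (replicates as separate rows)."""
    rows = []
    for s in ds.offline:
        if s.replicates is not None:
            for t, reps in zip(s.times, s.replicates):
                for i, v in enumerate(reps):
                    rows.append((t, s.name, v, i, s.units))
        else:
            for t, v in zip(s.times, s.values):
                rows.append((t, s.name, v, None, s.units))
    for f in ds.feeds:
        b = f.balance_series
        for t, v in zip(b.times, b.values):
            rows.append((t, b.name, v, None, b.units))
    pd.DataFrame(
        rows, columns=["time_h", "signal", "value", "replicate_id", "units"]
    ).to_csv(csv_path, index=False, float_format="%.10g")


def scenario_config(scn, ds: ProcessDataset) -> dict:
    """Evaluation config matching a synthetic scenario (written next to its CSV)."""
    signals: dict = {}
    for name, spec in ds.uncertainty.items():
        signals[name] = {
            "kind": spec.kind.value,
            "value": float(spec.value),
            "floor": float(spec.floor),
        }
    signals["sampling"] = {"kind": "absolute", "value": scn.syringe_sigma * 1000.0}
    for f in ds.feeds:
        signals[f"weight_{f.name}"] = {"kind": "absolute", "value": scn.balance_sigma}
    cfg = {
        "organism": scn.preset,
        "initial_volume_L": float(ds.initial_volume),
        "signals": signals,
        "feeds": [
            {
                "name": f.name,
                "concentration_g_per_L": float(f.concentration),
                "density_g_per_mL": float(f.density),
            }
            for f in ds.feeds
        ],
        "sample_events_mL": [[float(t), float(v) * 1000.0] for t, v in ds.sample_events],
        "evaluation": {
            "biomass_signal": "biomass",
            "balances": {
                comp: {"kind": kind, **({"feed": feed} if feed else {})}
                for comp, (kind, feed) in scn.component_balances.items()
            },
            "strict_dilution": bool(scn.strict_dilution),
            "savgol": {"window": 51, "order": 2},
            "mc": {"n": 500, "mode": "chained"},
        },
    }
    comps = list(scn.component_balances)
    uptakes = [c for c in comps if scn.component_balances[c][0] == "uptake"]
    prods = [c for c in comps if scn.component_balances[c][0] == "production"]
    if uptakes and prods:
        cfg["regression"] = {
            "x": uptakes[0],
            "y": prods[0],
            "method": "york",
            "magnitude_x": True,
        }
    if "viability" in scn.extra_signals:
        cfg["harvest"] = {
            "signal": "viability",
            "threshold": 90.0,
            "certainty": 0.9,
            "direction": "above",
        }
    return cfg
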