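"""On-disk formats: sweep bundles (meta.json + sweeps.csv) and fit records.

A bundle directory holds ``meta.json`` (protocol, scenario, seed, units,
drug events) and ``sweeps.csv`` with columns ``sweep_id, t_s, v_mV,
i_pA``; p/n leak templates, when present, live in ``pn_templates.csv``.
Units are written explicitly and validated on read: a bundle with
missing or unexpected units is rejected rather than silently rescaled.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .params import ScenarioConfig
from .protocols import DrugEvent, Sweep, SweepBundle, VoltageProtocol

__all__ = ["write_bundle", "read_bundle", "write_fit_record"]

_EXPECTED_UNITS = {"t": "s", "v": "mV", "i": "pA"}


def write_bundle(bundle: SweepBundle, path: str | Path) -> Path:
    """Serialize a bundle to a directory; returns the directory path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    proto = asdict(bundle.protocol)
    meta = {
        "units": bundle.units,
        "seed": bundle.seed,
        "protocol": proto,
        "scenario": json.loads(bundle.scenario.model_dump_json()),
        "drug_events": [asdict(e) for e in bundle.drug_events],
        "start_times_s": list(map(float, bundle.start_times_s)),
        "pn_n": bundle.pn_n,
        "has_pn_templates": bundle.pn_templates is not None,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2))
    frames = []
    for i, sw in enumerate(bundle.sweeps):
        frames.append(pd.DataFrame({
            "sweep_id": i, "t_s": sw.t_s, "v_mV": sw.v_mV, "i_pA": sw.i_pA}))
    pd.concat(frames, ignore_index=True).to_csv(path / "sweeps.csv", index=False,
                                                float_format="%.17g")
    if bundle.pn_templates is not None:
        frames = [pd.DataFrame({"sweep_id": i, "i_pA": t})
                  for i, t in enumerate(bundle.pn_templates)]
        pd.concat(frames, ignore_index=True).to_csv(path / "pn_templates.csv", index=False,
                                                    float_format="%.17g")
    return path


def read_bundle(path: str | Path) -> SweepBundle:
    """Load a bundle directory written by :func:`write_bundle`."""
    path = Path(path)
    meta_file = path / "meta.json"
    if not meta_file.exists():
        raise FileNotFoundError(f"no meta.json under {path}")
    meta = json.loads(meta_file.read_text())
    units = meta.get("units")
    if units is None:
        raise ValueError("bundle metadata is missing the units field")
    if units != _EXPECTED_UNITS:
        raise ValueError(f"unexpected units {units!r}; expected {_EXPECTED_UNITS}")
    proto_d = dict(meta["protocol"])
    proto_d["segments"] = [tuple(seg) for seg in proto_d["segments"]]
    proto = VoltageProtocol(**proto_d)
    scenario = ScenarioConfig.model_validate(meta["scenario"])
    df = pd.read_csv(path / "sweeps.csv", float_precision="round_trip")
    sweeps = []
    for i, grp in df.groupby("sweep_id", sort=True):
        sweeps.append(Sweep(t_s=grp.t_s.to_numpy(), v_mV=grp.v_mV.to_numpy(),
                            i_pA=grp.i_pA.to_numpy()))
    pn = None
    if meta.get("has_pn_templates") and (path / "pn_templates.csv").exists():
        dfp = pd.read_csv(path / "pn_templates.csv", float_precision="round_trip")
        pn = [grp.i_pA.to_numpy() for _, grp in dfp.groupby("sweep_id", sort=True)]
    return SweepBundle(
        sweeps=sweeps,
        start_times_s=np.asarray(meta["start_times_s"], float),
        protocol=proto, scenario=scenario, seed=meta["seed"],
        drug_events=[DrugEvent(**e) for e in meta["drug_events"]],
        pn_templates=pn, pn_n=meta.get("pn_n", 4), units=units,
    )


def write_fit_record(fit, path: str | Path, model: str) -> Path:
    """Write one fit result (parameters, SEs, diagnostics) as JSON."""
    path = Path(path)
    rec = {"model": model}
    d = fit.to_dict() if hasattr(fit, "to_dict") else asdict(fit)
    for k, v in d.items():
        rec[k] = v if not isinstance(v, (np.floating, np.integer)) else float(v)
    path.write_text(json.dumps(rec, indent=2, default=float))
    return path
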