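"""Plain-text serialization: count series as CSV, model specs as YAML."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model_core import CountSeries, Family, InnovationSpec, ModelSpec

__all__ = ["read_series_csv", "write_series_csv", "load_model_yaml", "save_model_yaml"]


def write_series_csv(series: CountSeries, path) -> None:
    """Write a series as CSV with columns (t, x); the t=0 row carries X_0."""
    t = np.arange(0, series.x.size + 1)
    x = np.concatenate(([series.x0], series.x))
    pd.DataFrame({"t": t, "x": x}).to_csv(path, index=False)


def read_series_csv(path, T: int) -> CountSeries:
    """Read a (t, x) CSV; a t=0 row, if present, is taken as X_0."""
    df = pd.read_csv(path).sort_values("t")
    x0 = 0
    if (df["t"] == 0).any():
        x0 = int(df.loc[df["t"] == 0, "x"].iloc[0])
        df = df[df["t"] > 0]
    return CountSeries(x=df["x"].to_numpy(), T=T, x0=x0)


def save_model_yaml(spec: ModelSpec, path, x0: int = 0, burn_in: int = 0, seed=None):
    doc = {
        "T": int(spec.T),
        "alpha": [[float(a) for a in row] for row in spec.alpha],
        "r": [int(v) for v in spec.r],
        "family": spec.innovations.family.value,
        "lam": [float(v) for v in spec.innovations.lam],
        "x0": int(x0),
        "burn_in": int(burn_in),
    }
    if spec.innovations.rho is not None:
        doc["rho"] = [float(v) for v in spec.innovations.rho]
    if seed is not None:
        doc["seed"] = int(seed)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_model_yaml(path) -> tuple[ModelSpec, dict]:
    """Load a model config; returns (spec, extras) where extras holds
    x0 / burn_in / seed defaults for simulation."""
    doc = yaml.safe_load(Path(path).read_text())
    innov = InnovationSpec(
        family=Family(doc["family"]),
        lam=np.asarray(doc["lam"], dtype=float),
        rho=np.asarray(doc["rho"], dtype=float) if "rho" in doc else None,
    )
    spec = ModelSpec(
        T=int(doc["T"]),
        alpha=np.asarray(doc["alpha"], dtype=float),
        r=np.asarray(doc["r"]),
        innovations=innov,
    )
    extras = {
        "x0": int(doc.get("x0", 0)),
        "burn_in": int(doc.get("burn_in", 0)),
        "seed": doc.get("seed"),
    }
    return spec, extras
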