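"""Moment-trajectory container and tabular writers shared by all backends."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd


@dataclass
class MomentTrajectory:
    """A named moment/cumulant evaluated on a time grid.

    ``method`` records provenance: "closed_form", "diagram_engine", or
    "simulation"; ``vertex_order`` the perturbative order where relevant.
    """

    times: np.ndarray
    values: np.ndarray
    quantity: str                      # kappa1..kappa4, m1..m4, K3, K4, xi
    method: str
    vertex_order: Optional[int] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same shape")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.times,
            "quantity": self.quantity,
            "value": self.values,
            "method": self.method,
            "vertex_order": "" if self.vertex_order is None else self.vertex_order,
        })


def write_tsv(path, trajectories, manifest: Optional[dict] = None) -> None:
    """Write trajectories as TSV with a '#'-prefixed JSON manifest line."""
    frames = [tr.to_frame() for tr in trajectories]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["t", "quantity", "value", "method", "vertex_order"])
    with open(path, "w") as fh:
        if manifest is not None:
            fh.write("# " + json.dumps(manifest, sort_keys=True) + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_tsv(path):
    """Round-trip reader for :func:`write_tsv`; returns (manifest, DataFrame)."""
    manifest = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            manifest = json.loads(first[1:].strip())
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
    return manifest, df


def write_json(path, trajectories, manifest: Optional[dict] = None) -> None:
    payload = {
        "manifest": manifest or {},
        "trajectories": [
            {
                "quantity": tr.quantity,
                "method": tr.method,
                "vertex_order": tr.vertex_order,
                "times": tr.times.tolist(),
                "values": tr.values.tolist(),
            }
            for tr in trajectories
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
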