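"""File formats: the spectra container and delimited tables.

One HDF5 file per participant-region holds the complex FID, the
acquisition metadata as attributes, and (optionally) the generative ground
truth as a JSON provenance string.  A flat CSV export (index, real,
imaginary) is provided for interoperability.  Marker/cohort tables and fit
results are plain tab-separated text.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import FID, AcquisitionParams
from .voigtfit import FitResult

__all__ = [
    "save_fid", "load_fid", "fid_to_csv", "fid_from_csv",
    "save_table", "load_table", "save_fit_result",
]

_ACQ_FIELDS = ("n_points", "spectral_width", "transmitter_frequency",
               "repetition_time", "echo_time")


def save_fid(path, fid: FID, truth=None) -> None:
    """Write a FID container: /fid complex dataset + acquisition attrs.

    ``truth`` (any dataclass or dict) is stored as a JSON provenance
    attribute so a simulated spectrum carries its generative state.
    """
    import h5py

    with h5py.File(path, "w") as h5:
        ds = h5.create_dataset("fid", data=fid.samples)
        for name in _ACQ_FIELDS:
            ds.attrs[name] = getattr(fid.acq, name)
        ds.attrs["history"] = json.dumps(list(fid.history))
        if truth is not None:
            if dataclasses.is_dataclass(truth):
                truth = dataclasses.asdict(truth)
            h5.attrs["provenance"] = json.dumps(truth)


def load_fid(path) -> tuple[FID, dict | None]:
    """Read a FID container; returns (FID, provenance dict or None)."""
    import h5py

    with h5py.File(path, "r") as h5:
        ds = h5["fid"]
        samples = np.asarray(ds[...], dtype=complex)
        acq = AcquisitionParams(**{k: ds.attrs[k].item() if hasattr(ds.attrs[k], "item")
                                   else ds.attrs[k] for k in _ACQ_FIELDS})
        acq = dataclasses.replace(acq, n_points=len(samples))
        history = tuple(json.loads(ds.attrs.get("history", "[]")))
        truth = json.loads(h5.attrs["provenance"]) if "provenance" in h5.attrs else None
    return FID(samples=samples, acq=acq, history=history), truth


def fid_to_csv(path, fid: FID) -> None:
    """Flat CSV export: index, real, imaginary (one row per complex sample)."""
    pd.DataFrame({
        "index": np.arange(len(fid.samples)),
        "real": fid.samples.real,
        "imaginary": fid.samples.imag,
    }).to_csv(path, index=False)


def fid_from_csv(path, acq: AcquisitionParams) -> FID:
    df = pd.read_csv(path)
    samples = df["real"].to_numpy() + 1j * df["imaginary"].to_numpy()
    acq = dataclasses.replace(acq, n_points=len(samples))
    return FID(samples=samples, acq=acq, history=({"op": "load_csv", "path": str(path)},))


def save_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def load_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_fit_result(path, fit: FitResult, metadata: dict | None = None) -> None:
    """Fit table (one row per resonance) preceded by a key/value metadata block."""
    lines = [f"# {k}: {v}" for k, v in (metadata or {}).items()]
    lines.append(f"# residual_rms: {fit.residual_rms!r}")
    lines.append(f"# converged: {fit.converged}")
    frame = fit.to_frame()
    text = "\n".join(lines) + ("\n" if lines else "") + frame.to_csv(sep="\t", index=False)
    Path(path).write_text(text)
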