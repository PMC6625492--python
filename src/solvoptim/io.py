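"""Readers/writers for descriptor tables, σ-profiles, experiment logs, state.

File dialects: descriptor tables and experiment logs are comma-separated
UTF-8 CSV with a header row and '.' decimals; σ-profiles are two-column
whitespace-delimited text (σ in e Å⁻², p(σ) in Å²) with '#' comments; state
and manifests are JSON.  Readers validate ranges and never silently coerce
out-of-range objective values.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .descriptors import (
    ALL_DESCRIPTOR_COLUMNS,
    SCALAR_DESCRIPTORS,
    SIGMA3_COLUMNS,
    SIGMA5_COLUMNS,
    SigmaProfile,
    SolventLibrary,
    SolventRecord,
)
from .errors import InvalidArgumentError, SchemaError


# --------------------------------------------------------------------------
# Descriptor tables
# --------------------------------------------------------------------------

def read_library(path, skip_bad: bool = False) -> SolventLibrary:
    """Read a descriptor CSV (mandatory ``id`` column) into a library.

    Descriptor columns follow the documented schema; absent columns become
    missing values; unknown columns are ignored with a note in the
    provenance.  Rows with non-numeric descriptor cells raise a
    :class:`SchemaError` naming the row and column, unless ``skip_bad``.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    if "id" not in df.columns:
        raise SchemaError(f"{path}: missing mandatory 'id' column")
    known = {"id", "name", *ALL_DESCRIPTOR_COLUMNS}
    extra = [c for c in df.columns if c not in known]
    records, bad_rows = [], []
    for row_i, row in df.iterrows():
        scalars, s5, s3 = {}, np.full(5, np.nan), np.full(3, np.nan)
        ok = True
        for c in ALL_DESCRIPTOR_COLUMNS:
            raw = row.get(c)
            if raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw == "":
                v = np.nan
            else:
                try:
                    v = float(raw)
                except ValueError:
                    if skip_bad:
                        ok = False
                        break
                    raise SchemaError(
                        f"{path}: non-numeric value {raw!r} at row {row_i}, "
                        f"column {c!r}"
                    )
            if c in SCALAR_DESCRIPTORS:
                scalars[c] = v
            elif c in SIGMA5_COLUMNS:
                s5[SIGMA5_COLUMNS.index(c)] = v
            else:
                s3[SIGMA3_COLUMNS.index(c)] = v
        if not ok:
            bad_rows.append(row_i)
            continue
        records.append(
            SolventRecord(
                id=str(row["id"]),
                name=str(row.get("name", row["id"])),
                scalars=scalars,
                sigma5=s5,
                sigma3=s3,
            )
        )
    note = f"read from {path.name}"
    if bad_rows:
        note += f"; skipped {len(bad_rows)} malformed rows"
    if extra:
        note += f"; ignored columns {extra}"
    return SolventLibrary(records, provenance=note)


def write_library(library: SolventLibrary, path) -> None:
    df = library.table.reset_index()
    df.to_csv(path, index=False)


# --------------------------------------------------------------------------
# σ-profile files
# --------------------------------------------------------------------------

def read_sigma_profile(path) -> SigmaProfile:
    """Two-column whitespace text: σ (e Å⁻²), p(σ) (Å²); '#' comments."""
    arr = np.loadtxt(path, comments="#", ndmin=2)
    if arr.shape[1] != 2:
        raise SchemaError(f"{path}: expected two columns, got {arr.shape[1]}")
    return SigmaProfile(arr[:, 0], arr[:, 1])


def write_sigma_profile(profile: SigmaProfile, path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# sigma_e_per_A2  p_sigma_A2\n")
        for s, d in zip(profile.sigma, profile.density):
            fh.write(f"{float(s)!r} {float(d)!r}\n")


# --------------------------------------------------------------------------
# Experiment logs
# --------------------------------------------------------------------------

LOG_COLUMNS = ("solvent_id", "temperature_C", "conversion_pct", "de_pct")
MIXTURE_LOG_COLUMNS = ("x1", "x2", "x3", "temperature_C", "conversion_pct", "de_pct")


def read_experiment_log(path, mixture: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read an experiment log CSV; returns (raw rows, replicate-grouped rows).

    Pure-solvent logs carry ``solvent_id``; mixture logs carry ``x1..x3``.
    Objective ranges are validated (conversion ∈ [0, 100], d.e. ∈
    [−100, 100]); out-of-range rows raise naming the row.  Grouping averages
    replicates per condition and reports the replicate count and spread.
    """
    df = pd.read_csv(path)
    cols = MIXTURE_LOG_COLUMNS if mixture else LOG_COLUMNS
    missing = [c for c in cols if c not in df.columns]
    if missing and not df.empty:
        raise SchemaError(f"{path}: missing columns {missing}")
    if df.empty:
        empty = pd.DataFrame(columns=list(cols))
        return empty, empty
    bad = df.index[(df["conversion_pct"] < 0) | (df["conversion_pct"] > 100)]
    if len(bad):
        raise SchemaError(f"{path}: conversion out of [0, 100] at rows {list(bad)}")
    bad = df.index[(df["de_pct"] < -100) | (df["de_pct"] > 100)]
    if len(bad):
        raise SchemaError(f"{path}: d.e. out of [−100, 100] at rows {list(bad)}")
    keys = ["x1", "x2", "x3", "temperature_C"] if mixture else [
        "solvent_id", "temperature_C"]
    grouped = (
        df.groupby(keys, sort=False)
        .agg(
            conversion_pct=("conversion_pct", "mean"),
            de_pct=("de_pct", "mean"),
            n_replicates=("conversion_pct", "size"),
            conversion_sd=("conversion_pct", lambda s: s.std(ddof=1) if len(s) > 1 else 0.0),
            de_sd=("de_pct", lambda s: s.std(ddof=1) if len(s) > 1 else 0.0),
        )
        .reset_index()
    )
    return df, grouped


def write_experiment_log(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# --------------------------------------------------------------------------
# Run configuration and manifests
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated run settings, serialised verbatim into every manifest."""

    conversion_model: int = 4
    de_model: int = 1
    sigma3_boundaries: tuple[float, ...] = (-0.010, 0.010)
    sigma5_boundaries: tuple[float, ...] = (-0.015, -0.005, 0.005, 0.015)
    kernel: str = "matern52"
    n_restarts: int = 10
    n_repeats: int = 100
    batch_size: int = 5
    temperature_bounds: tuple[float, float] = (40.0, 100.0)
    thresholds: tuple[float, float] = (80.0, 65.0)
    seed: int = 0

    def __post_init__(self):
        from .descriptors import MODEL_FEATURES

        for m in (self.conversion_model, self.de_model):
            if m not in MODEL_FEATURES:
                raise InvalidArgumentError(f"unknown model id {m}")
        if list(self.sigma3_boundaries) != sorted(self.sigma3_boundaries) or list(
            self.sigma5_boundaries
        ) != sorted(self.sigma5_boundaries):
            raise InvalidArgumentError("segment boundaries must be increasing")
        if self.kernel not in ("matern52", "rbf"):
            raise InvalidArgumentError(f"unknown kernel {self.kernel!r}")
        if self.n_repeats < 1 or self.batch_size < 1 or self.n_restarts < 1:
            raise InvalidArgumentError("counts must be ≥ 1")
        if self.temperature_bounds[0] > self.temperature_bounds[1]:
            raise InvalidArgumentError("infeasible temperature bounds")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for k in ("sigma3_boundaries", "sigma5_boundaries", "temperature_bounds",
                  "thresholds"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, config: RunConfig, inputs: Sequence[str] = (),
                   extra: dict | None = None) -> None:
    """JSON provenance record: config, seed, package version, input digests."""
    doc = {
        "package": "solvoptim",
        "version": __version__,
        "config": config.to_dict(),
        "inputs": {str(p): file_digest(p) for p in inputs},
    }
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


# --------------------------------------------------------------------------
# Surrogate serialization
# --------------------------------------------------------------------------

def surrogate_to_dict(model) -> dict:
    return {
        "kernel": model.kernel,
        "ard": model.ard,
        "lengthscales": model.lengthscales.tolist(),
        "signal_variance": model.signal_variance,
        "noise_variance": model.noise_variance,
        "x_mean": model.x_mean.tolist(),
        "x_scale": model.x_scale.tolist(),
        "y_mean": model.y_mean,
        "y_scale": model.y_scale,
        "X_train": model.X_train.tolist(),
        "y_train": model.y_train.tolist(),
        "log_marginal_likelihood": model.log_marginal_likelihood,
        "seed": model.seed,
    }


def surrogate_from_dict(d: dict):
    from .surrogate import GPSurrogate

    m = GPSurrogate(
        kernel=d["kernel"],
        ard=d["ard"],
        lengthscales=np.asarray(d["lengthscales"], dtype=float),
        signal_variance=float(d["signal_variance"]),
        noise_variance=float(d["noise_variance"]),
        X_train=np.asarray(d["X_train"], dtype=float),
        y_train=np.asarray(d["y_train"], dtype=float),
        x_mean=np.asarray(d["x_mean"], dtype=float),
        x_scale=np.asarray(d["x_scale"], dtype=float),
        y_mean=float(d["y_mean"]),
        y_scale=float(d["y_scale"]),
        log_marginal_likelihood=float(d["log_marginal_likelihood"]),
        seed=d.get("seed"),
    )
    m._factorize()
    return m
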