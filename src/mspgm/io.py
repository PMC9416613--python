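"""File formats: numeric matrices, label tables, and model containers.

Matrix dialects (samples are always columns):

* CSV/TSV — header row of sample ids, first column of row ids.
* HDF5 — datasets ``data``, ``sample_ids``, ``row_ids``.
* NPZ — arrays ``data``, ``sample_ids``, ``row_ids``.

Labels are two-column TSV (``sample_id``, ``category``).  Fitted models are
stored in a single HDF5 (or NPZ) container, lossless at 64-bit precision:
per-subject groups hold ``P``, ``mu`` and ``rho2``, the root holds
``Sigma_c`` and the fit metadata; decoders store ``P_com``, ``P_ind`` and
their penalties.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import LatentGaussianSpec
from .decoder import VisualDecoder
from .individual import IndividualPGMModel
from .shared import FitInfo, SharedPGMModel

__all__ = [
    "load_matrix",
    "save_matrix",
    "load_labels",
    "save_labels",
    "save_model",
    "load_model",
    "save_decoder",
    "load_decoder",
]


def _kind(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix in {".csv", ".tsv", ".txt"}:
        return "csv"
    if suffix in {".h5", ".hdf5", ".hdf"}:
        return "hdf5"
    if suffix == ".npz":
        return "npz"
    raise ValueError(f"unrecognized file extension {suffix!r} for {path}")


def load_matrix(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a matrix; returns ``(data, sample_ids, row_ids)`` with samples as columns."""
    kind = _kind(path)
    if kind == "csv":
        sep = "\t" if Path(path).suffix.lower() == ".tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        return df.to_numpy(dtype=float), [str(c) for c in df.columns], [
            str(r) for r in df.index
        ]
    if kind == "hdf5":
        with h5py.File(path, "r") as f:
            data = np.asarray(f["data"], dtype=float)
            sample_ids = [s.decode() if isinstance(s, bytes) else str(s)
                          for s in f["sample_ids"][()]]
            row_ids = [s.decode() if isinstance(s, bytes) else str(s)
                       for s in f["row_ids"][()]]
        return data, sample_ids, row_ids
    z = np.load(path, allow_pickle=False)
    return (
        np.asarray(z["data"], dtype=float),
        [str(s) for s in z["sample_ids"]],
        [str(s) for s in z["row_ids"]],
    )


def save_matrix(
    path: str | Path,
    data: np.ndarray,
    sample_ids: list[str] | None = None,
    row_ids: list[str] | None = None,
) -> None:
    data = np.asarray(data, dtype=float)
    if sample_ids is None:
        sample_ids = [f"sample{j}" for j in range(data.shape[1])]
    if row_ids is None:
        row_ids = [f"row{j}" for j in range(data.shape[0])]
    kind = _kind(path)
    if kind == "csv":
        sep = "\t" if Path(path).suffix.lower() == ".tsv" else ","
        pd.DataFrame(data, index=row_ids, columns=sample_ids).to_csv(path, sep=sep)
    elif kind == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=data)
            f.create_dataset("sample_ids", data=np.array(sample_ids, dtype="S"))
            f.create_dataset("row_ids", data=np.array(row_ids, dtype="S"))
    else:
        np.savez(
            path,
            data=data,
            sample_ids=np.array(sample_ids, dtype="U"),
            row_ids=np.array(row_ids, dtype="U"),
        )


def load_labels(path: str | Path) -> tuple[list[str], list[str]]:
    """Read a two-column TSV of (sample_id, category)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("label file needs columns sample_id and category")
    return list(df.iloc[:, 0]), list(df.iloc[:, 1])


def save_labels(
    path: str | Path, sample_ids: list[str], categories: list
) -> None:
    pd.DataFrame(
        {"sample_id": sample_ids, "category": [str(c) for c in categories]}
    ).to_csv(path, sep="\t", index=False)


# --- model containers -----------------------------------------------------


def _fit_info_json(info: FitInfo) -> str:
    return json.dumps(
        {
            "iterations": info.iterations,
            "loglik_trace": list(info.loglik_trace),
            "seed": info.seed,
            "max_iter": info.max_iter,
            "early_stop_tol": info.early_stop_tol,
            "converged_early": info.converged_early,
        }
    )


def _fit_info_from_json(s: str) -> FitInfo:
    d = json.loads(s)
    return FitInfo(
        iterations=d["iterations"],
        loglik_trace=list(d["loglik_trace"]),
        seed=d["seed"],
        max_iter=d["max_iter"],
        early_stop_tol=d.get("early_stop_tol"),
        converged_early=d.get("converged_early", False),
    )


def save_model(path: str | Path, model: SharedPGMModel) -> None:
    """Write a fitted PGM (shared or individual) to HDF5 or NPZ."""
    spec = model.spec
    kind = _kind(path)
    if kind == "hdf5":
        with h5py.File(path, "w") as f:
            f.attrs["model_kind"] = model.model_kind
            f.attrs["fit_info"] = _fit_info_json(model.fit_info)
            f.create_dataset("Sigma_c", data=spec.latent_cov)
            for i in range(spec.n_subjects):
                g = f.create_group(f"subjects/{i}")
                g.create_dataset("P", data=spec.loadings[i])
                g.create_dataset("mu", data=spec.means[i])
                g.attrs["rho2"] = spec.noise_vars[i]
    elif kind == "npz":
        arrays = {"Sigma_c": spec.latent_cov,
                  "noise_vars": np.array(spec.noise_vars)}
        for i in range(spec.n_subjects):
            arrays[f"P_{i}"] = spec.loadings[i]
            arrays[f"mu_{i}"] = spec.means[i]
        arrays["meta"] = np.array(
            [model.model_kind, _fit_info_json(model.fit_info)], dtype="U"
        )
        np.savez(path, **arrays)
    else:
        raise ValueError("model containers are HDF5 or NPZ")


def load_model(path: str | Path) -> SharedPGMModel:
    kind = _kind(path)
    if kind == "hdf5":
        with h5py.File(path, "r") as f:
            model_kind = f.attrs["model_kind"]
            info = _fit_info_from_json(f.attrs["fit_info"])
            latent_cov = np.asarray(f["Sigma_c"])
            indices = sorted(f["subjects"], key=int)
            loadings = [np.asarray(f[f"subjects/{i}/P"]) for i in indices]
            means = [np.asarray(f[f"subjects/{i}/mu"]) for i in indices]
            noise = [float(f[f"subjects/{i}"].attrs["rho2"]) for i in indices]
    elif kind == "npz":
        z = np.load(path, allow_pickle=False)
        model_kind, info_json = (str(s) for s in z["meta"])
        info = _fit_info_from_json(info_json)
        latent_cov = z["Sigma_c"]
        noise = [float(v) for v in z["noise_vars"]]
        loadings = [z[f"P_{i}"] for i in range(len(noise))]
        means = [z[f"mu_{i}"] for i in range(len(noise))]
    else:
        raise ValueError("model containers are HDF5 or NPZ")
    spec = LatentGaussianSpec(
        loadings=loadings, means=means, noise_vars=noise, latent_cov=latent_cov
    )
    cls = IndividualPGMModel if model_kind == "individual" else SharedPGMModel
    return cls(spec=spec, fit_info=info, model_kind=str(model_kind))


def save_decoder(path: str | Path, dec: VisualDecoder) -> None:
    kind = _kind(path)
    trace = np.asarray(dec.fit_info.get("objective_trace", []), dtype=float)
    if kind == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("P_com", data=dec.P_com)
            f.create_dataset("P_ind", data=dec.P_ind)
            f.create_dataset("objective_trace", data=trace)
            f.attrs["lambda_com"] = dec.lambda_com
            f.attrs["lambda_ind"] = dec.lambda_ind
            f.attrs["iterations"] = dec.fit_info.get("iterations", 0)
    elif kind == "npz":
        np.savez(
            path,
            P_com=dec.P_com,
            P_ind=dec.P_ind,
            objective_trace=trace,
            lambdas=np.array([dec.lambda_com, dec.lambda_ind]),
            iterations=np.array([dec.fit_info.get("iterations", 0)]),
        )
    else:
        raise ValueError("decoder containers are HDF5 or NPZ")


def load_decoder(path: str | Path) -> VisualDecoder:
    kind = _kind(path)
    if kind == "hdf5":
        with h5py.File(path, "r") as f:
            return VisualDecoder(
                P_com=np.asarray(f["P_com"]),
                P_ind=np.asarray(f["P_ind"]),
                lambda_com=float(f.attrs["lambda_com"]),
                lambda_ind=float(f.attrs["lambda_ind"]),
                fit_info={
                    "iterations": int(f.attrs["iterations"]),
                    "objective_trace": list(np.asarray(f["objective_trace"])),
                },
            )
    if kind == "npz":
        z = np.load(path, allow_pickle=False)
        return VisualDecoder(
            P_com=z["P_com"],
            P_ind=z["P_ind"],
            lambda_com=float(z["lambdas"][0]),
            lambda_ind=float(z["lambdas"][1]),
            fit_info={
                "iterations": int(z["iterations"][0]),
                "objective_trace": list(z["objective_trace"]),
            },
        )
    raise ValueError("decoder containers are HDF5 or NPZ")
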