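"""File formats: NIfTI interchange, HDF5 dataset containers, checkpoints.

Conventions
-----------
* A single image series travels as NIfTI (height x width x n volume) with a
  JSON sidecar carrying the echo-time list in milliseconds (or a bare eta
  grid), or inside an HDF5 file.
* Synthetic datasets are HDF5 containers: ``/records/{i}/series``, ``.../s0``,
  ``.../t`` with scalar attrs ``sigma`` and ``seed``, plus a JSON manifest of
  the generating configuration in the root attrs.
* Trained models are saved as ``.npz`` weight archives whose header carries
  the architecture spec, training config and echo schedule, so a schedule
  mismatch is detectable at load time.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .core import EchoSchedule, ImageSeries, ParameterMap
from .fitting import FitResult
from .nn.models import CNNSpec, NN1DSpec, build_cnn, build_nn1d
from .synth import SynthConfig, SynthRecord

__all__ = [
    "load_series",
    "save_series",
    "save_fit",
    "load_fit",
    "save_dataset",
    "load_dataset",
    "save_checkpoint",
    "load_checkpoint",
]


def _schedule_to_meta(schedule: EchoSchedule) -> dict:
    meta = {"eta": schedule.eta.tolist()}
    if schedule.te_ms is not None:
        meta["EchoTimesMs"] = schedule.te_ms.tolist()
    if schedule.te_max_ms is not None:
        meta["EchoTimeMaxMs"] = schedule.te_max_ms
    return meta


def _schedule_from_meta(meta: dict) -> EchoSchedule:
    if "EchoTimesMs" in meta:
        return EchoSchedule.from_te_ms(np.asarray(meta["EchoTimesMs"], dtype=float))
    if "eta" in meta:
        return EchoSchedule(eta=np.asarray(meta["eta"], dtype=float))
    raise ValueError("metadata carries neither EchoTimesMs nor eta")


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name.split(".")[0] + ".json")


def save_series(series: ImageSeries, path, fmt: str | None = None) -> None:
    """Write a series as NIfTI (+ JSON sidecar) or HDF5, chosen by extension."""
    path = Path(path)
    fmt = fmt or ("hdf5" if path.suffix in (".h5", ".hdf5") else "nifti")
    if fmt == "nifti":
        nib.save(nib.Nifti1Image(series.data, affine=np.eye(4)), path)
        meta = _schedule_to_meta(series.schedule)
        meta["normalized"] = series.normalized
        _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    elif fmt == "hdf5":
        with h5py.File(path, "w") as f:
            d = f.create_dataset("series", data=series.data)
            d.attrs["meta"] = json.dumps(
                {**_schedule_to_meta(series.schedule), "normalized": series.normalized}
            )
    else:
        raise ValueError(f"unknown format {fmt!r}")


def load_series(path, fmt: str | None = None) -> ImageSeries:
    """Read a series; NIfTI requires the JSON sidecar with echo metadata."""
    path = Path(path)
    fmt = fmt or ("hdf5" if path.suffix in (".h5", ".hdf5") else "nifti")
    if fmt == "nifti":
        img = nib.load(path)
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise FileNotFoundError(
                f"echo-time metadata missing: expected JSON sidecar {sidecar} "
                "with an 'EchoTimesMs' (ms) or 'eta' entry"
            )
        meta = json.loads(sidecar.read_text())
        data = np.asarray(img.dataobj, dtype=float)
        return ImageSeries(
            data, _schedule_from_meta(meta), normalized=bool(meta.get("normalized"))
        )
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            d = f["series"]
            meta = json.loads(d.attrs["meta"])
            return ImageSeries(
                d[...], _schedule_from_meta(meta), normalized=bool(meta.get("normalized"))
            )
    raise ValueError(f"unknown format {fmt!r}")


def save_fit(
    fit: FitResult, path, schedule: EchoSchedule | None = None, fmt: str | None = None
) -> None:
    """Persist estimated maps (+ t2_ms when the schedule has physical TEs)."""
    path = Path(path)
    fmt = fmt or ("nifti" if ".nii" in path.suffixes or path.suffix == ".nii" else "hdf5")
    maps = {"s0": fit.map.s0, "t": fit.map.t}
    if fit.map.sigma_rice is not None:
        maps["sigma_rice"] = fit.map.sigma_rice
    if schedule is not None and schedule.te_max_ms is not None:
        maps["t2_ms"] = fit.map.t * schedule.te_max_ms
    meta = {"method": fit.method}
    if schedule is not None:
        meta.update(_schedule_to_meta(schedule))
    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            for k, v in maps.items():
                f.create_dataset(k, data=v)
            f.create_dataset("residual_rms", data=fit.residual_rms)
            f.create_dataset("converged", data=fit.converged.astype(np.uint8))
            f.attrs["meta"] = json.dumps(meta)
    elif fmt == "nifti":
        stack = np.stack(list(maps.values()), axis=-1)
        nib.save(nib.Nifti1Image(stack, affine=np.eye(4)), path)
        meta["layers"] = list(maps.keys())
        _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def load_fit(path) -> FitResult:
    """Read a fit written by :func:`save_fit` (HDF5 container only)."""
    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["meta"])
        sigma = f["sigma_rice"][...] if "sigma_rice" in f else None
        return FitResult(
            map=ParameterMap(f["s0"][...], f["t"][...], sigma),
            method=meta["method"],
            residual_rms=f["residual_rms"][...],
            converged=f["converged"][...].astype(bool),
        )


def save_dataset(records: list[SynthRecord], path, config: SynthConfig | None = None) -> None:
    """Write synthetic records to the canonical HDF5 dataset container."""
    with h5py.File(path, "w") as f:
        grp = f.create_group("records")
        for i, rec in enumerate(records):
            g = grp.create_group(str(i))
            g.create_dataset("series", data=rec.series.data)
            g.create_dataset("s0", data=rec.truth.s0)
            g.create_dataset("t", data=rec.truth.t)
            g.attrs["sigma"] = rec.sigma
        f.attrs["n_records"] = len(records)
        if records:
            f.attrs["schedule"] = json.dumps(
                _schedule_to_meta(records[0].series.schedule)
            )
        if config is not None:
            manifest = dataclasses.asdict(config)
            manifest["schedule"] = _schedule_to_meta(config.schedule)
            f.attrs["manifest"] = json.dumps(manifest)


def load_dataset(path) -> list[SynthRecord]:
    with h5py.File(path, "r") as f:
        sched = _schedule_from_meta(json.loads(f.attrs["schedule"]))
        records = []
        for i in range(int(f.attrs["n_records"])):
            g = f[f"records/{i}"]
            records.append(
                SynthRecord(
                    series=ImageSeries(g["series"][...], sched),
                    truth=ParameterMap(g["s0"][...], g["t"][...]),
                    sigma=float(g.attrs["sigma"]),
                )
            )
        return records


def load_manifest(path) -> dict:
    with h5py.File(path, "r") as f:
        if "manifest" not in f.attrs:
            raise KeyError("dataset container has no manifest")
        return json.loads(f.attrs["manifest"])


def save_checkpoint(model, path, train_config=None, history=None) -> None:
    """Save weights + architecture + the training echo schedule as .npz."""
    spec = model.spec
    header = {
        "kind": model.input_kind,
        "spec": dataclasses.asdict(spec),
        "train_config": dataclasses.asdict(train_config) if train_config else None,
        "history": {
            "train_loss": history.train_loss,
            "val_loss": history.val_loss,
            "best_epoch": history.best_epoch,
        }
        if history is not None
        else None,
    }
    sched = getattr(model, "schedule", None)
    if sched is not None:
        header["schedule"] = _schedule_to_meta(sched)
    arrays = {f"p{i}": p.value for i, p in enumerate(model.parameters())}
    # batch-norm running statistics are buffers, not parameters
    from .nn.layers import BatchNorm2d

    for i, m in enumerate(mod for mod in model.modules() if isinstance(mod, BatchNorm2d)):
        arrays[f"bn{i}_mean"] = m.running_mean
        arrays[f"bn{i}_var"] = m.running_var
    np.savez(path, header=json.dumps(header), **arrays)


def load_checkpoint(path):
    """Rebuild the model from a checkpoint; returns (model, header dict)."""
    with np.load(path, allow_pickle=False) as z:
        header = json.loads(str(z["header"]))
        spec_kw = dict(header["spec"])
        if header["kind"] == "curve":
            model = build_nn1d(NN1DSpec(**spec_kw))
        else:
            spec_kw["channels"] = tuple(spec_kw["channels"])
            spec_kw["strides"] = tuple(spec_kw["strides"])
            model = build_cnn(CNNSpec(**spec_kw))
        state = [z[f"p{i}"] for i in range(len(model.parameters()))]
        model.load_state(state)
        from .nn.layers import BatchNorm2d

        for i, m in enumerate(
            mod for mod in model.modules() if isinstance(mod, BatchNorm2d)
        ):
            m.running_mean[...] = z[f"bn{i}_mean"]
            m.running_var[...] = z[f"bn{i}_var"]
    if "schedule" in header:
        model.schedule = _schedule_from_meta(header["schedule"])
    model.eval()
    return model, header
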