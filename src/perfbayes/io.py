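"""Configuration, file formats and run manifests.

Unit conventions: time in minutes, flows in mL/min/mL, concentrations in
mM.  Dynamic series are stored (t, y, x) — the axis order is recorded in
the file and checked on read, never silently transposed.  All arrays are
float64 internally.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .hbayes import PriorSpec
from .kinetics import SampledCurve
from .phantom import SyntheticSeries

__all__ = [
    "StudyConfig",
    "load_config",
    "save_config",
    "read_series",
    "write_series_npz",
    "write_maps",
    "read_aif_csv",
    "write_aif_csv",
    "write_manifest",
]

AXIS_ORDER = "tyx"


@dataclass(frozen=True)
class PhantomConfig:
    condition: str = "stress_defect"
    dt: float | None = None  # None: 0.012 min at stress, 0.017 at rest
    total_time: float = 3.0
    snr: float = 15.0
    n_realisations: int = 20
    tau0: float = 0.0


@dataclass(frozen=True)
class SamplerConfig:
    steps: int = 4000
    burn_in: int = 1000
    chains: int = 1

    def __post_init__(self) -> None:
        if self.steps <= self.burn_in:
            raise ValueError("steps must exceed burn_in")


@dataclass(frozen=True)
class NLLSConfig:
    n_starts: int = 100
    tol: float = 1e-8
    max_iter: int = 1000


@dataclass(frozen=True)
class EvalConfig:
    methods: tuple = ("bayes", "nlls1", "nlls100")
    conditions: tuple = ("rest", "stress", "stress_defect")


@dataclass(frozen=True)
class StudyConfig:
    """Resolved settings of a full simulation + fitting study."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    prior: PriorSpec = field(default_factory=PriorSpec)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    nlls: NLLSConfig = field(default_factory=NLLSConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)
    master_seed: int = 0
    out_dir: str = "results"


_SECTIONS = {
    "phantom": PhantomConfig,
    "prior": PriorSpec,
    "sampler": SamplerConfig,
    "nlls": NLLSConfig,
    "evaluation": EvalConfig,
}


def _build_section(cls, data: dict, section: str):
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown keys in '{section}': {sorted(unknown)}")
    coerced = {}
    for k, v in data.items():
        if isinstance(v, list):
            v = tuple(v)
        coerced[k] = v
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid value in '{section}': {exc}") from exc


def load_config(path: str | Path) -> StudyConfig:
    """Load a YAML study config; unspecified fields take the defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    top_known = {f.name for f in fields(StudyConfig)}
    unknown = set(data) - top_known
    if unknown:
        raise ValueError(f"unknown top-level keys: {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in data:
            kwargs[name] = _build_section(cls, data[name] or {}, name)
    for scalar in ("master_seed", "out_dir"):
        if scalar in data:
            kwargs[scalar] = data[scalar]
    return StudyConfig(**kwargs)


def save_config(config: StudyConfig, path: str | Path) -> None:
    """Write a config as YAML (lossless round trip through load_config)."""
    data = asdict(config)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def write_series_npz(sim: SyntheticSeries, path: str | Path) -> None:
    """Store a simulated series (clean, noisy, truth maps, AIF) as NPZ."""
    truth = sim.truth
    np.savez(
        path,
        clean=sim.clean,
        noisy=sim.noisy,
        mask=truth.mask,
        times=sim.aif.times,
        aif=sim.aif.values,
        sigma_noise=sim.sigma_noise,
        seed=sim.seed,
        condition=truth.condition,
        axis_order=AXIS_ORDER,
        **{f"truth_{k}": v for k, v in truth.maps.items()},
    )


def read_series(path: str | Path) -> dict:
    """Read a dynamic series (NPZ or NIfTI pair) into a dict.

    Returns at least ``series`` (t, y, x float64), ``mask``, ``times``.
    NPZ files must carry the ``axis_order`` tag written by this package;
    a mismatch is an error, never a silent transposition.
    """
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            if "axis_order" in z.files and str(z["axis_order"]) != AXIS_ORDER:
                raise ValueError(
                    f"axis order {z['axis_order']} does not match expected '{AXIS_ORDER}'"
                )
            if "mask" not in z.files:
                raise ValueError(
                    "no 'mask' in NPZ; save the myocardial mask alongside the series"
                )
            key = "noisy" if "noisy" in z.files else "series"
            out = {
                "series": z[key].astype(float),
                "mask": z["mask"].astype(bool),
                "times": z["times"].astype(float),
            }
            if "aif" in z.files:
                out["aif"] = SampledCurve(out["times"], z["aif"].astype(float))
            return out
    img = nib.load(path)
    descrip = str(img.header["descrip"].astype(str))
    if f"axes={AXIS_ORDER}" not in descrip:
        raise ValueError(
            f"NIfTI descrip {descrip!r} lacks 'axes={AXIS_ORDER}'; refusing to guess axis order"
        )
    mask_path = path.with_name(path.name.replace(".nii", "_mask.nii"))
    if not mask_path.exists():
        raise FileNotFoundError(
            f"mask volume {mask_path} not found; write the binary mask next to the series"
        )
    mask = np.asarray(nib.load(mask_path).dataobj).astype(bool)
    return {"series": np.asarray(img.dataobj, dtype=float), "mask": mask, "times": None}


def write_series_nifti(series: np.ndarray, mask: np.ndarray, path: str | Path) -> None:
    """Write a (t, y, x) series + mask as a NIfTI pair with an axis tag."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(series, dtype=np.float32), affine=np.eye(4))
    img.header["descrip"] = f"axes={AXIS_ORDER}".encode()
    nib.save(img, path)
    mimg = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine=np.eye(4))
    mimg.header["descrip"] = f"axes={AXIS_ORDER[1:]}".encode()
    nib.save(mimg, path.with_name(path.name.replace(".nii", "_mask.nii")))


def write_maps(maps: dict, path: str | Path, csv: bool = True) -> None:
    """Write parameter maps as NPZ (plus a flat CSV summary)."""
    path = Path(path)
    arrays = {k: np.asarray(v, dtype=float) for k, v in maps.items()}
    np.savez(path.with_suffix(".npz"), axis_order="yx", **arrays)
    if csv:
        import pandas as pd

        rows = []
        for k, v in arrays.items():
            for (i, j), val in np.ndenumerate(v):
                rows.append({"parameter": k, "row": i, "col": j, "value": val})
        pd.DataFrame(rows).to_csv(path.with_suffix(".csv"), index=False)


def write_aif_csv(aif: SampledCurve, path: str | Path) -> None:
    """Two-column CSV: time_min, concentration_mM."""
    np.savetxt(
        path,
        np.column_stack([aif.times, aif.values]),
        delimiter=",",
        header="time_min,concentration_mM",
        comments="",
    )


def read_aif_csv(path: str | Path) -> SampledCurve:
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    return SampledCurve(data[:, 0], data[:, 1])


def write_manifest(path: str | Path, config: StudyConfig | dict, **extra) -> None:
    """Record everything needed to reproduce a run (config, seeds, version)."""
    from . import __version__

    payload = {
        "config": asdict(config) if dataclasses.is_dataclass(config) else config,
        "package_version": __version__,
    }
    payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
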