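"""Dataset / image serialization: dense .npy arrays with a JSON sidecar."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .geometry import ImageGrid, SinogramGeometry, build_system_model
from .phantom import PhantomSpec, Ellipse, SimulatedDataset

__all__ = ["save_dataset", "load_dataset", "save_image"]


def save_image(path: Path | str, image: np.ndarray, meta: dict) -> None:
    path = Path(path)
    np.save(path.with_suffix(".npy"), np.asarray(image))
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def save_dataset(outdir: Path | str, ds: SimulatedDataset, spec: PhantomSpec,
                 grid: ImageGrid, geom: SinogramGeometry,
                 resolution_fwhm: float) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, arr in (("y", ds.y), ("r", ds.r), ("x_true", ds.x_true), ("mu", ds.mu)):
        np.save(out / f"{name}.npy", arr)
    np.savez(out / "masks.npz", **{k: v for k, v in ds.masks.items()})
    meta = {
        "grid": {"shape": list(grid.shape), "spacing": list(grid.spacing)},
        "geom": {
            "n_views": geom.n_views,
            "n_radial": geom.n_radial,
            "n_planes": geom.n_planes,
            "radial_spacing": geom.radial_spacing,
        },
        "resolution_fwhm": resolution_fwhm,
        "detection_efficiency": (
            ds.model.detection_efficiency if ds.model is not None else 1.0
        ),
        "true_counts": ds.true_counts,
        "seed": ds.seed,
        "norm_activity": ds.norm_activity,
        "phantom": [
            {
                "center": list(e.center),
                "semi_axes": list(e.semi_axes),
                "rotation_deg": e.rotation_deg,
                "activity": e.activity,
                "is_background": e.is_background,
            }
            for e in spec.ellipses
        ],
        "body_ellipse": spec.body_ellipse,
    }
    (out / "dataset.json").write_text(json.dumps(meta, indent=2))


def load_dataset(indir: Path | str) -> SimulatedDataset:
    """Rebuild a SimulatedDataset (including its system model) from disk."""
    d = Path(indir)
    meta = json.loads((d / "dataset.json").read_text())
    grid = ImageGrid(tuple(meta["grid"]["shape"]), tuple(meta["grid"]["spacing"]))
    g = meta["geom"]
    geom = SinogramGeometry(g["n_views"], g["n_radial"], g["n_planes"], g["radial_spacing"])
    mu = np.load(d / "mu.npy")
    model = build_system_model(grid, geom, mu_image=mu,
                               resolution_fwhm=meta["resolution_fwhm"],
                               detection_efficiency=meta.get("detection_efficiency", 1.0))
    masks = dict(np.load(d / "masks.npz"))
    return SimulatedDataset(
        y=np.load(d / "y.npy"),
        r=np.load(d / "r.npy"),
        x_true=np.load(d / "x_true.npy"),
        mu=mu,
        masks={k: v.astype(bool) for k, v in masks.items()},
        true_counts=meta["true_counts"],
        seed=meta["seed"],
        norm_activity=meta["norm_activity"],
        model=model,
    )
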