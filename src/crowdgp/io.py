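"""Serialization: feature/annotation tables, model directories, masks.

Conventions: annotation tables are delimited text with header
``instance_id,annotator_id,label`` (labels 1..K); reliability matrices are
exported as JSON keyed by annotator id with column-major lists; a model
directory holds JSON metadata, an ``.npz`` of arrays and the ELBO trace as
CSV; masks are single-channel PNG with integer class codes.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .crowd import AnnotationSet, ReliabilityState, TrueLabelPosterior
from .gp import SparseGPState
from .kernels import KernelParams
from .model import FitConfig, SVGPCRModel
from .patches import LabelMask


def read_features(path: str | Path) -> np.ndarray:
    """Feature table: CSV with one row per instance (header optional)."""
    df = pd.read_csv(path)
    return df.to_numpy(dtype=float)


def write_features(X: np.ndarray, path: str | Path) -> None:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    pd.DataFrame(X, columns=[f"x{j}" for j in range(X.shape[1])]).to_csv(
        path, index=False
    )


def read_annotations(path: str | Path, n_classes: int | None = None) -> AnnotationSet:
    return AnnotationSet.from_dataframe(pd.read_csv(path), n_classes=n_classes)


def write_annotations(Y: AnnotationSet, path: str | Path) -> None:
    Y.to_dataframe().to_csv(path, index=False)


def write_reliabilities(matrices: dict[int, np.ndarray], path: str | Path) -> None:
    """Reliability matrices as JSON keyed by annotator id, column-major."""
    payload = {
        str(a): np.asarray(R, dtype=float).flatten(order="F").tolist()
        for a, R in matrices.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_reliabilities(path: str | Path, n_classes: int) -> dict[int, np.ndarray]:
    payload = json.loads(Path(path).read_text())
    return {
        int(a): np.asarray(v, dtype=float).reshape(
            (n_classes, n_classes), order="F"
        )
        for a, v in payload.items()
    }


def save_model(model: SVGPCRModel, model_dir: str | Path) -> None:
    d = Path(model_dir)
    d.mkdir(parents=True, exist_ok=True)
    meta = {
        "n_classes": model.n_classes,
        "n_annotators": model.n_annotators,
        "kernel": {
            "variance": model.gp.kernel.variance,
            "lengthscale": model.gp.kernel.lengthscale,
        },
        "config": asdict(model.config),
    }
    (d / "meta.json").write_text(json.dumps(meta, indent=2))
    np.savez(
        d / "arrays.npz",
        inducing_locations=model.gp.inducing_locations,
        q_mean=model.gp.q_mean,
        q_chol=model.gp.q_chol,
        prior_alpha=model.reliabilities.prior_alpha,
        posterior_alpha=model.reliabilities.posterior_alpha,
        q_z_probs=model.q_z.probs,
        q_z_instances=model.q_z.instance_ids,
    )
    pd.DataFrame({"iteration": np.arange(len(model.trace)), "elbo": model.trace}).to_csv(
        d / "elbo_trace.csv", index=False
    )


def load_model(model_dir: str | Path) -> SVGPCRModel:
    d = Path(model_dir)
    meta = json.loads((d / "meta.json").read_text())
    arrays = np.load(d / "arrays.npz")
    gp = SparseGPState(
        arrays["inducing_locations"],
        arrays["q_mean"],
        arrays["q_chol"],
        KernelParams(**meta["kernel"]),
    )
    rel = ReliabilityState(arrays["prior_alpha"], arrays["posterior_alpha"])
    q_z = TrueLabelPosterior(arrays["q_z_probs"], arrays["q_z_instances"])
    trace = pd.read_csv(d / "elbo_trace.csv")["elbo"].to_numpy()
    return SVGPCRModel(
        gp,
        rel,
        q_z,
        trace,
        FitConfig(**meta["config"]),
        meta["n_classes"],
        meta["n_annotators"],
    )


def read_mask(path: str | Path) -> LabelMask:
    import imageio.v3 as iio

    grid = np.asarray(iio.imread(path))
    if grid.ndim == 3:  # collapse accidental RGB of a paletted export
        grid = grid[..., 0]
    return LabelMask(grid.astype(int), note=str(path))


def write_mask(mask: LabelMask, path: str | Path) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, mask.grid.astype(np.uint8))
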