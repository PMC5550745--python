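"""File formats: masks as 8-bit PNG/TIFF, tables as CSV, models as JSON.

Conventions: masks are written 0=background / 255=foreground with a JSON
sidecar carrying the physical pixel size; CSV is comma-separated UTF-8
with a header row and '.' decimals; every numeric artifact written by the
pipeline carries the master seed and a configuration hash in its sidecar.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .cluster import ZTransform
from .imaging import BinaryCellImage, ImagePipelineError, outline_of
from .morphometrics import DESCRIPTORS
from .tree import MorphotypeTree

__all__ = [
    "write_mask",
    "read_mask",
    "read_cell_image",
    "write_feature_table",
    "load_feature_table",
    "save_tree",
    "load_tree",
    "save_lda",
    "write_result",
]


def write_mask(path: str | Path, cell: BinaryCellImage, sidecar: dict | None = None) -> None:
    """Write the filled mask (and outline alongside) plus a JSON sidecar."""
    path = Path(path)
    filled = (cell.filled_mask.astype(np.uint8)) * 255
    outline = (cell.outline_mask.astype(np.uint8)) * 255
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, filled)
        tifffile.imwrite(path.with_stem(path.stem + "_outline"), outline)
    else:
        iio.imwrite(path, filled)
        iio.imwrite(path.with_stem(path.stem + "_outline"), outline)
    meta = {"pixel_size_um": cell.pixel_size_um}
    meta.update(sidecar or {})
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def _read_gray(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(path)
    else:
        img = iio.imread(path)
    if img.ndim == 3:  # collapse RGB(A) of an 8-bit export
        img = img[..., :3].mean(axis=2)
    return np.asarray(img)


def read_mask(path: str | Path) -> BinaryCellImage:
    """Read a filled-mask image (>=128 is foreground) and rebuild the pair."""
    path = Path(path)
    try:
        img = _read_gray(path)
    except Exception as exc:  # noqa: BLE001
        raise ImagePipelineError(f"cannot read mask {path}: {exc}") from exc
    filled = img >= 128
    sidecar = path.with_suffix(".json")
    pixel_size = 0.115
    if sidecar.exists():
        pixel_size = json.loads(sidecar.read_text()).get("pixel_size_um", pixel_size)
    return BinaryCellImage(filled, outline_of(filled), pixel_size)


def read_cell_image(path: str | Path) -> np.ndarray:
    """Read a grayscale cell crop (TIFF/PNG, 8/16-bit) for preprocessing."""
    path = Path(path)
    try:
        img = _read_gray(path)
    except Exception as exc:  # noqa: BLE001
        raise ImagePipelineError(f"cannot read image {path}: {exc}") from exc
    if img.ndim != 2:
        raise ImagePipelineError(f"{path}: expected a single-channel image")
    return img


def write_feature_table(
    table: pd.DataFrame, path: str | Path, provenance: dict | None = None
) -> None:
    path = Path(path)
    table.to_csv(path)
    if provenance:
        path.with_suffix(".json").write_text(json.dumps(provenance, indent=2, default=str))


def load_feature_table(path: str | Path, require_descriptors: bool = True) -> pd.DataFrame:
    path = Path(path)
    # keep_default_na off: the treatment tag "NA" is data, not a missing value
    table = pd.read_csv(path, index_col=0, keep_default_na=False, na_values=[""])
    if require_descriptors:
        missing = [d for d in DESCRIPTORS if d not in table.columns]
        if missing:
            raise ValueError(f"{path}: missing descriptor column(s) {missing}")
    return table


def save_tree(tree: MorphotypeTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_json())


def load_tree(path: str | Path) -> MorphotypeTree:
    return MorphotypeTree.from_json(Path(path).read_text())


def save_lda(model, ztransform: ZTransform | None, path: str | Path) -> None:
    """Serialize a discriminant model (plus the z-transform) to JSON."""
    payload = {
        "feature_names": list(model.feature_names),
        "classes": model.classes.tolist(),
        "coefficients": model.coefficients.tolist(),
        "constants": model.constants.tolist(),
        "std_coefficients": model.std_coefficients.tolist(),
        "eigenvalues": model.eigenvalues.tolist(),
        "proportion_of_trace": model.proportion_of_trace.tolist(),
        "centroids": model.centroids.to_dict(orient="index"),
        "n": model.n,
    }
    if ztransform is not None:
        payload["z_means"] = ztransform.means.to_dict()
        payload["z_sds"] = ztransform.sds.to_dict()
    Path(path).write_text(json.dumps(payload, indent=2))


def write_result(result, outdir: str | Path) -> None:
    """Write every numeric artifact of a pipeline run (no plots)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = {
        "seed": result.config.seed,
        "config_hash": result.config.config_hash(),
        "config": asdict(result.config),
    }
    write_feature_table(result.features, outdir / "features.csv", prov)
    result.metadata.to_csv(outdir / "metadata.csv")
    result.mmi.to_csv(outdir / "mmi.csv", header=True)
    result.cluster_labels.to_csv(outdir / "cluster_labels.csv")

    cm = result.cluster_model
    np.savetxt(
        outdir / "linkage.txt",
        cm.tree,
        header="left right height size (scipy condensed linkage)",
    )
    (outdir / "clustering.json").write_text(
        json.dumps(
            {
                "selected_descriptors": result.selected,
                "chosen_k": cm.chosen_k,
                "vrc": {int(k): float(v) for k, v in zip(cm.vrc.ks, cm.vrc.curve)},
                "thorndike": {
                    int(k): float(v) for k, v in zip(cm.thorndike.ks, cm.thorndike.curve)
                },
                "thorndike_k": cm.thorndike.chosen_k,
                "vrc_k": cm.vrc.chosen_k,
                "range_constrained": cm.range_constrained,
                **prov,
            },
            indent=2,
        )
    )
    save_lda(result.lda_model, cm.z_transform, outdir / "lda.json")
    (outdir / "lda_summary.json").write_text(
        json.dumps(
            {
                "wilks_lambda": result.wilks.lam,
                "chi2": result.wilks.chi2,
                "df": result.wilks.df,
                "p_value": result.wilks.p_value,
                "loo_accuracy": result.loo_accuracy,
                "proportion_of_trace": result.lda_model.proportion_of_trace.tolist(),
                **prov,
            },
            indent=2,
        )
    )
    result.pca_model.loadings.to_csv(outdir / "pca_loadings.csv")
    (outdir / "pca.json").write_text(
        json.dumps(
            {
                "explained": result.pca_model.explained.tolist(),
                "pc_parameters": list(result.pc_parameters),
                "splits": {
                    str(k): {
                        "descriptor": s.descriptor,
                        "p_value": None if np.isnan(s.p_value) else s.p_value,
                        "test": s.test_name,
                        "validated": s.validated,
                        "n_low": len(s.members_low),
                        "n_high": len(s.members_high),
                    }
                    for k, s in result.splits.items()
                },
                **prov,
            },
            indent=2,
        )
    )
    if result.tree is not None:
        save_tree(result.tree, outdir / "tree.json")
        result.tree_labels.to_csv(outdir / "tree_labels.csv")
        result.type_report.to_csv(outdir / "type_report.csv", index=False)
    result.cluster_report.to_csv(outdir / "cluster_report.csv", index=False)
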