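"""End-to-end pipeline: silhouettes -> descriptors -> morphotypes.

Stage order: measurement of the 15 descriptors per cell, multimodality
screening, z-normalization, Ward clustering with cluster-count selection,
discriminant characterization of the clusters, correlation PCA of the
remaining descriptors with sub-type splits, decision-tree fitting, and
distribution reporting.  Every stochastic step derives its seed from the
single master seed, so a rerun with the same configuration reproduces all
numeric outputs bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as cl
from . import discriminant as lda
from . import pca as pcamod
from . import tree as treemod
from .fractal import BoxCountConfig
from .imaging import BinaryCellImage, DEFAULT_PIXEL_SIZE_UM
from .morphometrics import DESCRIPTORS, compute_vector
from .synthetic import CohortSpec, SyntheticCell, generate_cohort

__all__ = ["PipelineConfig", "PipelineResult", "PipelineError", "measure_cells", "run_pipeline"]

log = logging.getLogger("gliamorph")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage (and cell)."""


@dataclass(frozen=True)
class PipelineConfig:
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    mmi_threshold: float = cl.MMI_THRESHOLD
    k_range: tuple[int, int] = (2, 9)
    seed: int = 42
    boxcount: BoxCountConfig = field(default_factory=BoxCountConfig)
    use_paper_chsr: bool = False  # pin node 1 at the published 1.93 cut
    pc_preset: str | None = None  # "paper" for the published PC descriptor pair
    split_alpha: float = 0.001

    def config_hash(self) -> str:
        payload = asdict(self)
        payload["k_range"] = list(self.k_range)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    features: pd.DataFrame  # cells x 15 descriptors (raw units)
    metadata: pd.DataFrame
    mmi: pd.Series
    selected: list[str]
    cluster_model: cl.ClusterModel
    cluster_labels: pd.Series  # at chosen k, renumbered by size
    lda_model: lda.DiscriminantModel
    wilks: lda.WilksResult
    loo_accuracy: float
    confusion: pd.DataFrame
    pca_model: pcamod.PCAModel
    pc_parameters: tuple[str, str]
    splits: dict[int, pcamod.SubtypeSplit]
    tree: treemod.MorphotypeTree | None
    tree_labels: pd.DataFrame | None
    cluster_report: pd.DataFrame
    type_report: pd.DataFrame | None
    notes: list[str]


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


@_stage("morphometrics")
def measure_cells(
    cells: list[SyntheticCell] | list[BinaryCellImage],
    boxcount: BoxCountConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """15-descriptor table for a list of cells.

    All cells share one grid-offset realization derived from ``seed`` (a
    cohort is measured under a single box-counting protocol); the
    12-placement average inside the estimator is what suppresses
    grid-placement bias.
    """
    boxcount = boxcount or BoxCountConfig()
    sub = int(np.random.SeedSequence([seed, boxcount.rng_seed]).generate_state(1)[0] % (2**31))
    cfg = BoxCountConfig(
        scale_base=boxcount.scale_base,
        min_box_px=boxcount.min_box_px,
        max_box_fraction=boxcount.max_box_fraction,
        n_grid_positions=boxcount.n_grid_positions,
        rng_seed=sub,
    )
    rows = {}
    for i, cell in enumerate(cells):
        image = cell.image if isinstance(cell, SyntheticCell) else cell
        cid = cell.cell_id if isinstance(cell, SyntheticCell) else f"cell_{i:04d}"
        try:
            rows[cid] = compute_vector(image, boxcount=cfg).to_dict()
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage 'morphometrics' failed on cell {cid}: {exc}") from exc
    table = pd.DataFrame.from_dict(rows, orient="index")[list(DESCRIPTORS)]
    table.index.name = "cell_id"
    return table


def run_pipeline(
    source: CohortSpec | tuple[list, pd.DataFrame],
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run every stage on a synthetic cohort or pre-measured inputs.

    ``source`` is either a :class:`CohortSpec` (cells are generated) or a
    ``(cells, metadata)`` pair of BinaryCellImages plus a metadata frame.
    When ``outdir`` is given all numeric artifacts are written there with
    seed and config-hash provenance (see :mod:`gliamorph.io`).
    """
    config = config or PipelineConfig()
    notes: list[str] = []

    if isinstance(source, CohortSpec):
        log.info("stage=simulate n_cells=%d seed=%d", source.n_cells, source.rng_seed)
        cells, metadata = generate_cohort(source)
    else:
        cells, metadata = source
    features = measure_cells(cells, boxcount=config.boxcount, seed=config.seed)
    metadata = metadata.loc[features.index]
    log.info("stage=morphometrics cells=%d descriptors=%d", *features.shape)

    mmis = cl.mmi_table(features)
    selected = cl.select_multimodal(mmis, threshold=config.mmi_threshold)
    log.info("stage=mmi selected=%d threshold=%.2f", len(selected), config.mmi_threshold)
    if len(selected) < 2:
        raise PipelineError(
            "stage 'mmi_selection' failed: fewer than two descriptors exceed "
            f"the MMI threshold {config.mmi_threshold}"
        )

    z, ztf = cl.z_normalize(features[selected])
    model = cl.fit_clusters(z, k_range=config.k_range, z_transform=ztf)
    if model.range_constrained:
        notes.append(f"cluster count range-constrained to k={model.chosen_k}")
    labels = pd.Series(model.labels, index=features.index, name="cluster")
    log.info(
        "stage=hca chosen_k=%d vrc_k=%d thorndike_k=%d",
        model.chosen_k, model.vrc.chosen_k, model.thorndike.chosen_k,
    )

    ldamodel = lda.fit_lda(z, labels.to_numpy(), strict=False)
    wilks = lda.wilks_test(ldamodel)
    acc, confusion = lda.loo_accuracy(z, labels.to_numpy())
    log.info("stage=lda functions=%d loo_accuracy=%.3f", ldamodel.n_functions, acc)

    complement = [d for d in DESCRIPTORS if d not in selected]
    if len(complement) < 2:
        notes.append("fewer than two descriptors left out of clustering; PCA uses all 15")
        complement = list(DESCRIPTORS)
    pca_model = pcamod.fit_pca(features[complement])
    pc_params = pcamod.select_pc_parameters(pca_model, preset=config.pc_preset)
    log.info("stage=pca pc1=%s pc2=%s", *pc_params)

    zfull = (features - features.mean()) / features.std(ddof=1)
    splits: dict[int, pcamod.SubtypeSplit] = {}
    sub_wiring = {1: pc_params[0], 3: pc_params[0], 2: pc_params[1], 4: pc_params[1]}
    for cluster_id in sorted(labels.unique()):
        desc = sub_wiring.get(cluster_id, pc_params[0])
        members = labels.index[labels == cluster_id]
        splits[cluster_id] = pcamod.split_cluster(
            zfull[desc], members, cluster_id, desc, alpha=config.split_alpha
        )

    tree = tree_labels = type_report = None
    if set(labels.unique()) == {1, 2, 3, 4}:
        tree = treemod.fit_thresholds(
            features,
            labels.to_numpy(),
            subtype_descriptors=sub_wiring,
            chsr_threshold=treemod.PAPER_CHSR_THRESHOLD if config.use_paper_chsr else None,
        )
        tree_labels = treemod.classify_table(features, tree)
        type_report = treemod.distribution_report(tree_labels, metadata, level="type")
        log.info("stage=tree training_agreement=%.3f", tree.training_agreement)
    else:
        notes.append(
            f"decision tree skipped: clustering produced k={model.chosen_k}, not 4"
        )
        warnings.warn(notes[-1])

    cluster_report = treemod.distribution_report(
        labels.to_frame(), metadata, level="cluster"
    )

    result = PipelineResult(
        config=config, features=features, metadata=metadata, mmi=mmis,
        selected=selected, cluster_model=model, cluster_labels=labels,
        lda_model=ldamodel, wilks=wilks, loo_accuracy=acc, confusion=confusion,
        pca_model=pca_model, pc_parameters=pc_params, splits=splits,
        tree=tree, tree_labels=tree_labels,
        cluster_report=cluster_report, type_report=type_report, notes=notes,
    )
    if outdir is not None:
        from . import io as gio

        gio.write_result(result, outdir)
    return result
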