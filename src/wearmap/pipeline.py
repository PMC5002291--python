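"""End-to-end study orchestration.

Reproduces the reference-cohort design of a retrieval study: standardize
and right-normalize all wear-scar images, train the SOM on the reference
(postmortem) subset only, delineate clusters on the u-matrix, assign the
held-out (revision / simulator) components to the existing clusters with
no further learning, then run the robustness protocol and the geometric /
statistical characterization, writing every table and a manifest that
suffices to reproduce the run bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import matplotlib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clusters import (ClusterMap, SOMClusterer, assign_clusters,
                       composition_table, delineate_clusters, umatrix)
from .geometry import (anova_by_cluster, cluster_summary, covariate_regression,
                       descriptor_table)
from .images import (STANDARD_SHAPE, WearScarImage, encode_cohort, read_mask,
                     attach_metadata, standardize, to_right_side, write_mask)
from .robustness import retrain_ensemble, robustness_report
from .som import SelfOrganizingMap
from .synthetic import CohortSpec, default_cohort_spec, sample_cohort

log = logging.getLogger("wearmap")

matplotlib.use("Agg")


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    # input: either a synthetic cohort spec, or a directory of masks + CSV
    synthetic: bool = True
    n_postmortem: int = 21
    n_revision: int = 54
    n_simulator: int = 6
    image_dir: str | None = None
    metadata_csv: str | None = None
    # training subset: sources whose components train the map
    training_sources: tuple[str, ...] = ("postmortem",)
    # SOM hyperparameters
    n_rows: int = 12
    n_cols: int = 10
    radius_initial: float = 4.0
    radius_final: float = 1.0
    n_epochs_rough: int = 10
    n_epochs_fine: int = 40
    kernel: str = "gaussian"
    mode: str = "batch"
    # delineation
    method: str = "threshold"
    q: float = 0.5
    merge_tolerance: float = 0.0
    # robustness
    robustness_seeds: tuple[int, ...] = (11, 22, 33)
    # misc
    master_seed: int = 0
    output_dir: str = "wearmap_out"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = (json.loads(text) if path.suffix == ".json"
                else yaml.safe_load(text))
        cfg = cls(**data)
        for fld in ("training_sources", "robustness_seeds"):
            setattr(cfg, fld, tuple(getattr(cfg, fld)))
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["training_sources"] = list(self.training_sources)
        d["robustness_seeds"] = list(self.robustness_seeds)
        return d

    def som_params(self) -> dict:
        return dict(n_rows=self.n_rows, n_cols=self.n_cols,
                    radius_initial=self.radius_initial,
                    radius_final=self.radius_final,
                    n_epochs_rough=self.n_epochs_rough,
                    n_epochs_fine=self.n_epochs_fine,
                    kernel=self.kernel, mode=self.mode)

    def clusterer_params(self) -> dict:
        return {**self.som_params(), "method": self.method, "q": self.q,
                "merge_tolerance": self.merge_tolerance}


def load_cohort(config: RunConfig
                ) -> tuple[list[WearScarImage], pd.DataFrame]:
    """Simulate or ingest the cohort described by the config."""
    if config.synthetic:
        spec = default_cohort_spec(master_seed=config.master_seed,
                                   n_postmortem=config.n_postmortem,
                                   n_revision=config.n_revision,
                                   n_simulator=config.n_simulator)
        return sample_cohort(spec)
    if not config.image_dir:
        raise ValueError("non-synthetic run needs image_dir")
    paths = sorted(Path(config.image_dir).glob("*.p[bn][mg]"))
    images = [read_mask(p) for p in paths]
    if config.metadata_csv:
        meta = pd.read_csv(config.metadata_csv)
        images = attach_metadata(images, meta)
        table = meta
    else:
        table = pd.DataFrame({"component_id": [i.component_id for i in images],
                              "source": [i.source for i in images],
                              "side": [i.side for i in images]})
    return images, table


def preprocess(images: Sequence[WearScarImage]) -> list[WearScarImage]:
    """Standardize to the 220 x 170 canvas and right-normalize."""
    return [to_right_side(standardize(img)) for img in images]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full study and write the report bundle.

    Returns a dict of the in-memory results (model, cluster map,
    assignment table, robustness summary, stats tables).  Identical
    configs produce byte-identical numeric outputs.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        log.info("stage: %s", name)
        return name

    current = stage("load")
    try:
        images, table = load_cohort(config)
        current = stage("preprocess")
        images = preprocess(images)
        img_dir = out / "images"
        img_dir.mkdir(exist_ok=True)
        for img in images:
            write_mask(img, img_dir / f"{img.component_id}.pbm")
        X = encode_cohort(images)
        np.save(out / "encoded.npy", X.astype(np.uint8))

        current = stage("training-subset selection")
        sources = table["source"].to_numpy()
        train_mask = np.isin(sources, config.training_sources)
        if not train_mask.any():
            raise ValueError(
                f"no components from training sources {config.training_sources}")

        current = stage("train")
        clusterer = SOMClusterer(**config.clusterer_params(),
                                 random_state=config.master_seed)
        clusterer.fit(X[train_mask])
        model = clusterer.som_
        model.save(out / "model.npz")

        current = stage("umatrix")
        u = clusterer.umatrix_
        np.savetxt(out / "umatrix.csv", u, delimiter=",")
        _save_umatrix_png(u, out / "umatrix.png")
        cmap = clusterer.clustermap_
        cmap.to_frame().to_csv(out / "clustermap.csv", index=False)

        current = stage("assign")
        assignments = clusterer.predict(X)
        assign_table = table.copy()
        assign_table["cluster"] = assignments
        assign_table["trained_on"] = train_mask
        assign_table.to_csv(out / "assignments.csv", index=False)
        comp = composition_table(assignments, table)
        comp.to_csv(out / "composition.csv")

        current = stage("robustness")
        ensemble = retrain_ensemble(X[train_mask], config.clusterer_params(),
                                    config.robustness_seeds, assign_data=X)
        runs = [a for _, _, a in ensemble]
        rob = robustness_report(runs)
        (out / "robustness.json").write_text(json.dumps(rob, indent=2))

        current = stage("geometry")
        desc = descriptor_table(images)
        stats_table = desc.merge(assign_table, on="component_id")
        desc.to_csv(out / "descriptors.csv", index=False)
        key_descriptors = [
            f"{c}_{m}" for c in ("medial", "lateral")
            for m in ("area_mm2", "perimeter_mm", "ml_stretch_mm",
                      "ap_stretch_mm")]
        cluster_summary(stats_table, key_descriptors).to_csv(
            out / "cluster_summary.csv")
        anova_rows = []
        for d in key_descriptors:
            try:
                f, p = anova_by_cluster(stats_table, d)
                anova_rows.append({"descriptor": d, "F": f, "p": p})
            except ValueError:
                pass
        pd.DataFrame(anova_rows).to_csv(out / "anova.csv", index=False)
        reg_rows = []
        for d in key_descriptors:
            for cov in ("time_in_host", "age_at_surgery"):
                if cov in stats_table:
                    reg_rows.append(covariate_regression(stats_table, d, cov))
        regressions = (pd.concat(reg_rows, ignore_index=True)
                       if reg_rows else pd.DataFrame())
        regressions.to_csv(out / "regressions.csv", index=False)

        current = stage("manifest")
        manifest = {
            "config": config.to_dict(),
            "wearmap_version": __version__,
            "numpy_version": np.__version__,
            "python_version": platform.python_version(),
            "n_components": int(len(images)),
            "n_training": int(train_mask.sum()),
            "n_clusters": int(cmap.n_clusters),
            "quantization_error": model.quantization_error(X[train_mask]),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {current!r}: {exc}") from exc

    return {
        "images": images, "table": assign_table, "model": model,
        "umatrix": u, "clustermap": cmap, "assignments": assignments,
        "composition": comp, "robustness": rob,
        "descriptors": desc, "regressions": regressions,
        "manifest": manifest,
    }


def sensitivity_scan(X_train: np.ndarray,
                     map_dims: Sequence[tuple[int, int]],
                     radius_pairs: Sequence[tuple[float, float]] | None = None,
                     base_config: RunConfig | None = None,
                     seed: int = 0) -> pd.DataFrame:
    """Quantization error of each (map size, radius pair) configuration on
    the training data.

    The selected configuration is the one with the smallest quantization
    error among those yielding at least 2 clusters — an automated proxy
    for requiring a well-defined clustering structure.
    """
    config = base_config or RunConfig()
    if radius_pairs is None:
        radius_pairs = [(config.radius_initial, config.radius_final)]
    combos = [(dims, radii) for dims in map_dims for radii in radius_pairs]
    if not combos:
        raise ValueError("sensitivity scan needs at least one configuration")
    rows = []
    for (r, c), (s0, s1) in combos:
        params = config.clusterer_params()
        params.update(n_rows=r, n_cols=c, radius_initial=s0, radius_final=s1)
        clst = SOMClusterer(**params, random_state=seed).fit(X_train)
        rows.append({
            "map_rows": r, "map_cols": c,
            "radius_initial": s0, "radius_final": s1,
            "quantization_error": clst.som_.quantization_error(X_train),
            "n_clusters": clst.clustermap_.n_clusters,
        })
    df = pd.DataFrame(rows)
    eligible = df[df["n_clusters"] >= 2]
    pool = eligible if len(eligible) else df
    df["selected"] = False
    df.loc[pool["quantization_error"].idxmin(), "selected"] = True
    return df


def _save_umatrix_png(u: np.ndarray, path: Path) -> None:
    """Color-coded u-matrix: light = valley (cluster), dark = ridge."""
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5 * u.shape[0] / max(u.shape[1], 1)))
    im = ax.imshow(u, cmap="gray_r", interpolation="nearest")
    fig.colorbar(im, ax=ax, label="mean neighbor distance")
    ax.set_xlabel("map column")
    ax.set_ylabel("map row")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
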