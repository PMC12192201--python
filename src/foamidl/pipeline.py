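"""End-to-end orchestration: simulate -> propose -> train -> refine -> evaluate.

The p-value map and bag layout are computed from the training portion only;
hold-out subjects never influence patch selection (no test leakage).  Every
stage is seeded from the run seed, and the report JSON contains no paths or
timestamps, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from .amidl import export_attention_csv
from .classifier import BagModel, bag_forward, train
from .config import RunConfig, SynthDataConfig
from .fssa import FSSAConfig, refine_classifier
from .metrics import evaluate, split_holdout
from .patch_proposal import (
    PatchBag,
    build_bag,
    group_ttest_map,
    select_bag_locations,
)
from .synthdata import SyntheticConfig, generate_cohort
from .volio import PatchCoord, ValidationError, Volume3D, read_volume

__all__ = ["default_synthetic_config", "run_pipeline", "save_model", "load_model"]

logger = logging.getLogger("foamidl")


def setup_logging(out_dir: Path | None = None, level: int = logging.INFO) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if out_dir is not None:
        handlers.append(logging.FileHandler(out_dir / "run.log"))
    root = logging.getLogger("foamidl")
    root.setLevel(level)
    root.handlers = handlers
    fmt = logging.Formatter("%(asctime)s %(name)s %(levelname)s: %(message)s")
    for h in handlers:
        h.setFormatter(fmt)


def default_synthetic_config(seed: int = 0, out_dir: str = "run") -> RunConfig:
    """The package's desk-scale reference run.

    48-cube cohort of 60 subjects per group with one 12-cube lesion at
    d = 1.5; bags of the k = 8 most discriminative 12-cubes; a slim
    PatchNet (channels 4-8-8-8) so the whole pipeline trains on one CPU in
    minutes while preserving the full bag/attention structure.
    """
    return RunConfig.model_validate(
        {
            "seed": seed,
            "out_dir": out_dir,
            "patch_proposal": {"width": 12, "k": 8},
            "patchnet": {"channels": (4, 8, 8, 8)},
            "classifier": {"epochs": 40, "patience": 15, "batch_size": 8},
            "fssa": {"n_max": 12, "n_min": 6, "t_max": 30},
        }
    )


def _synth_cfg(cfg: RunConfig) -> SyntheticConfig:
    s = cfg.synthdata
    return SyntheticConfig(
        shape=tuple(s.shape),
        n_per_group=s.n_per_group,
        lesion_regions=[PatchCoord(tuple(s.lesion_origin), s.lesion_width)],
        effect_size=s.effect_size,
        noise_sd=s.noise_sd,
        smoothness=s.smoothness,
        lesion_sign=s.lesion_sign,
        seed=cfg.seed,
    )


def _load_cohort(cfg: RunConfig) -> tuple[list[Volume3D], pd.DataFrame, list[PatchCoord] | None]:
    """Volumes + manifest (+ ground truth if synthetic)."""
    if cfg.manifest is not None:
        df = pd.read_csv(cfg.manifest)
        required = {"subject_id", "path", "label"}
        if not required.issubset(df.columns):
            raise ValidationError(
                f"manifest must have columns {sorted(required)}, got {list(df.columns)}"
            )
        volumes = []
        for row in df.itertuples():
            v = read_volume(row.path)
            v.subject_id = str(row.subject_id)
            volumes.append(v)
        gt_path = Path(cfg.manifest).parent / "ground_truth.csv"
        gt = None
        if gt_path.exists():
            g = pd.read_csv(gt_path)
            gt = [PatchCoord((int(r.ox), int(r.oy), int(r.oz)), int(r.W))
                  for r in g.itertuples()]
        return volumes, df, gt
    logger.info("no manifest given: generating synthetic cohort (seed=%d)", cfg.seed)
    volumes, labels, gt = generate_cohort(_synth_cfg(cfg))
    df = pd.DataFrame(
        {
            "subject_id": [v.subject_id for v in volumes],
            "path": "",
            "label": labels,
        }
    )
    return volumes, df, gt


def _bags_for(
    volumes: dict[str, Volume3D], manifest: pd.DataFrame, spec
) -> list[PatchBag]:
    bags = []
    for row in manifest.itertuples():
        bag = build_bag(volumes[str(row.subject_id)], spec)
        bag.label = int(row.label)
        bags.append(bag)
    return bags


def _class_weights(bags: list[PatchBag], mode: str | None) -> dict | None:
    if mode != "balanced":
        return None
    labels = np.array([b.label for b in bags])
    n = len(labels)
    return {c: n / (2.0 * max(int((labels == c).sum()), 1)) for c in (0, 1)}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full workflow and write all artifacts to ``cfg.out_dir``.

    Returns the evaluation report (also written as ``report.json``).
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    setup_logging(out_dir)
    (out_dir / "config.yaml").write_text(cfg.resolved_yaml())
    logger.info("run seed=%d out_dir=%s", cfg.seed, out_dir)

    stage = "load"
    try:
        volumes, manifest, ground_truth = _load_cohort(cfg)
        by_id = {v.subject_id: v for v in volumes}

        stage = "split"
        train_df, test_df = split_holdout(
            manifest, fraction=cfg.metrics.holdout_fraction, seed=cfg.seed
        )
        # carve a validation set out of the training portion for early
        # stopping and for the FSSA refinement objective
        fit_df, val_df = split_holdout(
            train_df, fraction=1.0 - cfg.classifier.val_fraction, seed=cfg.seed + 1
        )
        logger.info(
            "split: %d fit / %d val / %d held-out", len(fit_df), len(val_df), len(test_df)
        )

        stage = "patch_proposal"
        pp = cfg.patch_proposal
        train_vols = [by_id[str(r.subject_id)] for r in train_df.itertuples()]
        train_labels = train_df["label"].to_numpy()
        group_a = [v for v, y in zip(train_vols, train_labels) if y == 0]
        group_b = [v for v, y in zip(train_vols, train_labels) if y == 1]
        pmap = group_ttest_map(group_a, group_b, pp.width, statistic=pp.statistic)
        pmap.to_csv(out_dir / "pvalue_map.csv")
        spec = select_bag_locations(pmap, pp.k)
        spec.to_csv(out_dir / "bag_spec.csv")

        stage = "bags"
        fit_bags = _bags_for(by_id, fit_df, spec)
        val_bags = _bags_for(by_id, val_df, spec)
        test_bags = _bags_for(by_id, test_df, spec)

        stage = "train"
        cc = cfg.classifier
        model = BagModel.build(
            k=pp.k,
            patch_width=pp.width,
            patchnet_channels=tuple(cfg.patchnet.channels),
            attention_hidden=cfg.amidl.hidden,
            shared_descriptor_mlp=cfg.amidl.shared_descriptor_mlp,
            classifier_channels=tuple(cc.conv_channels),
            ablation_flags=tuple(cc.ablation),
            seed=cfg.seed,
            dtype=np.float32 if cc.dtype == "float32" else np.float64,
        )
        model, history = train(
            model,
            fit_bags,
            val_bags,
            lr=cc.lr,
            epochs=cc.epochs,
            batch_size=cc.batch_size,
            seed=cfg.seed,
            patience=cc.patience,
            class_weights=_class_weights(fit_bags, cc.class_weights),
            weight_decay=cc.weight_decay,
            attention_lr_mult=cc.attention_lr_mult,
            effect_supervision=cc.effect_supervision,
        )
        pd.DataFrame(history).to_csv(out_dir / "history.csv", index=False)
        save_model(model, out_dir / "model.npz")

        stage = "fssa_refine"
        refined = cfg.fssa.enabled and "no_fssa" not in model.ablation_flags
        if refined:
            fs = cfg.fssa
            model, trace = refine_classifier(
                model,
                val_bags,
                FSSAConfig(
                    n_max=fs.n_max, n_min=fs.n_min, t_max=fs.t_max,
                    c_max=fs.c_max, c_min=fs.c_min, gfm_m=fs.gfm_m,
                    seed=cfg.seed, c1_schedule=fs.c1_schedule,
                    sort_chain=fs.sort_chain,
                ),
                radius=fs.radius,
            )
            pd.DataFrame(trace).to_csv(out_dir / "fssa_trace.csv", index=False)
            save_model(model, out_dir / "model.npz")
        else:
            logger.info("FSSA refinement skipped (disabled or no_fssa ablation)")

        stage = "evaluate"
        preds = [bag_forward(b, model) for b in test_bags]
        labels = [b.label for b in test_bags]
        scores = [p.prob_positive for p in preds]
        report_metrics = evaluate(labels, scores, threshold=cfg.metrics.threshold)

        att_dir = out_dir / "attention"
        att_dir.mkdir(exist_ok=True)
        for bag, pred in zip(test_bags, preds):
            if pred.attention is not None:
                export_attention_csv(
                    att_dir / f"{bag.subject_id}.csv", bag.coords, pred.attention
                )

        report = {
            "seed": cfg.seed,
            "n_fit": len(fit_bags),
            "n_val": len(val_bags),
            "n_test": len(test_bags),
            "bag_size": pp.k,
            "patch_width": pp.width,
            "fssa_refined": bool(refined),
            "metrics": report_metrics.to_dict(),
        }
        if ground_truth is not None:
            report["localization"] = _localization_report(
                ground_truth, spec, test_bags, preds
            )
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
        logger.info("report: %s", json.dumps(report_metrics.to_dict(), sort_keys=True))
        return report
    except Exception as e:
        raise type(e)(f"pipeline stage '{stage}' failed: {e}") from e


def _localization_report(ground_truth, spec, test_bags, preds) -> dict:
    """Lesion-recovery summary for synthetic cohorts with known lesions."""
    gt = set(ground_truth)
    rank_first = bool(spec.coords[0] in gt)
    in_bag = any(c in gt for c in spec.coords)
    top_hits, n_pos = 0, 0
    for bag, pred in zip(test_bags, preds):
        if bag.label != 1 or pred.attention is None:
            continue
        n_pos += 1
        top = int(np.argmax(pred.attention.weights))
        if bag.coords[top] in gt:
            top_hits += 1
    return {
        "lesion_ranked_first": rank_first,
        "lesion_in_bag": bool(in_bag),
        "positive_test_bags": n_pos,
        "lesion_top_attention_rate": (top_hits / n_pos) if n_pos else float("nan"),
    }


# ---------------------------------------------------------------------------
# checkpointing


def save_model(model: BagModel, path: str | Path) -> Path:
    """Checkpoint a bag model (architecture meta + all state arrays)."""
    meta = {
        "k": model.k,
        "patch_width": model.patch_width,
        "ablation_flags": sorted(model.ablation_flags),
        "patchnet_channels": list(getattr(model.patchnet, "channels", ())),
        "attention_hidden": model.pooling.descriptor.hidden,
        "shared_descriptor_mlp": model.pooling.descriptor.shared,
        "classifier_channels": [
            model.classifier.conv1.weight.shape[0],
            model.classifier.conv2.weight.shape[0],
        ],
        "dtype": np.dtype(model.dtype).name,
    }
    arrays = {f"arr_{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, meta=json.dumps(meta, sort_keys=True), **arrays)
    return Path(path)


def load_model(path: str | Path) -> BagModel:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        arrays = [z[f"arr_{i}"] for i in range(len(z.files) - 1)]
    model = BagModel.build(
        k=meta["k"],
        patch_width=meta["patch_width"],
        patchnet_channels=tuple(meta["patchnet_channels"]) or (32, 64, 128, 128),
        attention_hidden=meta["attention_hidden"],
        shared_descriptor_mlp=meta["shared_descriptor_mlp"],
        classifier_channels=tuple(meta["classifier_channels"]),
        ablation_flags=tuple(meta["ablation_flags"]),
        dtype=np.dtype(meta["dtype"]),
    )
    model.load_state_arrays(arrays)
    return model
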