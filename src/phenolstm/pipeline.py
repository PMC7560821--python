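"""End-to-end orchestration: simulate → featurize → train → evaluate →
interpret → report, with a reproducibility manifest.

One master seed in the run configuration deterministically derives every
stage seed (via :class:`numpy.random.SeedSequence`), so each stage is
independently reproducible and two runs with identical config produce
hash-identical metrics and relevance JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import yaml

from . import __version__
from .features import assemble_features, standardize
from .interpret import activation_summary, probability_evolution, relevance
from .io import dump_scene_config, load_cube, load_scene, save_cube, save_scene
from .network import load_model, save_model
from .profiles import SceneConfig
from .simulate import generate_scene, split_train_test
from .training import TrainingConfig, evaluate, train

log = logging.getLogger(__name__)

STAGES = ("simulate", "featurize", "train", "evaluate", "interpret", "report")


@dataclass
class RunConfig:
    """Everything one pipeline run needs; maps 1:1 onto the YAML document."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    entropy_window: int = 5
    entropy_bins: int = 16
    train_fraction: float = 0.7
    split_mode: str = "pixel"
    training: TrainingConfig = field(default_factory=TrainingConfig)
    relevance_repeats: int = 10
    noise_fraction: float = 0.03
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "scene" in doc:
            from .io import load_scene_config  # reuse the parser via a temp file
            import tempfile

            with tempfile.NamedTemporaryFile("w", suffix=".yaml", delete=False) as f:
                yaml.safe_dump(doc["scene"], f)
                tmp = f.name
            kwargs["scene"] = load_scene_config(tmp)
            Path(tmp).unlink()
        if "training" in doc:
            kwargs["training"] = TrainingConfig(**doc["training"])
        for k in ("entropy_window", "entropy_bins", "train_fraction", "split_mode",
                  "relevance_repeats", "noise_fraction", "seed"):
            if k in doc:
                kwargs[k] = doc[k]
        return cls(**kwargs)


def _stage_seeds(master_seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(master_seed).generate_state(len(STAGES))
    return {s: int(v % (2 ** 31)) for s, v in zip(STAGES, state)}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(path: Path, text: str) -> None:
    path.write_text(text if text.endswith("\n") else text + "\n")


def run_pipeline(
    config: RunConfig,
    out_dir,
    resume: bool = False,
) -> Path:
    """Execute all stages, writing every artifact plus a RunManifest.

    With ``resume=True``, a stage whose outputs already exist is skipped, so
    deleting a single artifact recomputes only the stages that produce it.
    On stage failure, prior outputs are retained and the manifest records
    the failure point.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "figures").mkdir(exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {
        "software_version": __version__,
        "master_seed": config.seed,
        "stage_seeds": seeds,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
        "outputs": {},
        "failed_stage": None,
    }
    dump_scene_config(config.scene, out / "scene_config.yaml")
    (out / "run_config.yaml").write_text(yaml.safe_dump({
        "entropy_window": config.entropy_window,
        "entropy_bins": config.entropy_bins,
        "train_fraction": config.train_fraction,
        "split_mode": config.split_mode,
        "training": config.training.to_dict(),
        "relevance_repeats": config.relevance_repeats,
        "noise_fraction": config.noise_fraction,
        "seed": config.seed,
    }))

    def stage(name: str, outputs: list[str], fn) -> bool:
        paths = [out / o for o in outputs]
        if resume and all(p.exists() for p in paths):
            log.info("stage %s: outputs present, skipped", name)
            manifest["stages"][name] = {"skipped": True}
            return True
        log.info("stage %s: running", name)
        t0 = time.perf_counter()
        try:
            fn()
        except Exception:
            manifest["failed_stage"] = name
            _finalize_manifest(out, manifest)
            raise
        manifest["stages"][name] = {
            "skipped": False,
            "duration_s": round(time.perf_counter() - t0, 3),
        }
        return True

    # --- simulate -----------------------------------------------------------
    def do_simulate():
        cfg = config.scene
        cfg.seed = seeds["simulate"]
        save_scene(generate_scene(cfg), out / "scene.h5")

    stage("simulate", ["scene.h5"], do_simulate)

    # --- featurize ----------------------------------------------------------
    def do_featurize():
        scene = load_scene(out / "scene.h5")
        cube = assemble_features(scene, config.entropy_window, config.entropy_bins)
        train_idx, test_idx = split_train_test(
            scene, config.train_fraction, config.split_mode, seeds["featurize"]
        )
        train_cube = standardize(cube.subset(train_idx))
        test_cube = standardize(cube.subset(test_idx), (train_cube.mean, train_cube.scale))
        save_cube(train_cube, out / "features_train.h5")
        save_cube(test_cube, out / "features_test.h5")
        np.savez(out / "split.npz", train_idx=train_idx, test_idx=test_idx)

    stage("featurize", ["features_train.h5", "features_test.h5", "split.npz"], do_featurize)

    # --- train --------------------------------------------------------------
    def do_train():
        train_cube = load_cube(out / "features_train.h5")
        tc = config.training
        tc.seed = seeds["train"]
        model, history = train(tc, train_cube)
        save_model(model, out / "model.npz")
        _write_json(out / "history.json", json.dumps(history, indent=2, sort_keys=True))

    stage("train", ["model.npz", "history.json"], do_train)

    # --- evaluate -----------------------------------------------------------
    def do_evaluate():
        model = load_model(out / "model.npz")
        test_cube = load_cube(out / "features_test.h5")
        train_cube = load_cube(out / "features_train.h5")
        report = evaluate(
            model, test_cube,
            n_train=train_cube.n_samples,
            split_mode=config.split_mode,
            seed=config.seed,
        )
        _write_json(out / "metrics.json", report.to_json())
        report.to_table().to_csv(out / "metrics_table.csv", index=False)
        np.savetxt(out / "confusion_matrix.csv", report.confusion_matrix,
                   fmt="%d", delimiter=",",
                   header=",".join(report.class_names), comments="")

    stage("evaluate", ["metrics.json", "metrics_table.csv", "confusion_matrix.csv"],
          do_evaluate)

    # --- interpret ----------------------------------------------------------
    def do_interpret():
        model = load_model(out / "model.npz")
        test_cube = load_cube(out / "features_test.h5")
        for mode in ("predictor", "date"):
            res = relevance(
                model, test_cube, mode=mode,
                n_repeats=config.relevance_repeats,
                noise_fraction=config.noise_fraction,
                seed=seeds["interpret"],
            )
            _write_json(out / f"relevance_{mode}.json", res.to_json())
        summary = activation_summary(model, test_cube, by_class=True)
        _write_json(out / "activations.json", summary.to_json())
        # one representative probability trajectory per class
        trajectories = {}
        y = np.asarray(test_cube.labels, int)
        for k, name in enumerate(model.class_names):
            idx = np.flatnonzero(y == k)
            if idx.size:
                trajectories[name] = probability_evolution(
                    model, test_cube.values[idx[0]]
                ).tolist()
        _write_json(out / "probability_evolution.json",
                    json.dumps(trajectories, indent=2, sort_keys=True))

    stage("interpret", ["relevance_predictor.json", "relevance_date.json",
                        "activations.json", "probability_evolution.json"], do_interpret)

    # --- report -------------------------------------------------------------
    stage("report", ["report.md"], lambda: make_report(out))

    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][str(p.relative_to(out))] = _sha256(p)
    _finalize_manifest(out, manifest)
    return out


def _finalize_manifest(out: Path, manifest: dict) -> None:
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    _write_json(out / "manifest.json", json.dumps(manifest, indent=2, sort_keys=True))


def _fig(path: Path):
    plt.tight_layout()
    plt.savefig(path, dpi=110)
    plt.close()


def make_report(out_dir) -> Path:
    """Render a single human-readable report (markdown + PNG figures) from a
    completed run's artifacts; missing artifacts are flagged, not fatal."""
    out = Path(out_dir)
    figdir = out / "figures"
    figdir.mkdir(exist_ok=True)
    lines = ["# Land-use time-series classification report", ""]
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        m = json.loads(manifest_path.read_text())
        lines += [f"Software version: {m['software_version']}; "
                  f"master seed: {m['master_seed']}", ""]

    metrics_path = out / "metrics.json"
    if metrics_path.exists():
        metrics = json.loads(metrics_path.read_text())
        lines += [f"## Accuracy", "",
                  f"Overall accuracy: **{metrics['overall_accuracy']:.2f}%** "
                  f"on {metrics['n_test']} test samples "
                  f"({metrics['split_mode']} split).", "",
                  "| class | precision (%) | recall (%) | F-1 (%) |",
                  "|---|---|---|---|"]
        for name in metrics["class_names"]:
            pc = metrics["per_class"][name]
            lines.append(
                f"| {name} | {pc['precision']:.1f} | {pc['recall']:.1f} | {pc['f1']:.1f} |"
            )
        lines.append("")
    else:
        lines += ["## Accuracy", "", "*metrics.json missing — stage not run*", ""]

    for mode, items_label in (("predictor", "predictor"), ("date", "acquisition date")):
        path = out / f"relevance_{mode}.json"
        lines.append(f"## Relevance by {items_label}")
        lines.append("")
        if not path.exists():
            lines += [f"*relevance_{mode}.json missing — stage not run*", ""]
            continue
        res = json.loads(path.read_text())
        names, scores = res["item_names"], np.asarray(res["scores"])
        plt.figure(figsize=(8, 3))
        plt.bar(range(len(scores)), scores)
        plt.xticks(range(len(scores)), names, rotation=90, fontsize=6)
        plt.ylabel("normalized relevance")
        _fig(figdir / f"relevance_{mode}.png")
        order = np.argsort(-scores)
        top = ", ".join(f"{names[i]} ({scores[i]:.2f})" for i in order[:4])
        lines += [f"![relevance {mode}](figures/relevance_{mode}.png)", "",
                  f"Most relevant: {top}. Baseline accuracy "
                  f"{res['baseline_accuracy']:.2f}%.", ""]

    act_path = out / "activations.json"
    lines.append("## Hidden-unit activations")
    lines.append("")
    if act_path.exists():
        act = json.loads(act_path.read_text())
        heat = np.asarray(act["heatmap"])
        plt.figure(figsize=(8, 4))
        plt.imshow(heat, aspect="auto", cmap="viridis")
        plt.xlabel("timestep")
        plt.ylabel("hidden unit")
        plt.colorbar(label="mean activation")
        _fig(figdir / "activation_heatmap.png")
        plt.figure(figsize=(8, 3))
        plt.plot(act["mean_squared_by_date"])
        plt.xlabel("timestep")
        plt.ylabel("mean squared activation")
        _fig(figdir / "mean_squared_activations.png")
        if act.get("per_class_curves"):
            plt.figure(figsize=(8, 4))
            for name, curve in act["per_class_curves"].items():
                plt.plot(curve, label=name)
            plt.legend(fontsize=6, ncol=4)
            plt.xlabel("timestep")
            plt.ylabel("mean squared activation")
            _fig(figdir / "per_class_activations.png")
        lines += ["![heatmap](figures/activation_heatmap.png)", "",
                  "![mean squared](figures/mean_squared_activations.png)", ""]
    else:
        lines += ["*activations.json missing — stage not run*", ""]

    prob_path = out / "probability_evolution.json"
    lines.append("## Probability evolution")
    lines.append("")
    if prob_path.exists():
        trajs = json.loads(prob_path.read_text())
        classes = list(trajs)
        for name in classes[: min(4, len(classes))]:
            arr = np.asarray(trajs[name])
            plt.figure(figsize=(6, 3))
            plt.plot(arr)
            plt.title(f"per-timestep class probabilities — {name} pixel")
            plt.xlabel("timestep")
            plt.ylabel("probability")
            _fig(figdir / f"probability_{name}.png")
            lines.append(f"![{name}](figures/probability_{name}.png)")
        lines.append("")
    else:
        lines += ["*probability_evolution.json missing — stage not run*", ""]

    report = out / "report.md"
    report.write_text("\n".join(lines) + "\n")
    return report
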