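"""End-to-end orchestration: seeded stage execution with run manifests.

A single run seed fans out deterministically to per-stage seeds through
``numpy.random.SeedSequence``, and every stage writes a manifest recording
the exact configuration that produced its outputs.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .data import DetectionDataset, write_coco
from .detector import CTCDetector
from .evaluation import bootstrap_metrics
from .fixtures import FixtureConfig, make_detection_dataset, make_patch_bank
from .synthesis import SynthesisConfig, synthesize_dataset

__all__ = ["RunManifest", "run_pipeline", "stage_seeds"]


@dataclass
class RunManifest:
    config: dict
    seeds: dict
    outputs: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)
    version: str = __version__

    def write(self, directory):
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "manifest.json", "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def stage_seeds(run_seed: int, stages=("fixtures", "synth", "train", "eval")) -> dict:
    """Deterministic fan-out of one run seed into per-stage seeds (< 2**31)."""
    ss = np.random.SeedSequence(run_seed)
    children = ss.spawn(len(stages))
    return {name: int(child.generate_state(1)[0] % (2**31))
            for name, child in zip(stages, children)}


def run_pipeline(config: dict, out_dir) -> RunManifest:
    """Run fixtures -> synth -> train -> eval on the tiny profile.

    `config` keys (all optional): seed, fixtures (FixtureConfig overrides),
    synthesis (SynthesisConfig overrides), detector (CTCDetector params),
    n_boot, stages (subset to run).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    seeds = stage_seeds(seed)
    manifest = RunManifest(config=config, seeds=seeds)
    stages = config.get("stages", ["fixtures", "synth", "train", "eval"])

    t0 = time.time()
    fx = FixtureConfig(**{**config.get("fixtures", {}), "seed": seeds["fixtures"]})
    real = make_detection_dataset(fx)
    n_test = max(1, len(real) // 5)
    test = DetectionDataset(real.samples[-n_test:], real.class_names)
    train_ds = DetectionDataset(real.samples[:-n_test], real.class_names)
    write_coco(train_ds, out_dir / "real_train.json")
    write_coco(test, out_dir / "real_test.json")
    manifest.outputs["real_train"] = str(out_dir / "real_train.json")
    manifest.outputs["real_test"] = str(out_dir / "real_test.json")
    manifest.stage_seconds["fixtures"] = time.time() - t0

    synthetic = None
    if "synth" in stages:
        t0 = time.time()
        bank = make_patch_bank(fx, n_patches=config.get("n_patches", 40))
        from .fixtures import make_background
        rng = np.random.default_rng(seeds["synth"])
        backgrounds = [make_background(fx, rng) for _ in range(8)]
        sc = SynthesisConfig(**{**config.get("synthesis", {}), "seed": seeds["synth"]})
        synthetic = synthesize_dataset(bank, backgrounds, sc,
                                       class_names=real.class_names)
        write_coco(synthetic, out_dir / "synthetic.json")
        manifest.outputs["synthetic"] = str(out_dir / "synthetic.json")
        manifest.stage_seconds["synth"] = time.time() - t0

    if "train" in stages:
        t0 = time.time()
        det = CTCDetector(**{**config.get("detector", {}), "seed": seeds["train"]})
        det.fit(train_ds, synthetic=synthetic)
        manifest.stage_seconds["train"] = time.time() - t0

        t0 = time.time()
        report = bootstrap_metrics(det.evaluate(test),
                                   n_boot=int(config.get("n_boot", 200)),
                                   seed=seeds["eval"])
        with open(out_dir / "metrics.json", "w") as fh:
            json.dump({"recall": report.recall, "precision": report.precision,
                       "specificity": report.specificity,
                       "accuracy": report.accuracy, "map50": report.map50,
                       "bootstrap": report.bootstrap}, fh, indent=2)
        manifest.outputs["metrics"] = str(out_dir / "metrics.json")
        manifest.stage_seconds["eval"] = time.time() - t0

    manifest.write(out_dir)
    return manifest
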