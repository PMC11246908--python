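"""End-to-end pipeline driver: phantoms -> train -> predict -> measure.

Plumbing shared by the acceptance tests and the acceptance report script;
not part of the measurement method itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import geometry, keypoints, metrics, phantom
from .segnet import NetworkConfig, TrainConfig, build_network, predict_mask, train


@dataclass
class EndToEndResult:
    history: dict
    dice: dict[str, float]  # mean over test set, per class
    accuracy: dict[str, float]
    pck_table: "object"  # pandas DataFrame, thresholds x landmarks
    parameter_mae: dict[str, float]
    n_test: int
    n_measured: int  # test images that passed the full measurement pipeline


def run_end_to_end(
    n: int = 100,
    epochs: int = 30,
    seed: int = 0,
    population: phantom.PopulationConfig | None = None,
    log=None,
) -> EndToEndResult:
    """Generate ``n`` phantoms (8:1:1), train, and evaluate on the test split.

    PCK is computed at a 3 px threshold (phantom spacing is 1 mm/px); the
    parameter MAE compares the measured ParameterSet of each test phantom
    with its generating ground truth.
    """
    samples, manifest = phantom.generate_dataset(n, population, rng=seed)
    by_split = {
        split: [s for s, sp in zip(samples, manifest["split"]) if sp == split]
        for split in ("train", "val", "test")
    }
    train_set = [(s.image, s.mask) for s in by_split["train"]]
    val_set = [(s.image, s.mask) for s in by_split["val"]]

    model = build_network(
        NetworkConfig(input_size=train_set[0][0].shape, seed=seed)
    )
    history = train(
        model, train_set, TrainConfig(epochs=epochs, seed=seed),
        val_dataset=val_set, log=log,
    )

    dice = {"lumbar": [], "sacrum": []}
    accuracy = {"lumbar": [], "sacrum": []}
    pred_sets, ref_sets = [], []
    abs_errors: dict[str, list[float]] = {
        name: [] for name in geometry.PARAMETER_NAMES
    }
    n_measured = 0
    for sample in by_split["test"]:
        pred = predict_mask(model, sample.image)
        dice["lumbar"].append(metrics.dice_coefficient(pred, sample.mask, 1))
        dice["sacrum"].append(metrics.dice_coefficient(pred, sample.mask, 2))
        accuracy["lumbar"].append(metrics.pixel_accuracy(pred, sample.mask, 1))
        accuracy["sacrum"].append(metrics.pixel_accuracy(pred, sample.mask, 2))
        try:
            kps = keypoints.mask_to_keypoints(
                pred, pixel_spacing=sample.spec.pixel_spacing
            )
            measured = geometry.compute_all_parameters(kps)
        except Exception:  # anatomy/corner failures count against PCK & MAE
            continue
        n_measured += 1
        pred_sets.append(kps)
        truth_kps = geometry.KeyPointSet(
            points={k: sample.keypoints[k] for k in geometry.VOCABULARY},
            pixel_spacing=sample.spec.pixel_spacing,
            anterior_side=sample.spec.anterior_side,
        )
        ref_sets.append(truth_kps)
        for name in geometry.PARAMETER_NAMES:
            abs_errors[name].append(
                abs(getattr(measured, name) - getattr(sample.truth, name))
            )

    n_test = len(by_split["test"])
    pck_table = (
        metrics.pck(pred_sets, ref_sets, thresholds_mm=(1.0, 2.0, 3.0, 4.0, 5.0))
        if pred_sets else None
    )
    # Images that failed measurement contribute zero correct keypoints.
    if pck_table is not None and n_measured < n_test:
        pck_table = pck_table * (n_measured / n_test)
    return EndToEndResult(
        history=history,
        dice={k: float(np.mean(v)) for k, v in dice.items()},
        accuracy={k: float(np.mean(v)) for k, v in accuracy.items()},
        pck_table=pck_table,
        parameter_mae={
            name: (float(np.mean(v)) if v else float("nan"))
            for name, v in abs_errors.items()
        },
        n_test=n_test,
        n_measured=n_measured,
    )
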