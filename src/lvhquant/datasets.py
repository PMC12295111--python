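"""Desk-scale phantom datasets for training and evaluation.

These helpers fix the problem sizes used for in-package learning runs:
64-pixel slices at 2 mm spacing (128 mm field of view), one slice per ring
level, and a reduced-width classifier input. They exist so the command
line, the test-suite and the reproduction script all draw the same study
conditions.
"""

from __future__ import annotations

import numpy as np

from lvhquant.classifier import encode_subsegment
from lvhquant.phantom import PhantomSpec, make_cohort


def desk_phantom_spec(noise_sd: float = 0.02) -> PhantomSpec:
    """Phantom geometry small enough for CPU training runs.

    Pixel spacing stays at the clinical 1.25 mm (sub-pixel wall differences
    survive through partial-volume gray levels); the 20 mm cavity keeps the
    widest severe wall (32 mm) inside the reduced 120 mm field of view.
    """
    return PhantomSpec(
        image_size=96,
        pixel_spacing=1.25,
        cavity_radius=20.0,
        n_slices_per_level=1,
        noise_sd=noise_sd,
    )


def phantom_segmentation_cases(
    n_slices: int = 40,
    seed: int = 0,
    noise_sd: float = 0.0,
    severity_mix=(0.25, 0.25, 0.25, 0.25),
):
    """(image, myocardium mask) pairs from ring slices of a phantom cohort.

    Profiles vary per patient through the severity mix, so the segmenter
    sees thin and thick walls. Apex slices are excluded: the segmentation
    study concerns the annular myocardium.
    """
    base = desk_phantom_spec(noise_sd=noise_sd)
    n_patients = int(np.ceil(n_slices / 3))
    cohort = make_cohort(n_patients, severity_mix=severity_mix, seed=seed, base_spec=base)
    cases = []
    for stack, truth in cohort:
        for img, mask, label in zip(stack.slices, truth.masks, stack.level_labels):
            if label == "apex":
                continue
            cases.append((img, mask.astype(float)))
    return cases[:n_slices]


def phantom_classification_dataset(
    n_patients: int = 30,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
    regions_per_patient: int = 24,
    severity_mix=(0.25, 0.25, 0.25, 0.25),
    out_size: int = 64,
):
    """Sector-encoded (input, threshold-label) pairs from a phantom cohort.

    A balanced severity mix is used so every class is represented in the
    stratified splits; ``regions_per_patient`` ring regions are sampled per
    phantom to keep the dataset CPU-sized. Labels are the threshold scores
    of the analytic regional thickness, making the classifier a learned
    surrogate of the threshold scorer.
    """
    base = base_spec or desk_phantom_spec()
    cohort = make_cohort(n_patients, severity_mix=severity_mix, seed=seed, base_spec=base)
    rng = np.random.default_rng(seed + 1)
    dataset = []
    for stack, truth in cohort:
        ring_bins = [b for b in truth.partition.bins if b.level != "apex"]
        chosen = rng.choice(len(ring_bins), size=min(regions_per_patient, len(ring_bins)),
                            replace=False)
        level_to_slice = {lvl: k for k, lvl in enumerate(stack.level_labels)}
        for j in chosen:
            b = ring_bins[j]
            sc = truth.contours.slices[level_to_slice[b.level]]
            img = stack.slices[level_to_slice[b.level]]
            x = encode_subsegment(img, truth.partition, b.region_id, sc,
                                  truth.landmarks, out_size=out_size)
            dataset.append((x, truth.severity_truth[b.region_id]))
    return dataset
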