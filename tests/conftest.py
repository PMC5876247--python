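"""Shared fixtures.

The expensive multi-seed study batch (used by the source-recovery and
end-to-end detection tests) is computed once per session; each per-seed entry
stores only small summary records, not the raw epochs or inverters.
"""

from __future__ import annotations

import numpy as np
import pytest

from erpsource import (BmaSourceModel, WindowSpec, binarize_lfdr,
                       build_head_model, build_montage, build_source_space,
                       compute_lead_field, extract_feature, generate_study,
                       permutation_threshold)
from erpsource.inverse import FeatureVector

N_BATCH_SEEDS = 20
BATCH_PERMUTATIONS = 1000


@pytest.fixture(scope="session")
def head():
    return build_head_model()


@pytest.fixture(scope="session")
def montage():
    return build_montage("paper60")


@pytest.fixture(scope="session")
def small_space():
    return build_source_space(n_generators=200, n_compartments=8, seed=3)


@pytest.fixture(scope="session")
def small_leadfield(head, montage, small_space):
    return compute_lead_field(head, montage, small_space)


@pytest.fixture(scope="session")
def paper_study():
    """One full-size synthetic study (28 subjects, 60 channels, 40 trials)."""
    return generate_study("paper_like", 7)


def _seed_record(seed: int) -> dict:
    """All per-seed quantities the multi-seed tests assert on."""
    erps, info = generate_study("paper_like", seed)
    space, mont = info["space"], info["montage"]
    labels = space.compartment_labels
    gt = info["compartments"]
    t = erps.times_ms
    win = (t >= 330) & (t <= 440)

    # sensor-level planted-sign check at the channel nearest the N400 source
    ga = erps.data.mean(axis=0)
    diff = (ga[1] - ga[0])[:, win].mean(axis=1)     # intra mismatch - match
    cen = space.compartment_centroid(gt["N400_intra"])
    ch = int(np.argmax(mont.positions @ (cen / np.linalg.norm(cen))))
    sensor_sign_ok = bool(diff[ch] < 0)

    lf = compute_lead_field(info["head"], mont, space)
    inverter = BmaSourceModel(lf, space, max_size=2)

    # grand-average N400 mismatch feature -> compartment recovery
    grand = FeatureVector(
        values=erps.data[:, 1][:, :, win].mean(axis=(0, 2)),
        subject=-1, condition="intra_mismatch", component="N400")
    ism = inverter.invert(grand)
    sums = np.array([ism.magnitudes[labels == k].sum() for k in sorted(space.atlas)])
    recovery_argmax = int(np.argmax(sums))

    # per-subject N400 inversion in both tasks -> difference-map localization
    spec = WindowSpec("N400", 330.0, 440.0,
                      conditions=("intra_mismatch", "cross_mismatch"))
    bins = {"intra_mismatch": [], "cross_mismatch": []}
    for f in extract_feature(erps, spec):
        bins[f.condition].append(binarize_lfdr(inverter.invert(f)))
    dm = permutation_threshold(bins["intra_mismatch"], bins["cross_mismatch"],
                               n_iter=BATCH_PERMUTATIONS, q=0.05, seed=seed)
    masked = labels[dm.mask]
    union = {gt["N400_intra"], gt["N400_cross"]}
    frac = float(np.isin(masked, list(union)).mean()) if masked.size else 0.0
    return {
        "seed": seed,
        "sensor_sign_ok": sensor_sign_ok,
        "recovery_argmax": recovery_argmax,
        "n400_intra_label": gt["N400_intra"],
        "n400_cross_label": gt["N400_cross"],
        "n_masked": int(masked.size),
        "frac_masked_in_planted": frac,
    }


@pytest.fixture(scope="session")
def paper_batch():
    """Per-seed summary records over the multi-seed paper-like batch."""
    return [_seed_record(1000 + s) for s in range(N_BATCH_SEEDS)]
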