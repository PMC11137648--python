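"""Shared fixtures: phantom cohorts and reference models trained on them.

Everything is generated at test time from seeds; the heavier cohorts and
trained models are session-scoped so the whole suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from spinedss import diagnosis as dx
from spinedss import pfirrmann as pf
from spinedss import phantom as ph


@pytest.fixture(scope="session")
def disc_cohort():
    """100 sagittal phantoms x 5 discs: features, grades, ROIs, herniation flags.

    Each phantom carries all five Pfirrmann grades in a random order and
    random herniation flags, so both classification tasks see balanced,
    seed-reproducible data (100 discs per grade, roughly half herniated).
    """
    rng = np.random.default_rng(42)
    feats, grades, rois, herniated = [], [], [], []
    for i in range(100):
        cfg = ph.PhantomConfig(seed=10_000 + i)
        perm = rng.permutation(5) + 1
        herns = rng.random(5) < 0.5
        specs = [
            ph.DiscGroundTruth(
                level_index=j + 1,
                herniated=bool(h),
                pfirrmann=int(g),
                msu_size=2 if h else None,
                msu_zone="A" if h else None,
            )
            for j, (g, h) in enumerate(zip(perm, herns))
        ]
        p = ph.generate_sagittal(cfg, specs)
        pts = p.vertebra_centers
        for (p0, p1), d in zip(zip(pts[:-1], pts[1:]), specs):
            patch = pf.crop_pfirrmann_roi(p.image, p0, p1)
            feats.append(pf.build_feature_vector(patch).values)
            grades.append(d.pfirrmann)
            rois.append(dx.crop_disc_roi(p.image, p0, p1))
            herniated.append(d.herniated)
    return {
        "features": np.asarray(feats),
        "grades": np.asarray(grades),
        "rois": rois,
        "herniated": np.asarray(herniated),
    }


@pytest.fixture(scope="session")
def holdout_mask():
    """375 train / 125 held-out discs, interleaved so grades stay balanced."""
    return np.arange(500) % 4 != 3


@pytest.fixture(scope="session")
def pfirrmann_model(disc_cohort, holdout_mask):
    return pf.train_pfirrmann(
        disc_cohort["features"][holdout_mask],
        disc_cohort["grades"][holdout_mask],
        pf.MlpConfig(seed=0),
    )


@pytest.fixture(scope="session")
def diagnosis_model(disc_cohort, holdout_mask):
    rois = [r for r, m in zip(disc_cohort["rois"], holdout_mask) if m]
    labels = disc_cohort["herniated"][holdout_mask]
    return dx.train_diagnosis_model(rois, labels, seed=0)
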