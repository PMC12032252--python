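import numpy as np
import pandas as pd
import pytest

from hbscreen.synthetic_data import (
    CONTROL_MODEL_ID,
    ImageSimConfig,
    make_fixture_screen,
    synthesize_image,
)


@pytest.fixture(scope="session")
def fixture_screen():
    """Deterministic zero-noise 24-compound screen with planted truth."""
    return make_fixture_screen()


@pytest.fixture(scope="session")
def scored_fixture(fixture_screen):
    from hbscreen.pipeline import score_screen

    maps, raws, truth = fixture_screen
    results, qc = score_screen(maps, raws, CONTROL_MODEL_ID)
    return results, qc, truth


@pytest.fixture(scope="session")
def nuclei_field():
    """20 well-separated ellipse nuclei (60-120 px) in a 1024x1024 field."""
    cfg = ImageSimConfig(
        field_shape=(1024, 1024), n_cells=20, nucleus_diameter_range=(60, 120), seed=3
    )
    img, truth = synthesize_image(cfg)
    return cfg, img, truth.image


@pytest.fixture(scope="session")
def phenotype_features():
    """Per-cell features of normal vs fragmented fields on two 'plates'."""
    from hbscreen.cell_painting import extract_features

    tables = []
    seed = 0
    for model in ("HB-A", "HB-B"):
        for treat, pheno in (("DMSO", "normal"), ("drug", "fragmented")):
            img, truth = synthesize_image(
                ImageSimConfig(
                    field_shape=(512, 512), n_cells=8,
                    nucleus_diameter_range=(42, 70), phenotype=pheno, seed=seed,
                )
            )
            seed += 1
            t = truth.image
            tables.append(
                extract_features(
                    img, t.nuclei_mask, t.cell_mask,
                    metadata={"plate": model, "well": "A01",
                              "treatment": treat, "model": model},
                )
            )
    return pd.concat(tables, ignore_index=True)
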