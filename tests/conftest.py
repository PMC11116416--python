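import numpy as np
import pytest
from PIL import Image

from pelletox.dose_response import CONTROL, BioassayDataset, Vial


@pytest.fixture
def solid_png(tmp_path):
    """Factory writing a small solid-color PNG (RGBA, fully opaque)."""

    def _make(color, name="solid.png", size=(8, 8)):
        arr = np.zeros((size[1], size[0], 4), dtype=np.uint8)
        arr[..., :3] = color
        arr[..., 3] = 255
        path = tmp_path / name
        Image.fromarray(arr, "RGBA").save(path)
        return path

    return _make


@pytest.fixture
def assay_from_shifts():
    """Factory building a 4-dilution assay with chosen group mean shifts.

    ``shifts`` maps dilution -> shift in units of the within-vial SD
    (10 um) relative to the control mean increase of 300 um.
    """

    def _make(shifts, seed=7, sd=10.0, n_vials=4, n_larvae=35, egg=95.0,
              fert=98.0, control_increase=300.0):
        rng = np.random.default_rng(seed)
        vials = [
            Vial(f"c{i}", CONTROL,
                 egg + control_increase + rng.normal(0, sd, n_larvae))
            for i in range(n_vials)
        ]
        for d, shift in shifts.items():
            for i in range(n_vials):
                vials.append(
                    Vial(
                        f"d{d:g}_{i}",
                        d,
                        egg + control_increase + shift * sd
                        + rng.normal(0, sd, n_larvae),
                    )
                )
        return BioassayDataset("assay", egg, fert, vials)

    return _make
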