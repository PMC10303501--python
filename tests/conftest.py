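import numpy as np
import pytest

from phenofuse.segmentation import segment_scan
from phenofuse.synthetic import generate_phenotypes, render_scan


@pytest.fixture(scope="session")
def phenos5():
    """Five well-separated class phenotypes."""
    return generate_phenotypes(5, rng_seed=2)[0]


@pytest.fixture(scope="session")
def seed_scan(phenos5):
    """One seed scan with ground truth (6 objects)."""
    return render_scan(phenos5[0], "seed", 6, rng_seed=11, scan_id="s11")


@pytest.fixture(scope="session")
def pod_scan(phenos5):
    return render_scan(phenos5[1], "pod", 5, rng_seed=12, scan_id="p12")


@pytest.fixture(scope="session")
def object_bank(phenos5):
    """Normalized object images per organ: {organ: (images, labels)}."""
    bank = {}
    for organ in ("seed", "pod"):
        imgs, labs = [], []
        for s in range(15):
            k = s % 5
            scan, _ = render_scan(phenos5[k], organ, 4,
                                  rng_seed=s + (1000 if organ == "pod" else 0),
                                  scan_id=f"bank{s}")
            for obj in segment_scan(scan):
                imgs.append(obj.pixels)
                labs.append(k)
        bank[organ] = (imgs, np.asarray(labs))
    return bank


@pytest.fixture(scope="session")
def color_blobs():
    """A linearly separable 3-class image set: solid colors plus noise."""
    rng = np.random.default_rng(7)
    colors = [(200, 60, 60), (60, 200, 60), (60, 60, 200)]
    images, labels = [], []
    for i in range(75):
        k = i % 3
        img = np.clip(rng.normal(colors[k], 12, size=(64, 64, 3)), 0, 255)
        images.append(img.astype(np.uint8))
        labels.append(k)
    return images, np.asarray(labels)
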