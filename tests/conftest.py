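import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """One shared mid-size synthetic cohort with ground truth."""
    from carotid_gsm.synthetic_data import generate_cohort

    table, truth = generate_cohort(n=20000, seed=101)
    return table, truth


@pytest.fixture()
def composition_table():
    """Tiny unit-normalized composition table: closed-form worked examples."""
    items = ["bread", "apple", "milk", "beef", "soda"]
    return pd.DataFrame(
        {
            "energy_kcal": [2.5, 0.5, 0.6, 2.0, 0.4],
            "saturated_fat_g": [0.002, 0.0, 0.01, 0.03, 0.0],
            "total_fat_g": [0.01, 0.0, 0.035, 0.15, 0.0],
            "sodium_mg": [5.0, 0.0, 0.4, 0.7, 0.1],
            "grains_servings": [0.02, 0.0, 0.0, 0.0, 0.0],
            "fruits_servings": [0.0, 0.008, 0.0, 0.0, 0.0],
            "dairy_servings": [0.0, 0.0, 0.004, 0.0, 0.0],
            "meat_servings": [0.0, 0.0, 0.0, 0.01, 0.0],
            "sweets_servings": [0.0, 0.0, 0.0, 0.0, 0.003],
        },
        index=pd.Index(items, name="item"),
    )


def brute_force_point_in_polygon(px, py, vertices):
    """Scalar even-odd ray-casting oracle, independent of the package."""
    inside = False
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            x_cross = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_cross:
                inside = not inside
    return inside


def brute_force_median3x3(img):
    """Per-pixel sorted-neighborhood median with reflected borders."""
    img = np.asarray(img)
    h, w = img.shape
    out = np.empty_like(img)
    for r in range(h):
        for c in range(w):
            vals = []
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    rr = -rr - 1 if rr < 0 else (2 * h - rr - 1 if rr >= h else rr)
                    cc = -cc - 1 if cc < 0 else (2 * w - cc - 1 if cc >= w else cc)
                    vals.append(img[rr, cc])
            out[r, c] = sorted(vals)[4]
    return out
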