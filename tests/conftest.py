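"""Shared geometric fixtures: masks are built programmatically so every
expected value has a closed form or a brute-force oracle next to it."""

from __future__ import annotations

import numpy as np
import pytest

from morphorank.mask_io import CellImage

FIELD = 300


def make_cell(mask: np.ndarray, id: str = "test", standardized: bool = True) -> CellImage:
    return CellImage(id, mask.astype(np.uint8), 0.5, standardized=standardized)


def disk_mask(radius: float, field: int = FIELD, center: tuple[int, int] | None = None) -> np.ndarray:
    if center is None:
        center = (field // 2, field // 2)
    yy, xx = np.mgrid[:field, :field]
    return ((yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2)


def square_mask(side: int, field: int = FIELD) -> np.ndarray:
    m = np.zeros((field, field), dtype=bool)
    o = (field - side) // 2
    m[o : o + side, o : o + side] = True
    return m


def bar_mask(length: int = 100, thickness: int = 3, field: int = FIELD) -> np.ndarray:
    m = np.zeros((field, field), dtype=bool)
    r0 = field // 2 - thickness // 2
    c0 = (field - length) // 2
    m[r0 : r0 + thickness, c0 : c0 + length] = True
    return m


def plus_mask(arm: int = 61, field: int = FIELD) -> np.ndarray:
    """Two 1-px bars of `arm` pixels crossing at the field center."""
    m = np.zeros((field, field), dtype=bool)
    c = field // 2
    half = arm // 2
    m[c, c - half : c + half + 1] = True
    m[c - half : c + half + 1, c] = True
    return m


def star_mask(
    n_arms: int = 5, soma_radius: int = 8, arm_length: int = 50, field: int = FIELD
) -> np.ndarray:
    """Disk soma with straight 1-px arms radiating at equal angles."""
    m = disk_mask(soma_radius, field=field)
    c = field // 2
    for k in range(n_arms):
        a = 2 * np.pi * k / n_arms
        for t in np.linspace(0.0, arm_length, 4 * arm_length):
            r = int(round(c + (soma_radius - 1 + t) * np.sin(a)))
            cc = int(round(c + (soma_radius - 1 + t) * np.cos(a)))
            m[r, cc] = True
    return m


@pytest.fixture
def disk_cell() -> CellImage:
    return make_cell(disk_mask(40), id="disk40")
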