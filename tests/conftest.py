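"""Shared fixtures: synthetic pads at reduced resolution for unit tests."""

from __future__ import annotations

import numpy as np
import pytest

from sudoquant.synth import LabelledPad, PadSceneConfig, generate_pad, write_pad_png


@pytest.fixture
def make_pad():
    """Factory for labelled synthetic pads (default 300 dpi to keep unit
    tests fast; acceptance tests use the full 600 dpi protocol)."""

    def _make(
        fraction: float = 0.5,
        seed: int = 0,
        dpi: float = 300.0,
        noisy: bool = True,
        pattern: str = "uniform-mix",
    ) -> LabelledPad:
        cfg = PadSceneConfig(
            true_pink_fraction=fraction, seed=seed, dpi=dpi, pattern=pattern
        )
        if not noisy:
            cfg = cfg.noise_free()
        return generate_pad(cfg)

    return _make


@pytest.fixture
def pad_png(tmp_path, make_pad):
    """Write a default noisy pad to disk; returns (path, labelled_pad)."""
    pad = make_pad()
    path = tmp_path / "pad.png"
    write_pad_png(pad, path)
    return path, pad


def iou(a: np.ndarray, b: np.ndarray) -> float:
    return float((a & b).sum()) / float((a | b).sum())
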