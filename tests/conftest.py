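"""Shared fixtures: randomized in-memory scans and one small synthetic slide."""

from __future__ import annotations

import math

import numpy as np
import pytest

from glyarray import (ChannelFeatures, FixtureConfig, ScanResult, SpotRecord,
                      generate)


def random_scan(rng: np.random.Generator, *, allow_nan: bool = True) -> ScanResult:
    """A structurally valid random ScanResult (for roundtrip properties)."""
    channels = sorted(rng.choice([488, 532, 594, 635], size=rng.integers(1, 3),
                                 replace=False).tolist())
    n_blocks = int(rng.integers(1, 3))
    rows, cols = int(rng.integers(1, 4)), int(rng.integers(1, 4))
    spots = []
    for b in range(1, n_blocks + 1):
        for r in range(1, rows + 1):
            for c in range(1, cols + 1):
                feats = {}
                for wl in channels:
                    vals = rng.uniform(-100, 60000, size=4)
                    if allow_nan and rng.random() < 0.05:
                        vals[int(rng.integers(0, 4))] = math.nan
                    feats[wl] = ChannelFeatures(*[float(v) for v in vals])
                spots.append(SpotRecord(
                    block=b, row=r, column=c,
                    name=f"probe {b}-{r}-{c}", probe_key=f"PK{b}_{r}_{c}",
                    channel_features=feats,
                    flags=int(rng.choice([0, 0, 0, -50, -75, -100])),
                    x_um=float(rng.integers(0, 20000)) if rng.random() < 0.5 else None,
                    y_um=float(rng.integers(0, 20000)) if rng.random() < 0.5 else None))
    # x/y columns are all-or-nothing in a real GPR table
    if any(s.x_um is None and s.y_um is None for s in spots):
        for s in spots:
            s.x_um = s.y_um = None
    return ScanResult(
        slide_id="rand-slide", channels=channels, spots=spots,
        header_meta={"SlideID": "rand-slide", "PMTGain": str(int(rng.integers(300, 800))),
                     "Temperature": "23.5"})


@pytest.fixture(scope="session")
def small_slide(tmp_path_factory):
    """A 30-probe, 4-replicate noise-free-ish slide shared across tests."""
    cfg = FixtureConfig.default(n_probes=30, replicates=4, seed=3,
                                noise_cv=0.05)
    return generate(cfg, tmp_path_factory.mktemp("slide"))
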