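"""Synthetic slide generator: matched GAL + GPR + probe list with ground truth.

Every test and acceptance run works from slides generated here, so no
external scanner files are needed.  The generator emulates one fluorescence
channel of a printed glycan array:

* each probe has a true binding intensity (a.u.); its replicate spots read
  ``true · LN(1, noise_cv) + background_level`` where ``LN(1, cv)`` is a
  lognormal factor with mean 1 — fluorescence is positive and right-skewed,
  so multiplicative lognormal noise is the realistic choice;
* background features read ``background_level · LN(1, noise_cv/2)``;
* with probability ``outlier_prob`` a spot's foreground is multiplied by
  ``outlier_factor`` (simulating dust / comet artifacts);
* with probability ``flagged_prob`` a spot carries GenePix flag −100.

Foreground mean and median are drawn independently (real scanners report
correlated but distinct pixel statistics).  Output is deterministic given
the seed, down to the bytes of the emitted files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import ArrayGeometry, Quantity, SpotAssignment, write_gal, EMPTY_KEY
from .glycans import GlycanProbe, write_probe_csv
from .scan_io import ChannelFeatures, ScanResult, SpotRecord, write_gpr

__all__ = ["ProbeSpec", "FixtureConfig", "GeneratedSlide", "generate",
           "DEFAULT_SEQUENCE_PANEL"]

#: CFG-IUPAC sequences cycled over generated probes: lactose-core glycans,
#: sialylated and fucosylated antigens, O-glycan cores, plain oligomers.
DEFAULT_SEQUENCE_PANEL = [
    "Galb-4Glcb",                          # lactose
    "NeuAca-3Galb-4Glcb",                  # 3'-sialyllactose (lactose core)
    "NeuAca-6Galb-4Glcb",                  # 6'-sialyllactose (lactose core)
    "Gala-4Galb-4Glcb",                    # globotriose (lactose core)
    "Galb-4GlcNAcb",                       # LacNAc type 2
    "Galb-3GlcNAcb",                       # LacNAc type 1
    "NeuAca-3Galb-4GlcNAcb",               # 3'-sialyl LacNAc
    "NeuAca-6Galb-4GlcNAcb",               # 6'-sialyl LacNAc
    "Galb-4(Fuca-3)GlcNAcb",               # Lewis x
    "Galb-3(Fuca-4)GlcNAcb",               # Lewis a
    "NeuAca-3Galb-4(Fuca-3)GlcNAcb",       # sialyl-Lewis x
    "Fuca-2Galb-4GlcNAcb",                 # H type 2
    "Fuca-2Galb-3GlcNAcb",                 # H type 1
    "GalNAca-3(Fuca-2)Galb-4GlcNAcb",      # blood group A
    "Gala-3(Fuca-2)Galb-4GlcNAcb",         # blood group B
    "Gala-3Galb-4GlcNAcb",                 # linear B
    "Galb-3GalNAca",                       # T antigen
    "GlcNAcb-3GalNAca",                    # core 3
    "Galb-3(GlcNAcb-6)GalNAca",            # core 2
    "GlcNAcb-4GlcNAcb",                    # chitobiose
    "Mana-3(Mana-6)Manb-4GlcNAcb-4GlcNAcb",  # trimannosyl core
    "Glca-4Glcb",                          # maltose
    "Glcb-4Glcb",                          # cellobiose
    "Xylb-4Xylb",                          # xylobiose
    "GlcAb-3GlcNAcb",                      # hyaluronan unit
]


@dataclass
class ProbeSpec:
    probe_key: str
    sequence: str  # CFG-IUPAC
    true_intensity: float  # a.u.
    concentration: Quantity | None = None
    tag_name: str = "NGL"


@dataclass
class FixtureConfig:
    """Study conditions of one simulated slide."""

    probes: list[ProbeSpec]
    n_blocks: int = 4
    block_rows: int = 10
    block_cols: int = 10
    replicates_per_probe: int = 4
    noise_cv: float = 0.1
    background_level: float = 50.0
    outlier_prob: float = 0.0
    outlier_factor: float = 10.0
    flagged_prob: float = 0.0
    channel: int = 532
    slide_id: str = "synthetic-slide"
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.outlier_prob, self.flagged_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        total = len(self.probes) * self.replicates_per_probe
        capacity = self.n_blocks * self.block_rows * self.block_cols
        if total > capacity:
            raise ValueError(
                f"layout capacity {capacity} < {total} required spots")

    @classmethod
    def default(cls, n_probes: int = 200, replicates: int = 4, seed: int = 0,
                **overrides) -> "FixtureConfig":
        """Standard panel: ``n_probes`` probes cycling the sequence panel,
        true intensities log-uniform in [500, 50000] a.u., 50 µM spots."""
        rng = np.random.default_rng(seed)
        probes = []
        for i in range(n_probes):
            seq = DEFAULT_SEQUENCE_PANEL[i % len(DEFAULT_SEQUENCE_PANEL)]
            true = float(10 ** rng.uniform(math.log10(500), math.log10(50000)))
            probes.append(ProbeSpec(
                probe_key=f"P{i + 1:04d}", sequence=seq, true_intensity=true,
                concentration=Quantity(50, "µM"),
                tag_name="Cer32" if i % 2 == 0 else "AD"))
        spots = n_probes * replicates
        n_blocks = overrides.pop("n_blocks", 4)
        cols = overrides.pop("block_cols", 10)
        rows = overrides.pop("block_rows",
                             max(1, -(-spots // (n_blocks * cols))))
        return cls(probes=probes, replicates_per_probe=replicates, seed=seed,
                   n_blocks=n_blocks, block_rows=rows, block_cols=cols,
                   **overrides)


@dataclass
class GeneratedSlide:
    gal_path: Path
    gpr_path: Path
    probe_csv_path: Path
    truth_path: Path
    geometry: ArrayGeometry
    scan: ScanResult
    probes: list[GlycanProbe]
    truth: pd.DataFrame  # probe_key, concentration, true_intensity


def _ln_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Lognormal multiplicative factors with mean 1 and the given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def generate(config: FixtureConfig, outdir: str | Path) -> GeneratedSlide:
    """Emit matched GAL, GPR, probe CSV and ground-truth CSV into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    # --- geometry: probes repeated in round-robin, grid filled block-major,
    # leftover cells become EMPTY placeholders
    order = [p for _ in range(config.replicates_per_probe) for p in config.probes]
    addresses = [(b, r, c)
                 for b in range(1, config.n_blocks + 1)
                 for r in range(1, config.block_rows + 1)
                 for c in range(1, config.block_cols + 1)]
    assignments = []
    for addr, spec in zip(addresses, order):
        assignments.append(SpotAssignment(
            block=addr[0], row=addr[1], column=addr[2],
            probe_key=spec.probe_key, concentration=spec.concentration))
    for addr in addresses[len(order):]:
        assignments.append(SpotAssignment(
            block=addr[0], row=addr[1], column=addr[2], probe_key=EMPTY_KEY))
    geometry = ArrayGeometry(layout_id=f"{config.slide_id}-layout",
                             n_blocks=config.n_blocks,
                             spot_assignments=assignments)
    geometry.validate()

    # --- per-spot signal
    n = len(order)
    f_noise = _ln_factor(rng, config.noise_cv, n)
    fm_noise = _ln_factor(rng, config.noise_cv, n)
    b_noise = _ln_factor(rng, config.noise_cv / 2, n)
    bm_noise = _ln_factor(rng, config.noise_cv / 2, n)
    is_outlier = rng.random(n) < config.outlier_prob
    is_flagged = rng.random(n) < config.flagged_prob

    spots = []
    for i, (addr, spec) in enumerate(zip(addresses, order)):
        boost = config.outlier_factor if is_outlier[i] else 1.0
        feats = ChannelFeatures(
            f_mean=spec.true_intensity * f_noise[i] * boost + config.background_level,
            f_median=spec.true_intensity * fm_noise[i] * boost + config.background_level,
            b_mean=config.background_level * b_noise[i],
            b_median=config.background_level * bm_noise[i])
        spots.append(SpotRecord(
            block=addr[0], row=addr[1], column=addr[2],
            name=spec.probe_key, probe_key=spec.probe_key,
            channel_features={config.channel: feats},
            flags=-100 if is_flagged[i] else 0))
    for addr in addresses[len(order):]:  # EMPTY cells read pure background
        feats = ChannelFeatures(
            f_mean=config.background_level, f_median=config.background_level,
            b_mean=config.background_level, b_median=config.background_level)
        spots.append(SpotRecord(block=addr[0], row=addr[1], column=addr[2],
                                name=EMPTY_KEY, probe_key=EMPTY_KEY,
                                channel_features={config.channel: feats}))

    scan = ScanResult(
        slide_id=config.slide_id, channels=[config.channel], spots=spots,
        header_meta={"Type": "GenePix Results 3", "SlideID": config.slide_id,
                     "PMTGain": "600",
                     "Wavelengths": str(config.channel)})
    scan.validate()

    probes = [GlycanProbe(probe_key=s.probe_key, display_name=s.probe_key,
                          sequences={"CFG-IUPAC": s.sequence},
                          tag={"tag_name": s.tag_name, "description": ""})
              for s in config.probes]
    truth = pd.DataFrame({
        "probe_key": [s.probe_key for s in config.probes],
        "concentration": [str(s.concentration) if s.concentration else ""
                          for s in config.probes],
        "true_intensity": [s.true_intensity for s in config.probes]})

    gal_path = write_gal(geometry, outdir / f"{config.slide_id}.gal")
    gpr_path = write_gpr(scan, outdir / f"{config.slide_id}.gpr")
    probe_csv_path = outdir / f"{config.slide_id}-probes.csv"
    write_probe_csv(probes, probe_csv_path)
    truth_path = outdir / f"{config.slide_id}-truth.csv"
    truth.to_csv(truth_path, index=False)
    return GeneratedSlide(gal_path=gal_path, gpr_path=gpr_path,
                          probe_csv_path=probe_csv_path, truth_path=truth_path,
                          geometry=geometry, scan=scan, probes=probes,
                          truth=truth)
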