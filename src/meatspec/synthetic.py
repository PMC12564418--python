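"""Synthetic two-class ATR-FTIR-like spectra.

Real mid-IR meat spectra are a superposition of protein, lipid and
carbohydrate absorption bands on top of instrument baseline drift,
multiplicative scatter from imperfect crystal contact, and detector noise.
The generator emulates exactly that structure: Gaussian bands at the
literature positions for pork tissue, class-specific band intensities
(the target class shows stronger lipid CH and Amide II bands, the other
class stronger carbonyl/polysaccharide bands), a per-sample linear baseline,
a per-sample log-normal scatter factor, and per-replicate additive noise
plus a smooth baseline wiggle between repositionings of the sample.

Three replicates per sample are emitted, mirroring standard acquisition
practice; downstream modelling averages them via
:func:`meatspec.io.average_replicates`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .io import SpectraSet

__all__ = ["PeakSpec", "SyntheticConfig", "DEFAULT_PEAKS", "generate", "null_dataset"]


@dataclass(frozen=True)
class PeakSpec:
    """One Gaussian absorption band.

    ``class_effect`` multiplies the amplitude for class-1 samples: >1 means
    the band is stronger in the target class, <1 stronger in the other class.
    """

    center: float          # cm^-1
    width: float           # Gaussian sd, cm^-1
    base_amplitude: float  # AU
    class_effect: float = 1.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("peak width must be positive")
        if self.base_amplitude < 0:
            raise ValueError("base_amplitude must be >= 0")
        if self.class_effect <= 0:
            raise ValueError("class_effect must be positive")


# Band library for pork tissue mid-IR spectra: positions, assignments and
# which class carries the stronger band.  Strong trends get a 1.15 factor,
# marginal ones 1.05 (inverted when the non-target class is stronger).
DEFAULT_PEAKS: tuple[PeakSpec, ...] = (
    PeakSpec(3285, 60.0, 0.50, 1 / 1.05),  # O-H/N-H stretch (Amide A), slightly stronger class 0
    PeakSpec(2955, 14.0, 0.55, 1.15),      # CH3 asym stretch, lipids -- stronger class 1
    PeakSpec(2920, 12.0, 0.60, 1.05),      # CH2 asym stretch, marginally stronger class 1
    PeakSpec(2850, 12.0, 0.35, 1.15),      # CH2/CH3 sym stretch -- stronger class 1
    PeakSpec(1650, 18.0, 1.00, 1.00),      # Amide I, no class difference
    PeakSpec(1540, 15.0, 0.55, 1.15),      # Amide II -- stronger class 1
    PeakSpec(1450, 12.0, 0.25, 1 / 1.05),  # Amide III shoulder, slightly stronger class 0
    PeakSpec(1400, 10.0, 0.30, 1.15),      # CH2 scissoring -- stronger class 1
    PeakSpec(1330, 10.0, 0.12, 1.00),      # COO- sym stretch, no clear difference
    PeakSpec(1240, 12.0, 0.30, 1 / 1.05),  # Amide III / C-N, slightly stronger class 0
    PeakSpec(1080, 14.0, 0.30, 1.05),      # P=O stretch, slightly stronger class 1
    PeakSpec(1030, 12.0, 0.22, 1 / 1.15),  # C-O stretch -- stronger class 0
    PeakSpec(970, 8.0, 0.12, 1 / 1.05),    # C-O-C stretch, slightly stronger class 0
    PeakSpec(920, 8.0, 0.10, 1 / 1.15),    # aromatic C-H bend -- stronger class 0
)


@dataclass
class SyntheticConfig:
    """Generation parameters; the defaults are the study conditions."""

    n_per_class: int = 40
    replicates: int = 3
    grid: tuple[float, float, float] = (600.0, 4000.0, 2.0)  # (low, high, step) cm^-1
    peaks: tuple[PeakSpec, ...] = field(default_factory=lambda: DEFAULT_PEAKS)
    baseline_offset_sd: float = 0.02   # AU
    baseline_slope_sd: float = 5e-6    # AU per cm^-1
    scatter_sd: float = 0.05           # sd of log multiplicative factor
    noise_sd: float = 0.005            # AU, per replicate
    replicate_jitter_sd: float = 0.003  # AU, smooth per-replicate wiggle
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 3:
            raise ValueError("n_per_class must be >= 3")
        if self.grid[2] <= 0:
            raise ValueError("grid step must be positive")
        if min(self.noise_sd, self.replicate_jitter_sd, self.scatter_sd) < 0:
            raise ValueError("noise/jitter/scatter sds must be >= 0")

    def wavenumbers(self) -> np.ndarray:
        lo, hi, step = self.grid
        return np.arange(lo, hi + step / 2, step)


def _clean_class_means(cfg: SyntheticConfig) -> np.ndarray:
    """Noise-free class mean spectra, shape (2, p)."""
    w = cfg.wavenumbers()
    means = np.zeros((2, w.size))
    for pk in cfg.peaks:
        if not (w[0] <= pk.center <= w[-1]):
            warnings.warn(
                f"peak at {pk.center} cm^-1 lies outside the grid and is skipped",
                stacklevel=3,
            )
            continue
        shape = np.exp(-0.5 * ((w - pk.center) / pk.width) ** 2)
        means[0] += pk.base_amplitude * shape
        means[1] += pk.base_amplitude * pk.class_effect * shape
    return means


def generate(cfg: SyntheticConfig) -> SpectraSet:
    """Draw a labelled replicate-level dataset, reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    w = cfg.wavenumbers()
    p = w.size
    means = _clean_class_means(cfg)

    rows, sample_ids, replicate_ids, labels = [], [], [], []
    # smooth-jitter kernel width ~ 25 grid points
    for label in (0, 1):
        for k in range(cfg.n_per_class):
            sid = f"C{label}S{k:03d}"
            baseline = (
                rng.normal(0.0, cfg.baseline_offset_sd)
                + rng.normal(0.0, cfg.baseline_slope_sd) * (w - w[0])
            )
            scatter = float(np.exp(rng.normal(0.0, cfg.scatter_sd)))
            clean = scatter * means[label] + baseline
            for r in range(cfg.replicates):
                spec = clean + rng.normal(0.0, cfg.noise_sd, size=p)
                if cfg.replicate_jitter_sd > 0:
                    wiggle = gaussian_filter1d(rng.normal(0.0, 1.0, size=p), 25.0)
                    sd = wiggle.std()
                    if sd > 0:
                        spec = spec + cfg.replicate_jitter_sd * wiggle / sd
                rows.append(spec)
                sample_ids.append(sid)
                replicate_ids.append(r + 1)
                labels.append(label)

    return SpectraSet(
        wavenumbers=w,
        absorbance=np.vstack(rows),
        sample_id=np.array(sample_ids, dtype=object),
        replicate_id=np.array(replicate_ids),
        label=np.array(labels),
    )


def null_dataset(cfg: SyntheticConfig) -> SpectraSet:
    """Same generative process with every class effect forced to 1.

    Labels then carry no signal; any classifier should sit at chance, which
    calibrates the type-I behaviour of the whole pipeline.
    """
    flat = replace(
        cfg,
        peaks=tuple(replace(pk, class_effect=1.0) for pk in cfg.peaks),
    )
    return generate(flat)
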