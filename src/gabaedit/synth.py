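"""Synthetic multi-coil edited acquisitions with controlled imperfections.

This module turns simulated basis FIDs into raw k-space data the way the
scanner would have produced them for the two protocols this package
emulates: a single-voxel acquisition (1x1x1 "encoding", 64 edited + 64
non-edited repetitions) and a phase-encoded array (e.g. 8x8x1, one shot per
cycle).  On top of the clean signal it injects, with recorded ground truth:

* per-average frequency drift (linear by default, optional random walk) and
  zero-order phase jitter — the instabilities that corrupt edited
  differences between cycles;
* i.i.d. circular Gaussian noise per coil sample;
* residual water at the carrier;
* out-of-volume contamination ("unspoiled coherence" residuals), modelled
  phenomenologically as extra spectral components at chosen grid positions.
  In single-voxel mode these leak into the acquisition attenuated only by
  the outer-volume-suppression efficiency; with phase encoding they are
  localised to their own voxel and reach the target voxel only through the
  point-spread function.

The averaging order is blocked (all edited averages, then all non-edited),
matching an editing/non-editing repetition scheme, so a linear drift
produces a systematic frequency offset between the two cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .sequence import FID, SequenceParams
from .simulate import BasisSet

__all__ = ["PhantomConfig", "CoilSensitivities", "EncodingSpec", "MultiCoilCSI",
           "make_sensitivities", "generate_acquisition", "CYCLES",
           "default_brain_concentrations"]

#: cycle ordering of the first data axis
CYCLES = ("edited", "non_edited")


def default_brain_concentrations() -> dict:
    """Relative metabolite concentrations of the default brain-like phantom.

    NAA is the unit of scale; values are chosen to give GABA/NAA fitted
    ratios of the magnitude seen in vivo (~0.1) with typical relative
    levels of the other basis metabolites.
    """
    return {
        "NAA": 1.0, "Cr": 0.66, "Cho": 0.26, "Glu": 0.8, "Gln": 0.25,
        "GABA": 0.1, "GSH": 0.2, "NAAG": 0.15, "MM_pseudo": 0.3,
    }


@dataclass
class PhantomConfig:
    """Spatial layout, composition and nuisance signals of a phantom.

    ``region_map`` holds, per grid voxel, an integer index into the sorted
    region labels of ``concentrations``; by default a single region fills
    the grid.  ``contamination`` entries are ``(location, component,
    amplitude)`` with ``location`` a grid index triple and ``component`` a
    metabolite name resolvable in the basis set.  ``vss_suppression`` is
    the fraction of contamination removed when single-voxel outer-volume
    suppression is emulated (0.95 -> 5% of it leaks in).
    """

    grid_shape: tuple = (1, 1, 1)
    voxel_mm: tuple = (20.0, 20.0, 20.0)
    concentrations: dict = field(default_factory=lambda: {"brain": default_brain_concentrations()})
    linewidth_hz: float | dict = 9.0
    region_map: np.ndarray | None = None
    residual_water_amp: float = 0.0
    residual_water_lw_hz: float = 25.0
    mm_extra_lw_hz: float = 30.0
    contamination: list = field(default_factory=list)
    contamination_lw_hz: float = 15.0
    vss_suppression: float = 0.95

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        if any(n < 1 for n in self.grid_shape):
            raise ValueError("grid_shape entries must be >= 1")
        for label, concs in self.concentrations.items():
            for met, c in concs.items():
                if c < 0:
                    raise ValueError(f"negative concentration {label}/{met}")
        if self.region_map is None:
            self.region_map = np.zeros(self.grid_shape, dtype=int)
        else:
            self.region_map = np.asarray(self.region_map, dtype=int)
            if self.region_map.shape != self.grid_shape:
                raise ValueError("region_map shape must equal grid_shape")
        n_regions = len(self.concentrations)
        if self.region_map.size and (self.region_map.min() < 0
                                     or self.region_map.max() >= n_regions):
            raise ValueError("region_map indices out of range")
        if not 0.0 <= self.vss_suppression <= 1.0:
            raise ValueError("vss_suppression must be in [0, 1]")

    @property
    def region_labels(self) -> tuple:
        return tuple(sorted(self.concentrations))

    def region_linewidth(self, label: str) -> float:
        if isinstance(self.linewidth_hz, dict):
            return float(self.linewidth_hz[label])
        return float(self.linewidth_hz)


@dataclass
class CoilSensitivities:
    """Complex receive-sensitivity map per coil over the phantom grid."""

    maps: np.ndarray  # (n_coils, nx, ny, nz)

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=np.complex128)
        if self.maps.ndim != 4:
            raise ValueError("sensitivity maps must be (n_coils, nx, ny, nz)")
        if self.maps.shape[0] < 1:
            raise ValueError("need at least one coil")
        flat = self.maps.reshape(self.maps.shape[0], -1)
        if np.any(np.all(flat == 0, axis=1)):
            raise ValueError("all-zero coil map")

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    @property
    def grid_shape(self) -> tuple:
        return self.maps.shape[1:]


def make_sensitivities(n_coils: int, grid, seed: int = 0,
                       uniform: bool = False) -> CoilSensitivities:
    """Smooth synthetic complex coil maps (deterministic per seed).

    Each map is a low-order complex spatial polynomial: a coil-specific
    constant plus random linear and quadratic terms over the normalised
    grid coordinates, with a random overall phase.  ``uniform=True``
    returns constant unit maps instead (handy for identity oracles).
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    grid = tuple(int(g) for g in grid)
    if uniform:
        return CoilSensitivities(np.ones((n_coils, *grid), dtype=np.complex128))
    rng = np.random.default_rng(seed)
    axes = [np.linspace(-1.0, 1.0, g) if g > 1 else np.zeros(1) for g in grid]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    maps = np.empty((n_coils, *grid), dtype=np.complex128)
    for c in range(n_coils):
        lin = rng.normal(0, 0.4, 3)
        quad = rng.normal(0, 0.15, 3)
        base = 1.0 + rng.normal(0, 0.2)
        phase = rng.uniform(-np.pi, np.pi) + 0.3 * (
            rng.normal() * xx + rng.normal() * yy + rng.normal() * zz)
        mag = base + lin[0] * xx + lin[1] * yy + lin[2] * zz \
            + quad[0] * xx ** 2 + quad[1] * yy ** 2 + quad[2] * zz ** 2
        mag = np.clip(np.abs(mag), 0.1, None)  # keep coils everywhere sensitive
        maps[c] = mag * np.exp(1j * phase)
    return CoilSensitivities(maps)


@dataclass(frozen=True)
class EncodingSpec:
    """Phase-encoding matrix and repetition count of one acquisition."""

    matrix: tuple = (1, 1, 1)
    n_averages: int = 64

    def __post_init__(self) -> None:
        object.__setattr__(self, "matrix", tuple(int(n) for n in self.matrix))
        if any(n < 1 for n in self.matrix):
            raise ValueError("encoding matrix entries must be >= 1")
        if self.n_averages < 1:
            raise ValueError("n_averages must be >= 1")

    @property
    def is_single_voxel(self) -> bool:
        return self.matrix == (1, 1, 1)

    @classmethod
    def single_voxel(cls, n_averages: int = 64) -> "EncodingSpec":
        return cls(matrix=(1, 1, 1), n_averages=n_averages)

    @classmethod
    def csi(cls, matrix=(8, 8, 1), n_averages: int = 1) -> "EncodingSpec":
        return cls(matrix=matrix, n_averages=n_averages)


@dataclass
class MultiCoilCSI:
    """Raw edited/non-edited multi-average multi-coil (k-space) data.

    ``data`` is indexed ``(cycle, average, coil, kx, ky, kz, time)`` with
    the cycle axis ordered as :data:`CYCLES`.  ``truth`` carries the
    injected ground truth for synthetic data (drift/phase tables, phantom,
    sensitivities, noise level); it is absent for data loaded from files
    written without it.
    """

    data: np.ndarray
    encoding: EncodingSpec
    params: SequenceParams
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.ndim != 7:
            raise ValueError("data must be (cycle, avg, coil, kx, ky, kz, t)")
        if self.data.shape[0] != 2:
            raise ValueError("first axis must hold the two editing cycles")
        if self.data.shape[3:6] != self.encoding.matrix:
            raise ValueError("spatial shape inconsistent with encoding matrix")
        if self.data.shape[1] != self.encoding.n_averages:
            raise ValueError("average count inconsistent with encoding")
        if self.data.shape[-1] != self.params.n_points:
            raise ValueError("time axis inconsistent with params.n_points")

    @property
    def n_coils(self) -> int:
        return self.data.shape[2]

    def save_hdf5(self, target) -> None:
        own = isinstance(target, (str, bytes))
        f = h5py.File(target, "a") if own else target
        try:
            if "csi" in f:
                del f["csi"]
            grp = f.create_group("csi")
            grp.create_dataset("data", data=self.data)
            grp.attrs["matrix"] = self.encoding.matrix
            grp.attrs["n_averages"] = self.encoding.n_averages
            for key in ("te_ms", "tr_ms", "larmor_mhz", "carrier_ppm", "sweep_hz",
                        "n_points", "edit_on_ppm", "edit_off_ppm", "edit_fwhm_hz"):
                grp.attrs[key] = getattr(self.params, key)
            if self.truth is not None:
                tg = grp.create_group("truth")
                tg.create_dataset("drift_hz", data=self.truth["drift_hz"])
                tg.create_dataset("phase_deg", data=self.truth["phase_deg"])
                tg.create_dataset("coil_maps", data=self.truth["coils"].maps)
                tg.attrs["noise_sd"] = self.truth["noise_sd"]
                tg.attrs["seed"] = self.truth["seed"]
        finally:
            if own:
                f.close()

    @classmethod
    def load_hdf5(cls, source) -> "MultiCoilCSI":
        own = isinstance(source, (str, bytes))
        f = h5py.File(source, "r") if own else source
        try:
            grp = f["csi"]
            attrs = dict(grp.attrs)
            params = SequenceParams(**{k: (int(attrs[k]) if k == "n_points" else float(attrs[k]))
                                       for k in ("te_ms", "tr_ms", "larmor_mhz",
                                                 "carrier_ppm", "sweep_hz", "n_points",
                                                 "edit_on_ppm", "edit_off_ppm",
                                                 "edit_fwhm_hz")})
            enc = EncodingSpec(matrix=tuple(int(v) for v in attrs["matrix"]),
                               n_averages=int(attrs["n_averages"]))
            truth = None
            if "truth" in grp:
                tg = grp["truth"]
                truth = {
                    "drift_hz": tg["drift_hz"][()],
                    "phase_deg": tg["phase_deg"][()],
                    "coils": CoilSensitivities(tg["coil_maps"][()]),
                    "noise_sd": float(tg.attrs["noise_sd"]),
                    "seed": int(tg.attrs["seed"]),
                }
            return cls(data=grp["data"][()], encoding=enc, params=params, truth=truth)
        finally:
            if own:
                f.close()


def _voxel_signals(basis: BasisSet, phantom: PhantomConfig, cycle: str) -> np.ndarray:
    """Noiseless per-voxel FIDs (nx, ny, nz, t) for one editing cycle."""
    fids = basis.cycle_fids(cycle)
    labels = phantom.region_labels
    n_t = basis.params.n_points
    region_fids = np.zeros((len(labels), n_t), dtype=np.complex128)
    for r, label in enumerate(labels):
        lw = phantom.region_linewidth(label)
        acc = np.zeros(n_t, dtype=np.complex128)
        for met, conc in phantom.concentrations[label].items():
            if conc == 0.0:
                continue
            if met not in fids:
                raise ValueError(f"metabolite {met!r} absent from basis set")
            extra = phantom.mm_extra_lw_hz if met == "MM_pseudo" else 0.0
            acc += conc * fids[met].broadened(lw + extra).samples
        if phantom.residual_water_amp:
            if "water" not in fids:
                raise ValueError("residual water requested but 'water' absent from basis")
            acc += phantom.residual_water_amp * \
                fids["water"].broadened(phantom.residual_water_lw_hz).samples
        region_fids[r] = acc
    return region_fids[phantom.region_map]


def _contamination_signals(basis: BasisSet, phantom: PhantomConfig, cycle: str):
    """[(location, fid_samples), ...] for the out-of-volume components."""
    fids = basis.cycle_fids(cycle)
    out = []
    for loc, component, amplitude in phantom.contamination:
        if component not in fids:
            raise ValueError(f"contamination component {component!r} absent from basis")
        samples = amplitude * fids[component].broadened(phantom.contamination_lw_hz).samples
        out.append((tuple(int(v) for v in loc), samples))
    return out


def generate_acquisition(basis: BasisSet, phantom: PhantomConfig,
                         coils: CoilSensitivities, encoding: EncodingSpec,
                         noise_sd: float = 0.02,
                         drift_hz_per_avg: float = 0.0,
                         phase_sd_deg: float = 0.0,
                         seed: int = 0,
                         drift_model: str = "linear") -> MultiCoilCSI:
    """Generate raw data for both editing cycles of one acquisition.

    Each average is the spatially encoded, coil-weighted sum of the
    phantom's voxel signals, frequency-shifted and phase-rotated by the
    injected per-average errors, plus circular Gaussian noise of standard
    deviation ``noise_sd`` per real/imaginary component and sample.
    Averages are ordered blockwise (edited block first), and the drift
    index runs globally across the blocks.  Identical seeds give
    bit-identical datasets.
    """
    if coils.grid_shape != phantom.grid_shape:
        raise ValueError("coil map grid does not match phantom grid")
    if not encoding.is_single_voxel and encoding.matrix != phantom.grid_shape:
        raise ValueError(
            f"encoding matrix {encoding.matrix} must be 1x1x1 or match the "
            f"phantom grid {phantom.grid_shape}")
    if drift_model not in ("linear", "random_walk"):
        raise ValueError("drift_model must be 'linear' or 'random_walk'")
    params = basis.params
    n_avg, n_coils, n_t = encoding.n_averages, coils.n_coils, params.n_points
    rng = np.random.default_rng(seed)

    g = np.arange(2 * n_avg, dtype=float)
    if drift_model == "linear":
        drift = drift_hz_per_avg * g
    else:
        drift = np.cumsum(rng.normal(0.0, abs(drift_hz_per_avg), 2 * n_avg))
    drift = drift.reshape(2, n_avg)
    phase = rng.normal(0.0, phase_sd_deg, (2, n_avg))

    t = params.time_axis()
    data = np.empty((2, n_avg, n_coils, *encoding.matrix, n_t), dtype=np.complex128)
    for ci, cycle in enumerate(CYCLES):
        vox = _voxel_signals(basis, phantom, cycle)          # (nx,ny,nz,t)
        contam = _contamination_signals(basis, phantom, cycle)
        if encoding.is_single_voxel:
            base = np.einsum("cxyz,xyzt->ct", coils.maps, vox)
            leak = 1.0 - phantom.vss_suppression
            for loc, samples in contam:
                base += leak * coils.maps[(slice(None), *loc)][:, None] * samples
            base = base[:, None, None, None, :]              # (coil,1,1,1,t)
        else:
            img = vox.copy()
            for loc, samples in contam:
                img[loc] = img[loc] + samples
            weighted = coils.maps[..., None] * img[None, ...]  # (coil,nx,ny,nz,t)
            base = np.fft.fft2(weighted, axes=(1, 2))
        for a in range(n_avg):
            fac = np.exp(-2j * np.pi * drift[ci, a] * t
                         + 1j * np.deg2rad(phase[ci, a]))
            data[ci, a] = base * fac
    if noise_sd > 0:
        data += rng.normal(0.0, noise_sd, data.shape) \
            + 1j * rng.normal(0.0, noise_sd, data.shape)
    truth = {"drift_hz": drift, "phase_deg": phase, "phantom": phantom,
             "coils": coils, "noise_sd": noise_sd, "seed": seed}
    return MultiCoilCSI(data=data, encoding=encoding, params=params, truth=truth)
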