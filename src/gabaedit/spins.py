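"""Metabolite spin systems: the table of record for chemical shifts and J.

Values follow the standard proton-metabolite literature compilations used to
build in-vitro basis sets (shifts in ppm, scalar couplings in Hz).  Some
systems are deliberately reduced to keep Hilbert dimensions small while
preserving the resonances that matter for edited GABA work between 1.8 and
4.1 ppm:

* Cr is the 3.027 ppm methyl singlet (proton weight 3).
* GSH keeps the cysteinyl CH-CH2 subsystem plus the glycine singlet.
* ``MM_pseudo`` is a two-spin stand-in for the macromolecule pool: a 3.0 ppm
  resonance J-coupled (7 Hz) to a partner at 1.7 ppm, which is the mechanism
  by which MM co-edits when the edit-off pulse is not mirrored about 1.7 ppm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpinSystem", "build_spin_system", "UnsupportedMetaboliteError",
           "available_metabolites", "BASIS_METABOLITES"]

MAX_SPINS = 8  # Hilbert dimension capped at 2**8 = 256


class UnsupportedMetaboliteError(ValueError):
    """Raised for a metabolite name outside the built-in library."""


@dataclass(frozen=True)
class SpinSystem:
    """Chemical shifts (ppm) and scalar-coupling matrix (Hz) of one molecule.

    ``proton_scale`` carries the multiplicity weight of each simulated spin,
    e.g. 3 for a methyl group represented by a single spin.
    """

    name: str
    shifts_ppm: tuple
    j_hz: np.ndarray = field(repr=False)
    proton_scale: tuple = None

    def __post_init__(self) -> None:
        shifts = tuple(float(s) for s in self.shifts_ppm)
        object.__setattr__(self, "shifts_ppm", shifts)
        n = len(shifts)
        if n == 0:
            raise ValueError("spin system needs at least one spin")
        if n > MAX_SPINS:
            raise ValueError(
                f"{self.name}: {n} spins exceeds the {MAX_SPINS}-spin limit "
                f"(Hilbert dimension {2**n} > {2**MAX_SPINS})"
            )
        if any(s < 0.0 or s > 10.0 for s in shifts):
            raise ValueError(f"{self.name}: chemical shifts must lie in [0, 10] ppm")
        j = np.array(self.j_hz, dtype=float)
        if j.shape != (n, n):
            raise ValueError(f"{self.name}: J matrix must be {n}x{n}")
        if not np.allclose(j, j.T, atol=1e-12):
            raise ValueError(f"{self.name}: J matrix must be symmetric")
        if not np.allclose(np.diag(j), 0.0, atol=1e-12):
            raise ValueError(f"{self.name}: J matrix must have zero diagonal")
        j.setflags(write=False)
        object.__setattr__(self, "j_hz", j)
        scale = self.proton_scale
        if scale is None:
            scale = (1.0,) * n
        scale = tuple(float(s) for s in scale)
        if len(scale) != n:
            raise ValueError(f"{self.name}: proton_scale length mismatch")
        if any(s <= 0 for s in scale):
            raise ValueError(f"{self.name}: proton_scale must be positive")
        object.__setattr__(self, "proton_scale", scale)

    @property
    def n_spins(self) -> int:
        return len(self.shifts_ppm)

    @property
    def dim(self) -> int:
        return 2 ** self.n_spins


def _jmat(n: int, couplings: dict) -> np.ndarray:
    j = np.zeros((n, n))
    for (a, b), val in couplings.items():
        j[a, b] = j[b, a] = val
    return j


def _system(name, shifts, couplings=None, scale=None) -> SpinSystem:
    n = len(shifts)
    return SpinSystem(name=name, shifts_ppm=tuple(shifts),
                      j_hz=_jmat(n, couplings or {}), proton_scale=scale)


# --- table of record -------------------------------------------------------
# GABA: 4-CH2 (3.013), 3-CH2 (1.889), 2-CH2 (2.284); vicinal J ~= 7.3 Hz.
# Glu/Gln: alpha CH + beta/gamma CH2 with literature couplings.
# NAA/NAAG: acetyl CH3 singlet + aspartyl ABX.
_LIBRARY = {
    "GABA": dict(
        shifts=[3.013, 3.013, 1.889, 1.889, 2.284, 2.284],
        couplings={(0, 2): 7.3, (0, 3): 7.3, (1, 2): 7.3, (1, 3): 7.3,
                   (2, 4): 7.3, (2, 5): 7.3, (3, 4): 7.3, (3, 5): 7.3},
    ),
    "Cr": dict(shifts=[3.027], scale=[3.0]),
    "Cho": dict(shifts=[3.185], scale=[9.0]),
    "NAA": dict(
        shifts=[2.008, 4.382, 2.673, 2.486],
        couplings={(1, 2): 3.86, (1, 3): 9.82, (2, 3): -15.59},
        scale=[3.0, 1.0, 1.0, 1.0],
    ),
    "NAAG": dict(
        shifts=[2.042, 4.607, 2.721, 2.519],
        couplings={(1, 2): 4.41, (1, 3): 9.52, (2, 3): -15.91},
        scale=[3.0, 1.0, 1.0, 1.0],
    ),
    "Glu": dict(
        shifts=[3.746, 2.042, 2.120, 2.336, 2.352],
        couplings={(0, 1): 7.33, (0, 2): 4.65, (1, 2): -14.85,
                   (1, 3): 6.43, (1, 4): 8.48, (2, 3): 8.39, (2, 4): 6.88,
                   (3, 4): -15.92},
    ),
    "Gln": dict(
        shifts=[3.753, 2.129, 2.109, 2.432, 2.454],
        couplings={(0, 1): 5.84, (0, 2): 6.53, (1, 2): -14.45,
                   (1, 3): 9.16, (1, 4): 6.35, (2, 3): 6.88, (2, 4): 9.25,
                   (3, 4): -15.55},
    ),
    "GSH": dict(
        shifts=[4.561, 2.926, 2.975, 3.769],
        couplings={(0, 1): 7.09, (0, 2): 4.71, (1, 2): -14.06},
        scale=[1.0, 1.0, 1.0, 2.0],
    ),
    "MM_pseudo": dict(
        shifts=[3.0, 1.7],
        couplings={(0, 1): 7.0},
        scale=[2.0, 2.0],
    ),
    "water": dict(shifts=[4.7], scale=[2.0]),
}

#: metabolites of the quantification basis set
BASIS_METABOLITES = ("NAA", "Glu", "Gln", "GABA", "GSH", "NAAG")


def available_metabolites() -> tuple:
    return tuple(sorted(_LIBRARY))


def build_spin_system(name: str) -> SpinSystem:
    """Return the canonical spin system for a supported metabolite name.

    Repeated calls return equal values.  Unknown names raise
    :class:`UnsupportedMetaboliteError`.
    """
    try:
        spec = _LIBRARY[name]
    except KeyError:
        raise UnsupportedMetaboliteError(
            f"unsupported metabolite {name!r}; known: {', '.join(available_metabolites())}"
        ) from None
    return _system(name, spec["shifts"], spec.get("couplings"), spec.get("scale"))
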