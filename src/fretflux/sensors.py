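"""Genetically encoded FRET sensor models.

A ratiometric FRET biosensor is summarised by a one-site Hill binding
curve mapping analyte concentration (mM) to a fluorescence ratio::

    R(c) = r_min + (r_max - r_min) * c**h / (kd**h + c**h)

The reported ratio increases monotonically with analyte for both sensor
presets.  For the lactate sensor (an mTFP/Venus pair whose FRET
efficiency drops when lactate binds) this corresponds to reporting the
donor/acceptor ratio; for the glucose sensor (eCFP/Citrine, FRET rises
with glucose) it corresponds to acceptor/donor.  Keeping a single
orientation means every downstream readout ("more analyte -> larger
ratio") shares one sign convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SensorModel", "LACONIC", "FLIIP", "get_sensor"]


@dataclass(frozen=True)
class SensorModel:
    """One-site Hill binding sensor.

    Parameters
    ----------
    analyte : str
        ``"lactate"`` or ``"glucose"``.
    kd : float
        Half-saturation constant, mM.
    hill : float
        Hill coefficient (> 0).
    r_min : float
        Ratio at zero analyte.
    r_max : float
        Ratio at saturation.
    """

    analyte: str
    kd: float
    hill: float
    r_min: float
    r_max: float

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("kd must be > 0")
        if self.hill <= 0:
            raise ValueError("hill must be > 0")
        if not (self.r_max > self.r_min > 0):
            raise ValueError("need r_max > r_min > 0")

    # ------------------------------------------------------------------
    def forward(self, c):
        """Ratio reported at analyte concentration ``c`` (mM).

        Accepts scalars or arrays; rejects negative concentrations.
        """
        c = np.asarray(c, dtype=float)
        if np.any(c < 0):
            raise ValueError("concentration must be >= 0")
        occ = c**self.hill / (self.kd**self.hill + c**self.hill)
        out = self.r_min + (self.r_max - self.r_min) * occ
        return float(out) if out.ndim == 0 else out

    def inverse(self, r, tol: float = 1e-9):
        """Analyte concentration (mM) producing ratio ``r``.

        Exact algebraic inverse of :meth:`forward`, clipped into
        ``[0, inf)``.  Ratios outside ``[r_min - tol, r_max + tol]`` are
        rejected as out of sensor range; ratios inside the tolerance
        band but beyond the open range are clipped to the boundary
        (``r <= r_min`` maps to 0; ``r >= r_max`` is unresolvable and
        only accepted within ``tol``, mapping to the concentration where
        occupancy is ``1 - eps`` is not meaningful, so it is clipped to
        the value at ``r_max - tol``).
        """
        r = np.asarray(r, dtype=float)
        if np.any(r < self.r_min - tol) or np.any(r > self.r_max + tol):
            raise ValueError("out of sensor range")
        span = self.r_max - self.r_min
        # clip into the invertible open interval
        occ = np.clip((r - self.r_min) / span, 0.0, 1.0 - tol / span)
        c = self.kd * (occ / (1.0 - occ)) ** (1.0 / self.hill)
        c = np.maximum(c, 0.0)
        return float(c) if c.ndim == 0 else c

    def gain(self, c):
        """Local slope dR/dc (ratio units per mM) at concentration ``c``."""
        c = np.asarray(c, dtype=float)
        if np.any(c < 0):
            raise ValueError("concentration must be >= 0")
        h, kd = self.hill, self.kd
        num = (self.r_max - self.r_min) * h * kd**h * c ** (h - 1.0)
        den = (kd**h + c**h) ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            g = np.where((c == 0) & (h != 1.0), 0.0 if h > 1 else np.inf, num / den)
        if h == 1.0:
            g = num / den  # finite at 0 for h == 1
        return float(g) if np.ndim(g) == 0 else g

    @property
    def dynamic_range(self) -> float:
        return self.r_max - self.r_min


#: Lactate sensor preset (ratio rises with lactate).
LACONIC = SensorModel(analyte="lactate", kd=1.0, hill=1.0, r_min=1.0, r_max=1.3)

#: Glucose sensor preset (ratio rises with glucose).
FLIIP = SensorModel(analyte="glucose", kd=0.6, hill=1.0, r_min=1.0, r_max=1.8)

_PRESETS = {"laconic": LACONIC, "fliip": FLIIP}


def get_sensor(name: str) -> SensorModel:
    """Look up a sensor preset by name (``laconic`` or ``fliip``)."""
    try:
        return _PRESETS[name.lower()]
    except KeyError:
        raise KeyError(f"unknown sensor {name!r}; choose from {sorted(_PRESETS)}") from None


def sensor_forward(c, sensor: SensorModel):
    """Functional alias for :meth:`SensorModel.forward`."""
    return sensor.forward(c)


def sensor_inverse(r, sensor: SensorModel, tol: float = 1e-9):
    """Functional alias for :meth:`SensorModel.inverse`."""
    return sensor.inverse(r, tol=tol)
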