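"""ECoG forward model: point dipoles in a homogeneous medium.

Each region is a scalar source (dipole orientation ignored) whose strength
is its excitatory population rate; the signal at sensor k is the
distance-weighted sum

    s_k(t) = gain * sum_i nu_e_i(t) / ||x_k - c_i||^p

with p = 2 by default (point-dipole far field).  The model is linear in the
rates, so superposition holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .connectome import SensorLayout
from .errors import ContractError, ParameterError, ValidationError

__all__ = ["EcogConfig", "ecog_forward", "write_ecog", "read_ecog"]


@dataclass
class EcogConfig:
    layout: SensorLayout
    exponent: float = 2.0
    gain: float = 1.0

    def __post_init__(self) -> None:
        if self.exponent < 1:
            raise ParameterError(f"distance exponent must be >= 1, got {self.exponent}")


def ecog_forward(
    rates: np.ndarray, centres: np.ndarray, cfg: EcogConfig
) -> np.ndarray:
    """Map per-region excitatory rates to per-sensor signals.

    ``rates`` is (n_times, n_regions) (or (n_regions,) for one sample),
    ``centres`` is (n_regions, 3).  Returns (n_times, n_sensors).
    """
    rates = np.atleast_2d(np.asarray(rates, dtype=float))
    centres = np.asarray(centres, dtype=float)
    if centres.ndim != 2 or centres.shape[1] != 3:
        raise ContractError(f"centres must be (n_regions, 3), got {centres.shape}")
    if rates.shape[1] != centres.shape[0]:
        raise ContractError(
            f"rates cover {rates.shape[1]} regions but centres describe {centres.shape[0]}"
        )
    pos = cfg.layout.positions
    diff = pos[:, None, :] - centres[None, :, :]
    dist = np.linalg.norm(diff, axis=2)  # (n_sensors, n_regions)
    if np.any(dist == 0):
        k, i = np.argwhere(dist == 0)[0]
        raise ValidationError(
            f"sensor {k} coincides with the centre of region {i}; the forward "
            "model diverges at zero distance"
        )
    gains = cfg.gain / dist**cfg.exponent
    return rates @ gains.T


def write_ecog(series: np.ndarray, times: np.ndarray, path: str | Path) -> Path:
    """Write `time_ms sensor_0 ... sensor_{m-1}` text columns."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    series = np.atleast_2d(np.asarray(series, dtype=float))
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        m = series.shape[1] if series.size else 0
        header = "time_ms " + " ".join(f"sensor_{k}" for k in range(m))
        path.write_text("# " + header + "\n")
        return path
    if series.shape[0] != times.size:
        raise ContractError("series rows must match the number of time samples")
    m = series.shape[1]
    header = "time_ms " + " ".join(f"sensor_{k}" for k in range(m))
    data = np.column_stack([times, series])
    np.savetxt(path, data, fmt="%.17g", header=header)
    return path


def read_ecog(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read the file written by :func:`write_ecog` -> (times, series)."""
    data = np.loadtxt(path, ndmin=2)
    if data.size == 0:
        return np.empty(0), np.empty((0, 0))
    return data[:, 0], data[:, 1:]
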