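"""Synthetic connectomes, region geometry and sensor layouts.

A connectome is the structural scaffold of the whole-brain network: a
directed matrix of coupling strengths ``W[target, source]``, a symmetric
matrix of tract lengths (mm) and 3-D region centres (mm).  Together with a
conduction speed the tract lengths define inter-regional transmission
delays.  The generator below produces atlas-like synthetic connectomes so
the full co-simulation workflow runs without any external download: weights
are heavy-tailed (log-normal) and directed, tract lengths are Euclidean
centre distances inflated by a tortuosity factor, and two mirror-symmetric
regions are flagged for simulation at the spiking scale (standing in for
left/right hippocampal CA1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ParameterError, ValidationError

__all__ = [
    "Connectome",
    "SensorLayout",
    "generate_synthetic_connectome",
    "generate_sensor_grid",
    "compute_delays",
    "normalize_weights",
    "read_connectome",
    "write_connectome",
    "read_sensor_layout",
    "write_sensor_layout",
]


@dataclass
class Connectome:
    """Inter-regional coupling strengths, tract lengths and geometry.

    weights
        ``n x n`` non-negative coupling strengths, row = target region,
        column = source region, zero diagonal.  Directedness is allowed and
        never assumed away.
    tract_lengths
        ``n x n`` symmetric non-negative lengths in mm, zero diagonal.
    centres
        ``n x 3`` region centres in mm.
    spiking_regions
        Indices of regions simulated at the spiking (microcircuit) scale.
    """

    weights: np.ndarray
    tract_lengths: np.ndarray
    centres: np.ndarray
    labels: list[str] = field(default_factory=list)
    spiking_regions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.tract_lengths = np.asarray(self.tract_lengths, dtype=float)
        self.centres = np.asarray(self.centres, dtype=float)
        n = self.weights.shape[0]
        if self.weights.shape != (n, n):
            raise ValidationError(f"weights must be square, got {self.weights.shape}")
        if self.tract_lengths.shape != (n, n):
            raise ValidationError(
                f"tract_lengths shape {self.tract_lengths.shape} does not match "
                f"weights shape {self.weights.shape}"
            )
        if self.centres.shape != (n, 3):
            raise ValidationError(f"centres must be ({n}, 3), got {self.centres.shape}")
        for name, m in (("weights", self.weights), ("tract_lengths", self.tract_lengths)):
            if not np.all(np.isfinite(m)):
                i, j = np.argwhere(~np.isfinite(m))[0]
                raise ValidationError(f"{name}[{i},{j}] is not finite")
            if np.any(m < 0):
                i, j = np.argwhere(m < 0)[0]
                raise ValidationError(f"{name}[{i},{j}] = {m[i, j]} is negative")
            if np.any(np.diag(m) != 0):
                i = int(np.argwhere(np.diag(m) != 0)[0][0])
                raise ValidationError(f"{name} diagonal entry [{i},{i}] must be zero")
        if not np.allclose(self.tract_lengths, self.tract_lengths.T):
            raise ValidationError("tract_lengths must be symmetric")
        if not np.all(np.isfinite(self.centres)):
            raise ValidationError("centres contain non-finite values")
        if not self.labels:
            self.labels = [f"region_{i:03d}" for i in range(n)]
        if len(self.labels) != n:
            raise ValidationError(f"expected {n} labels, got {len(self.labels)}")
        if not self.spiking_regions:
            raise ValidationError("spiking_regions must contain at least one region")
        for r in self.spiking_regions:
            if not (0 <= int(r) < n):
                raise ValidationError(f"spiking region index {r} out of range [0, {n})")
        self.spiking_regions = [int(r) for r in self.spiking_regions]

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


@dataclass
class SensorLayout:
    """Positions (mm) and labels of surface sensors, with hemisphere tags."""

    positions: np.ndarray
    labels: list[str] = field(default_factory=list)
    hemispheres: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        m = self.positions.shape[0]
        if m < 1 or self.positions.shape[1] != 3:
            raise ValidationError(f"positions must be (m>=1, 3), got {self.positions.shape}")
        if not np.all(np.isfinite(self.positions)):
            raise ValidationError("sensor positions contain non-finite values")
        if not self.labels:
            self.labels = [f"sensor_{i:02d}" for i in range(m)]
        if not self.hemispheres:
            self.hemispheres = ["?"] * m
        if len(self.labels) != m or len(self.hemispheres) != m:
            raise ValidationError("labels/hemispheres length must match positions")

    @property
    def n_sensors(self) -> int:
        return self.positions.shape[0]


def generate_synthetic_connectome(
    n_regions: int,
    density: float = 0.3,
    length_scale_mm: float = 10.0,
    seed: int = 0,
    *,
    min_distance_mm: float = 2.0,
    tortuosity_range: tuple[float, float] = (1.0, 1.5),
    n_spiking: int = 2,
) -> Connectome:
    """Generate a random directed connectome with plausible geometry.

    Region centres are drawn uniformly in a cube of side ``length_scale_mm``
    with a minimum pairwise separation ``min_distance_mm`` (so delays never
    collapse to zero).  The first ``n_spiking`` regions are placed mirror
    symmetrically about the mid-sagittal plane and flagged as spiking-scale
    regions.  Weights are log-normal on a directed Erdos-Renyi skeleton of
    the requested density; tract lengths are Euclidean distances inflated by
    a symmetric tortuosity factor sampled uniformly in ``tortuosity_range``
    (always >= 1, so lengths are never shorter than the straight line).
    Identical seeds give bitwise-identical connectomes.
    """
    n_regions = int(n_regions)
    if n_regions < 2:
        raise ParameterError(f"n_regions must be >= 2, got {n_regions}")
    if not (0.0 < density <= 1.0):
        raise ParameterError(f"density must be in (0, 1], got {density}")
    if length_scale_mm <= 0:
        raise ParameterError(f"length_scale_mm must be > 0, got {length_scale_mm}")
    if not (1 <= n_spiking <= n_regions):
        raise ParameterError(f"n_spiking must be in [1, n_regions], got {n_spiking}")
    lo, hi = tortuosity_range
    if lo < 1.0 or hi < lo:
        raise ParameterError(f"tortuosity_range must satisfy 1 <= lo <= hi, got {tortuosity_range}")

    rng = np.random.default_rng(seed)
    box = float(length_scale_mm)
    centres = np.empty((n_regions, 3))
    placed = 0
    attempts = 0
    while placed < n_regions:
        attempts += 1
        if attempts > 100_000:
            raise ParameterError(
                "could not place regions with the requested minimum separation; "
                "reduce min_distance_mm or n_regions"
            )
        p = rng.uniform(0.0, box, size=3)
        # mirror-symmetric spiking pair(s) about the x = box/2 plane
        if placed < n_spiking and n_spiking >= 2:
            if placed % 2 == 0:
                p[0] = rng.uniform(0.0, 0.4 * box)
            else:
                p[0] = box - centres[placed - 1, 0]
                p[1:] = centres[placed - 1, 1:]
        if placed > 0:
            d = np.linalg.norm(centres[:placed] - p, axis=1)
            if np.any(d < min_distance_mm):
                continue
        centres[placed] = p
        placed += 1

    dist = np.linalg.norm(centres[:, None, :] - centres[None, :, :], axis=2)
    tort = rng.uniform(lo, hi, size=(n_regions, n_regions))
    tort = np.triu(tort, 1)
    tort = tort + tort.T
    lengths = dist * tort
    np.fill_diagonal(lengths, 0.0)

    mask = rng.random((n_regions, n_regions)) < density
    np.fill_diagonal(mask, False)
    weights = np.where(mask, rng.lognormal(mean=0.0, sigma=1.0, size=(n_regions, n_regions)), 0.0)
    np.fill_diagonal(weights, 0.0)

    labels = []
    for i in range(n_regions):
        if i < n_spiking:
            side = "L" if i % 2 == 0 else "R"
            labels.append(f"CA1-{side}" if n_spiking == 2 else f"SPK{i}-{side}")
        else:
            labels.append(f"region_{i:03d}")
    return Connectome(
        weights=weights,
        tract_lengths=lengths,
        centres=centres,
        labels=labels,
        spiking_regions=list(range(n_spiking)),
    )


def generate_sensor_grid(
    connectome: Connectome,
    n_per_hemisphere: int = 8,
    elevation_mm: float = 2.0,
    seed: int = 0,
) -> SensorLayout:
    """Two surface grids of ECoG-style sensors, one per hemisphere.

    Sensors sit on a plane ``elevation_mm`` above the highest region centre,
    arranged in a 2 x (n/2) grid per hemisphere spanning the bounding box of
    the regions in that hemisphere.
    """
    if n_per_hemisphere < 1:
        raise ParameterError("n_per_hemisphere must be >= 1")
    c = connectome.centres
    z_top = float(c[:, 2].max()) + float(elevation_mm)
    x_mid = float((c[:, 0].min() + c[:, 0].max()) / 2.0)
    positions, labels, hemis = [], [], []
    for hemi, (x_lo, x_hi) in (("L", (c[:, 0].min(), x_mid)), ("R", (x_mid, c[:, 0].max()))):
        n_cols = max(1, (n_per_hemisphere + 1) // 2)
        n_rows = max(1, math.ceil(n_per_hemisphere / n_cols))
        xs = np.linspace(x_lo + 0.1 * (x_hi - x_lo), x_hi - 0.1 * (x_hi - x_lo), n_cols)
        ys = np.linspace(c[:, 1].min(), c[:, 1].max(), n_rows)
        k = 0
        for y in ys:
            for x in xs:
                if k >= n_per_hemisphere:
                    break
                positions.append([x, y, z_top])
                labels.append(f"ECOG-{hemi}{k:02d}")
                hemis.append(hemi)
                k += 1
    return SensorLayout(positions=np.array(positions), labels=labels, hemispheres=hemis)


def compute_delays(conn: Connectome, speed: float, dt: float) -> np.ndarray:
    """Transmission delays (ms): tract length over conduction speed.

    Each delay is rounded *up* to the nearest positive multiple of ``dt``
    and clamped at one step minimum, so windowed communication can never
    arrive early and every connected pair has a delay of at least one
    integration step.
    """
    if speed <= 0:
        raise ParameterError(f"conduction speed must be > 0, got {speed}")
    if dt <= 0:
        raise ParameterError(f"dt must be > 0, got {dt}")
    raw = conn.tract_lengths / float(speed)
    # ceil with a small tolerance so exact multiples do not round one step up
    steps = np.ceil(raw / dt - 1e-9).astype(int)
    steps = np.maximum(steps, 1)
    return steps * float(dt)


def normalize_weights(W: np.ndarray, mode: str = "row_sum") -> np.ndarray:
    """Normalize a non-negative coupling matrix.

    ``row_sum``: each non-zero row is scaled to sum to 1 (total afferent
    drive comparable across regions); ``max``: the global maximum becomes 1;
    ``none``: returned unchanged (copy).  Zero rows are left untouched and
    the zero diagonal is preserved by construction.
    """
    W = np.asarray(W, dtype=float)
    if np.any(W < 0):
        i, j = np.argwhere(W < 0)[0]
        raise ValidationError(f"weights[{i},{j}] = {W[i, j]} is negative")
    if mode == "none":
        return W.copy()
    if mode == "row_sum":
        sums = W.sum(axis=1, keepdims=True)
        safe = np.where(sums > 0, sums, 1.0)
        return W / safe
    if mode == "max":
        m = W.max()
        return W.copy() if m == 0 else W / m
    raise ParameterError(f"unknown normalization mode {mode!r}")


_FMT = "%.17g"


def write_connectome(conn: Connectome, directory: str | Path) -> dict[str, Path]:
    """Write whitespace-delimited text files (one matrix row per line)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "weights": d / "weights.txt",
        "tract_lengths": d / "tract_lengths.txt",
        "centres": d / "centres.txt",
        "labels": d / "labels.txt",
        "spiking_regions": d / "spiking_regions.txt",
    }
    np.savetxt(paths["weights"], conn.weights, fmt=_FMT)
    np.savetxt(paths["tract_lengths"], conn.tract_lengths, fmt=_FMT)
    np.savetxt(paths["centres"], conn.centres, fmt=_FMT)
    paths["labels"].write_text("\n".join(conn.labels) + "\n")
    paths["spiking_regions"].write_text(
        " ".join(str(i) for i in conn.spiking_regions) + "\n"
    )
    return paths


def _load_matrix(path: str | Path, name: str) -> np.ndarray:
    try:
        m = np.loadtxt(path, ndmin=2)
    except ValueError as exc:
        raise ValidationError(f"{name} file {path}: {exc}") from exc
    bad = np.argwhere(~np.isfinite(m))
    if bad.size:
        i, j = bad[0]
        raise ValidationError(f"{name} file {path}: entry [{i},{j}] is not finite")
    return m


def read_connectome(
    weights_path: str | Path,
    lengths_path: str | Path,
    centres_path: str | Path,
    labels_path: str | Path | None = None,
    spiking_regions: list[int] | str | Path | None = None,
) -> Connectome:
    """Read a connectome from text files, validating shapes and signs.

    Errors name the offending file and cell.
    """
    W = _load_matrix(weights_path, "weights")
    L = _load_matrix(lengths_path, "tract_lengths")
    C = _load_matrix(centres_path, "centres")
    n = W.shape[0]
    if W.shape != (n, n):
        raise ValidationError(f"weights file {weights_path}: matrix {W.shape} is not square")
    if L.shape != (n, n):
        raise ValidationError(
            f"tract_lengths file {lengths_path}: shape {L.shape} does not match weights {W.shape}"
        )
    if C.shape != (n, 3):
        raise ValidationError(f"centres file {centres_path}: expected ({n}, 3), got {C.shape}")
    for name, path, M in (("weights", weights_path, W), ("tract_lengths", lengths_path, L)):
        neg = np.argwhere(M < 0)
        if neg.size:
            i, j = neg[0]
            raise ValidationError(f"{name} file {path}: entry [{i},{j}] = {M[i, j]} is negative")
    labels: list[str] = []
    if labels_path is not None:
        labels = Path(labels_path).read_text().split()
    if spiking_regions is None:
        regions = [0]
    elif isinstance(spiking_regions, (str, Path)):
        regions = [int(x) for x in Path(spiking_regions).read_text().split()]
    else:
        regions = list(spiking_regions)
    return Connectome(W, L, C, labels=labels, spiking_regions=regions)


def read_connectome_dir(directory: str | Path) -> Connectome:
    """Read the file set produced by :func:`write_connectome`."""
    d = Path(directory)
    labels = d / "labels.txt"
    spiking = d / "spiking_regions.txt"
    return read_connectome(
        d / "weights.txt",
        d / "tract_lengths.txt",
        d / "centres.txt",
        labels_path=labels if labels.exists() else None,
        spiking_regions=spiking if spiking.exists() else None,
    )


def write_sensor_layout(layout: SensorLayout, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for i in range(layout.n_sensors):
            x, y, z = layout.positions[i]
            fh.write(
                f"{x:.17g} {y:.17g} {z:.17g} {layout.labels[i]} {layout.hemispheres[i]}\n"
            )
    return path


def read_sensor_layout(path: str | Path) -> SensorLayout:
    positions, labels, hemis = [], [], []
    for ln, line in enumerate(Path(path).read_text().splitlines()):
        parts = line.split()
        if not parts:
            continue
        if len(parts) < 3:
            raise ValidationError(f"sensor file {path}: line {ln + 1} has fewer than 3 columns")
        positions.append([float(p) for p in parts[:3]])
        labels.append(parts[3] if len(parts) > 3 else f"sensor_{ln:02d}")
        hemis.append(parts[4] if len(parts) > 4 else "?")
    if not positions:
        raise ValidationError(f"sensor file {path} is empty")
    return SensorLayout(np.array(positions), labels=labels, hemispheres=hemis)
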