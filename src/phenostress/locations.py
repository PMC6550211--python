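"""Stay-location clustering and location anonymization.

Locations (planar coordinates, meters) are summarized as unique stay
locations — maximal time-contiguous runs dwelling more than 60 min within a
1-km radius of their running centroid — with everything else labeled
commuting. Anonymization applies one random rigid transform (rotation +
translation) per subject, preserving all pairwise distances.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import StayConfig

__all__ = ["StayLocation", "cluster_stay_locations", "anonymize_locations"]


@dataclass
class StayLocation:
    centroid: tuple[float, float]
    start_s: float
    end_s: float

    @property
    def dwell_s(self) -> float:
        return self.end_s - self.start_s


def cluster_stay_locations(times: np.ndarray, xy: np.ndarray,
                           config: StayConfig | None = None
                           ) -> tuple[list[StayLocation], np.ndarray]:
    """Detect stay locations; returns ``(stays, labels)``.

    ``labels[i]`` is the stay index for point i or −1 for commuting. A run
    grows while every candidate point stays within ``radius_m`` of the
    run's running centroid; it becomes a stay when its dwell exceeds
    ``min_dwell_s``.
    """
    config = config or StayConfig()
    times = np.asarray(times, dtype=float)
    xy = np.asarray(xy, dtype=float)
    n = len(times)
    labels = np.full(n, -1, dtype=int)
    stays: list[StayLocation] = []
    i = 0
    while i < n:
        centroid = xy[i].astype(float)
        j = i + 1
        while j < n:
            cand = (centroid * (j - i) + xy[j]) / (j - i + 1)
            if np.max(np.linalg.norm(xy[i : j + 1] - cand, axis=1)) > config.radius_m:
                break
            centroid = cand
            j += 1
        dwell = times[j - 1] - times[i]
        if dwell > config.min_dwell_s:
            labels[i:j] = len(stays)
            stays.append(StayLocation(centroid=(float(centroid[0]), float(centroid[1])),
                                      start_s=float(times[i]), end_s=float(times[j - 1])))
            i = j
        else:
            i += 1
    return stays, labels


def anonymize_locations(xy: np.ndarray, seed: int | np.random.Generator) -> np.ndarray:
    """One random rigid transform (rotation then translation) per call."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    xy = np.asarray(xy, dtype=float)
    theta = rng.uniform(0, 2 * np.pi)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    shift = rng.uniform(-50_000, 50_000, size=2)
    return xy @ rot.T + shift
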