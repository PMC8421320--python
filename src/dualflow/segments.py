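"""AHA 17-segment left-ventricular model and coronary territory mapping."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_SEGMENTS = 17

#: Standard assignment of AHA segments to coronary artery territories.
TERRITORY_MAP: dict[int, str] = {
    **{s: "LAD" for s in (1, 2, 7, 8, 13, 14, 17)},
    **{s: "RCA" for s in (3, 4, 9, 10, 15)},
    **{s: "LCx" for s in (5, 6, 11, 12, 16)},
}
TERRITORIES = ("LAD", "RCA", "LCx")


def territory_of(segment_id: int) -> str:
    """Coronary territory (LAD/RCA/LCx) feeding an AHA segment (1-17)."""
    try:
        return TERRITORY_MAP[int(segment_id)]
    except (KeyError, TypeError, ValueError):
        raise ValueError(f"unknown AHA segment id {segment_id!r}") from None


@dataclass(frozen=True)
class SegmentModel:
    """Segment identifiers, territory map and per-segment weights.

    Weights default to equal (1/17) and must be positive and sum to one;
    volume weighting is configurable by passing explicit weights.
    """

    weights: np.ndarray = field(
        default_factory=lambda: np.full(N_SEGMENTS, 1.0 / N_SEGMENTS))

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.shape != (N_SEGMENTS,):
            raise ValueError(f"weights must have length {N_SEGMENTS}")
        if not np.all(w > 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be positive and sum to 1")

    @property
    def segment_ids(self) -> list[int]:
        return list(range(1, N_SEGMENTS + 1))

    def territory_members(self, territory: str) -> list[int]:
        if territory not in TERRITORIES:
            raise ValueError(f"unknown territory {territory!r}")
        return [s for s in self.segment_ids if TERRITORY_MAP[s] == territory]

    def territory_weights(self, territory: str) -> np.ndarray:
        """Member weights renormalised within the territory."""
        idx = np.array(self.territory_members(territory)) - 1
        w = self.weights[idx]
        return w / w.sum()

    def global_mean(self, segment_values: np.ndarray) -> float:
        """Volume-weighted global mean of 17 segmental values."""
        v = np.asarray(segment_values, dtype=float)
        if v.shape != (N_SEGMENTS,):
            raise ValueError(f"expected {N_SEGMENTS} segmental values")
        return float(np.sum(self.weights * v))
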